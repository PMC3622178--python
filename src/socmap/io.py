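"""File adapters for the pipeline's tabular and genomic formats.

Dialects (all plain text):

* cross genotypes: CSV, rows = individuals, first column ``phenotype``,
  remaining columns = marker names (values 0/1/2, empty = missing), paired
  with a map CSV (marker, chrom, cM).
* strain SNP matrix: CSV, rows = loci (chrom, pos, id), one column per
  strain; paired labels CSV (strain, label).
* activity series: CSV with columns (time_hours, counts) plus bin size.
* BED: 3+ tab-separated columns, 0-based half-open, no header.
* narrowPeak: BED6+4; column 10 is the summit offset from ``start``
  (-1 = unknown, defaulted to the interval midpoint with a warning).
* FASTA via plain text (toy genomes only).

Parsing is fail-fast: malformed cells raise with the row/column named.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from socmap.peaks import PEAK_COLUMNS, PeakSet
from socmap.simulate import ActivitySeries, CrossPopulation, StrainGenotypeMatrix

# ---------------------------------------------------------------------------
# cross population


def write_cross(cross: CrossPopulation, genotype_path, map_path) -> None:
    geno = pd.DataFrame(
        cross.genotypes.astype(float), columns=cross.marker_map["name"]
    ).replace(-1.0, np.nan)
    geno.insert(0, "phenotype", cross.phenotypes)
    geno.to_csv(genotype_path, index=False)
    cross.marker_map.to_csv(map_path, index=False)


def read_cross(genotype_path, map_path) -> CrossPopulation:
    geno = pd.read_csv(genotype_path)
    marker_map = pd.read_csv(map_path)
    if "phenotype" not in geno.columns:
        raise ValueError("genotype CSV must have a 'phenotype' first column")
    pheno = pd.to_numeric(geno["phenotype"], errors="coerce")
    if pheno.isna().any():
        row = int(pheno.index[pheno.isna()][0])
        raise ValueError(f"non-numeric phenotype at row {row}")
    markers = marker_map["name"].tolist()
    missing_cols = [m for m in markers if m not in geno.columns]
    if missing_cols:
        raise ValueError(f"genotype CSV missing marker columns: {missing_cols}")
    g = geno[markers].apply(pd.to_numeric, errors="coerce")
    bad = g.notna() & ~g.isin([0, 1, 2])
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col][bad[col]].index[0])
        raise ValueError(f"invalid genotype at row {row}, marker {col!r}")
    return CrossPopulation(
        g.fillna(-1).to_numpy(dtype=np.int8), pheno.to_numpy(float), marker_map
    )


# ---------------------------------------------------------------------------
# strain panel


def write_strain_matrix(matrix: StrainGenotypeMatrix, matrix_path, labels_path) -> None:
    df = matrix.loci.copy()
    for i, s in enumerate(matrix.strains):
        col = matrix.alleles[i].astype(float)
        df[s] = np.where(col < 0, np.nan, col)
    df.to_csv(matrix_path, index=False)
    pd.DataFrame({"strain": matrix.strains, "label": matrix.labels}).to_csv(
        labels_path, index=False
    )


def read_strain_matrix(matrix_path, labels_path) -> StrainGenotypeMatrix:
    df = pd.read_csv(matrix_path)
    lab = pd.read_csv(labels_path)
    strains = lab["strain"].astype(str).tolist()
    alleles = (
        df[strains].apply(pd.to_numeric, errors="raise").fillna(-1).to_numpy(np.int8)
    ).T
    return StrainGenotypeMatrix(
        strains, lab["label"].to_numpy(object), alleles, df[["chrom", "pos", "id"]]
    )


# ---------------------------------------------------------------------------
# activity series


def write_activity(series: ActivitySeries, path) -> None:
    t = series.start_time + (np.arange(len(series.values)) + 0.5) * series.bin_minutes / 60
    pd.DataFrame({"time_hours": t, "counts": series.values}).to_csv(path, index=False)


def read_activity(path, bin_minutes: float | None = None) -> ActivitySeries:
    df = pd.read_csv(path)
    counts = pd.to_numeric(df["counts"], errors="coerce")
    if counts.isna().any():
        row = int(counts.index[counts.isna()][0])
        raise ValueError(f"non-numeric counts at row {row}")
    if bin_minutes is None:
        t = pd.to_numeric(df["time_hours"]).to_numpy()
        if len(t) < 2:
            raise ValueError("cannot infer bin size from a single row")
        bin_minutes = float(np.median(np.diff(t)) * 60)
    start = float(df["time_hours"].iloc[0] * 60 - bin_minutes / 2) / 60
    return ActivitySeries(counts.to_numpy(float), bin_minutes, start)


# ---------------------------------------------------------------------------
# BED / narrowPeak


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end", "name")) -> None:
    cols = [c for c in columns if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"malformed BED line {int(vals.index[vals.isna()][0]) + 1}")
        df[col] = vals.astype(int)
    return df


NARROWPEAK_NAMES = [
    "chrom", "start", "end", "name", "score_int", "strand",
    "signalValue", "pValue", "qValue", "peak_offset",
]


def write_narrowpeak(peaks: PeakSet, path) -> None:
    df = peaks.peaks
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"peak_{i + 1}" for i in range(len(df))],
            "score_int": np.clip(df["score"].round().astype(int), 0, 1000),
            "strand": ".",
            "signalValue": df["score"],
            "pValue": -1,
            "qValue": -1,
            "peak_offset": df["summit"] - df["start"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path, factor: str = "", genotype: str = "") -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_NAMES)
    offset = pd.to_numeric(df["peak_offset"], errors="coerce")
    unknown = offset.isna() | (offset < 0)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} peak(s) with unknown summit; defaulted to midpoint"
        )
    midpoint = (df["end"] - df["start"]) // 2
    summit = df["start"] + offset.where(~unknown, midpoint).astype(int)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "summit": summit.astype(int),
            "score": pd.to_numeric(df["signalValue"], errors="raise").astype(float),
        }
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(out, factor=factor, genotype=genotype)


# ---------------------------------------------------------------------------
# FASTA (toy genomes), config


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before first header")
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
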