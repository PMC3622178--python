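"""Interval-specific strain haplotype analysis.

The mapping logic: laboratory inbred strains are mosaics of a few ancestral
subspecific haplotypes, so a phenotype caused by an ancestral allele must lie
where every phenotype-positive (suppressor) strain diverges from the
reference strain while every phenotype-negative strain is identical by
descent with it. The module computes windowed per-strain divergence from the
reference, calls phenotype-concordant candidate intervals, filters candidate
quantitative trait nucleotides by perfect strain-partition concordance, and
checks subspecific-ancestry (M. domesticus vs M. musculus) concordance over
an interval.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from socmap.simulate import StrainGenotypeMatrix

DEFAULT_WINDOW_SNPS = 25
DEFAULT_TAU_HI = 0.20
DEFAULT_TAU_LO = 0.02


@dataclass
class DivergenceProfile:
    """Windowed fraction of SNPs at which each strain differs from the reference.

    ``windows`` has one row per window (chrom, start, end, n_snps); windows
    tile each chromosome's SNPs without overlap. ``divergence[i, w]`` is the
    fraction of window w's non-missing calls at which strain i differs from
    the reference (NaN when a strain has no non-missing call in the window).
    """

    windows: pd.DataFrame
    divergence: np.ndarray
    strains: list[str]
    labels: np.ndarray


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    window_indices: list[int]
    n_snps: int
    mean_divergence: dict[str, float] = field(default_factory=dict)
    genes: list[str] | None = None


def pairwise_divergence(
    matrix: StrainGenotypeMatrix,
    window: int = DEFAULT_WINDOW_SNPS,
    by: str = "snp",
) -> DivergenceProfile:
    """Windowed pairwise divergence of every strain from the reference.

    ``by='snp'`` tiles each chromosome into consecutive blocks of ``window``
    SNPs (the last block keeps the remainder); ``by='bp'`` tiles the
    position range into ``window``-bp bins. Missing calls are excluded from
    the denominator; a window where a strain has no comparable call gets
    NaN and is excluded from concordance calling downstream.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ref_idx = int(np.flatnonzero(matrix.labels == "reference")[0])
    ref = matrix.alleles[ref_idx]
    diff = (matrix.alleles != ref[None, :]) & (matrix.alleles >= 0) & (ref[None, :] >= 0)
    valid = (matrix.alleles >= 0) & (ref[None, :] >= 0)

    win_rows = []
    d_cols = []
    for chrom, g in matrix.loci.groupby("chrom", sort=False):
        idx = g.index.to_numpy()
        pos = g["pos"].to_numpy()
        if by == "snp":
            starts = np.arange(0, len(idx), window)
            blocks = [idx[s : s + window] for s in starts]
        elif by == "bp":
            edges = np.arange(pos[0], pos[-1] + window, window)
            blocks = [
                idx[(pos >= lo) & (pos < lo + window)] for lo in edges
            ]
            blocks = [b for b in blocks if len(b)]
        else:
            raise ValueError("by must be 'snp' or 'bp'")
        for b in blocks:
            nd = diff[:, b].sum(axis=1).astype(float)
            nv = valid[:, b].sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(nv > 0, nd / np.maximum(nv, 1), np.nan)
            win_rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[np.searchsorted(idx, b[0])]),
                    "end": int(pos[np.searchsorted(idx, b[-1])]) + 1,
                    "n_snps": len(b),
                }
            )
            d_cols.append(d)
    windows = pd.DataFrame(win_rows)
    divergence = np.column_stack(d_cols) if d_cols else np.empty((matrix.n_strains, 0))
    return DivergenceProfile(windows, divergence, list(matrix.strains), matrix.labels)


def concordance_scan(
    profile: DivergenceProfile,
    tau_hi: float = DEFAULT_TAU_HI,
    tau_lo: float = DEFAULT_TAU_LO,
) -> list[CandidateInterval]:
    """Call candidate intervals where divergence is phenotype-concordant.

    A window is concordant iff every suppressor strain with a defined
    divergence has d >= tau_hi AND every non-suppressor strain has
    d <= tau_lo (at least one defined strain required in each class).
    Maximal runs of consecutive concordant windows within a chromosome merge
    into intervals bounded by the outermost concordant windows.
    """
    if tau_lo >= tau_hi:
        raise ValueError("tau_lo must be < tau_hi")
    sup = profile.labels == "suppressor"
    nonsup = np.isin(profile.labels, ["non_suppressor", "reference"]) & ~sup
    nonsup &= profile.labels != "reference"  # reference vs itself is trivially 0
    if sup.sum() == 0 or nonsup.sum() == 0:
        raise ValueError("need >= 1 suppressor and >= 1 non-suppressor strain")

    d = profile.divergence
    concordant = np.zeros(len(profile.windows), dtype=bool)
    for w in range(len(profile.windows)):
        ds = d[sup, w]
        dn = d[nonsup, w]
        ds, dn = ds[~np.isnan(ds)], dn[~np.isnan(dn)]
        if len(ds) == 0 or len(dn) == 0:
            continue
        concordant[w] = bool(ds.min() >= tau_hi and dn.max() <= tau_lo)

    intervals: list[CandidateInterval] = []
    windows = profile.windows
    for chrom, g in windows.groupby("chrom", sort=False):
        idx = g.index.to_numpy()
        mask = concordant[idx]
        run: list[int] = []
        for k, w in enumerate(idx):
            if mask[k]:
                run.append(int(w))
            if run and (not mask[k] or k == len(idx) - 1):
                rows = windows.loc[run]
                mean_div = {
                    s: float(np.nanmean(d[i, run]))
                    for i, s in enumerate(profile.strains)
                }
                intervals.append(
                    CandidateInterval(
                        str(chrom),
                        int(rows["start"].min()),
                        int(rows["end"].max()),
                        list(run),
                        int(rows["n_snps"].sum()),
                        mean_div,
                    )
                )
                run = []
    return intervals


def annotate_genes(
    interval: CandidateInterval, annotation: pd.DataFrame
) -> CandidateInterval:
    """Attach genes overlapping the interval by >= 1 bp (half-open), in
    positional order. Malformed annotation rows are skipped with a logged count.
    """
    required = {"chrom", "start", "end", "name"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    ann = annotation.copy()
    numeric = ann[["start", "end"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | (numeric["start"] >= numeric["end"])
    if bad.any():
        warnings.warn(f"skipped {int(bad.sum())} malformed annotation row(s)")
        ann = ann[~bad]
    ann = ann.assign(start=numeric.loc[ann.index, "start"].astype(int),
                     end=numeric.loc[ann.index, "end"].astype(int))
    sel = (
        (ann["chrom"].astype(str) == interval.chrom)
        & (ann["start"] < interval.end)
        & (ann["end"] > interval.start)
    )
    genes = ann.loc[sel].sort_values("start")["name"].astype(str).tolist()
    return replace(interval, genes=genes)


@dataclass
class ConcordantSNP:
    index: int
    chrom: str
    pos: int
    id: str
    suppressor_allele: int


def qtn_concordance_filter(
    matrix: StrainGenotypeMatrix, strict: bool = True
) -> list[ConcordantSNP]:
    """SNPs whose alleles perfectly partition suppressor vs non-suppressor strains.

    The reference strain is counted in the non-suppressor class (it carries
    the non-suppressor allele by definition of the cross). A SNP is
    concordant iff all suppressor strains share one allele, all
    non-suppressor strains share the other, and (in strict mode) no call is
    missing. Returns an empty list with a warning when the matrix has no SNPs.
    """
    if matrix.n_snps == 0:
        warnings.warn("no SNPs in region")
        return []
    sup = matrix.labels == "suppressor"
    nonsup = ~sup  # reference + non_suppressor
    if sup.sum() == 0 or nonsup.sum() == 0:
        raise ValueError("both phenotype classes must be represented")
    out: list[ConcordantSNP] = []
    for j in range(matrix.n_snps):
        col = matrix.alleles[:, j]
        if strict and np.any(col < 0):
            continue
        a_sup = np.unique(col[sup & (col >= 0)])
        a_non = np.unique(col[nonsup & (col >= 0)])
        if len(a_sup) != 1 or len(a_non) != 1 or a_sup[0] == a_non[0]:
            continue
        row = matrix.loci.iloc[j]
        out.append(
            ConcordantSNP(j, str(row["chrom"]), int(row["pos"]), str(row["id"]),
                          int(a_sup[0]))
        )
    return out


@dataclass
class AncestryCheckResult:
    per_strain: pd.DataFrame  # strain, label, subspecies, coverage, partial
    verdict: bool
    excluded: list[str]


def ancestry_check(
    interval: CandidateInterval,
    ancestry: pd.DataFrame,
    labels: dict[str, str],
) -> AncestryCheckResult:
    """Check subspecific-origin concordance of an interval across strains.

    ``ancestry`` rows are (strain, chrom, start, end, subspecies) with
    subspecies in {"Dom", "Mus"} and non-overlapping segments per strain.
    Each strain's interval assignment is the subspecies covering the
    majority of the interval by bp (flagged ``partial`` when segments do not
    fully cover it). The verdict is True iff every suppressor strain maps to
    Dom and every non-suppressor strain (including the reference) to Mus.
    Strains labeled but absent from the table are excluded with a warning.
    """
    rows = []
    excluded = []
    span = interval.end - interval.start
    for strain, label in labels.items():
        seg = ancestry[
            (ancestry["strain"] == strain)
            & (ancestry["chrom"].astype(str) == interval.chrom)
        ]
        if seg.empty:
            excluded.append(strain)
            continue
        bp = {}
        for r in seg.itertuples(index=False):
            ov = min(r.end, interval.end) - max(r.start, interval.start)
            if ov > 0:
                bp[r.subspecies] = bp.get(r.subspecies, 0) + ov
        covered = sum(bp.values())
        if covered == 0:
            excluded.append(strain)
            continue
        subspecies = max(bp, key=bp.get)
        rows.append(
            {
                "strain": strain,
                "label": label,
                "subspecies": subspecies,
                "coverage": covered / span,
                "partial": covered < span,
            }
        )
    if excluded:
        warnings.warn(f"strains absent from ancestry table: {excluded}")
    per_strain = pd.DataFrame(rows)
    verdict = bool(len(per_strain)) and all(
        (r["subspecies"] == "Dom") == (r["label"] == "suppressor")
        for _, r in per_strain.iterrows()
    )
    return AncestryCheckResult(per_strain, verdict, excluded)
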