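"""Pipeline orchestration: run selected stages in dependency order from a
single config, with per-stage seed derivation and a reproducibility manifest.

Each stochastic stage derives its own random stream from the global seed
salted with the stage name (CRC32), so adding or removing a stage never
shifts another stage's stream. The manifest records the config hash, every
non-default scientific parameter, and a SHA-256 checksum of each output
file; deterministic stages reproduce identical checksums under identical
config + inputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from socmap import anova, ase, binding, haplotype, io, peaks, periodogram, qtl, simulate

STAGE_ORDER = [
    "simulate",
    "phenotype",
    "qtlscan",
    "hapscan",
    "qtn",
    "ase",
    "binding",
    "peaks",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-name-salted seed (stable across runs and platforms)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "started": self.started,
                    "finished": self.finished,
                    "failed_stage": self.failed_stage,
                },
                fh,
                indent=2,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in paths}


def validate_config(config: dict) -> list[str]:
    """Exhaustive schema check; returns a list of violations (empty = valid)."""
    problems = []
    stages = config.get("stages", STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        problems.append(f"unknown stages: {unknown}")
    if "seed" in config and not isinstance(config["seed"], int):
        problems.append("seed must be an integer")
    for key in ("out_dir",):
        if key in config and not isinstance(config[key], str):
            problems.append(f"{key} must be a string path")
    params = config.get("params", {})
    if not isinstance(params, dict):
        problems.append("params must be a mapping of stage -> parameter block")
    else:
        for stage, block in params.items():
            if stage not in STAGE_ORDER:
                problems.append(f"params for unknown stage {stage!r}")
            elif not isinstance(block, dict):
                problems.append(f"params.{stage} must be a mapping")
    for inp in config.get("inputs", {}).values():
        if not Path(inp).exists():
            problems.append(f"missing input: {inp}")
    return problems


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Execute the selected stages in dependency order.

    ``config`` is a mapping (or path to a YAML file) with keys ``seed``,
    ``out_dir``, ``stages`` (subset of the canonical order) and ``params``
    (per-stage overrides). Outputs of each stage are written before its
    dependents start; a stage failure aborts downstream stages and the
    partial manifest records the failure.
    """
    if not isinstance(config, dict):
        config = io.read_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n- " + "\n- ".join(problems))

    seed = int(config.get("seed", 0))
    out_dir = io.ensure_dir(config.get("out_dir", "socmap_run"))
    stages = [s for s in STAGE_ORDER if s in config.get("stages", STAGE_ORDER)]
    params = config.get("params", {})
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    manifest = RunManifest(
        seed, cfg_hash, started=datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in stages:
            runner = _STAGE_RUNNERS[stage]
            block = dict(params.get(stage, {}))
            try:
                outputs, info = runner(out_dir, stage_seed(seed, stage), block)
            except Exception as exc:  # abort downstream stages
                manifest.failed_stage = stage
                manifest.stages[stage] = {"error": str(exc)}
                break
            manifest.stages[stage] = {
                "params": block,
                "seed": stage_seed(seed, stage),
                "outputs": _checksums(outputs),
                **info,
            }
    manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest.to_json(out_dir / "manifest.json")
    if manifest.failed_stage is not None:
        raise RuntimeError(
            f"stage {manifest.failed_stage!r} failed: "
            f"{manifest.stages[manifest.failed_stage]['error']}"
        )
    return manifest


# ---------------------------------------------------------------------------
# stage runners: (out_dir, seed, params) -> (output paths, extra manifest info)


def _stage_simulate(out_dir: Path, seed: int, p: dict):
    n = p.get("n_f2", 222)
    n_markers = p.get("n_markers", 40)
    qtl_marker = p.get("qtl_marker", 15)
    effects = simulate.EffectModel(**p.get("effects", {}))
    cross = simulate.simulate_f2_cross(
        n, {"1": np.linspace(0, 100, n_markers)}, qtl_marker, effects, seed
    )
    io.write_cross(cross, out_dir / "cross_genotypes.csv", out_dir / "cross_map.csv")

    positions = np.arange(160_000_000, 190_000_000, p.get("snp_spacing", 15_000))
    panel = simulate.simulate_strain_panel(
        p.get("n_sup", 8),
        p.get("n_nonsup", 7),
        positions,
        tuple(p.get("causal_interval", (173_300_000, 174_200_000))),
        p.get("div_rate_in", 0.8),
        p.get("div_rate_out", 0.02),
        seed + 1,
    )
    io.write_strain_matrix(
        panel, out_dir / "strain_matrix.csv", out_dir / "strain_labels.csv"
    )

    series = simulate.simulate_activity(
        p.get("period", 24.0), p.get("n_days", 7), p.get("bin_minutes", 6),
        p.get("amplitude", 50.0), p.get("noise_sd", 10.0), seed + 2,
    )
    io.write_activity(series, out_dir / "activity.csv")

    bs = simulate.simulate_binding_series(
        p.get("bmax", 1.0), p.get("kd", 5.0),
        p.get("concentrations", [0.5, 1, 2, 5, 10, 20, 50]),
        p.get("noise_cv", 0.05), p.get("replicates", 3), seed + 3,
    )
    pd.DataFrame(
        {
            "concentration_nM": np.repeat(bs.concentrations, bs.signals.shape[1]),
            "replicate": np.tile(
                np.arange(1, bs.signals.shape[1] + 1), len(bs.concentrations)
            ),
            "signal": bs.signals.ravel(),
        }
    ).to_csv(out_dir / "binding.csv", index=False)

    pk_a, pk_b = simulate.simulate_peak_sets(
        {"chr1": p.get("chrom_size", 30_000_000)},
        p.get("n_shared", 300), p.get("n_only_a", 200), p.get("n_only_b", 150),
        p.get("summit_jitter_sd", 40.0), seed=seed + 4,
    )
    io.write_narrowpeak(pk_a, out_dir / "peaks_a.narrowPeak")
    io.write_narrowpeak(pk_b, out_dir / "peaks_b.narrowPeak")

    ased = simulate.simulate_ase_data(p.get("true_fraction", 0.8), seed=seed + 5)
    ased.standard_curve.to_csv(out_dir / "ase_standard_curve.csv", index=False)
    pd.DataFrame({"delta_ct": ased.cdna_delta_ct}).to_csv(
        out_dir / "ase_cdna.csv", index=False
    )
    io.write_config(
        {
            "n_alt_colonies": ased.n_alt_colonies,
            "n_total_colonies": ased.n_total_colonies,
            "peak_alt": float(ased.peak_alt),
            "peak_ref": float(ased.peak_ref),
            "cal_alt": float(ased.cal_alt),
            "cal_ref": float(ased.cal_ref),
        },
        out_dir / "ase_other.yaml",
    )
    outputs = [
        out_dir / f
        for f in [
            "cross_genotypes.csv", "cross_map.csv", "strain_matrix.csv",
            "strain_labels.csv", "activity.csv", "binding.csv",
            "peaks_a.narrowPeak", "peaks_b.narrowPeak",
            "ase_standard_curve.csv", "ase_cdna.csv", "ase_other.yaml",
        ]
    ]
    return outputs, {"qtl_marker": qtl_marker}


def _stage_phenotype(out_dir: Path, seed: int, p: dict):
    series = io.read_activity(out_dir / "activity.csv")
    res = periodogram.chi_square_periodogram(
        series,
        tuple(p.get("period_range", (20.0, 28.0))),
        p.get("alpha", 0.001),
    )
    pd.DataFrame(
        {
            "trial_period_h": res.trial_periods,
            "qp": res.qp,
            "significance_line": res.significance_line,
        }
    ).to_csv(out_dir / "periodogram.csv", index=False)
    summary = {
        "peak_period_h": res.peak_period,
        "amplitude": res.amplitude,
        "mean_daily_activity": res.mean_daily_activity,
        "arrhythmic": res.arrhythmic,
        "alpha": res.alpha,
    }
    with open(out_dir / "periodogram_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return [out_dir / "periodogram.csv", out_dir / "periodogram_summary.json"], summary


def _stage_qtlscan(out_dir: Path, seed: int, p: dict):
    cross = io.read_cross(out_dir / "cross_genotypes.csv", out_dir / "cross_map.csv")
    thr = qtl.permutation_thresholds(
        cross, p.get("n_perm", 1000), tuple(p.get("alphas", (0.63, 0.05, 0.001))), seed
    )
    scan = qtl.genome_scan(cross, thr)
    scan.table.to_csv(out_dir / "qtl_scan.csv", index=False)
    with open(out_dir / "qtl_thresholds.json", "w") as fh:
        json.dump(
            {"n_perm": thr.n_perm,
             "thresholds": {str(a): t for a, t in thr.thresholds.items()},
             "peak_marker": scan.peak_marker,
             "max_lrs": scan.max_lrs()},
            fh, indent=2,
        )
    info = {"peak_marker": scan.peak_marker, "max_lrs": scan.max_lrs()}
    return [out_dir / "qtl_scan.csv", out_dir / "qtl_thresholds.json"], info


def _stage_hapscan(out_dir: Path, seed: int, p: dict):
    matrix = io.read_strain_matrix(
        out_dir / "strain_matrix.csv", out_dir / "strain_labels.csv"
    )
    profile = haplotype.pairwise_divergence(matrix, p.get("window", 25))
    intervals = haplotype.concordance_scan(
        profile, p.get("tau_hi", 0.20), p.get("tau_lo", 0.02)
    )
    div = pd.concat(
        [profile.windows,
         pd.DataFrame(profile.divergence.T, columns=profile.strains)], axis=1
    )
    div.to_csv(out_dir / "divergence_windows.csv", index=False)
    io.write_bed(
        pd.DataFrame(
            [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "name": f"interval_{k + 1}"}
                for k, iv in enumerate(intervals)
            ],
            columns=["chrom", "start", "end", "name"],
        ),
        out_dir / "candidate_intervals.bed",
    )
    info = {"n_intervals": len(intervals)}
    if intervals:
        top = max(intervals, key=lambda iv: iv.n_snps)
        info.update({"top_interval": [top.chrom, top.start, top.end]})
    return [out_dir / "divergence_windows.csv", out_dir / "candidate_intervals.bed"], info


def _stage_qtn(out_dir: Path, seed: int, p: dict):
    matrix = io.read_strain_matrix(
        out_dir / "strain_matrix.csv", out_dir / "strain_labels.csv"
    )
    region = p.get("region")
    if region:
        lo, hi = region
        sel = (matrix.loci["pos"] >= lo) & (matrix.loci["pos"] < hi)
        matrix = simulate.StrainGenotypeMatrix(
            matrix.strains, matrix.labels,
            matrix.alleles[:, sel.to_numpy()],
            matrix.loci[sel].reset_index(drop=True),
        )
    snps = haplotype.qtn_concordance_filter(matrix, p.get("strict", True))
    pd.DataFrame(
        [{"chrom": s.chrom, "pos": s.pos, "id": s.id,
          "suppressor_allele": s.suppressor_allele} for s in snps],
        columns=["chrom", "pos", "id", "suppressor_allele"],
    ).to_csv(out_dir / "concordant_snps.csv", index=False)
    return [out_dir / "concordant_snps.csv"], {"n_concordant": len(snps)}


def _stage_ase(out_dir: Path, seed: int, p: dict):
    curve_df = pd.read_csv(out_dir / "ase_standard_curve.csv")
    curve = ase.fit_standard_curve(curve_df["fraction"], curve_df["delta_ct"])
    cdna = pd.read_csv(out_dir / "ase_cdna.csv")["delta_ct"]
    other = io.read_config(out_dir / "ase_other.yaml")
    qpcr = ase.estimate_fraction_qpcr(curve, float(cdna.mean()))
    colonies = ase.estimate_fraction_colonies(
        other["n_alt_colonies"], other["n_total_colonies"]
    )
    chrom = ase.estimate_fraction_chromatogram(
        other["peak_alt"], other["peak_ref"], other["cal_alt"] / other["cal_ref"]
    )
    rows = pd.DataFrame(
        [
            {"method": e.method, "fraction": e.fraction,
             "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value}
            for e in (qpcr, colonies, chrom)
        ]
    )
    rows.to_csv(out_dir / "ase_estimates.csv", index=False)
    info = {
        "curve_slope": curve.slope,
        "curve_r2": curve.r_squared,
        "fractions": {e.method: e.fraction for e in (qpcr, colonies, chrom)},
    }
    return [out_dir / "ase_estimates.csv"], info


def _stage_binding(out_dir: Path, seed: int, p: dict):
    df = pd.read_csv(out_dir / "binding.csv")
    wide = df.pivot(index="concentration_nM", columns="replicate", values="signal")
    series = simulate.BindingSeries(
        wide.index.to_numpy(float), wide.to_numpy(float)
    )
    fit = binding.fit_saturation(series, p.get("model", "hyperbola"))
    pd.DataFrame(
        [{"bmax": fit.bmax, "bmax_se": fit.bmax_se, "kd_nM": fit.kd,
          "kd_se": fit.kd_se, "model": fit.model, "rss": fit.rss,
          "converged": fit.converged}]
    ).to_csv(out_dir / "binding_fit.csv", index=False)
    return [out_dir / "binding_fit.csv"], {"kd_nM": fit.kd, "bmax": fit.bmax}


def _stage_peaks(out_dir: Path, seed: int, p: dict):
    a = io.read_narrowpeak(out_dir / "peaks_a.narrowPeak", factor="USF1")
    b = io.read_narrowpeak(out_dir / "peaks_b.narrowPeak", factor="CLOCK")
    halfwidth = p.get("halfwidth", 120)
    n_overlap = int(peaks.overlapping_mask(a, b, halfwidth).sum())
    report = {
        "n_a": len(a),
        "n_b": len(b),
        "n_a_overlapping_b": n_overlap,
        "halfwidth": halfwidth,
    }
    with open(out_dir / "peak_overlap.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return [out_dir / "peak_overlap.json"], report


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "phenotype": _stage_phenotype,
    "qtlscan": _stage_qtlscan,
    "hapscan": _stage_hapscan,
    "qtn": _stage_qtn,
    "ase": _stage_ase,
    "binding": _stage_binding,
    "peaks": _stage_peaks,
}
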