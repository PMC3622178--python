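"""Candidate prioritization by tissue co-expression and allele-specific
expression (ASE) estimation by three independent assays.

The three ASE estimators measure the fraction of transcripts carrying the
alternate (BALB) allele in F1 hybrid cDNA, where genomic DNA is an exact
50:50 internal control and any departure in cDNA indicates a cis-regulatory
expression difference:

1. qPCR: allele-specific primers give a cycle-threshold difference
   ΔCt = Ct(reference assay) - Ct(alternate assay). With PCR efficiency 2,
   ΔCt = log2(f / (1 - f)), so logit(f) is linear in ΔCt; the slope is
   calibrated on genomic mixtures of known fractions (a standard curve).
2. Colony counting: cloned amplicons are typed by a restriction-site
   polymorphism; allele counts are binomial.
3. Chromatogram peak ratio: fluorescent base-call peak heights at the
   diagnostic SNP, calibrated against a 1:1 genomic mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit


@dataclass
class StandardCurve:
    """Least-squares line of logit(fraction) on ΔCt.

    On ideal-efficiency data the slope is ln(2) and the intercept 0.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("standard curve slope must be finite and nonzero")

    def predict_logit(self, delta_ct: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(delta_ct, dtype=float) + self.intercept

    def delta_ct_at(self, fraction: float) -> float:
        """Inverse: the ΔCt predicted for a given allele fraction."""
        return (logit(fraction) - self.intercept) / self.slope


@dataclass
class AlleleFractionEstimate:
    fraction: float
    ci_low: float
    ci_high: float
    method: str  # "qpcr" | "colony" | "chromatogram"
    n: int | None = None
    p_value: float | None = None  # exact test vs 0.5, colony method only


def prioritize_by_coexpression(
    expression: pd.DataFrame,
    gene_class: pd.Series,
    min_similarity: float = 0.6,
) -> pd.DataFrame:
    """Select candidate genes whose tissue profile tracks the clock genes.

    ``expression`` is genes x tissues (copy numbers); ``gene_class`` maps
    gene -> {"candidate", "clock_reference"}. Each gene is z-scored across
    tissues, the clock centroid is the mean z-profile of the reference clock
    genes, and a candidate is selected iff its Pearson correlation with the
    centroid is >= ``min_similarity``. Returns a frame with per-gene
    similarity scores and the selection flag (all genes scored).
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    values = expression.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    usable = sd > 0
    if (~usable).any():
        warnings.warn(
            f"excluded {int((~usable).sum())} zero-variance gene(s) from scoring"
        )
    z = np.full_like(values, np.nan)
    z[usable] = (values[usable] - values[usable].mean(axis=1, keepdims=True)) / sd[
        usable, None
    ]

    classes = gene_class.reindex(expression.index)
    clock = (classes == "clock_reference").to_numpy() & usable
    if clock.sum() < 2:
        raise ValueError("need >= 2 usable clock reference genes")
    centroid = z[clock].mean(axis=0)
    c_sd = centroid.std(ddof=0)
    if c_sd == 0:
        raise ValueError("clock centroid has zero variance")
    cc = (centroid - centroid.mean()) / c_sd

    similarity = np.full(len(expression), np.nan)
    similarity[usable] = (z[usable] * cc[None, :]).mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_class": classes.to_numpy(),
            "similarity": similarity,
            "selected": (classes == "candidate").to_numpy()
            & usable
            & (similarity >= min_similarity),
        },
        index=expression.index,
    )
    return out


def fit_standard_curve(mix_fractions, delta_ct) -> StandardCurve:
    """Fit the allele-fraction standard curve from genomic-DNA mixtures."""
    f = np.asarray(mix_fractions, dtype=float)
    d = np.asarray(delta_ct, dtype=float)
    if len(f) != len(d):
        raise ValueError("mix_fractions and delta_ct lengths differ")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("mixture fractions must be strictly inside (0, 1)")
    if len(np.unique(d)) < 2:
        raise ValueError("need >= 2 distinct ΔCt values")
    y = logit(f)
    res = stats.linregress(d, y)
    pred = res.slope * d + res.intercept
    dof = max(len(f) - 2, 1)
    resid_sd = float(np.sqrt(((y - pred) ** 2).sum() / dof))
    return StandardCurve(
        float(res.slope), float(res.intercept), float(res.rvalue**2), resid_sd, len(f)
    )


def estimate_fraction_qpcr(
    curve: StandardCurve, delta_ct: float, z: float = 1.96
) -> AlleleFractionEstimate:
    """Invert the standard curve at an observed cDNA ΔCt.

    The CI propagates the curve's residual SD on the logit scale (delta
    method: logit +/- z * residual_sd, then inverse-logit).
    """
    lg = float(curve.predict_logit(delta_ct))
    return AlleleFractionEstimate(
        float(expit(lg)),
        float(expit(lg - z * curve.residual_sd)),
        float(expit(lg + z * curve.residual_sd)),
        "qpcr",
    )


def estimate_fraction_colonies(n_alt: int, n_total: int) -> AlleleFractionEstimate:
    """Binomial allele-fraction estimate from typed colony counts.

    Clopper-Pearson 95% CI and a two-sided exact binomial test against the
    50:50 expectation of genomic DNA.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_alt <= n_total:
        raise ValueError("need 0 <= n_alt <= n_total")
    test = stats.binomtest(n_alt, n_total, p=0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return AlleleFractionEstimate(
        n_alt / n_total,
        float(ci.low),
        float(ci.high),
        "colony",
        n=n_total,
        p_value=float(test.pvalue),
    )


def estimate_fraction_chromatogram(
    peak_alt: float,
    peak_ref: float,
    calibration: float = 1.0,
) -> AlleleFractionEstimate:
    """Allele fraction from fluorescent peak heights at the diagnostic SNP.

    ``calibration`` is the alt/ref height ratio measured on a 1:1 genomic
    mixture (correcting dye/incorporation bias): the corrected ratio is
    r = (peak_alt / peak_ref) / calibration and fraction = r / (1 + r).
    No replication structure, so no CI is reported (bounds set to the point
    estimate).
    """
    if peak_alt <= 0 or peak_ref <= 0:
        raise ValueError("peak heights must be > 0")
    if calibration <= 0:
        raise ValueError("calibration ratio must be > 0")
    r = (peak_alt / peak_ref) / calibration
    f = r / (1.0 + r)
    return AlleleFractionEstimate(float(f), float(f), float(f), "chromatogram")
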