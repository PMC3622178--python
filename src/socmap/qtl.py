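"""Single-marker genome scan for an F2 intercross with empirical
genome-wide significance thresholds from phenotype permutation.

At each typed marker the phenotype is regressed on the genotype class as an
unordered factor (the "free" genetic model, up to 3 classes in an F2):
F = MS_between / MS_within, and the likelihood-ratio statistic
LRS = n * ln(RSS_null / RSS_genotype). Missing genotypes are dropped
marker-wise. Genome-wide thresholds come from permuting phenotypes against
genotype rows and recording the maximum LRS per permutation; the threshold
at level alpha is the empirical (1 - alpha) quantile of that distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from socmap.simulate import CrossPopulation

INF_SENTINEL = np.inf


@dataclass
class MarkerTestResult:
    f: float
    lrs: float
    df: tuple[int, int]
    n_used: int
    degenerate: bool = False  # RSS within genotype classes exactly 0
    skipped: bool = False


@dataclass
class PermutationThresholds:
    n_perm: int
    thresholds: dict[float, float]  # alpha -> genome-wide LRS threshold
    max_distribution: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        alphas = sorted(self.thresholds)
        values = [self.thresholds[a] for a in alphas]
        if any(values[i] < values[i + 1] for i in range(len(values) - 1)):
            raise ValueError("thresholds must be non-increasing in alpha")

    def __getitem__(self, alpha: float) -> float:
        return self.thresholds[alpha]


@dataclass
class ScanResult:
    table: pd.DataFrame  # per marker: chrom, name, cM, f, lrs, df1, df2, n_used, flags
    thresholds: PermutationThresholds | None = None

    @property
    def peak_marker(self) -> int:
        ok = ~self.table["skipped"]
        return int(self.table.index[ok][self.table.loc[ok, "lrs"].argmax()])

    def max_lrs(self) -> float:
        return float(self.table.loc[~self.table["skipped"], "lrs"].max())


def _anova_stats(genos: np.ndarray, pheno: np.ndarray) -> MarkerTestResult:
    n = len(pheno)
    classes = np.unique(genos)
    k = len(classes)
    grand = pheno.mean()
    ss_total = ((pheno - grand) ** 2).sum()
    ss_between = 0.0
    for c in classes:
        sel = genos == c
        ss_between += sel.sum() * (pheno[sel].mean() - grand) ** 2
    rss = ss_total - ss_between
    df1, df2 = k - 1, n - k
    if ss_total == 0:
        return MarkerTestResult(0.0, 0.0, (df1, df2), n)
    if rss <= max(1e-12 * ss_total, 0.0):
        return MarkerTestResult(INF_SENTINEL, INF_SENTINEL, (df1, df2), n, degenerate=True)
    f = (ss_between / df1) / (rss / df2) if df2 > 0 else INF_SENTINEL
    lrs = n * np.log(ss_total / rss)
    return MarkerTestResult(float(f), float(lrs), (df1, df2), n)


def marker_regression(cross: CrossPopulation, marker: int) -> MarkerTestResult:
    """One-way ANOVA of phenotype on genotype class at one marker.

    Individuals with a missing genotype at the marker are dropped. Markers
    with fewer than two observed genotype classes are skipped with a warning;
    an exact genotype-phenotype determination yields an infinite statistic
    flagged ``degenerate``.
    """
    genos = cross.genotypes[:, marker]
    mask = genos >= 0
    genos, pheno = genos[mask], cross.phenotypes[mask]
    if len(np.unique(genos)) < 2:
        warnings.warn(f"marker {marker}: fewer than 2 genotype classes; skipped")
        return MarkerTestResult(np.nan, np.nan, (0, 0), int(mask.sum()), skipped=True)
    return _anova_stats(genos, pheno)


def genome_scan(
    cross: CrossPopulation, thresholds: PermutationThresholds | None = None
) -> ScanResult:
    """Apply marker regression at every marker, in map order."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(cross.n_markers):
            r = marker_regression(cross, j)
            rows.append(
                {
                    "f": r.f,
                    "lrs": r.lrs,
                    "df1": r.df[0],
                    "df2": r.df[1],
                    "n_used": r.n_used,
                    "degenerate": r.degenerate,
                    "skipped": r.skipped,
                }
            )
    table = pd.concat([cross.marker_map.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return ScanResult(table, thresholds)


def _max_lrs_matrix(genotypes: np.ndarray, pheno_matrix: np.ndarray) -> np.ndarray:
    """Genome-wide max LRS for each phenotype column (vectorized scan).

    ``pheno_matrix`` has shape (n_individuals, n_scans). Missing genotypes
    are dropped marker-wise, matching ``marker_regression``.
    """
    n_scans = pheno_matrix.shape[1]
    # center columns up front: avoids catastrophic cancellation in the
    # sums-of-squares shortcut when phenotypes are (near-)constant
    pheno_matrix = pheno_matrix - pheno_matrix.mean(axis=0, keepdims=True)
    scale = (pheno_matrix**2).sum(axis=0).max()
    max_lrs = np.zeros(n_scans)
    for j in range(genotypes.shape[1]):
        genos = genotypes[:, j]
        mask = genos >= 0
        g = genos[mask]
        classes = np.unique(g)
        if len(classes) < 2:
            continue
        y = pheno_matrix[mask, :]
        n = y.shape[0]
        tot = y.sum(axis=0)
        ss_total = (y**2).sum(axis=0) - tot**2 / n
        ss_between = np.zeros(n_scans)
        for c in classes:
            sel = g == c
            ss_between += y[sel, :].sum(axis=0) ** 2 / sel.sum()
        ss_between -= tot**2 / n
        rss = np.maximum(ss_total - ss_between, 0.0)
        tiny = 1e-12 * max(scale, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            lrs = np.where(
                ss_total <= tiny,
                0.0,
                np.where(rss <= tiny, np.inf,
                         n * np.log(ss_total / np.maximum(rss, 1e-300))),
            )
        max_lrs = np.maximum(max_lrs, lrs)
    return max_lrs


def permutation_thresholds(
    cross: CrossPopulation,
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.63, 0.05, 0.001),
    seed: int = 0,
) -> PermutationThresholds:
    """Empirical genome-wide LRS thresholds by phenotype permutation.

    The default levels follow the suggestive / significant / highly
    significant convention (alpha 0.63, 0.05, 0.001).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if any(not 0 < a < 1 for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perms = np.column_stack(
        [rng.permutation(cross.phenotypes) for _ in range(n_perm)]
    )
    maxima = _max_lrs_matrix(cross.genotypes, perms)
    thresholds = {
        float(a): float(np.quantile(maxima, 1.0 - a)) for a in alphas
    }
    return PermutationThresholds(n_perm, thresholds, maxima)
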