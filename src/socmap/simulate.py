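"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and an integer seed:
identical calls return bit-identical outputs. Defaults encode the effect
structure of the study system — a Clock mutation that lengthens free-running
period by ~0.6 h in heterozygotes on the reference background, suppressed
semidominantly (to ~0.3 h at one suppressor-allele dose, fully at two) by a
BALB-derived allele at a single autosomal locus; a strain panel in which
suppressor strains share an ancestral divergent haplotype over the causal
interval while non-suppressor strains are identical by descent with the
reference there; an 80:20 allelic expression bias driven by a cis-regulatory
promoter variant; and hyperbolic one-site saturation binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from socmap.peaks import PEAK_COLUMNS, PeakSet

# ---------------------------------------------------------------------------
# effect model and containers


@dataclass(frozen=True)
class EffectModel:
    """Phenotype model for Clock-mutant heterozygotes in an F2 cross.

    Parameters (hours unless noted):

    base_period
        Free-running period of a wild-type animal on the reference (B6)
        background; 23.7 h is typical for this strain.
    clock_het_effect
        Period lengthening caused by one mutant Clock allele on a
        non-suppressor background (~0.6 h).
    clock_hom_effect
        Lengthening in mutant homozygotes (~4 h); kept for completeness, the
        mapping cross phenotypes heterozygotes only.
    soc_suppression
        Fractional suppression of the mutant effect per suppressor-allele
        dose, applied semidominantly: the expressed effect is
        ``clock_het_effect * (1 - soc_suppression * dose / 2)`` for dose in
        {0, 1, 2}. 1.0 means complete suppression in suppressor homozygotes.
    residual_sd
        SD of Gaussian residual period variation between animals.
    """

    base_period: float = 23.7
    clock_het_effect: float = 0.6
    clock_hom_effect: float = 4.0
    soc_suppression: float = 1.0
    residual_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.base_period <= 0:
            raise ValueError("base_period must be > 0")
        if not 0.0 <= self.soc_suppression <= 1.0:
            raise ValueError("soc_suppression must be in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def genotype_mean(self, dose: np.ndarray | int) -> np.ndarray:
        dose = np.asarray(dose)
        effect = self.clock_het_effect * (1.0 - self.soc_suppression * dose / 2.0)
        return self.base_period + effect


@dataclass
class CrossPopulation:
    """An F2 intercross: marker genotypes plus a quantitative phenotype.

    ``genotypes[i, j]`` counts suppressor-strain (BALB) alleles at marker j
    in individual i (0, 1, 2; -1 = missing). ``marker_map`` has one row per
    marker with columns chrom, name, cM (and optionally bp), in map order.
    All phenotyped individuals are Clock-mutant heterozygotes.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x markers)")
        if len(self.phenotypes) != self.genotypes.shape[0]:
            raise ValueError("phenotype length must match genotype rows")
        if self.genotypes.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length must match genotype columns")
        if not np.all(np.isfinite(self.phenotypes)):
            raise ValueError("phenotypes must be finite")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class StrainGenotypeMatrix:
    """Strains x SNP biallelic matrix with phenotype labels.

    ``alleles[i, j]`` is 0 (reference allele), 1 (alternate) or -1 (missing).
    ``labels[i]`` is one of {"reference", "suppressor", "non_suppressor"};
    exactly one strain is the reference. ``loci`` has columns chrom, pos, id
    with positions strictly increasing within each chromosome.
    """

    strains: list[str]
    labels: np.ndarray
    alleles: np.ndarray
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.alleles.shape != (len(self.strains), len(self.loci)):
            raise ValueError("alleles must be strains x loci")
        if (self.labels == "reference").sum() != 1:
            raise ValueError("exactly one reference strain required")
        for _, g in self.loci.groupby("chrom"):
            if not np.all(np.diff(g["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_snps(self) -> int:
        return len(self.loci)


@dataclass
class ActivitySeries:
    """Equally binned activity (or bioluminescence) counts."""

    values: np.ndarray
    bin_minutes: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be > 0")

    @property
    def duration_hours(self) -> float:
        return len(self.values) * self.bin_minutes / 60.0


@dataclass
class BindingSeries:
    """Saturation-binding series: bound signal vs probe concentration.

    ``signals`` has shape (n_concentrations, n_replicates).
    """

    concentrations: np.ndarray
    signals: np.ndarray
    complex_label: str = ""
    genotype_label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if self.signals.shape[0] != len(self.concentrations):
            raise ValueError("signals rows must match concentrations")
        if np.any(self.signals < 0):
            raise ValueError("signals must be >= 0")


@dataclass
class AseSimData:
    """Synthetic allele-specific expression data for the three estimators."""

    standard_curve: pd.DataFrame  # columns: fraction, delta_ct
    cdna_delta_ct: np.ndarray
    n_alt_colonies: int
    n_total_colonies: int
    peak_alt: float
    peak_ref: float
    cal_alt: float
    cal_ref: float
    true_fraction: float


# ---------------------------------------------------------------------------
# generators


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray:
    """Recombination fraction from map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _simulate_gametes(
    rng: np.random.Generator, n: int, positions_by_chrom: dict[str, np.ndarray]
) -> np.ndarray:
    """One meiosis per individual: a 0/1 haplotype over all markers."""
    chunks = []
    for positions in positions_by_chrom.values():
        m = len(positions)
        hap = np.empty((n, m), dtype=np.int8)
        hap[:, 0] = rng.integers(0, 2, size=n)
        if m > 1:
            r = haldane_r(np.diff(positions))
            switch = rng.random((n, m - 1)) < r
            hap[:, 1:] = np.cumsum(switch, axis=1) % 2
            hap[:, 1:] ^= hap[:, [0]]
        chunks.append(hap)
    return np.concatenate(chunks, axis=1)


def simulate_f2_cross(
    n: int,
    marker_positions: Mapping[str, Sequence[float]],
    qtl_marker: int,
    effects: EffectModel = EffectModel(),
    seed: int = 0,
) -> CrossPopulation:
    """Simulate an F2 intercross of Clock-mutant heterozygotes.

    Each individual receives two independent gametes simulated as Markov
    chains along each chromosome with inter-marker recombination fractions
    from the Haldane map function. The phenotype is the genotype-class mean
    from ``effects`` at ``qtl_marker`` (a global index into the concatenated
    marker list) plus Gaussian residual noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positions_by_chrom = {}
    for chrom, pos in marker_positions.items():
        pos = np.asarray(pos, dtype=float)
        if len(pos) == 0:
            raise ValueError(f"chromosome {chrom!r} has no markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions must be strictly increasing on {chrom!r}")
        positions_by_chrom[str(chrom)] = pos
    total_markers = sum(len(p) for p in positions_by_chrom.values())
    if not 0 <= qtl_marker < total_markers:
        raise ValueError("qtl_marker out of range")

    rng = np.random.default_rng(seed)
    genotypes = _simulate_gametes(rng, n, positions_by_chrom) + _simulate_gametes(
        rng, n, positions_by_chrom
    )
    dose = genotypes[:, qtl_marker]
    phenotypes = effects.genotype_mean(dose) + rng.normal(0.0, effects.residual_sd, n)

    rows = []
    for chrom, pos in positions_by_chrom.items():
        for k, p in enumerate(pos):
            rows.append((chrom, f"{chrom}_{k + 1}", float(p)))
    marker_map = pd.DataFrame(rows, columns=["chrom", "name", "cM"])
    return CrossPopulation(genotypes, phenotypes, marker_map)


def simulate_strain_panel(
    n_sup: int,
    n_nonsup: int,
    snp_positions: Sequence[int],
    causal_interval: tuple[int, int],
    div_rate_in: float,
    div_rate_out: float,
    seed: int = 0,
    chrom: str = "1",
) -> StrainGenotypeMatrix:
    """Simulate a strain panel with an implanted ancestral divergent segment.

    The reference strain carries the reference allele everywhere. All
    suppressor strains share one divergent haplotype inside
    ``causal_interval`` (per-SNP divergence drawn once, with probability
    ``div_rate_in``, for the shared haplotype) and carry independent
    background divergence at rate ``div_rate_out`` elsewhere; non-suppressor
    strains are identical by descent with the reference inside the interval
    and diverge at ``div_rate_out`` outside.
    """
    if not 0 <= div_rate_in <= 1 or not 0 <= div_rate_out <= 1:
        raise ValueError("divergence rates must be in [0, 1]")
    positions = np.asarray(snp_positions, dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("empty SNP list")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("SNP positions must be strictly increasing")
    lo, hi = causal_interval
    in_mask = (positions >= lo) & (positions < hi)
    if not in_mask.any():
        raise ValueError("causal interval contains no SNPs")

    rng = np.random.default_rng(seed)
    m = len(positions)
    shared = np.zeros(m, dtype=np.int8)
    shared[in_mask] = rng.random(in_mask.sum()) < div_rate_in

    strains = ["REF"]
    labels = ["reference"]
    rows = [np.zeros(m, dtype=np.int8)]
    for i in range(n_sup):
        row = (rng.random(m) < div_rate_out).astype(np.int8)
        row[in_mask] = shared[in_mask]
        strains.append(f"SUP{i + 1}")
        labels.append("suppressor")
        rows.append(row)
    for i in range(n_nonsup):
        row = (rng.random(m) < div_rate_out).astype(np.int8)
        row[in_mask] = 0
        strains.append(f"NS{i + 1}")
        labels.append("non_suppressor")
        rows.append(row)

    loci = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"snp{k + 1}" for k in range(m)]}
    )
    return StrainGenotypeMatrix(strains, np.array(labels, dtype=object), np.vstack(rows), loci)


def simulate_activity(
    period: float,
    n_days: int,
    bin_minutes: float,
    amplitude: float,
    noise_sd: float,
    seed: int = 0,
    waveform: str = "rectified_sine",
) -> ActivitySeries:
    """Noisy rhythmic activity series of the given free-running period.

    The deterministic part is a rectified sinusoid (or square wave) of the
    given period; Gaussian noise is added and counts are floored at zero.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n_bins = int(round(n_days * 24 * 60 / bin_minutes))
    t = (np.arange(n_bins) + 0.5) * bin_minutes / 60.0
    phase = np.sin(2 * np.pi * t / period)
    if waveform == "rectified_sine":
        signal = amplitude * np.clip(phase, 0.0, None)
    elif waveform == "square":
        signal = amplitude * (phase > 0)
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    rng = np.random.default_rng(seed)
    values = signal + rng.normal(0.0, noise_sd, n_bins) if noise_sd > 0 else signal
    return ActivitySeries(np.clip(values, 0.0, None), bin_minutes)


def simulate_binding_series(
    bmax: float,
    kd: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    complex_label: str = "",
    genotype_label: str = "",
) -> BindingSeries:
    """One-site hyperbolic binding with multiplicative (CV) noise.

    bound = bmax * x / (kd + x) * (1 + N(0, noise_cv)) per replicate;
    negative draws are truncated at zero.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    x = np.asarray(concentrations, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    x = np.sort(x)
    mean = bmax * x / (kd + x)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_cv, size=(len(x), replicates)) if noise_cv > 0 else 0.0
    signals = np.clip(mean[:, None] * (1.0 + noise), 0.0, None)
    if np.isscalar(noise):
        signals = np.tile(mean[:, None], (1, replicates))
    return BindingSeries(x, signals, complex_label, genotype_label)


def simulate_peak_sets(
    chrom_sizes: Mapping[str, int],
    n_shared: int,
    n_only_a: int,
    n_only_b: int,
    summit_jitter_sd: float = 0.0,
    score_model=None,
    seed: int = 0,
    min_spacing: int = 500,
    peak_halfwidth: int = 200,
) -> tuple[PeakSet, PeakSet]:
    """Paired peak sets with a controlled number of shared binding sites.

    ``n_shared`` anchor sites appear in both sets, each set's summit drawn
    independently as anchor + N(0, summit_jitter_sd); exclusive sites are
    placed at least ``min_spacing`` bp from any other site. ``score_model``
    is a callable (rng, n) -> scores; the default is lognormal intensity.
    """
    for v in (n_shared, n_only_a, n_only_b):
        if v < 0:
            raise ValueError("peak counts must be >= 0")
    n_total = n_shared + n_only_a + n_only_b
    rng = np.random.default_rng(seed)
    if score_model is None:
        score_model = lambda r, n: r.lognormal(mean=3.0, sigma=0.8, size=n)

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    genome = int(sizes.sum())
    margin = peak_halfwidth + 4 * max(summit_jitter_sd, 1.0)
    base = min_spacing + 2 * margin
    slack = genome - 2 * margin - n_total * base
    if n_total and slack < 0:
        raise ValueError("genome too small to place requested peaks at required spacing")

    # concatenated-genome placement: guaranteed gap `base` between anchors
    # plus random exponential slack apportioned across the gaps
    if n_total:
        extra = rng.exponential(1.0, size=n_total + 1)
        extra = extra / extra.sum() * slack
        gaps = np.concatenate([[margin + extra[0]], base + extra[1:n_total]])
        anchors_lin = np.cumsum(gaps)
    else:
        anchors_lin = np.empty(0)
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    def to_chrom(linear: np.ndarray) -> tuple[list[str], np.ndarray]:
        idx = np.searchsorted(bounds, linear, side="right") - 1
        idx = np.clip(idx, 0, len(chroms) - 1)
        return [chroms[i] for i in idx], (linear - bounds[idx]).astype(np.int64)

    roles = np.array(
        ["shared"] * n_shared + ["a"] * n_only_a + ["b"] * n_only_b, dtype=object
    )
    rng.shuffle(roles)

    def build(role_sel: np.ndarray, jitter: bool) -> PeakSet:
        lin = anchors_lin[role_sel]
        if jitter and summit_jitter_sd > 0:
            lin = lin + rng.normal(0.0, summit_jitter_sd, size=len(lin))
        chrom_names, pos = to_chrom(np.sort(lin))
        rows = []
        scores = score_model(rng, len(pos))
        for c, p, s in zip(chrom_names, pos, scores):
            p = int(min(max(p, peak_halfwidth), chrom_sizes[c] - peak_halfwidth - 1))
            rows.append((c, p - peak_halfwidth, p + peak_halfwidth, p, float(s)))
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS).sort_values(["chrom", "start"])
        return PeakSet(df.reset_index(drop=True))

    sel_shared = roles == "shared"
    set_a = build(sel_shared | (roles == "a"), jitter=True)
    set_b = build(sel_shared | (roles == "b"), jitter=True)
    # with zero jitter the shared anchors are identical in both sets
    return set_a, set_b


def ideal_delta_ct(fraction: float | np.ndarray) -> np.ndarray:
    """ΔCt between alternate- and reference-allele assays at PCR efficiency 2.

    Sign convention: ΔCt = Ct(reference assay) - Ct(alternate assay), so a
    higher alternate-allele fraction gives a larger ΔCt; at 50:50 ΔCt = 0.
    """
    f = np.asarray(fraction, dtype=float)
    return np.log2(f / (1.0 - f))


def simulate_ase_data(
    true_fraction: float,
    mix_fractions: Sequence[float] = (0.25, 0.5, 0.75),
    n_mixture_reps: int = 3,
    n_cdna: int = 6,
    n_colonies: int = 172,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    chromatogram_cv: float = 0.05,
) -> AseSimData:
    """Synthetic allele-mixture data under a cis-regulatory expression bias.

    Genomic-DNA mixtures at ``mix_fractions`` give the qPCR standard curve
    (ΔCt = log2(f/(1-f)) + noise); cDNA ΔCt observations are generated at
    ``true_fraction``; colony counts are Binomial(n_colonies, true_fraction);
    chromatogram peak heights are proportional to allele abundance with
    multiplicative noise, plus a 1:1 calibration pair.
    """
    if not 0.0 < true_fraction < 1.0:
        raise ValueError("true_fraction must be in (0, 1)")
    fr = np.asarray(mix_fractions, dtype=float)
    if np.any((fr <= 0) | (fr >= 1)):
        raise ValueError("mixture fractions must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)

    frac_col = np.repeat(fr, n_mixture_reps)
    dct = ideal_delta_ct(frac_col) + rng.normal(0.0, ct_noise_sd, len(frac_col))
    curve = pd.DataFrame({"fraction": frac_col, "delta_ct": dct})

    cdna = ideal_delta_ct(true_fraction) + rng.normal(0.0, ct_noise_sd, n_cdna)
    n_alt = int(rng.binomial(n_colonies, true_fraction))

    scale = 1000.0
    noise = lambda: max(1e-9, 1.0 + rng.normal(0.0, chromatogram_cv))
    peak_alt = scale * true_fraction * noise()
    peak_ref = scale * (1.0 - true_fraction) * noise()
    cal_alt = scale * 0.5 * noise()
    cal_ref = scale * 0.5 * noise()
    return AseSimData(
        curve, cdna, n_alt, n_colonies, peak_alt, peak_ref, cal_alt, cal_ref, true_fraction
    )
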