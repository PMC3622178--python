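"""Small published facts about the study system, plus a synthetic stand-in
for the unpublished promoter polymorphism table.

These are inputs, not results: the strain phenotype classification from the
F1 interaction analysis, the reported subspecific-origin (M. domesticus vs
M. musculus) segment assignments of 16 laboratory strains over the candidate
interval on chromosome 1, reported apparent Kd/Bmax regimes for
CLOCK:BMAL1 and USF complexes at four native E-boxes (used as realistic
parameter regimes for simulation), and the printed genome-wide co-occupancy
counts (USF1 peaks overlapping merged CLOCK:BMAL1 sites).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from socmap.simulate import StrainGenotypeMatrix

#: strain -> phenotype label; the reference strain (C57BL/6J) carries the
#: non-suppressor allele by definition of the mapping cross.
STRAIN_LABELS: dict[str, str] = {
    "C57BL/6J": "reference",
    "C58/J": "non_suppressor",
    "BTBR T+tf/J": "non_suppressor",
    "I/LnJ": "non_suppressor",
    "MA/MyJ": "non_suppressor",
    "JF1/Ms": "non_suppressor",
    "MOLF/EiJ": "non_suppressor",
    "CZECHII/EiJ": "non_suppressor",
    "BALB/cJ": "suppressor",
    "A/J": "suppressor",
    "AKR/J": "suppressor",
    "C3H/HeJ": "suppressor",
    "DBA/2J": "suppressor",
    "FVB/NJ": "suppressor",
    "SJL/J": "suppressor",
    "129S1/SvImJ": "suppressor",
}

#: candidate interval on chromosome 1 (bp, half-open)
CANDIDATE_INTERVAL = (173_300_000, 174_200_000)

#: genome-wide co-occupancy counts: (USF1-overlapped CLOCK:BMAL1 sites,
#: total CLOCK:BMAL1 sites) per Clock genotype
COOCCUPANCY_COUNTS: dict[str, tuple[int, int]] = {
    "wildtype": (497, 3412),
    "clock_mutant": (1916, 5072),
}

#: USF1 peak totals per genotype (for the fourfold-increase comparison)
USF1_PEAK_TOTALS: dict[str, int] = {"wildtype": 1885, "clock_mutant": 6091}


def ancestry_table() -> pd.DataFrame:
    """Reported subspecific-origin segments over the candidate interval.

    Columns: strain, chrom, start, end (bp), subspecies ("Dom" or "Mus").
    Two strains carry the proximal/distal ancestry breakpoints and thus have
    two segments each.
    """
    full = CANDIDATE_INTERVAL
    rows = [
        ("BALB/cJ", *full, "Dom"),
        ("A/J", *full, "Dom"),
        ("AKR/J", 173_300_000, 173_302_142, "Mus"),
        ("AKR/J", 173_302_461, 174_200_000, "Dom"),
        ("C3H/HeJ", *full, "Dom"),
        ("DBA/2J", *full, "Dom"),
        ("FVB/NJ", *full, "Dom"),
        ("SJL/J", *full, "Dom"),
        ("129S1/SvImJ", *full, "Dom"),
        ("C57BL/6J", *full, "Mus"),
        ("C58/J", 173_300_000, 174_028_368, "Mus"),
        ("C58/J", 174_187_607, 174_200_000, "Dom"),
        ("BTBR T+tf/J", *full, "Mus"),
        ("I/LnJ", *full, "Mus"),
        ("JF1/Ms", *full, "Mus"),
        ("MOLF/EiJ", *full, "Mus"),
        ("CZECHII/EiJ", *full, "Mus"),
    ]
    return pd.DataFrame(rows, columns=["strain", "start", "end", "subspecies"]).assign(
        chrom="1"
    )[["strain", "chrom", "start", "end", "subspecies"]]


def ebox_binding_parameters() -> pd.DataFrame:
    """Reported apparent Kd (nM) and Bmax (a.u.) regimes at four E-boxes.

    Used as realistic parameter regimes when simulating saturation-binding
    series; columns: ebox, complex, kd_nM, bmax.
    """
    rows = [
        ("Dbp_EP", "CLOCK:BMAL1 WT", 2.01, 0.97),
        ("Dbp_EP", "CLOCK:BMAL1 mutant", 32.94, 1.25),
        ("Dbp_EP", "USF1 WT", 42.8, 0.83),
        ("Dbp_EP", "USF1 mutant", 49.56, 0.87),
        ("Dbp_EI2", "CLOCK:BMAL1 WT", 0.71, 0.79),
        ("Dbp_EI2", "CLOCK:BMAL1 mutant", 6.18, 2.38),
        ("Dbp_EI2", "USF1 WT", 6.10, 2.25),
        ("Dbp_EI2", "USF1 mutant", 9.64, 2.10),
        ("Per2_E", "CLOCK:BMAL1 WT", 2.00, 0.26),
        ("Per2_E", "CLOCK:BMAL1 mutant", 8.05, 0.43),
        ("Per2_E", "USF1 WT", 17.81, 0.36),
        ("Per2_E", "USF1 mutant", 16.71, 0.41),
        ("Per1_EP1", "CLOCK:BMAL1 WT", 16.55, 0.74),
        ("Per1_EP1", "CLOCK:BMAL1 mutant", 43.69, 7.38),
        ("Per1_EP1", "USF1 WT", 33.36, 3.06),
        ("Per1_EP1", "USF1 mutant", 58.62, 7.96),
    ]
    return pd.DataFrame(rows, columns=["ebox", "complex", "kd_nM", "bmax"])


def synthetic_promoter_snp_table() -> StrainGenotypeMatrix:
    """Synthetic reconstruction of the promoter-region polymorphism table.

    The real strain-by-polymorphism table for the ~1000-bp promoter fragment
    is unpublished; this synthetic stand-in encodes its reported structure:
    16 strains (8 suppressor, 8 non-suppressor including the reference), 14
    polymorphisms, of which exactly 7 perfectly match the phenotype
    partition. The 7 discordant columns use patterns that break the
    partition in distinct ways (private alleles, partial sharing, an allele
    crossing the phenotype boundary).
    """
    strains = list(STRAIN_LABELS)
    labels = np.array([STRAIN_LABELS[s] for s in strains], dtype=object)
    sup = labels == "suppressor"

    n_snps = 14
    alleles = np.zeros((len(strains), n_snps), dtype=np.int8)
    concordant_cols = [1, 3, 5, 7, 9, 11, 13]
    for j in concordant_cols:
        alleles[sup, j] = 1
    # discordant patterns
    alleles[np.flatnonzero(sup)[:4], 0] = 1          # only half the suppressors
    alleles[np.flatnonzero(~sup)[1], 2] = 1          # private to one non-suppressor
    alleles[sup, 4] = 1
    alleles[np.flatnonzero(~sup)[2], 4] = 1          # crosses the boundary
    alleles[np.flatnonzero(sup)[0], 6] = 1           # private to one suppressor
    alleles[sup, 8] = 1
    alleles[np.flatnonzero(sup)[3], 8] = 0           # one suppressor reverts
    alleles[:, 10] = 1
    alleles[0, 10] = 0                               # near-monomorphic
    alleles[np.flatnonzero(sup)[2:6], 12] = 1        # partial sharing

    positions = 100 + 64 * np.arange(n_snps)
    loci = pd.DataFrame(
        {"chrom": "1", "pos": positions, "id": [f"prom_snp{j + 1}" for j in range(n_snps)]}
    )
    return StrainGenotypeMatrix(strains, labels, alleles, loci)
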