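"""ChIP-seq peak-list algebra: summit-window overlap, Venn co-occupancy,
top-site intensity comparison and E-box motif counting.

Peaks are genomic intervals with a single-bp summit (position of maximum read
pileup) and a score (binding intensity). Following the field's convention for
factor co-binding, two peaks "overlap" when their summits fall within a fixed
window of each other (summit +/- 120 bp by default, i.e. |delta| <= 240 bp),
not when their intervals intersect. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HALFWIDTH = 120

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "score"]


@dataclass
class PeakSet:
    """A sorted set of scored peaks for one factor/genotype combination.

    ``peaks`` holds columns chrom, start, end, summit, score with
    0-based half-open intervals and ``start <= summit < end``.
    """

    peaks: pd.DataFrame
    factor: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        df = self.peaks.reset_index(drop=True)
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("peaks require start < end")
            bad = (df["summit"] < df["start"]) | (df["summit"] >= df["end"])
            if bad.any():
                raise ValueError("summit must satisfy start <= summit < end")
            if (df["score"] < 0).any():
                raise ValueError("scores must be >= 0")
            if not df.sort_values(["chrom", "start"]).index.equals(df.index):
                warnings.warn("peak set not sorted; sorting by (chrom, start)")
                df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.peaks = df

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class OverlapReport:
    """Three-set Venn region counts plus the co-occupancy fraction.

    ``venn`` maps a frozenset of set names to the number of peaks (counted
    per originating set, see ``per_set``) in that exclusive region;
    ``per_set`` gives, for each input set, how many of its peaks overlap each
    combination of the other two. ``cb_sites`` is the number of merged
    CLOCK/BMAL1 sites used as the co-occupancy denominator and
    ``cooccupied`` the number of those touched by at least one peak of the
    first set; ``fraction = cooccupied / cb_sites``.
    """

    per_set: dict[str, dict[frozenset, int]]
    cb_sites: int
    cooccupied: int
    fraction: float | None
    definition: str = (
        "denominator: summit-merged union of the second and third peak sets; "
        "numerator: merged sites overlapped (summit distance <= 2*halfwidth) "
        "by >= 1 peak of the first set"
    )

    @property
    def percent(self) -> float | None:
        return None if self.fraction is None else 100.0 * self.fraction


@dataclass
class MotifCounts:
    motif: str
    per_peak: np.ndarray
    total: int
    clipped: int = 0


def cooccupancy_fraction(n_overlap: int, n_sites: int) -> float:
    """Co-occupancy as a percentage, e.g. 1916/5072 -> 37.78...

    The printed form (``format_percent``) rounds to the nearest integer.
    """
    if n_sites <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * n_overlap / n_sites


def format_percent(percent: float) -> str:
    return f"{int(round(percent))}%"


def summit_overlap(
    a: PeakSet, b: PeakSet, halfwidth: int = DEFAULT_HALFWIDTH
) -> np.ndarray:
    """All index pairs (i, j) with same chromosome and |summit_i - summit_j|
    <= 2*halfwidth (inclusive), found by a sweep over sorted summits.

    Returns an integer array of shape (n_pairs, 2) indexing into ``a.peaks``
    and ``b.peaks``.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    window = 2 * halfwidth
    pairs: list[tuple[int, int]] = []
    b_by_chrom = {c: g for c, g in b.peaks.groupby("chrom")}
    for chrom, ga in a.peaks.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        sa = ga["summit"].to_numpy()
        sb = gb["summit"].to_numpy()
        order_b = np.argsort(sb, kind="stable")
        sb_sorted = sb[order_b]
        lo = np.searchsorted(sb_sorted, sa - window, side="left")
        hi = np.searchsorted(sb_sorted, sa + window, side="right")
        ia = ga.index.to_numpy()
        ib = gb.index.to_numpy()[order_b]
        for k in range(len(sa)):
            for j in range(lo[k], hi[k]):
                pairs.append((ia[k], ib[j]))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    out = np.array(pairs, dtype=int)
    return out[np.lexsort((out[:, 1], out[:, 0]))]


def overlapping_mask(a: PeakSet, b: PeakSet, halfwidth: int = DEFAULT_HALFWIDTH) -> np.ndarray:
    """Boolean mask over ``a``: True where a peak overlaps >= 1 peak of ``b``.

    A peak counts once regardless of how many partners it has.
    """
    mask = np.zeros(len(a), dtype=bool)
    pairs = summit_overlap(a, b, halfwidth)
    if len(pairs):
        mask[np.unique(pairs[:, 0])] = True
    return mask


def merge_summits(
    sets: list[PeakSet], halfwidth: int = DEFAULT_HALFWIDTH, factor: str = "merged"
) -> PeakSet:
    """Summit-merge the union of several peak sets into non-redundant sites.

    Peaks whose summits chain within 2*halfwidth of each other (single-linkage
    along the sorted summit order, per chromosome) collapse into one site with
    a score-weighted mean summit and summed score. Idempotent: merging an
    already-merged set returns it unchanged.
    """
    frames = [s.peaks for s in sets if len(s)]
    if not frames:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS), factor=factor)
    allp = pd.concat(frames, ignore_index=True)
    window = 2 * halfwidth
    rows = []
    for chrom, g in allp.groupby("chrom"):
        g = g.sort_values("summit")
        summits = g["summit"].to_numpy(dtype=float)
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        scores = g["score"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(summits) > window) + 1
        for idx in np.split(np.arange(len(g)), breaks):
            w = scores[idx]
            if w.sum() > 0:
                summit = int(round(np.average(summits[idx], weights=w)))
            else:
                summit = int(round(summits[idx].mean()))
            start = int(starts[idx].min())
            end = int(ends[idx].max())
            summit = min(max(summit, start), end - 1)
            rows.append((chrom, start, end, summit, float(w.sum())))
    merged = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(merged, factor=factor)


def venn_cooccupancy(
    usf1: PeakSet,
    clock: PeakSet,
    bmal1: PeakSet,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> OverlapReport:
    """Three-factor co-occupancy report.

    For every input set, each peak is assigned to the Venn region given by
    which of the other two sets it summit-overlaps, so region counts sum to
    the set's cardinality. The co-occupancy fraction uses the summit-merged
    union of the second and third sets (the "CLOCK:BMAL1 sites") as
    denominator and the number of merged sites overlapped by the first set as
    numerator.
    """
    named = {"USF1": usf1, "CLOCK": clock, "BMAL1": bmal1}
    per_set: dict[str, dict[frozenset, int]] = {}
    for name, ps in named.items():
        others = [(n, p) for n, p in named.items() if n != name]
        masks = {n: overlapping_mask(ps, p, halfwidth) for n, p in others}
        regions: dict[frozenset, int] = {}
        names = [n for n, _ in others]
        for combo_size in range(3):
            for combo in itertools.combinations(names, combo_size):
                key = frozenset((name,) + combo)
                sel = np.ones(len(ps), dtype=bool)
                for n in names:
                    sel &= masks[n] if n in combo else ~masks[n]
                regions[key] = int(sel.sum())
        per_set[name] = regions

    cb = merge_summits([clock, bmal1], halfwidth, factor="CLOCK:BMAL1")
    n_cb = len(cb)
    if n_cb == 0:
        warnings.warn("no CLOCK/BMAL1 sites: co-occupancy fraction undefined")
        return OverlapReport(per_set, 0, 0, None)
    cooccupied = int(overlapping_mask(cb, usf1, halfwidth).sum())
    return OverlapReport(per_set, n_cb, cooccupied, cooccupied / n_cb)


@dataclass
class TopSitesComparison:
    n_top: int
    summary: pd.DataFrame  # per set: median, q1, q3
    statistic: float
    p_value: float


def top_sites_compare(a: PeakSet, b: PeakSet, top: int | float) -> TopSitesComparison:
    """Compare binding intensity of the strongest sites of two peak sets.

    ``top`` is a count or, if < 1, a fraction of each set (e.g. 0.1 for the
    top decile). Scores are ranked descending with ties broken by
    (score desc, chrom, start) for determinism; the two top-score lists are
    compared with a two-sided Wilcoxon rank-sum (Mann-Whitney) test.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both peak sets must be non-empty")

    def top_scores(ps: PeakSet, n: int) -> np.ndarray:
        if n > len(ps):
            warnings.warn(f"top={n} larger than set size {len(ps)}; clipped")
            n = len(ps)
        df = ps.peaks.sort_values(
            ["score", "chrom", "start"], ascending=[False, True, True]
        )
        return df["score"].to_numpy()[:n]

    def n_for(ps: PeakSet) -> int:
        return max(1, int(round(top * len(ps)))) if 0 < top < 1 else int(top)

    sa, sb = top_scores(a, n_for(a)), top_scores(b, n_for(b))
    res = stats.mannwhitneyu(sa, sb, alternative="two-sided", method="asymptotic")
    summary = pd.DataFrame(
        {
            "set": [a.factor or "a", b.factor or "b"],
            "n_top": [len(sa), len(sb)],
            "median": [np.median(sa), np.median(sb)],
            "q1": [np.percentile(sa, 25), np.percentile(sb, 25)],
            "q3": [np.percentile(sa, 75), np.percentile(sb, 75)],
        }
    )
    return TopSitesComparison(len(sa), summary, float(res.statistic), float(res.pvalue))


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_occurrences(seq: str, motif: str) -> int:
    """Overlap-aware exact occurrence count; ambiguous bases never match."""
    count = start = 0
    while True:
        pos = seq.find(motif, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def motif_count(
    peaks: PeakSet,
    sequences,
    motif: str = "CACGTG",
    flank: int = 0,
) -> MotifCounts:
    """Count exact motif occurrences within each peak window (+/- flank).

    ``sequences`` is any mapping chrom -> sequence string (a dict or an
    indexed FASTA object). The canonical E-box CACGTG is its own reverse
    complement, so one strand suffices; non-palindromic motifs are scanned on
    both strands and the per-strand counts summed.
    """
    motif = motif.upper()
    rc = reverse_complement(motif)
    palindromic = motif == rc
    counts = np.zeros(len(peaks), dtype=int)
    clipped = 0
    for i, row in enumerate(peaks.peaks.itertuples(index=False)):
        try:
            chrom_seq = str(sequences[row.chrom])
        except KeyError:
            raise KeyError(f"no sequence for chromosome {row.chrom!r}")
        start = row.start - flank
        end = row.end + flank
        if start < 0 or end > len(chrom_seq):
            clipped += 1
            start, end = max(0, start), min(len(chrom_seq), end)
        window = chrom_seq[start:end].upper()
        n = _count_occurrences(window, motif)
        if not palindromic:
            n += _count_occurrences(window, rc)
        counts[i] = n
    if clipped:
        warnings.warn(f"{clipped} peak window(s) clipped to sequence bounds")
    return MotifCounts(motif, counts, int(counts.sum()), clipped)


def interval_overlap(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Alternative overlap mode: pairs whose half-open intervals intersect."""
    pairs = []
    b_by_chrom = {c: g for c, g in b.peaks.groupby("chrom")}
    for chrom, ga in a.peaks.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        for i, ra in ga.iterrows():
            sel = (gb["start"] < ra["end"]) & (gb["end"] > ra["start"])
            pairs.extend((i, j) for j in gb.index[sel])
    if not pairs:
        return np.empty((0, 2), dtype=int)
    out = np.array(pairs, dtype=int)
    return out[np.lexsort((out[:, 1], out[:, 0]))]
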