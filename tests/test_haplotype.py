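"""Haplotype concordance mapping: divergence windows, interval calling,
QTN filtering and ancestry checks, each against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from socmap import datasets, haplotype, simulate
from socmap.haplotype import CandidateInterval
from socmap.simulate import StrainGenotypeMatrix


def toy_matrix(alleles, labels, positions=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_strains, n_snps = alleles.shape
    if positions is None:
        positions = 100 * (np.arange(n_snps) + 1)
    strains = [f"s{i}" for i in range(n_strains)]
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"x{j}" for j in range(n_snps)]}
    )
    return StrainGenotypeMatrix(strains, np.asarray(labels, dtype=object), alleles, loci)


class TestPairwiseDivergence:
    def test_identical_and_fully_divergent_strains(self):
        m = toy_matrix(
            [[0] * 10, [0] * 10, [1] * 10],
            ["reference", "non_suppressor", "suppressor"],
        )
        prof = haplotype.pairwise_divergence(m, window=5)
        assert np.allclose(prof.divergence[1], 0.0)
        assert np.allclose(prof.divergence[2], 1.0)

    def test_hand_counted_window(self):
        row = [1, 0, 1, 0, 0, 0, 0, 0, 0, 0]  # 2 of first 5 differ
        m = toy_matrix([[0] * 10, row], ["reference", "suppressor"])
        prof = haplotype.pairwise_divergence(m, window=5)
        assert prof.divergence[1, 0] == pytest.approx(0.4)
        assert prof.divergence[1, 1] == pytest.approx(0.0)

    def test_missing_excluded_from_denominator(self):
        row = [1, -1, -1, 0, 0]
        m = toy_matrix([[0] * 5, row], ["reference", "suppressor"])
        prof = haplotype.pairwise_divergence(m, window=5)
        assert prof.divergence[1, 0] == pytest.approx(1 / 3)

    def test_all_missing_window_is_nan(self):
        m = toy_matrix([[0, 0], [-1, -1]], ["reference", "suppressor"])
        prof = haplotype.pairwise_divergence(m, window=2)
        assert np.isnan(prof.divergence[1, 0])

    def test_snp_order_invariance_within_window(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(3, 8))
        alleles[0] = 0
        m1 = toy_matrix(alleles, ["reference", "suppressor", "non_suppressor"])
        perm = rng.permutation(8)
        m2 = toy_matrix(
            alleles[:, perm], ["reference", "suppressor", "non_suppressor"],
            positions=100 * (np.arange(8) + 1),
        )
        p1 = haplotype.pairwise_divergence(m1, window=8)
        p2 = haplotype.pairwise_divergence(m2, window=8)
        np.testing.assert_allclose(p1.divergence, p2.divergence)


class TestConcordanceScan:
    def brute_force_windows(self, matrix, window, tau_hi, tau_lo):
        prof = haplotype.pairwise_divergence(matrix, window)
        sup = matrix.labels == "suppressor"
        non = matrix.labels == "non_suppressor"
        out = []
        for w in range(len(prof.windows)):
            ds = prof.divergence[sup, w]
            dn = prof.divergence[non, w]
            ds, dn = ds[~np.isnan(ds)], dn[~np.isnan(dn)]
            out.append(
                len(ds) > 0 and len(dn) > 0 and ds.min() >= tau_hi and dn.max() <= tau_lo
            )
        return out

    def test_implanted_segment_recovered_within_one_window(self):
        pos = np.arange(0, 30_000_000, 15_000)
        truth = (10_000_000, 10_900_000)
        m = simulate.simulate_strain_panel(8, 7, pos, truth, 0.8, 0.02, seed=0)
        prof = haplotype.pairwise_divergence(m, 25)
        ivs = haplotype.concordance_scan(prof)
        assert len(ivs) == 1
        window_bp = 25 * 15_000
        assert abs(ivs[0].start - truth[0]) <= window_bp
        assert abs(ivs[0].end - truth[1]) <= window_bp

    def test_no_divergence_no_intervals(self):
        m = toy_matrix(
            np.zeros((4, 12), dtype=int),
            ["reference", "suppressor", "non_suppressor", "non_suppressor"],
        )
        prof = haplotype.pairwise_divergence(m, window=3)
        assert haplotype.concordance_scan(prof) == []

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        labels = ["reference", "suppressor", "suppressor", "non_suppressor"]
        for _ in range(20):
            alleles = rng.integers(0, 2, size=(4, 12))
            alleles[0] = 0
            m = toy_matrix(alleles, labels)
            prof = haplotype.pairwise_divergence(m, window=3)
            ivs = haplotype.concordance_scan(prof, 0.5, 0.34)
            flags = self.brute_force_windows(m, 3, 0.5, 0.34)
            covered = sorted(w for iv in ivs for w in iv.window_indices)
            assert covered == [w for w, f in enumerate(flags) if f]

    def test_threshold_monotonicity(self):
        # loosening either threshold never loses a concordant window
        rng = np.random.default_rng(4)
        alleles = rng.integers(0, 2, size=(5, 30))
        alleles[0] = 0
        labels = ["reference", "suppressor", "suppressor", "non_suppressor",
                  "non_suppressor"]
        m = toy_matrix(alleles, labels)
        prof = haplotype.pairwise_divergence(m, window=5)

        def windows(tau_hi, tau_lo):
            return {
                w
                for iv in haplotype.concordance_scan(prof, tau_hi, tau_lo)
                for w in iv.window_indices
            }

        strict = windows(0.6, 0.2)
        assert strict <= windows(0.4, 0.2)  # lower tau_hi
        assert strict <= windows(0.6, 0.4)  # higher tau_lo

    def test_bad_thresholds_rejected(self):
        m = toy_matrix([[0, 0], [1, 1], [0, 0]],
                       ["reference", "suppressor", "non_suppressor"])
        prof = haplotype.pairwise_divergence(m, window=2)
        with pytest.raises(ValueError):
            haplotype.concordance_scan(prof, 0.1, 0.5)


class TestAnnotateGenes:
    IV = CandidateInterval("1", 1000, 2000, [], 0)

    def test_empty_annotation(self):
        ann = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        assert haplotype.annotate_genes(self.IV, ann).genes == []

    def test_half_open_boundary_excluded(self):
        ann = pd.DataFrame(
            [
                {"chrom": "1", "start": 2000, "end": 2100, "name": "abutting"},
                {"chrom": "1", "start": 1999, "end": 2100, "name": "overlaps"},
                {"chrom": "1", "start": 900, "end": 1000, "name": "abuts_left"},
            ]
        )
        assert haplotype.annotate_genes(self.IV, ann).genes == ["overlaps"]

    def test_malformed_rows_skipped_with_warning(self):
        ann = pd.DataFrame(
            [
                {"chrom": "1", "start": 1500, "end": 1400, "name": "inverted"},
                {"chrom": "1", "start": "oops", "end": 1600, "name": "bad"},
                {"chrom": "1", "start": 1100, "end": 1200, "name": "good"},
            ]
        )
        with pytest.warns(UserWarning, match="malformed"):
            iv = haplotype.annotate_genes(self.IV, ann)
        assert iv.genes == ["good"]

    @given(st.integers(0, 2**31 - 1))
    def test_property_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 3000, 15)
        ann = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], 15),
                "start": starts,
                "end": starts + rng.integers(1, 500, 15),
                "name": [f"g{i}" for i in range(15)],
            }
        )
        iv = haplotype.annotate_genes(self.IV, ann)
        expected = [
            r["name"]
            for _, r in ann.sort_values("start").iterrows()
            if r["chrom"] == "1" and r["start"] < 2000 and r["end"] > 1000
        ]
        assert iv.genes == expected


class TestQtnConcordance:
    def test_perfect_partition_concordant(self):
        m = toy_matrix(
            [[0, 0], [1, 0], [1, 1], [0, 1]],
            ["reference", "suppressor", "suppressor", "non_suppressor"],
        )
        hits = haplotype.qtn_concordance_filter(m)
        assert [s.index for s in hits] == [0]

    def test_one_discordant_strain_breaks_it(self):
        m = toy_matrix(
            [[0], [1], [0], [0]],
            ["reference", "suppressor", "suppressor", "non_suppressor"],
        )
        assert haplotype.qtn_concordance_filter(m) == []

    def test_strict_mode_drops_missing(self):
        m = toy_matrix(
            [[0], [1], [-1], [0]],
            ["reference", "suppressor", "suppressor", "non_suppressor"],
        )
        assert haplotype.qtn_concordance_filter(m, strict=True) == []
        lenient = haplotype.qtn_concordance_filter(m, strict=False)
        assert [s.index for s in lenient] == [0]

    def test_synthetic_promoter_table_has_seven_of_fourteen(self):
        tab = datasets.synthetic_promoter_snp_table()
        hits = haplotype.qtn_concordance_filter(tab)
        assert tab.n_snps == 14 and len(hits) == 7

    @given(st.integers(0, 2**31 - 1))
    def test_property_matches_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_strains, n_snps = 8, 14
        alleles = rng.choice([0, 1, 1, -1], size=(n_strains, n_snps))
        alleles[0] = np.abs(alleles[0])  # keep the reference callable
        labels = ["reference"] + ["suppressor"] * 4 + ["non_suppressor"] * 3
        m = toy_matrix(alleles, labels)
        got = {s.index for s in haplotype.qtn_concordance_filter(m)}
        expected = set()
        for j in range(n_snps):
            col = alleles[:, j]
            if (col < 0).any():
                continue
            sup_alleles = set(col[1:5].tolist())
            non_alleles = set(col[[0, 5, 6, 7]].tolist())
            if len(sup_alleles) == 1 and len(non_alleles) == 1 and sup_alleles != non_alleles:
                expected.add(j)
        assert got == expected


class TestAncestryCheck:
    INTERVAL = CandidateInterval("1", *datasets.CANDIDATE_INTERVAL, [], 0)

    def strain_labels(self):
        # the published table omits one labeled strain; restrict to its strains
        table = datasets.ancestry_table()
        return {s: l for s, l in datasets.STRAIN_LABELS.items()
                if s in set(table["strain"])}

    def test_published_segments_are_concordant(self):
        res = haplotype.ancestry_check(
            self.INTERVAL, datasets.ancestry_table(), self.strain_labels()
        )
        assert res.verdict

    def test_breakpoint_strain_majority_call(self):
        res = haplotype.ancestry_check(
            self.INTERVAL, datasets.ancestry_table(), self.strain_labels()
        )
        akr = res.per_strain.set_index("strain").loc["AKR/J"]
        assert akr["subspecies"] == "Dom" and akr["partial"]

    def test_one_relabeled_suppressor_breaks_verdict(self):
        table = datasets.ancestry_table().copy()
        table.loc[table["strain"] == "DBA/2J", "subspecies"] = "Mus"
        res = haplotype.ancestry_check(self.INTERVAL, table, self.strain_labels())
        assert not res.verdict

    def test_absent_strain_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            res = haplotype.ancestry_check(
                self.INTERVAL, datasets.ancestry_table(), datasets.STRAIN_LABELS
            )
        assert "MA/MyJ" in res.excluded
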