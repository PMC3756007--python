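"""NG86 site counting, pathway-averaged differences, and pN/pS categories."""

import itertools

import numpy as np
import pytest

from poolscan._codon import BASES, SENSE_CODONS, STOP_CODONS
from poolscan.selection import (
    OrfPair,
    count_differences,
    match_orf_pairs,
    ng86_site_counts,
    scan_populations,
    score_pair,
)

from conftest import oracle_codon_paths, translate


ALL_CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]


def pair(seq_a, seq_b, gene="g1"):
    return OrfPair(gene, "a", "b", seq_a, seq_b)


class TestSiteCounts:
    def test_phe_codon(self):
        # TTT: only TTT->TTC (third position) is synonymous; TTA/TTG are Leu
        n, s = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_codon_has_no_synonymous_site(self):
        n, s = ng86_site_counts("TGG")
        assert (n, s) == (3.0, 0.0)

    def test_sites_sum_to_length(self):
        rng = np.random.default_rng(5)
        seq = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=100))
        n, s = ng86_site_counts(seq)
        assert n + s == pytest.approx(len(seq))

    def test_not_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("ATGC")

    def test_all_64_codons_match_enumeration_oracle(self):
        for codon in ALL_CODONS:
            syn = sum(
                1
                for pos in range(3)
                for b in BASES
                if b != codon[pos]
                and (codon[:pos] + b + codon[pos + 1 :]) not in STOP_CODONS
                and translate(codon[:pos] + b + codon[pos + 1 :]) == translate(codon)
            )
            n, s = ng86_site_counts(codon)
            assert s == pytest.approx(syn / 3), codon
            assert n == pytest.approx(3 - syn / 3), codon


class TestCountDifferences:
    def test_identical_sequences(self):
        assert count_differences(pair("ATGGAA", "ATGGAA")) == (0.0, 0.0, 0)

    def test_single_synonymous_difference(self):
        assert count_differences(pair("GAA", "GAG")) == (0.0, 1.0, 1)

    def test_two_hit_codon_hand_average(self):
        # TTT -> GTA via TTT->GTT->GTA (both nonsyn) or TTT->TTA->GTA
        # (Phe->Leu nonsyn, then Leu->Val nonsyn): every step nonsynonymous
        nd, sd, n_diffs = count_differences(pair("TTT", "GTA"))
        paths = oracle_codon_paths("TTT", "GTA")
        expected_n = sum(p[0] for p in paths) / len(paths)
        expected_s = sum(p[1] for p in paths) / len(paths)
        assert nd == pytest.approx(expected_n)
        assert sd == pytest.approx(expected_s)
        assert n_diffs == 2

    def test_random_codon_pairs_match_path_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            ca, cb = (
                SENSE_CODONS[rng.integers(61)],
                SENSE_CODONS[rng.integers(61)],
            )
            nd, sd, n_diffs = count_differences(pair(ca, cb))
            paths = oracle_codon_paths(ca, cb)
            k = sum(1 for x, y in zip(ca, cb) if x != y)
            if paths:
                assert nd == pytest.approx(sum(p[0] for p in paths) / len(paths))
                assert sd == pytest.approx(sum(p[1] for p in paths) / len(paths))
            else:  # all orderings pass through stops: count all nonsynonymous
                assert (nd, sd) == (float(k), 0.0)
            assert nd + sd == pytest.approx(n_diffs)


class TestScorePair:
    def orf(self, body_codons):
        return "ATG" + body_codons

    def test_min_snps_filter(self):
        seq_a = self.orf("GAA" * 60)
        seq_b = seq_a[:10] + ("C" if seq_a[10] != "C" else "T") + seq_a[11:]
        score = score_pair(pair(seq_a, seq_b))
        assert score.category == "filtered"
        assert score.filter_reason == "min_snps"

    def test_short_orf_filtered(self):
        score = score_pair(pair("ATG" + "GAA" * 49, "ATG" + "GAA" * 49))
        assert score.filter_reason == "min_len"

    def test_internal_stop_filtered(self):
        seq_a = self.orf("GAA" * 60)
        seq_b = seq_a[:6] + "TAA" + seq_a[9:]
        assert score_pair(pair(seq_a, seq_b)).filter_reason == "internal_stop"

    def test_zero_synonymous_filtered(self):
        seq_a = self.orf("GAA" * 60)
        # three nonsynonymous changes (GAA->GTA), no synonymous ones
        b = list(seq_a)
        for ci in (5, 10, 15):
            b[3 * ci + 1] = "T"
        score = score_pair(pair(seq_a, "".join(b)))
        assert score.filter_reason == "zero_synonymous"

    def test_excess_nonsynonymous_is_strong_and_ratio_consistent(self):
        seq_a = self.orf("GAA" * 120)
        b = list(seq_a)
        # two synonymous changes (GAA->GAG), many nonsynonymous (GAA->GTA)
        for ci in (5, 10):
            b[3 * ci + 2] = "G"
        for ci in range(20, 40):
            b[3 * ci + 1] = "T"
        score = score_pair(pair(seq_a, "".join(b)))
        assert (score.nd, score.sd) == (20.0, 2.0)
        assert score.ratio == pytest.approx(
            (score.nd / score.n_sites) / (score.sd / score.s_sites)
        )
        assert score.ratio > 1.0
        assert score.category == "strong"

    def test_moderate_band_open_left_closed_right(self):
        # ratio exactly 1 must be moderate, not strong
        seq_a = self.orf("GAA" * 120)
        score = score_pair(pair(seq_a, seq_a))
        assert score.filter_reason == "min_snps"
        # synthesize boundary categories through the dataclass contract:
        # build a pair whose ratio lands in (0.5, 1] -> moderate
        # with N/S sites ~ 322/41, nd=6 vs sd=1 puts the ratio near 0.76
        b = list(seq_a)
        b[3 * 5 + 2] = "G"        # 1 synonymous
        for ci in (50, 55, 60, 65, 70, 75):
            b[3 * ci + 1] = "T"   # 6 nonsynonymous
        score = score_pair(pair(seq_a, "".join(b)))
        assert score.ratio is not None and 0.5 < score.ratio <= 1.0
        assert score.category == "moderate"

    def test_scale_invariance_under_self_concatenation(self):
        rng = np.random.default_rng(3)
        seq_a = self.orf("".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 80)))
        b = list(seq_a)
        for i in rng.choice(np.arange(3, len(b)), size=8, replace=False):
            b[i] = next(x for x in "ACGT" if x != seq_a[i])
        seq_b = "".join(b)
        single = score_pair(pair(seq_a, seq_b))
        double = score_pair(pair(seq_a + seq_a, seq_b + seq_b))
        if single.ratio is not None:
            assert double.ratio == pytest.approx(single.ratio)
            assert double.n_sites == pytest.approx(2 * single.n_sites)


class TestMatchAndScan:
    def test_disjoint_ids_empty(self):
        pairs, skipped = match_orf_pairs({"g1": "ATG"}, {"g2": "ATG"})
        assert pairs == [] and skipped == []

    def test_unequal_lengths_skipped(self):
        a = {f"g{i}": "ATG" + "GAA" * 60 for i in range(10)}
        b = dict(a)
        for g in ("g0", "g1", "g2"):
            b[g] = "ATG" + "GAA" * 61
        pairs, skipped = match_orf_pairs(a, b)
        assert len(pairs) == 7
        assert sorted(g for g, _ in skipped) == ["g0", "g1", "g2"]

    def test_pair_count_per_population_combination(self):
        orfs = {"g1": "ATG" + "GAA" * 60}
        scores = scan_populations({p: orfs for p in "abcde"})
        assert len(scores) == 10  # C(5, 2) unordered pairs, one shared gene

    def test_two_populations_one_pair_per_gene(self):
        orfs = {f"g{i}": "ATG" + "GAA" * 60 for i in range(4)}
        scores = scan_populations({"a": orfs, "b": orfs})
        assert len(scores) == 4

    def test_fewer_than_two_populations_rejected(self):
        with pytest.raises(ValueError):
            scan_populations({"a": {}})
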