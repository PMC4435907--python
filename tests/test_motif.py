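"""PFM/PWM construction, exact score distributions, and scanning."""

import itertools
from collections import defaultdict

import numpy as np
import pytest

import hibtarget as ht
from hibtarget.motif import encode_sequence, reverse_complement

from conftest import random_pfm


class TestReadPfm:
    def test_rows_are_bases(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text("25 25\n25 25\n25 25\n25 25\n")
        pfm = ht.read_pfm(p)
        assert pfm.width == 2
        assert np.allclose(pfm.column_totals, 100)

    def test_transposed_dialect_equals_untransposed(self, tmp_path):
        mat = np.arange(1, 13, dtype=float).reshape(4, 3)
        a = tmp_path / "a.pfm"
        a.write_text("\n".join(" ".join(map(str, row)) for row in mat))
        b = tmp_path / "b.pfm"
        b.write_text("\n".join(" ".join(map(str, row)) for row in mat.T))
        pfm_a = ht.read_pfm(a, dialect="rows-are-bases")
        pfm_b = ht.read_pfm(b, dialect="rows-are-positions")
        assert np.array_equal(pfm_a.counts, pfm_b.counts)

    def test_hand_written_column_totals(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text("A 10 0 3\nC 1 2 3\nG 0 5 3\nT 4 4 3\n")
        pfm = ht.read_pfm(p)
        assert list(pfm.column_totals) == [15, 11, 12]

    def test_base_labels_normalize_order(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text("T 4 4\nG 3 3\nC 2 2\nA 1 1\n")
        pfm = ht.read_pfm(p)
        assert list(pfm.counts[:, 0]) == [1, 2, 3, 4]  # A, C, G, T

    @pytest.mark.parametrize(
        "text", ["1 2\n3 x\n5 6\n7 8\n", "1 2\n3 4\n5 6\n", "1 -2\n3 4\n5 6\n7 8\n"]
    )
    def test_malformed_matrices_rejected(self, tmp_path, text):
        p = tmp_path / "bad.pfm"
        p.write_text(text)
        with pytest.raises(ValueError):
            ht.read_pfm(p)


class TestBackground:
    def test_uniform_sequence(self):
        bg = ht.build_background(["ACGT" * 10], bg_pseudo=0.0)
        assert np.allclose(bg.probs, 0.25)

    def test_smoothing_floor(self):
        bg = ht.build_background(["A" * 100], bg_pseudo=0.01)
        assert bg.probs[0] < 1
        assert np.all(bg.probs[1:] > 0)
        assert np.isclose(bg.probs.sum(), 1)

    def test_gc_rich_composition_recovered(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15], size=10_000))
        bg = ht.build_background([seq], bg_pseudo=0.01)
        assert np.all(np.abs(bg.probs - [0.15, 0.35, 0.35, 0.15]) < 0.02)

    def test_ambiguous_bases_excluded(self):
        bg = ht.build_background(["ACGTNNNN"], bg_pseudo=0.0)
        assert np.allclose(bg.probs, 0.25)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ht.build_background([])


class TestPfmToPwm:
    def test_counts_matching_background_score_zero(self, uniform_bg):
        pfm = ht.PositionFrequencyMatrix(np.full((4, 3), 25.0))
        pwm = ht.pfm_to_pwm(pfm, uniform_bg, pseudocount=1, decimals=1)
        assert np.all(pwm.weights == 0.0)

    def test_hand_evaluated_log_odds(self, uniform_bg):
        pfm = ht.PositionFrequencyMatrix(np.array([[97.0], [1.0], [1.0], [1.0]]))
        pwm = ht.pfm_to_pwm(pfm, uniform_bg, pseudocount=1, decimals=1)
        # round(log2(((97 + 0.25)/101)/0.25), 1) = 1.9
        assert pwm.weights[0, 0] == pytest.approx(1.9)

    def test_weights_on_rounding_lattice(self, dr1_pwm):
        scaled = dr1_pwm.weights * 10
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)

    def test_zero_pseudocount_with_zero_count_rejected(self, uniform_bg):
        pfm = ht.PositionFrequencyMatrix(np.array([[10.0], [0.0], [5.0], [5.0]]))
        with pytest.raises(ValueError):
            ht.pfm_to_pwm(pfm, uniform_bg, pseudocount=0)


class TestScoreDistribution:
    def test_single_column_enumeration(self, uniform_bg):
        pwm = ht.PositionWeightMatrix(
            np.array([[1.0], [0.0], [0.0], [-1.0]]), background=uniform_bg
        )
        dist = ht.score_distribution(pwm)
        probs = dict(zip(dist.scores, dist.probs))
        assert probs[1.0] == pytest.approx(0.25)
        assert probs[0.0] == pytest.approx(0.5)
        assert probs[-1.0] == pytest.approx(0.25)
        assert dist.pvalue(1.0) == pytest.approx(0.25)

    def test_probabilities_sum_to_one_and_tail_monotone(self, dr1_pwm):
        dist = ht.score_distribution(dr1_pwm)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.pvalues) <= 1e-15)

    def test_boundary_pvalues(self, uniform_bg):
        rng = np.random.default_rng(3)
        pfm = random_pfm(rng, 4)
        pwm = ht.pfm_to_pwm(pfm, uniform_bg)
        dist = ht.score_distribution(pwm)
        assert dist.pvalues[0] == pytest.approx(1.0)
        # p-value at the max equals the probability of the argmax word(s)
        consensus_prob = np.prod(
            [uniform_bg.probs[np.argmax(pwm.int_weights[:, j])] for j in range(4)]
        )
        assert dist.pvalues[-1] >= consensus_prob - 1e-12

    def test_dp_equals_exhaustive_enumeration(self, uniform_bg):
        rng = np.random.default_rng(11)
        for width in (2, 3, 4):
            pfm = random_pfm(rng, width)
            bg = ht.BackgroundModel(rng.dirichlet([5, 5, 5, 5]))
            pwm = ht.pfm_to_pwm(pfm, bg)
            dist = ht.score_distribution(pwm)
            acc = defaultdict(float)
            for word in itertools.product(range(4), repeat=width):
                s = sum(int(pwm.int_weights[b, j]) for j, b in enumerate(word))
                acc[s] += float(np.prod([bg.probs[b] for b in word]))
            support = np.array(sorted(acc))
            assert np.array_equal(support, dist.support)
            assert np.allclose([acc[s] for s in support], dist.probs, atol=1e-12)


class TestScan:
    def test_sequence_shorter_than_width(self, dr1_pwm):
        assert ht.scan(dr1_pwm, {"s": "ACGT"}, pval_upper=0.5) == []

    def test_planted_consensus_found_once(self, dr1_pfm, dr1_pwm):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        cons = dr1_pfm.consensus()
        seq = seq[:100] + cons + seq[100 + len(cons) :]
        hits = ht.scan(dr1_pwm, {"s": seq}, pval_upper=5e-7)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 100 and plus[0].end == 100 + dr1_pfm.width
        assert plus[0].score == pytest.approx(dr1_pwm.max_score)

    def test_reverse_complement_strand_symmetry(self, dr1_pfm, dr1_pwm):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        seq = seq[:500] + dr1_pfm.consensus() + seq[500 + dr1_pfm.width :]
        L = len(seq)
        fwd = ht.scan(dr1_pwm, {"s": seq}, pval_upper=1e-4)
        rev = ht.scan(dr1_pwm, {"s": reverse_complement(seq)}, pval_upper=1e-4)
        flipped = sorted(
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+", h.score)
            for h in rev
        )
        assert flipped == sorted((h.start, h.end, h.strand, h.score) for h in fwd)

    def test_windows_with_ambiguous_bases_skipped(self, dr1_pfm, dr1_pwm):
        cons = dr1_pfm.consensus()
        broken = cons[:5] + "N" + cons[6:]
        assert ht.scan(dr1_pwm, {"s": broken}, pval_upper=1.0) == []

    def test_alphabet_error(self, dr1_pwm):
        with pytest.raises(ValueError):
            ht.scan(dr1_pwm, {"s": "ACGTRYACGT" * 3}, pval_upper=1.0)

    def test_hit_pvalues_consistent_with_distribution(self, dr1_pwm):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        dist = ht.score_distribution(dr1_pwm)
        hits = ht.scan(dr1_pwm, {"s": seq}, pval_upper=1e-2)
        assert hits, "loose threshold should produce hits"
        for h in hits:
            assert h.pvalue == pytest.approx(float(dist.pvalue(h.score)))

    def test_scan_deterministic_and_name_order_invariant(self, dr1_pwm):
        rng = np.random.default_rng(7)
        seqs = {
            name: "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
            for name in ("b", "a", "c")
        }
        h1 = ht.scan(dr1_pwm, seqs, pval_upper=1e-3)
        h2 = ht.scan(dr1_pwm, dict(reversed(list(seqs.items()))), pval_upper=1e-3)
        assert h1 == h2
        assert [h.seq_id for h in h1] == sorted(h.seq_id for h in h1)


def test_encode_sequence_codes():
    assert list(encode_sequence("ACGTN")) == [0, 1, 2, 3, 4]
    assert list(encode_sequence("acgtn")) == [0, 1, 2, 3, 4]
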