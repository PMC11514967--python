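import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfdiff.motifs import (PPM, PWM, AlignedSequence, anchor_peak_window,
                           encode, estimate_class_ppms, gini_coefficient,
                           jaspar_roundtrip, mask_core, ppm_to_pwm, read_jaspar,
                           reverse_complement, scan_best_hit, scan_scores,
                           score_threshold, select_pwm_version, write_jaspar)

UNIFORM = np.full((6, 4), 0.25)


class TestJasparIO:
    def test_counts_normalized(self):
        text = ">MA0000.1 X\nA [ 60 0 ]\nC [ 20 100 ]\nG [ 10 0 ]\nT [ 10 0 ]\n"
        ppm = read_jaspar(io.StringIO(text))[0]
        assert np.allclose(ppm.probs.sum(axis=1), 1)
        assert np.allclose(ppm.probs[0], [0.6, 0.2, 0.1, 0.1])
        assert np.allclose(ppm.probs[1], [0, 1, 0, 0])

    def test_zero_column_rejected(self):
        text = ">M X\nA [ 0 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n"
        with pytest.raises(ValueError, match="zero"):
            read_jaspar(io.StringIO(text))

    def test_roundtrip(self, rng):
        p = rng.dirichlet(np.ones(4), size=9)
        ppm = PPM(p, name="RT test")
        back = jaspar_roundtrip(ppm)
        assert np.allclose(back.probs, ppm.probs, atol=1e-9)

    def test_plain_dialect(self, tmp_path):
        f = tmp_path / "m.pfm"
        write_jaspar(PPM(UNIFORM, "u"), str(f), scale=40)
        assert read_jaspar(str(f))[0].length == 6


class TestPpmToPwm:
    def test_uniform_gives_zero(self):
        pwm = ppm_to_pwm(PPM(UNIFORM))
        assert np.allclose(pwm.weights, 0)

    def test_hand_evaluated_formula(self):
        # single certain position, pseudocount 0.01, uniform background
        ppm = PPM(np.array([[1.0, 0, 0, 0]]))
        pwm = ppm_to_pwm(ppm, pseudocount=0.01)
        w_hit = math.log2((1 + 0.01 * 0.25) / (1.01 * 0.25))
        w_miss = math.log2((0 + 0.01 * 0.25) / (1.01 * 0.25))
        assert pwm.weights[0, 0] == pytest.approx(w_hit)
        assert np.allclose(pwm.weights[0, 1:], w_miss)

    def test_zero_prob_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            ppm_to_pwm(PPM(np.array([[1.0, 0, 0, 0]])), pseudocount=0.0)


def brute_force_best(seq, pwm):
    """Enumerate every window on both strands; independent of the scanner."""
    K = pwm.length
    best = None
    for i in range(len(seq) - K + 1):
        for strand, w in ((("+"), seq[i:i + K]),
                          (("-"), reverse_complement(seq[i:i + K]))):
            if "N" in w:
                continue
            s = sum(pwm.weights[k, "ACGT".index(c)] for k, c in enumerate(w))
            if best is None or s > best[0]:
                best = (s, i, strand)
    return best


class TestScanning:
    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(25):
            K = int(rng.integers(4, 10))
            pwm = PWM(rng.normal(size=(K, 4)))
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 200))
            hit = scan_best_hit(seq, pwm)
            ref = brute_force_best(seq, pwm)
            assert hit.score == pytest.approx(ref[0])

    def test_consensus_hit_forward(self):
        w = np.full((5, 4), -1.0)
        for k, c in enumerate("ACGTA"):
            w[k, "ACGT".index(c)] = 1.0
        pwm = PWM(w)
        seq = "GGGGGACGTAGGGGG"
        hit = scan_best_hit(seq, pwm)
        assert (hit.offset, hit.strand, hit.score) == (5, "+", 5.0)

    def test_reverse_complement_symmetry(self, rng):
        pwm = PWM(rng.normal(size=(6, 4)))
        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 80))
        h1 = scan_best_hit(seq, pwm)
        h2 = scan_best_hit(reverse_complement(seq), pwm)
        assert h1.score == pytest.approx(h2.score)
        assert h1.strand != h2.strand or h1.score == pytest.approx(
            scan_scores(encode(seq), pwm).max())

    def test_all_n_returns_none(self):
        pwm = PWM(np.ones((4, 4)))
        assert scan_best_hit("N" * 50, pwm) is None

    def test_span_shorter_than_pwm_errors(self):
        with pytest.raises(ValueError):
            scan_best_hit("ACGTACGT", PWM(np.ones((6, 4))), span=(0, 4))


class TestScoreThreshold:
    def test_matches_exhaustive_enumeration(self, rng):
        # exact tail probabilities by enumerating all 4^K sequences
        K = 5
        pwm = PWM(np.round(rng.normal(size=(K, 4)), 3))
        thr = score_threshold(pwm, 1e-2, precision=1e-4)
        scores = np.zeros(1)
        for k in range(K):
            scores = (scores[:, None] + pwm.weights[k][None, :]).ravel()
        assert (scores >= thr).mean() <= 1e-2
        # one grid step lower would exceed the p-value
        assert (scores >= thr - 2e-4).mean() > 1e-2 or thr <= scores.min()


class TestAnchoring:
    def test_planted_consensus_is_centered(self, core_ppm):
        pwm = ppm_to_pwm(core_ppm)
        cons = pwm.consensus()
        K = len(cons)
        rng = np.random.default_rng(5)
        bg = "".join("ACGT"[j] for j in rng.integers(0, 4, 1100))
        raw = bg[:500] + cons + bg[500 + K:]
        # nominal summit = 550, planted core at 500..511 (within jitter range)
        res = anchor_peak_window(raw, pwm, halfwidth=500)
        assert res is not None
        seq, span, strand = res
        assert len(seq) == 1000
        mid = 500 + K // 2  # hit midpoint in raw coordinates
        assert span == (500 - K // 2, 500 - K // 2 + K)
        assert seq[span[0]:span[1]] in (cons, reverse_complement(cons))

    def test_minus_strand_reoriented(self, core_ppm):
        pwm = ppm_to_pwm(core_ppm)
        cons = pwm.consensus()
        K = len(cons)
        rng = np.random.default_rng(6)
        bg = "".join("ACGT"[j] for j in rng.integers(0, 4, 1100))
        raw = bg[:540] + reverse_complement(cons) + bg[540 + K:]
        seq, span, strand = anchor_peak_window(raw, pwm, halfwidth=500)
        assert strand == "-"
        assert seq[span[0]:span[1]] == cons  # window flipped into motif frame

    def test_no_hit_dropped(self, core_ppm):
        pwm = ppm_to_pwm(core_ppm)
        thr = score_threshold(pwm, 1e-4)
        assert anchor_peak_window("A" * 1100, pwm, threshold=thr) is None


class TestVersionSelection:
    def test_discriminative_version_wins(self, rng):
        good = PPM(np.eye(4)[([0, 1, 2, 3, 0, 1])] * 0.97
                   + (1 - 0.97) / 3 * (1 - np.eye(4)[([0, 1, 2, 3, 0, 1])]))
        decoy = PPM(np.full((6, 4), 0.25))
        cons = "ACGTAC"
        wins_a, wins_b = [], []
        for i in range(40):
            bg = "".join("ACGT"[j] for j in rng.integers(0, 4, 200))
            wins_a.append(bg[:90] + cons + bg[96:])  # class 1 carries the motif
            wins_b.append(bg)
        labels = [1] * 40 + [0] * 40
        idx, pwm, a = select_pwm_version([decoy, good], wins_a + wins_b, labels,
                                         halfwidth=100)
        assert idx == 1
        assert a > 0.8


class TestClassPpms:
    def test_exact_frequencies(self):
        p1, p2 = estimate_class_ppms(["ACGT", "ACGT"], ["AAAA", "CCCC"])
        assert np.allclose(p1.probs, np.eye(4)[[0, 1, 2, 3]])
        assert np.allclose(p2.probs[0], [0.5, 0.5, 0, 0])

    def test_valid_ppm_for_random_input(self, rng):
        sites = ["".join("ACGT"[j] for j in rng.integers(0, 4, 8))
                 for _ in range(30)]
        p1, p2 = estimate_class_ppms(sites[:15], sites[15:])
        assert np.allclose(p1.probs.sum(axis=1), 1)
        assert np.allclose(p2.probs.sum(axis=1), 1)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            estimate_class_ppms(["ACGT"], ["ACG"])


class TestMaskCore:
    def test_mask_and_idempotence(self):
        s = AlignedSequence("AAACGTACGTAAA", 1, core_span=(3, 10))
        m = mask_core(s)
        assert m.seq == "AAA" + "N" * 7 + "AAA"
        assert mask_core(m).seq == m.seq
        assert len(m.seq) == len(s.seq)

    def test_requires_core_span(self):
        with pytest.raises(ValueError):
            mask_core(AlignedSequence("ACGT", 0))


class TestGini:
    def test_equal_weights_zero(self):
        assert gini_coefficient(np.full((5, 4), 0.3)) == pytest.approx(0.0)

    def test_single_nonzero(self):
        for K in (2, 5, 25):
            w = np.zeros((K, 4))
            w[0, 0] = 2.5
            assert gini_coefficient(w) == pytest.approx((4 * K - 1) / (4 * K))

    def test_hand_computed_lorenz(self):
        # |w| = (0, 0, 1, 1, 2): cumulative shares (0, 0, .25, .5, 1);
        # area under the Lorenz polyline = 0.25, so G = (0.5-0.25)/0.5 = 0.5
        assert gini_coefficient(np.array([[0.0, 0.0, 1.0, 1.0, 2.0]])) \
            == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        w = rng.normal(size=(7, 4))
        g = gini_coefficient(w)
        for c in (2.0, -3.5, 1e-6, 1e6):
            assert gini_coefficient(c * w) == pytest.approx(g, abs=1e-12)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            gini_coefficient(np.zeros((3, 4)))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4,
                    max_size=40),
           st.floats(0.01, 1e6))
    def test_scale_invariance_property(self, weights, c):
        w = np.array(weights).reshape(1, -1)
        if np.abs(w).sum() == 0:
            return
        assert gini_coefficient(c * w) == pytest.approx(gini_coefficient(w),
                                                        abs=1e-9)
        assert 0 <= gini_coefficient(w) <= 1
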