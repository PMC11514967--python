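"""Discriminative-PWM learning on aligned fixed-length sites."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tfdiff.dm import (dm_score, extract_core_flank, fit_discriminative_pwm,
                       one_hot_sites, pwm_site_scores, two_ppm_baseline)
from tfdiff.glm import lasso_logistic_path, unpenalized_logistic
from tfdiff.motifs import AlignedSequence, estimate_class_ppms, gini_coefficient
from tfdiff.stats import auroc


def random_sites(rng, n, K, probs=None):
    if probs is None:
        probs = np.full((K, 4), 0.25)
    out = []
    for _ in range(n):
        u = rng.random(K)
        cum = np.cumsum(probs, axis=1)
        out.append("".join("ACGT"[j] for j in (u[:, None] < cum).argmax(axis=1)))
    return out


def site_probs(K, pos, nt, p):
    probs = np.full((K, 4), 0.25)
    probs[pos] = (1 - p) / 3
    probs[pos, "ACGT".index(nt)] = p
    return probs


class TestOneHot:
    def test_rows_sum_to_one_except_n(self):
        X = one_hot_sites(["ACGN"])
        assert X.shape == (1, 4, 4)
        assert list(X[0].sum(axis=1)) == [1, 1, 1, 0]


class TestExtractCoreFlank:
    def test_lengths_and_overflow(self):
        s = AlignedSequence("A" * 20 + "ACGTACGTAC" + "C" * 20, 1, core_span=(20, 30))
        assert extract_core_flank(s, 0) == "ACGTACGTAC"
        assert len(extract_core_flank(s, 4)) == 18
        edge = AlignedSequence("ACGTACGTAC" + "C" * 30, 1, core_span=(0, 10))
        assert extract_core_flank(edge, 4) is None

    def test_requires_core(self):
        with pytest.raises(ValueError):
            extract_core_flank(AlignedSequence("ACGT", 1), 0)


class TestFit:
    def test_perfectly_separable_position(self, rng):
        base = random_sites(rng, 200, 6)
        a = [s[:2] + "A" + s[3:] for s in base[:100]]
        b = [s[:2] + "C" + s[3:] for s in base[100:]]
        d = fit_discriminative_pwm(a, b, seed=0)
        hot = np.abs(d.weights).argmax()
        assert hot in (2 * 4 + 0, 2 * 4 + 1)  # position 2, A or C
        assert d.weights[2, 0] > 0 > d.weights[2, 1]
        scores = pwm_site_scores(a + b, d.weights)
        assert auroc(scores, [1] * 100 + [0] * 100) == 1.0

    def test_no_signal_shrinks_to_zero(self, rng):
        a = random_sites(rng, 150, 5)
        b = random_sites(rng, 150, 5)
        d = fit_discriminative_pwm(a, b, seed=0, lambda_rule="1se")
        assert np.abs(d.weights).max() < 0.25
        held_a = random_sites(rng, 300, 5)
        held_b = random_sites(rng, 300, 5)
        s = pwm_site_scores(held_a + held_b, d.weights)
        assert abs(auroc(s, [1] * 300 + [0] * 300) - 0.5) < 0.1

    def test_binary_feature_closed_form_auroc(self, rng):
        # P(A at pos) 0.9 vs 0.1: AUROC = .9*.9 + .5*(.9*.1+.1*.9) = 0.90
        K, n = 8, 2000
        a = random_sites(rng, n, K, site_probs(K, 3, "A", 0.9))
        b = random_sites(rng, n, K, site_probs(K, 3, "A", 0.1))
        tr = slice(0, int(0.7 * n))
        te = slice(int(0.7 * n), n)
        d = fit_discriminative_pwm(a[tr], b[tr], seed=0)
        s = pwm_site_scores(a[te] + b[te], d.weights)
        n_te = n - int(0.7 * n)
        assert auroc(s, [1] * n_te + [0] * n_te) == pytest.approx(0.90, abs=0.03)

    def test_label_swap_negates_weights(self, rng):
        a = random_sites(rng, 80, 5, site_probs(5, 1, "G", 0.8))
        b = random_sites(rng, 80, 5)
        d1 = fit_discriminative_pwm(a, b, seed=0, penalized=False)
        d2 = fit_discriminative_pwm(b, a, seed=0, penalized=False)
        assert np.allclose(d1.weights, -d2.weights, atol=1e-3)

    def test_unpenalized_matches_independent_optimizer(self, rng):
        # lambda = 0, K <= 3, n <= 50: scipy BFGS on the exact likelihood
        for K in (1, 2, 3):
            a = random_sites(rng, 25, K, site_probs(K, 0, "A", 0.7))
            b = random_sites(rng, 25, K)
            X = one_hot_sites(a + b).reshape(50, -1)
            y = np.r_[np.ones(25), np.zeros(25)]

            def nll(theta):
                eta = X @ theta[:-1] + theta[-1]
                return -(y * eta - np.logaddexp(0, eta)).sum()

            ref = min(minimize(nll, np.zeros(4 * K + 1), method="BFGS",
                               options={"gtol": 1e-9, "maxiter": 2000}).fun
                      for _ in range(1))
            coef, b0 = unpenalized_logistic(X, y)
            ours = nll(np.r_[coef, b0])
            assert ours == pytest.approx(ref, abs=1e-3)


class TestLassoPath:
    def test_sparsity_monotone_in_lambda(self, rng):
        X = rng.normal(size=(120, 12))
        y = (X[:, 0] + 0.5 * X[:, 3] + rng.normal(size=120) > 0).astype(float)
        lams, coefs, _ = lasso_logistic_path(X, y, n_lambdas=25)
        nz = (coefs != 0).sum(axis=1)
        assert nz[0] == 0  # above lambda_max everything is zero
        assert (np.diff(nz) >= -1e-9).all() or nz[-1] >= nz[0]
        # largest lambdas kill everything; smallest keep the signal
        assert coefs[-1, 0] != 0

    def test_penalized_fit_is_simpler(self, rng):
        # Gini of the LASSO PWM >= Gini of the unpenalized fit (sparser model)
        from tfdiff.dm import fit_discriminative_pwm

        for seed in range(3):
            r = np.random.default_rng(seed)
            a = random_sites(r, 120, 8, site_probs(8, 2, "A", 0.85))
            b = random_sites(r, 120, 8)
            d_l1 = fit_discriminative_pwm(a, b, seed=seed)
            d_ml = fit_discriminative_pwm(a, b, seed=seed, penalized=False)
            assert gini_coefficient(d_l1.weights) > gini_coefficient(d_ml.weights)


class TestDmScore:
    def test_zero_pwm_scores_zero(self):
        from tfdiff.dm import DiscriminativePWM
        from tfdiff.motifs import PWM

        d = DiscriminativePWM(PWM(np.zeros((4, 4)), source="discriminative"),
                              0.0, 0.1, 0)
        assert dm_score("ACGT", d) == 0.0

    def test_n_contributes_nothing(self, rng):
        from tfdiff.dm import DiscriminativePWM
        from tfdiff.motifs import PWM

        w = rng.normal(size=(4, 4))
        d = DiscriminativePWM(PWM(w, source="discriminative"), 0.0, 0.1, 0)
        assert dm_score("ANGT", d) == pytest.approx(
            w[0, 0] + w[2, 2] + w[3, 3])

    def test_length_mismatch(self):
        from tfdiff.dm import DiscriminativePWM
        from tfdiff.motifs import PWM

        d = DiscriminativePWM(PWM(np.zeros((4, 4)), source="discriminative"),
                              0.0, 0.1, 0)
        with pytest.raises(ValueError):
            dm_score("ACGTA", d)


class TestTwoPpmBaseline:
    def test_identical_ppms_chance(self, rng):
        sites = random_sites(rng, 200, 6)
        labels = [1] * 100 + [0] * 100
        p1, _ = estimate_class_ppms(sites[:100], sites[100:], pseudocount=1)
        a = two_ppm_baseline(p1, p1, sites, labels, sites, labels)
        assert abs(a - 0.5) < 0.12

    def test_separated_ppms_discriminate(self, rng):
        pa = site_probs(6, 2, "A", 0.9)
        pb = site_probs(6, 2, "T", 0.9)
        a = random_sites(rng, 300, 6, pa)
        b = random_sites(rng, 300, 6, pb)
        sites = a + b
        labels = np.r_[np.ones(300), np.zeros(300)]
        tr = np.zeros(600, dtype=bool)
        tr[:200] = True
        tr[300:500] = True
        p1, p2 = estimate_class_ppms([s for s, t in zip(sites, tr) if t and True][:200],
                                     [s for s, t in zip(sites[300:], tr[300:]) if t],
                                     pseudocount=1)
        av = two_ppm_baseline(p1, p2,
                              [s for s, t in zip(sites, tr) if t], labels[tr],
                              [s for s, t in zip(sites, tr) if not t], labels[~tr])
        assert av > 0.85

    def test_never_beats_discriminative_by_much(self, rng):
        K, n = 6, 800
        a = random_sites(rng, n, K, site_probs(K, 2, "A", 0.9))
        b = random_sites(rng, n, K, site_probs(K, 2, "A", 0.1))
        ntr = int(0.7 * n)
        labels_te = [1] * (n - ntr) + [0] * (n - ntr)
        d = fit_discriminative_pwm(a[:ntr], b[:ntr], seed=0)
        dm_auc = auroc(pwm_site_scores(a[ntr:] + b[ntr:], d.weights), labels_te)
        p1, p2 = estimate_class_ppms(a[:ntr], b[:ntr], pseudocount=1)
        two = two_ppm_baseline(p1, p2, a[:ntr] + b[:ntr],
                               [1] * ntr + [0] * ntr,
                               a[ntr:] + b[ntr:], labels_te)
        assert two <= dm_auc + 0.02
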