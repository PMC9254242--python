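"""Association cascade primitives: OPLS-DA VIP, adjusted logistic, BH-FDR,
fixed-effect meta-analysis, proportional-odds progression regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from lipidcascade.association import (SeparationError, adjusted_logistic,
                                      bh_fdr, firth_logistic, meta_fixed,
                                      oplsda_vip, ordinal_progression,
                                      run_cascade)

from conftest import cohort_views, small_config
from lipidcascade.cohort import generate_cohort


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_logistic_mle(x, y, lo=-8.0, hi=8.0, rounds=6, pts=41):
    """Brute-force grid-search MLE of logit(y) = a + b x, refined to <1e-4."""
    def nll(a, b):
        eta = a + b * x[None, None, :] if np.ndim(a) else a + b * x
        eta = np.clip(eta, -40, 40)
        return -(y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)
    a_lo = b_lo = lo
    a_hi = b_hi = hi
    for _ in range(rounds):
        A = np.linspace(a_lo, a_hi, pts)
        B = np.linspace(b_lo, b_hi, pts)
        L = nll(A[:, None, None], B[None, :, None])
        i, j = np.unravel_index(np.argmin(L), L.shape)
        da = (a_hi - a_lo) / (pts - 1)
        db = (b_hi - b_lo) / (pts - 1)
        a_lo, a_hi = A[i] - 2 * da, A[i] + 2 * da
        b_lo, b_hi = B[j] - 2 * db, B[j] + 2 * db
    return A[i], B[j]


def grid_ordinal_mle(x, y3):
    """Brute-force MLE of a 3-level proportional-odds model via scipy on the
    exact likelihood (independent parameterization from the implementation)."""
    def nll(theta):
        t1, dt, b = theta
        t2 = t1 + np.exp(dt)
        eta = b * x
        p0 = 1 / (1 + np.exp(-(t1 - eta)))
        p1 = 1 / (1 + np.exp(-(t2 - eta))) - p0
        p2 = 1 - p0 - p1
        probs = np.stack([p0, p1, p2]).clip(1e-12)
        return -np.log(probs[y3, np.arange(len(x))]).sum()
    best = None
    for start in ([-1, 0, 0], [0, 0.5, -1], [0.5, -0.5, 1]):
        r = optimize.minimize(nll, start, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10,
                                       "maxiter": 5000})
        if best is None or r.fun < best.fun:
            best = r
    return best.x[2]


class TestVIP:
    def test_vip_normalization_identity(self, rng):
        X = rng.standard_normal((40, 25))
        y = rng.integers(0, 2, 40)
        vip = oplsda_vip(X, y)
        assert abs((vip ** 2).sum() - 25) < 1e-8

    def test_informative_variable_above_one(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        X = np.column_stack([y + 0.05 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        vip = oplsda_vip(X, y)
        assert vip[0] > 1 > vip[1]
        # cross-check against a direct single-component PLS1 weight vector
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w = np.abs(w / np.linalg.norm(w)) * np.sqrt(2)
        assert vip[0] == pytest.approx(w[0], rel=0.1)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="classes"):
            oplsda_vip(rng.standard_normal((10, 3)), np.ones(10))

    def test_zero_variance_column_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            oplsda_vip(X, rng.integers(0, 2, 10))


class TestLogistic:
    def test_matches_grid_search_oracle_on_tiny_data(self):
        x = np.array([-1.2, -0.5, -0.1, 0.3, 0.8, 1.1, 1.9, -2.0])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 0.0])
        res = adjusted_logistic(x, y)
        a, b = grid_logistic_mle(x, y)
        assert res.beta == pytest.approx(b, abs=1e-4)

    def test_rescaling_identity(self, rng):
        x = rng.standard_normal(60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(float)
        r1 = adjusted_logistic(x, y)
        r2 = adjusted_logistic(3.0 * x, y)
        assert r1.beta == pytest.approx(3.0 * r2.beta, rel=1e-6)

    def test_null_lipid_or_near_one(self, rng):
        x = rng.standard_normal(4000)
        y = rng.integers(0, 2, 4000).astype(float)
        r = adjusted_logistic(x, y)
        assert abs(r.beta) < 3 * r.se
        assert r.ci_low <= r.or_ <= r.ci_high

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)] + np.linspace(0, 0.1, 20)
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            adjusted_logistic(x, y)

    def test_firth_fallback_finite_on_separated_data(self):
        x = np.r_[np.linspace(-2, -1, 8), np.linspace(1, 2, 8)]
        y = np.r_[np.zeros(8), np.ones(8)]
        X = np.column_stack([np.ones(16), x])
        beta, se = firth_logistic(X, y)
        assert np.all(np.isfinite(beta)) and np.all(np.isfinite(se))
        assert 0 < beta[1] < 15


class TestFDR:
    def test_single_p_equals_q(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_monotone_and_order_invariant(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        q2 = bh_fdr(np.asarray(ps)[perm])
        np.testing.assert_allclose(q2, q[perm])
        assert np.all(q >= np.asarray(ps) - 1e-12)


class TestMeta:
    def test_identical_studies_closed_form(self):
        r = meta_fixed([(0.4, 0.1), (0.4, 0.1)])
        assert r.beta == pytest.approx(0.4)
        assert r.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_computed_pooling(self):
        r = meta_fixed([(-0.5, 0.2), (-0.3, 0.4)])
        assert r.beta == pytest.approx(-0.46, abs=5e-4)
        assert r.se == pytest.approx(0.1789, abs=5e-5)

    def test_pooled_se_below_component_ses(self, rng):
        effs = [(float(b), float(s)) for b, s in
                zip(rng.standard_normal(4), rng.uniform(0.1, 0.5, 4))]
        r = meta_fixed(effs)
        assert r.se <= min(s for _, s in effs)

    def test_weighted_mean_identity(self):
        effs = [(0.2, 0.1), (-0.1, 0.3), (0.5, 0.2)]
        w = np.array([1 / s ** 2 for _, s in effs])
        b = np.array([b for b, _ in effs])
        assert meta_fixed(effs).beta == pytest.approx((w @ b) / w.sum())

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([(0.1, 0.0), (0.2, 0.1)])


class TestOrdinal:
    def test_matches_direct_mle_oracle_on_tiny_data(self):
        x = np.array([0.13, -0.13, 0.64, 0.1, -0.54, 0.36, 1.3, 0.95, -0.7, -1.27])
        y = np.array([2, 0, 2, 0, 1, 0, 2, 2, 0, 0])
        res = ordinal_progression(x, y)
        assert res.beta == pytest.approx(grid_ordinal_mle(x, y), abs=1e-4)

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        latent = -0.5 * x + rng.logistic(size=n)
        y = np.digitize(latent, [-1.0, 1.0])
        r = ordinal_progression(x, y)
        assert abs(r.beta - (-0.5)) < 2 * r.se

    def test_collapsed_binary_consistent_under_proportional_odds(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        latent = 0.7 * x + rng.logistic(size=n)
        y = np.digitize(latent, [-1.0, 1.0])
        r_ord = ordinal_progression(x, y)
        r_bin = adjusted_logistic(x, (y == 2).astype(float))
        assert abs(r_ord.beta - r_bin.beta) < 2 * np.hypot(r_ord.se, r_bin.se)

    def test_null_or_near_one(self, rng):
        x = rng.standard_normal(3000)
        y = rng.integers(0, 3, 3000)
        r = ordinal_progression(x, y)
        assert abs(r.beta) < 3 * r.se

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            ordinal_progression(np.arange(5.0), np.ones(5))


class TestCascade:
    def test_counts_non_increasing_and_signals_recovered(self):
        bundle = generate_cohort(small_config(seed=2))
        trace, records = run_cascade(*cohort_views(bundle))
        c = trace.counts()
        assert all(a >= b for a, b in zip(c, c[1:]))
        assert trace.identified == 60
        survivors = set(records.attrs["surviving_lipids"])
        assert survivors <= set(bundle.lipids.lipid_ids)

    def test_record_table_schema(self, small_bundle):
        _, records = run_cascade(*cohort_views(small_bundle))
        assert {"lipid_id", "comparison", "stage", "OR", "p"} <= set(records.columns)
        fitted = records[records["OR"].notna()]
        assert (fitted["OR"] > 0).all()
        assert ((fitted["p"] > 0) & (fitted["p"] <= 1)).all()
        assert (fitted["ci_low"] <= fitted["OR"] + 1e-12).all()
        assert (fitted["OR"] <= fitted["ci_high"] + 1e-12).all()
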