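"""Differential-expression machinery against independent oracles.

The NB exact test is checked against a from-scratch enumeration of the
conditional split distribution written with raw log-gammas (no shared code),
against the exact binomial test in the zero-dispersion limit, and against
Monte-Carlo null calibration.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dosagebalance.diffexpr import (
    bh_adjust,
    call_dems,
    de_test,
    equalize_libraries,
    estimate_dispersion,
    nb_exact_test,
    ratio_t_test,
)
from dosagebalance.preprocess import CountMatrix, rpm_normalize


def enumeration_oracle(counts_a, counts_b, phi):
    """Brute-force conditional-distribution p-value via raw log-gamma pmfs."""
    sa, sb = sum(counts_a), sum(counts_b)
    t, na, nb = sa + sb, len(counts_a), len(counts_b)
    if t == 0:
        return 1.0

    def log_nb(k, r, m):
        return (
            math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(r / (r + m)) + (k * math.log(m / (r + m)) if k else 0.0)
        )

    def log_binom(k, n, p):
        return (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + (k * math.log(p) if k else 0.0)
            + ((n - k) * math.log1p(-p) if n - k else 0.0)
        )

    if phi == 0:
        logq = [log_binom(a, t, na / (na + nb)) for a in range(t + 1)]
    else:
        mu = t / (na + nb)
        ra, rb = na / phi, nb / phi
        logq = [
            log_nb(a, ra, na * mu) + log_nb(t - a, rb, nb * mu) for a in range(t + 1)
        ]
    mx = max(logq)
    z = mx + math.log(sum(math.exp(v - mx) for v in logq))
    logq = [v - z for v in logq]
    obs = logq[sa]
    return min(1.0, sum(math.exp(v) for v in logq if v <= obs + 1e-12))


class TestNbExactTest:
    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 1.0])
    def test_matches_enumeration_oracle(self, phi, rng):
        for _ in range(60):
            t = int(rng.integers(1, 201))
            sa = int(rng.integers(0, t + 1))
            na, nb = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            ca = [sa] + [0] * (na - 1)
            cb = [t - sa] + [0] * (nb - 1)
            p = nb_exact_test(ca, cb, phi)
            assert p == pytest.approx(enumeration_oracle(ca, cb, phi), abs=1e-9)

    def test_small_two_replicate_case_enumeration(self):
        p = nb_exact_test([2, 3], [10, 12], 0.1)
        assert p == pytest.approx(enumeration_oracle([2, 3], [10, 12], 0.1), abs=1e-12)

    def test_zero_dispersion_equals_exact_binomial(self, rng):
        for _ in range(40):
            t = int(rng.integers(1, 150))
            sa = int(rng.integers(0, t + 1))
            p_nb = nb_exact_test([sa], [t - sa], 0.0)
            p_binom = stats.binomtest(sa, t, 0.5).pvalue
            assert p_nb == pytest.approx(p_binom, abs=1e-9)

    def test_unequal_group_sizes_shift_the_null_share(self):
        # with 3 libraries vs 1 at equal size, the null share of group A is 3/4
        p_nb = nb_exact_test([10, 0, 0], [2], 0.0)
        p_binom = stats.binomtest(10, 12, 0.75).pvalue
        assert p_nb == pytest.approx(p_binom, abs=1e-9)

    def test_identical_group_rates_give_p_one(self):
        assert nb_exact_test([5, 5], [5, 5], 0.1) == pytest.approx(1.0)
        assert nb_exact_test([0], [0], 0.3) == 1.0

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=3),
        st.lists(st.integers(0, 50), min_size=1, max_size=3),
        st.sampled_from([0.0, 0.1, 0.5]),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetric_under_group_swap(self, ca, cb, phi):
        assert nb_exact_test(ca, cb, phi) == pytest.approx(
            nb_exact_test(cb, ca, phi), abs=1e-10
        )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], -0.1)

    def test_library_size_equalization(self):
        # doubling group-B libraries halves its effective counts
        p_unequal = nb_exact_test([10, 10], [20, 20], 0.0, library_sizes=[1000, 1000, 2000, 2000])
        p_equal = nb_exact_test([10, 10], [10, 10], 0.0, library_sizes=[1000] * 4)
        assert p_unequal == pytest.approx(p_equal, rel=1e-6)


class TestDispersionEstimation:
    def _cm(self, y, reps):
        df = pd.DataFrame(y, columns=[f"s{i}" for i in range(2 * reps)])
        return CountMatrix(df, {f"s{i}": ("A" if i < reps else "B") for i in range(2 * reps)})

    def test_poisson_counts_estimate_near_zero(self, rng):
        mu = rng.lognormal(3, 1, 200)
        y = rng.poisson(mu[:, None], (200, 8))
        est = estimate_dispersion(self._cm(y, 4), [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert est.common < 0.05

    def test_nb_dispersion_recovered(self, rng):
        phi, r = 0.2, 5.0
        mu = rng.lognormal(3, 1, 500)
        y = rng.negative_binomial(r, r / (r + mu[:, None]), (500, 8))
        est = estimate_dispersion(self._cm(y, 4), [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert 0.1 <= est.common <= 0.3

    def test_single_feature_tagwise_equals_common(self):
        cm = self._cm(np.array([[3, 5, 4, 6]]), 2)
        est = estimate_dispersion(cm, ["s0", "s1"], ["s2", "s3"])
        assert est.tagwise.iloc[0] == pytest.approx(est.common)

    def test_full_shrinkage_returns_common_everywhere(self, rng):
        y = rng.poisson(20, (50, 6))
        cm = self._cm(y, 3)
        est = estimate_dispersion(
            cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"], shrinkage_weight=1.0
        )
        assert np.allclose(est.tagwise.values, est.common)

    def test_all_zero_matrix_is_an_error(self):
        cm = self._cm(np.zeros((5, 4), dtype=int), 2)
        with pytest.raises(ValueError):
            estimate_dispersion(cm, ["s0", "s1"], ["s2", "s3"])


class TestBhAdjust:
    def test_closed_form_small_case(self):
        fdr = bh_adjust([0.01, 0.02, 0.03])
        assert fdr == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_order_preserving(self, rng):
        p = rng.uniform(size=30)
        fdr = bh_adjust(p)
        # monotone mapping: a smaller p never gets a larger fdr
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)

    def test_null_uniform_yields_no_discoveries(self, rng):
        hits = 0
        for _ in range(200):
            fdr = bh_adjust(rng.uniform(size=1000))
            hits += int((fdr < 0.05).sum() > 0)
        # global-null BH family-wise discovery rate is at most ~alpha
        assert hits / 200 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDems:
    def test_boundary_is_strict(self):
        res = pd.DataFrame(
            {"logFC": [1.0, -1.0], "fdr": [0.049, 0.05]}, index=["a", "b"]
        )
        dems, counts = call_dems(res)
        assert list(dems.index) == ["a"]
        assert counts == {"up": 1, "down": 0, "total": 1}


class TestRatioTTest:
    def test_identical_ratio_sets_give_p_one(self):
        t, p = ratio_t_test([0.1, 0.2, 0.15], [0.1, 0.2, 0.15])
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        t, p = ratio_t_test([0.1, 0.2, 0.15], [0.5, 0.6, 0.55])
        # closed-form two-sample t with 4 df
        expected = stats.ttest_ind([0.1, 0.2, 0.15], [0.5, 0.6, 0.55]).pvalue
        assert p == pytest.approx(expected)
        assert p < 0.01

    def test_zero_variance_equal_means(self):
        assert ratio_t_test([0.3, 0.3], [0.3, 0.3])[1] == 1.0

    def test_null_type_i_error(self, rng):
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            _, p = ratio_t_test(rng.normal(size=3), rng.normal(size=3))
            hits += int(p < 0.05)
        assert abs(hits / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestDeTable:
    @staticmethod
    def _simulate_comparison(rng, n_null, n_true, reps, phi, fc, mu0=200.0):
        mu = np.full(n_null + n_true, mu0)
        mu_b = mu.copy()
        mu_b[n_null:] *= fc
        r = 1 / phi
        ya = rng.negative_binomial(r, r / (r + mu[:, None]), (n_null + n_true, reps))
        yb = rng.negative_binomial(r, r / (r + mu_b[:, None]), (n_null + n_true, reps))
        cols = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
        df = pd.DataFrame(np.hstack([ya, yb]), columns=cols,
                          index=[f"f{i}" for i in range(n_null + n_true)])
        cm = CountMatrix(df, {c: c[0].upper() for c in cols})
        nm = rpm_normalize(cm, {c: 1_000_000 for c in cols})
        res = de_test(cm, nm, [f"b{i}" for i in range(reps)], [f"a{i}" for i in range(reps)])
        return res, [f"f{i}" for i in range(n_null, n_null + n_true)]

    def test_power_on_known_effects(self, rng):
        """1.5-fold effects at dispersion 0.05, 3 reps: detection well above the
        null rate, logFC estimates centred on the truth (bounds from a 60-rep
        Monte-Carlo calibration of these exact conditions)."""
        res, true_ids = self._simulate_comparison(rng, 180, 20, 3, 0.05, 1.5)
        raw_hits = int((res.loc[true_ids, "p"] < 0.05).sum())
        null_ids = [f for f in res.index if f not in true_ids]
        null_hits = int((res.loc[null_ids, "p"] < 0.05).sum())
        assert raw_hits >= 5                       # null expectation is 1
        assert null_hits <= 20                     # 180 * 0.05 = 9 expected
        assert res.loc[true_ids, "logFC"].mean() == pytest.approx(np.log2(1.5), abs=0.15)

    def test_power_monotone_in_fold_change_and_replicates(self, rng):
        res_weak, t1 = self._simulate_comparison(rng, 0, 150, 3, 0.05, 1.5)
        res_strong, t2 = self._simulate_comparison(rng, 0, 150, 3, 0.05, 3.0)
        res_more_reps, t3 = self._simulate_comparison(rng, 0, 150, 6, 0.05, 1.5)
        weak = (res_weak.loc[t1, "p"] < 0.05).mean()
        assert (res_strong.loc[t2, "p"] < 0.05).mean() > weak
        assert (res_more_reps.loc[t3, "p"] < 0.05).mean() > weak

    def test_equalize_libraries_targets_geometric_mean(self):
        df = pd.DataFrame({"s1": [100], "s2": [100]})
        libs = pd.Series({"s1": 1000.0, "s2": 4000.0})
        out = equalize_libraries(df, libs)
        # geometric mean 2000: s1 scales x2, s2 scales x0.5
        assert out["s1"].iloc[0] == 200 and out["s2"].iloc[0] == 50
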