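import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dosagebalance.dosage import (
    ComparisonEvidence,
    ComparisonSpec,
    apply_control_exclusion,
    classify_cis_response,
    classify_trans_response,
    compute_ratios,
    expected_ratios,
    kmeans_1d,
    median_trans_ratio,
)
from dosagebalance.preprocess import NormalizedMatrix


def _cmp(name, d_e, d_c, series="diploid_aneuploid", line="L1"):
    return ComparisonSpec(name, ("E",), ("C",), (d_e, d_c), series, line)


class TestExpectedRatios:
    # the analytic reference lines: inverse = d_c/d_e, direct = d_e/d_c
    @pytest.mark.parametrize(
        "d_e,d_c,inverse,direct",
        [
            (1, 2, 2.0, 0.5),    # monosomy / diploid
            (3, 2, 0.67, 1.5),   # trisomy / diploid
            (4, 2, 0.5, 2.0),    # tetrasomy / diploid
            (4, 3, 0.75, 1.33),  # tetrasomy / trisomy
            (2, 1, 0.5, 2.0),    # disomy / haploid
            (1, 2, 2.0, 0.5),    # haploid / diploid (ploidy series)
            (3, 2, 0.67, 1.5),   # triploid / diploid
        ],
    )
    def test_reference_lines(self, d_e, d_c, inverse, direct):
        r = expected_ratios(_cmp("c", d_e, d_c))
        assert r.inverse_fc == inverse
        assert r.direct_fc == direct

    def test_product_is_exactly_one(self):
        for d_e, d_c in itertools.product(range(1, 5), range(1, 5)):
            r = expected_ratios(_cmp("c", d_e, d_c))
            assert r.direct * r.inverse == 1

    def test_degenerate_comparison_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = expected_ratios(_cmp("c", 2, 2))
        assert r.direct_fc == r.inverse_fc == 1.0


def _nm(data, genotype_of):
    df = pd.DataFrame(data)
    return NormalizedMatrix(df, pd.Series(1, index=df.columns), genotype_of)


class TestComputeRatios:
    def _setup(self, exp_vals, ctl_vals):
        data = {}
        for i, v in enumerate(zip(*exp_vals)):
            data[f"e{i}"] = list(v)
        for i, v in enumerate(zip(*ctl_vals)):
            data[f"c{i}"] = list(v)
        genotype = {s: ("E" if s.startswith("e") else "C") for s in data}
        return _nm(data, genotype)

    def test_group_mean_ratio(self):
        nm = self._setup([[8, 12]], [[4, 6]])
        fc = compute_ratios(nm, _cmp("1D/2D", 1, 2), [0])
        assert fc.iloc[0] == pytest.approx(2.0)

    def test_zero_control_mean_is_undefined(self):
        nm = self._setup([[5, 5]], [[0, 0]])
        fc = compute_ratios(nm, _cmp("c", 1, 2), [0])
        assert np.isnan(fc.iloc[0])

    def test_empty_kept_set(self):
        nm = self._setup([[1, 1]], [[1, 1]])
        fc = compute_ratios(nm, _cmp("c", 1, 2), [])
        assert fc.empty

    def test_median_excludes_undefined(self):
        s = pd.Series([0.5, 0.67, 2.0, np.nan], index=list("abcd"))
        assert median_trans_ratio(s, list("abcd")) == pytest.approx(0.67)
        assert median_trans_ratio(pd.Series([1.0, 1.0], index=["a", "b"]), ["a", "b"]) == 1.0

    def test_median_requires_defined_values(self):
        with pytest.raises(ValueError):
            median_trans_ratio(pd.Series([np.nan], index=["a"]), ["a"])


def _sse(vals):
    v = np.asarray(vals, dtype=float)
    return ((v - v.mean()) ** 2).sum() if len(v) else 0.0


def brute_force_kmeans(values, k=2):
    """Exhaustive search over all assignments (oracle for small n)."""
    n = len(values)
    best = math.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        cost = sum(
            _sse([values[i] for i in range(n) if assign[i] == c]) for c in range(k)
        )
        best = min(best, cost)
    return best


def _dp_objective(values, k=2):
    labels, _ = kmeans_1d(values, k)
    return sum(_sse(np.asarray(values)[labels == c]) for c in range(k))


class TestKmeans1d:
    def test_separated_groups(self):
        vals = [0.9, 1.0, 1.1, 1.9, 2.0, 2.1]
        labels, centers = kmeans_1d(vals, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert sorted(centers) == pytest.approx([1.0, 2.0])

    def test_matches_exhaustive_oracle_up_to_n12(self, rng):
        for n in range(2, 13):
            vals = list(np.round(rng.uniform(0, 3, n), 3))
            assert _dp_objective(vals) == pytest.approx(brute_force_kmeans(vals), abs=1e-9)

    def test_beats_or_ties_lloyd_restarts(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 5, int(rng.integers(4, 20)))
            dp = _dp_objective(list(vals))
            for _ in range(20):
                centers = rng.choice(vals, 2, replace=False)
                for _ in range(30):
                    d = np.abs(vals[:, None] - centers[None, :])
                    lab = d.argmin(axis=1)
                    if len(set(lab)) < 2:
                        break
                    new = np.array([vals[lab == c].mean() for c in range(2)])
                    if np.allclose(new, centers):
                        break
                    centers = new
                lloyd = sum(_sse(vals[lab == c]) for c in range(2))
                assert dp <= lloyd + 1e-9

    def test_deterministic(self, rng):
        vals = list(rng.uniform(0, 1, 15))
        l1, c1 = kmeans_1d(vals)
        l2, c2 = kmeans_1d(vals)
        assert np.array_equal(l1, l2) and np.array_equal(c1, c2)

    def test_degenerate_identical_values(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_1d([1.0, 1.0, 1.0], 2)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            kmeans_1d([1.0], 2)


class TestControlExclusion:
    def test_removes_b_responsive_features(self):
        out = apply_control_exclusion(["m1", "m2", "m3", "m4", "m5"], ["m1", "m2"])
        assert list(out) == ["m3", "m4", "m5"]

    def test_empty_dem_set_is_identity(self):
        out = apply_control_exclusion(["m1", "m2"], [])
        assert list(out) == ["m1", "m2"]


def _ev(name, d_e, d_c, series, logfc, fdr, fc=None):
    if fc is None:
        fc = 2.0 ** logfc
    return ComparisonEvidence(name, d_e, d_c, series, logfc, fdr, fc)


DIP = "diploid_aneuploid"
HAP = "haploid_aneuploid"
SIG, NS = 0.01, 0.5


class TestCisClassification:
    def test_dosage_tracking_series_is_direct(self):
        # cis RPM ~ {1D:5, 2D:10, 3D:15}: down in 1D/2D, up in 3D/2D
        evs = [
            _ev("1D/2D", 1, 2, DIP, math.log2(0.5), SIG),
            _ev("3D/2D", 3, 2, DIP, math.log2(1.5), SIG),
        ]
        assert classify_cis_response("m", "L", evs).label == "direct_dosage"

    def test_opposing_series_is_negative_dosage(self):
        evs = [
            _ev("1D/2D", 1, 2, DIP, 1.0, SIG),
            _ev("3D/2D", 3, 2, DIP, -0.6, SIG),
        ]
        assert classify_cis_response("m", "L", evs).label == "negative_dosage"

    def test_flat_insignificant_series_is_compensation(self):
        evs = [
            _ev("1D/2D", 1, 2, DIP, math.log2(0.85), NS),
            _ev("3D/2D", 3, 2, DIP, math.log2(1.1), NS),
        ]
        assert classify_cis_response("m", "L", evs).label == "compensation"

    def test_large_insignificant_ratio_is_unclassified(self):
        evs = [_ev("1D/2D", 1, 2, DIP, math.log2(1.8), NS)]
        assert classify_cis_response("m", "L", evs).label == "unclassified"

    def test_up_in_both_directions_is_increased(self):
        evs = [
            _ev("1D/2D", 1, 2, DIP, 0.8, SIG),
            _ev("3D/2D", 3, 2, DIP, 0.7, SIG),
        ]
        assert classify_cis_response("m", "L", evs).label == "increased"

    def test_down_in_both_directions_is_decreased(self):
        evs = [
            _ev("1D/2D", 1, 2, DIP, -0.8, SIG),
            _ev("4D/2D", 4, 2, DIP, -0.7, SIG),
        ]
        assert classify_cis_response("m", "L", evs).label == "decreased"

    def test_conflicting_series_is_mixed(self):
        # dosage-tracking on the diploid background, opposing on the haploid one
        evs = [
            _ev("3D/2D", 3, 2, DIP, 0.6, SIG),
            _ev("h2D/h1D", 2, 1, HAP, -0.6, SIG),
        ]
        assert classify_cis_response("m", "L", evs).label == "mixed"

    def test_no_evidence_is_unclassified(self):
        assert classify_cis_response("m", "L", []).label == "unclassified"

    def test_single_significant_aligned_call_suffices_for_direct(self):
        evs = [
            _ev("1D/2D", 1, 2, DIP, -1.0, SIG),
            _ev("3D/2D", 3, 2, DIP, 0.2, NS),
        ]
        assert classify_cis_response("m", "L", evs).label == "direct_dosage"

    def test_invariant_to_evidence_order(self, rng):
        evs = [
            _ev("1D/2D", 1, 2, DIP, -1.0, SIG),
            _ev("3D/2D", 3, 2, DIP, 0.6, SIG),
            _ev("h2D/h1D", 2, 1, HAP, 0.9, SIG),
        ]
        labels = set()
        for perm in itertools.permutations(evs):
            labels.add(classify_cis_response("m", "L", list(perm)).label)
        assert len(labels) == 1


def trans_truth_table_oracle(a, b, c):
    """Hand-enumerated expected label for directions in (1D/2D, 3D/2D, h2D/h1D).

    a: direction in the monosomy comparison (segment dosage decreased),
    b: trisomy comparison (increased), c: disomy/haploid comparison (increased);
    each one of 'u' (significant up), 'd' (significant down), 'n' (ns).
    """
    table = {
        ("n", "n", "n"): "unclassified",
        ("u", "n", "n"): "unclassified",
        ("d", "n", "n"): "unclassified",
        ("n", "u", "n"): "unclassified",
        ("n", "d", "n"): "unclassified",
        ("n", "n", "u"): "unclassified",
        ("n", "n", "d"): "unclassified",
        ("u", "u", "n"): "increased",
        ("u", "d", "n"): "inverse_trans",
        ("u", "n", "u"): "increased",
        ("u", "n", "d"): "inverse_trans",
        ("d", "u", "n"): "positive_trans",
        ("d", "d", "n"): "decreased",
        ("d", "n", "u"): "positive_trans",
        ("d", "n", "d"): "decreased",
        ("n", "u", "u"): "positive_trans",
        ("n", "u", "d"): "mixed",
        ("n", "d", "u"): "mixed",
        ("n", "d", "d"): "inverse_trans",
        ("u", "u", "u"): "increased",
        ("u", "u", "d"): "mixed",
        ("u", "d", "u"): "mixed",
        ("u", "d", "d"): "inverse_trans",
        ("d", "u", "u"): "positive_trans",
        ("d", "u", "d"): "mixed",
        ("d", "d", "u"): "mixed",
        ("d", "d", "d"): "decreased",
    }
    return table[(a, b, c)]


class TestTransClassification:
    @pytest.mark.parametrize("pattern", list(itertools.product("udn", repeat=3)))
    def test_full_truth_table(self, pattern):
        a, b, c = pattern
        lf = {"u": 1.0, "d": -1.0, "n": 0.1}
        sg = {"u": SIG, "d": SIG, "n": NS}
        evs = [
            _ev("1D/2D", 1, 2, DIP, lf[a], sg[a]),
            _ev("3D/2D", 3, 2, DIP, lf[b], sg[b]),
            _ev("h2D/h1D", 2, 1, HAP, lf[c], sg[c]),
        ]
        call = classify_trans_response("m", "L", evs)
        assert call.label == trans_truth_table_oracle(a, b, c), pattern

    def test_disomy_only_evidence_is_classifiable(self):
        evs = [_ev("h2D/h1D", 2, 1, HAP, 1.0, SIG)]
        assert classify_trans_response("m", "L", evs).label == "positive_trans"
        evs = [_ev("h2D/h1D", 2, 1, HAP, -1.0, SIG)]
        assert classify_trans_response("m", "L", evs).label == "inverse_trans"

    def test_no_evidence_is_unclassified(self):
        assert classify_trans_response("m", "L", []).label == "unclassified"
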