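"""Rank tests against exhaustive-enumeration oracles; effect sizes; KDE."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

import tissuedc as t
from tissuedc.exceptions import DegenerateInputError, ParameterError


# -- independent enumeration oracles (hand-rolled midranks, itertools) -------

def midranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mwu_oracle(x, y):
    """Exact two-sided P: deviation of U from n*m/2 over all assignments."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks = midranks(pooled)
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2
    mean = n * m / 2
    hits = total = 0
    for subset in combinations(range(n + m), n):
        u = sum(ranks[i] for i in subset) - n * (n + 1) / 2
        total += 1
        if abs(u - mean) >= abs(u_obs - mean) - 1e-9:
            hits += 1
    return u_obs, hits / total


def wilcoxon_oracle(d):
    """Exact two-sided P over all 2^n sign patterns of |differences|."""
    d = [v for v in d if v != 0]
    n = len(d)
    ranks = midranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    mean = n * (n + 1) / 4
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            hits += 1
    return w_obs, hits / 2**n


# -- Mann-Whitney -------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = t.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)  # 2 of 20 arrangements

    def test_interleaved_pair_counting(self):
        res = t.mann_whitney_u([1, 3], [2, 4])
        assert res.statistic == 1  # one of four pairs has x > y

    def test_identical_samples(self):
        res = t.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(3 * 3 / 2)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_all_small_sizes(self):
        """Exact P equals the permutation distribution for all n, m <= 6."""
        rng = np.random.default_rng(17)
        for n, m in product(range(2, 7), range(2, 7)):
            x = np.round(rng.normal(0, 1, n), 1)
            y = np.round(rng.normal(0.5, 1, m), 1)
            u_oracle, p_oracle = mwu_oracle(x, y)
            res = t.mann_whitney_u(x, y)
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        x, y = [1, 2, 2, 5], [2, 3, 3, 8]
        u_oracle, p_oracle = mwu_oracle(x, y)
        res = t.mann_whitney_u(x, y)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(1, 1, 40)
        res = t.mann_whitney_u(x, y)
        assert 0 < res.p_value < 0.05
        assert res.z < 0

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            t.mann_whitney_u([], [1.0])


# -- Wilcoxon -----------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_extremum(self):
        res = t.wilcoxon_signed_rank(np.arange(2.0, 10.0), np.ones(8))
        assert res.statistic == 8 * 9 / 2  # W+ = n(n+1)/2 = 36

    def test_matches_sign_pattern_enumeration(self):
        d = [1, -2, 3, -4, 5, 6, 7, 8]
        w_oracle, p_oracle = wilcoxon_oracle(d)
        res = t.wilcoxon_signed_rank(np.array(d, dtype=float), np.zeros(8))
        assert res.statistic == pytest.approx(w_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_enumeration_many_small_inputs(self):
        """Exact P equals sign-flip enumeration for all n <= 10 pairs."""
        rng = np.random.default_rng(23)
        for n in range(5, 11):
            d = np.round(rng.normal(0.4, 1, n), 1)
            d[d == 0] = 0.1
            w_oracle, p_oracle = wilcoxon_oracle(d.tolist())
            res = t.wilcoxon_signed_rank(d, np.zeros(n))
            assert res.statistic == pytest.approx(w_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_antisymmetry_under_swap(self):
        x = np.array([2.0, 5.0, 1.0, 7.0, 3.0, 9.0])
        y = np.array([1.0, 2.0, 4.0, 3.0, 2.0, 5.0])
        a = t.wilcoxon_signed_rank(x, y)
        b = t.wilcoxon_signed_rank(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.z == pytest.approx(-b.z)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            t.wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            t.wilcoxon_signed_rank([1.0, 2.0], [0.0, 0.0])


# -- effect sizes -------------------------------------------------------------

class TestEffectSize:
    @pytest.mark.parametrize("p,expected", [
        (0.0019, 0.55),   # mean cell size
        (0.0005, 0.61),   # SD of cell size
        (0.026, 0.39),    # mean deformation
        (0.0023, 0.54),   # mean area ratio
        (0.013, 0.44),    # SD of area ratio
    ])
    def test_published_pairs_at_n32(self, p, expected):
        r, _ = t.effect_size_r(p_two_sided=p, n_total=32)
        assert r == pytest.approx(expected, abs=0.01)

    def test_null_boundary(self):
        r, label = t.effect_size_r(p_two_sided=1.0, n_total=10)
        assert r == 0.0
        assert label == "negligible"

    @pytest.mark.parametrize("r,label", [
        (0.05, "negligible"), (0.1, "small"), (0.29, "small"),
        (0.3, "moderate"), (0.5, "moderate"), (0.5001, "large"),
    ])
    def test_cohen_boundaries(self, r, label):
        assert t.cohen_label(r) == label

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            t.effect_size_r(p_two_sided=0.0, n_total=5)
        with pytest.raises(ParameterError):
            t.effect_size_r(p_two_sided=1.2, n_total=5)


# -- Pearson ------------------------------------------------------------------

class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(1.0, 8.0)
        r, p, df = t.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 5

    def test_perfect_anticorrelation(self):
        x = np.arange(1.0, 6.0)
        r, _, _ = t.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, _, _ = t.pearson_r(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            t.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# -- sample summaries and KDE -------------------------------------------------

class TestSampleSummary:
    def test_all_positive_is_hundred_percent(self):
        ev = pd.DataFrame({"deformation": [0.1, 0.2],
                           "area_um2": [50.0, 60.0],
                           "fl_cd45_max": [1e4, 1e4]})
        s = t.sample_summary(ev, cd45_threshold=100.0)
        assert s["pct_cd45_pos"] == 100.0

    def test_median_deformation(self):
        ev = pd.DataFrame({"deformation": [0.1, 0.2, 0.3]})
        assert t.sample_summary(ev)["median_deformation"] == pytest.approx(0.2)

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            t.sample_summary(pd.DataFrame({"deformation": []}))


class TestKde:
    def test_densest_event_maps_to_one(self, rng):
        ev = pd.DataFrame({"a": rng.normal(0, 1, 400), "b": rng.normal(0, 1, 400)})
        dens, _ = t.kde_norm(ev, "a", "b")
        assert dens.max() == pytest.approx(1.0, abs=1e-9)
        assert ((dens >= 0) & (dens <= 1)).all()

    def test_bimodal_data_splits_high_contour(self, rng):
        # exactly mirror-symmetric clusters: two equal-height modes
        x = rng.normal(6, 0.5, 300)
        y = rng.normal(0, 0.5, 300)
        ev = pd.DataFrame({"a": np.r_[x, -x], "b": np.r_[y, y]})
        _, contours = t.kde_norm(ev, "a", "b")
        assert len(contours[0.95]) >= 2  # one tight contour per mode

    def test_degenerate_input_rejected(self):
        ev = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(DegenerateInputError):
            t.kde_norm(ev, "a", "b")


def test_significance_star_convention():
    assert t.significance_stars(0.0005) == "***"
    assert t.significance_stars(0.005) == "**"
    assert t.significance_stars(0.03) == "*"
    assert t.significance_stars(0.2) == "NS"
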