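"""Core-quality indices, diversity measures and the test battery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mungcore as mc
from mungcore.errors import ComputationError
from mungcore.evaluation import evenness, kl_distance, sign_test_pair
from mungcore.traits import TraitDescriptor

from oracles import welch_t

QD = lambda n: TraitDescriptor(n, "quantitative")


def test_summary_stats_basic_shapes():
    s = mc.summary_stats([1.0, 2.0, 3.0, 4.0], "x")
    assert s.mean == 2.5 and s.skewness == pytest.approx(0.0, abs=1e-12)
    assert s.iqr == pytest.approx(1.5)
    right_tail = mc.summary_stats([1, 2, 3, 4, 100.0], "y")
    assert right_tail.skewness > 0
    const = mc.summary_stats([5.0, 5.0, 5.0], "z")
    assert const.sd == 0 and const.iqr == 0 and math.isnan(const.skewness)


def test_summary_cv_undefined_at_zero_mean():
    with pytest.warns(UserWarning, match="CV undefined"):
        s = mc.summary_stats([-1.0, 1.0], "x")
    assert math.isnan(s.cv)


# ---------------------------------------------------------------------------
# Hu indices and class coverage
# ---------------------------------------------------------------------------

def random_quant_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "q1": rng.normal(10, 2, n),
        "q2": rng.normal(50, 8, n),
    }, index=[f"G{i:03d}" for i in range(n)])


def test_hu_identity_core_fixed_point():
    ec = random_quant_table()
    md, vd, cr, vr = mc.hu_indices(ec, ec)
    assert md == 0.0 and vd == 0.0
    assert cr == pytest.approx(100.0)
    assert vr == pytest.approx(100.0)


def test_hu_cr_hand_arithmetic():
    ec = pd.DataFrame({"q1": [0.0, 4.0, 8.0], "q2": [0.0, 5.0, 10.0]},
                      index=["a", "b", "c"])
    cc = pd.DataFrame({"q1": [0.0, 4.0], "q2": [0.0, 10.0]}, index=["a", "b"])
    cc["q1"] = [0.0, 4.0]  # range 4 of 8 -> 50%; q2 range 10 of 10 -> 100%
    _, _, cr, _ = mc.hu_indices(ec, cc)
    assert cr == pytest.approx(75.0)


def test_hu_interior_dropout_inflates_vr_keeps_cr():
    rng = np.random.default_rng(4)
    x = np.sort(rng.normal(20, 4, 200))
    ec = pd.DataFrame({"q": x}, index=[f"G{i:03d}" for i in range(200)])
    keep = list(ec.index[:25]) + list(ec.index[-25:])  # extremes only
    cc = ec.loc[keep]
    md, vd, cr, vr = mc.hu_indices(ec, cc)
    assert cr == pytest.approx(100.0)
    assert vr > 100.0


def test_class_coverage_identity_and_partial():
    desc = [QD("q"), TraitDescriptor("c", "qualitative", "", ("A", "B", "C"))]
    table = pd.DataFrame({
        "q": np.linspace(0, 10, 12),
        "c": ["A"] * 6 + ["B"] * 5 + ["C"],
    }, index=[f"G{i:02d}" for i in range(12)])
    cov, ratio = mc.class_coverage(table, table, desc)
    assert cov == 100.0 and ratio == 1.0
    # dropping the only C carrier loses a state
    cov2, ratio2 = mc.class_coverage(table, table.iloc[:-1], desc)
    assert ratio2 < 1.0
    assert cov2 < 100.0


# ---------------------------------------------------------------------------
# Shannon
# ---------------------------------------------------------------------------

def test_shannon_uniform_and_degenerate():
    h, j, hmax = mc.shannon_indices([10, 10])
    assert h == pytest.approx(math.log(2))
    assert j == pytest.approx(1.0)
    h, j, hmax = mc.shannon_indices([20, 0, 0], k=3)
    assert h == 0.0 and j == 0.0
    with pytest.raises(ComputationError):
        mc.shannon_indices([5], k=1)


def test_shannon_hmax_depends_on_descriptor_not_support():
    # 5 possible states, only 2 observed
    h, j, hmax = mc.shannon_indices([30, 10, 0, 0, 0], k=5)
    assert hmax == pytest.approx(math.log(5))
    assert j == pytest.approx(h / math.log(5))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(counts=st.lists(st.integers(0, 50), min_size=2, max_size=9).filter(
    lambda c: sum(c) > 0))
def test_shannon_bounds_property(counts):
    h, j, hmax = mc.shannon_indices(counts)
    assert -1e-12 <= h <= hmax + 1e-12
    assert -1e-12 <= j <= 1.0 + 1e-12
    uniform = len(set(counts)) == 1
    assert (abs(j - 1.0) < 1e-12) == uniform


# ---------------------------------------------------------------------------
# sign tests
# ---------------------------------------------------------------------------

def test_sign_test_balance_extreme_and_ties():
    ec = pd.Series({f"t{i}": 1.0 for i in range(8)})
    cc_balanced = ec.copy()
    cc_balanced.iloc[:4] += 1
    cc_balanced.iloc[4:] -= 1
    assert mc.sign_tests(ec, cc_balanced).p == pytest.approx(1.0)

    cc_up = ec.iloc[:7] + 1.0  # 7 pluses, 0 minuses
    res = mc.sign_tests(ec.iloc[:7], cc_up)
    assert res.p == pytest.approx(2 * 0.5 ** 7)

    res = mc.sign_tests(ec, ec)
    assert math.isnan(res.p) and "ties" in res.note


def test_sign_test_pair_on_tables():
    ec = random_quant_table(seed=2)
    cc = ec.iloc[:20] * 1.0
    mean_res, var_res = sign_test_pair(ec, cc)
    assert mean_res.label == "sign" and var_res.label == "sign"


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def corr_of(seed, n=40, p=5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"q{i}" for i in range(p)]).corr()


def test_mantel_identity_and_determinism():
    m = corr_of(0)
    res = mc.mantel_test(m, m, permutations=199, seed=1)
    assert res.statistic == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0 / 200.0, abs=0.03)
    res2 = mc.mantel_test(m, corr_of(5), permutations=199, seed=9)
    res3 = mc.mantel_test(m, corr_of(5), permutations=199, seed=9)
    assert res2.p == res3.p and res2.statistic == res3.statistic


def test_mantel_rejects_constant_offdiagonal():
    m = pd.DataFrame(np.eye(4))
    with pytest.raises(ComputationError):
        mc.mantel_test(m, m, permutations=99)


# ---------------------------------------------------------------------------
# distribution battery
# ---------------------------------------------------------------------------

def test_battery_identical_samples_are_null():
    x = np.linspace(0, 10, 40)
    res = mc.distribution_tests(x, x)
    assert res["t"].statistic == pytest.approx(0.0)
    assert res["ks"].statistic == 0.0
    assert res["kl"].statistic == 0.0
    for lab in ("t", "newman_keuls", "levene", "wilcoxon", "ks"):
        assert res[lab].p > 0.9


def test_battery_separated_samples_significant():
    res = mc.distribution_tests([1, 2, 3, 4, 5], [101, 102, 103, 104, 105])
    assert res["t"].p < 1e-4
    assert res["ks"].p < 0.01
    assert res["kl"].statistic > 0


def test_welch_t_matches_direct_formula():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [2.0, 3.0, 4.0, 5.0]
    res = mc.distribution_tests(list(x) + [2.5], list(y) + [3.5])
    t_or, df_or = welch_t(np.array(y + [3.5]), np.array(x + [2.5]))
    assert res["t"].statistic == pytest.approx(t_or, rel=1e-12)
    assert res["t"].df == pytest.approx(df_or, rel=1e-12)


def test_battery_small_samples_flagged_undefined():
    res = mc.distribution_tests([1.0, 2.0], [1.0, 2.0, 3.0])
    assert all(math.isnan(r.statistic) for r in res.values())
    assert all("sample < 5" in r.note for r in res.values())


def test_kl_distance_symmetry_and_positivity():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 300)
    y = rng.normal(2, 1, 300)
    assert kl_distance(x, y) == pytest.approx(kl_distance(y, x), rel=1e-12)
    assert kl_distance(x, y) > kl_distance(x, x) == 0.0


def test_ks_pvalues_approximately_uniform_under_null():
    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(200):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        pvals.append(mc.distribution_tests(x, y)["ks"].p)
    pvals = np.array(pvals)
    # crude uniformity check: mean near 1/2, moderate rejection rate at 5%
    assert abs(pvals.mean() - 0.5) < 0.1
    assert (pvals < 0.05).mean() < 0.12


def test_qq_data_identity_scale_and_length():
    x = np.linspace(0, 10, 30)
    qq = mc.qq_data(x, x)
    assert np.allclose(qq["ec_quantile"], qq["cc_quantile"])
    qq2 = mc.qq_data(x, 2 * x)
    ratio = qq2["cc_quantile"] / qq2["ec_quantile"].replace(0, np.nan)
    assert np.allclose(ratio.dropna(), 2.0)
    qq3 = mc.qq_data(np.arange(50.0), np.arange(20.0))
    assert len(qq3) == 20


def test_evenness_helper():
    assert evenness(0.33, math.log(2)) == pytest.approx(0.476, abs=1.5e-3)
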