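"""Augmented-design analysis: Federer adjustment, ANOVA, CDs, Bartlett."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mungcore as mc
from mungcore.errors import ComputationError, DesignError
from mungcore.simulate import QuantTraitSpec, SyntheticConfig

from conftest import make_fieldbook, random_fieldbook
from oracles import anova_lstsq, bartlett_statistic, sample_with_exact_variance


def test_worked_example_block_effects_and_adjustment(worked_example_fieldbook):
    adj = mc.adjust_means(worked_example_fieldbook)
    assert adj.block_effects.loc[1, "GY"] == pytest.approx(-1.5)
    assert adj.block_effects.loc[2, "GY"] == pytest.approx(1.5)
    assert adj.block_effects["GY"].sum() == pytest.approx(0.0, abs=1e-12)
    # observed 20 in block 2 -> 18.5
    assert adj.means.loc["T3", "GY"] == pytest.approx(18.5)
    assert adj.means.loc["T1", "GY"] == pytest.approx(16.5)
    # check adjusted means are their raw across-block means
    assert adj.means.loc["C1", "GY"] == pytest.approx(11.0)
    assert adj.means.loc["C2", "GY"] == pytest.approx(14.0)


def test_equal_check_means_leave_tests_unchanged():
    fb = make_fieldbook(
        block_values={1: {"C1": 9.0, "C2": 13.0}, 2: {"C1": 12.0, "C2": 10.0}},
        tests_per_block={1: {"T1": 7.0}, 2: {"T2": 19.0}})
    adj = mc.adjust_means(fb)
    assert (adj.block_effects["GY"] == 0).all()
    assert adj.means.loc["T1", "GY"] == 7.0
    assert adj.means.loc["T2", "GY"] == 19.0


def test_zero_error_synthetic_recovers_truth_exactly():
    quant = [QuantTraitSpec("Q1", mean=30.0, vg=6.0, ve=0.0)]
    cfg = SyntheticConfig(n_test=40, n_blocks=4, checks=("C1", "C2"),
                          reps_per_check_per_block=2, quant_traits=quant,
                          block_sd=2.0, seed=5)
    coll = mc.generate_collection(cfg)
    adj = mc.adjust_means(coll.fieldbook)
    truth = coll.truth.true_entry_mean("Q1")
    tests = adj.test_means()["Q1"]
    assert np.allclose(tests, truth.loc[tests.index], atol=1e-9)


def test_adjustment_idempotence():
    rng = np.random.default_rng(1)
    fb = random_fieldbook(rng, n_blocks=4, n_checks=3, reps=2, n_tests=12)
    adj = mc.adjust_means(fb)
    plots = fb.plots.copy()
    plots["GY"] = plots["GY"] - adj.block_effects.loc[plots["block"], "GY"].to_numpy()
    fb2 = mc.FieldBook(plots, fb.descriptors)
    adj2 = mc.adjust_means(fb2)
    assert np.allclose(adj2.block_effects["GY"], 0.0, atol=1e-10)


def test_recovery_improves_with_smaller_error_variance():
    mses = []
    for ve in (9.0, 1.0, 0.01):
        cfg = SyntheticConfig(
            n_test=120, n_blocks=4, checks=("C1", "C2"),
            reps_per_check_per_block=2,
            quant_traits=[QuantTraitSpec("Q1", 30.0, vg=4.0, ve=ve)],
            block_sd=1.0, seed=8)
        coll = mc.generate_collection(cfg)
        adj = mc.adjust_means(coll.fieldbook)
        truth = coll.truth.true_entry_mean("Q1")
        tests = adj.test_means()["Q1"]
        mses.append(float(((tests - truth.loc[tests.index]) ** 2).mean()))
    assert mses[0] > mses[1] > mses[2]


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_error_df_and_degenerate_checks():
    fb = make_fieldbook(
        block_values={1: {"C1": 10.0, "C2": 10.0}, 2: {"C1": 10.0, "C2": 10.0}},
        tests_per_block={1: {"T1": 12.0}, 2: {"T2": 8.0}})
    table = mc.abd_anova(fb, "GY")
    assert table.error_df == 1  # (b-1)(c-1) with r=1
    assert table.ve == 0.0
    assert table.table.loc["error", "ss"] == 0.0


@pytest.mark.parametrize("spec", [(2, 2, 1, 6), (3, 2, 2, 9), (4, 3, 1, 10),
                                  (3, 3, 2, 12)])
def test_anova_matches_least_squares_oracle(spec):
    b, c, r, t = spec
    rng = np.random.default_rng(100 + b * 10 + c + r)
    for _ in range(5):
        fb = random_fieldbook(rng, n_blocks=b, n_checks=c, reps=r, n_tests=t)
        table = mc.abd_anova(fb, "GY").table
        ss_block, ss_trt, ss_err = anova_lstsq(fb, "GY")
        assert table.loc["block", "ss"] == pytest.approx(ss_block, rel=1e-8)
        assert table.loc["treatment", "ss"] == pytest.approx(ss_trt, rel=1e-8)
        assert table.loc["error", "ss"] == pytest.approx(ss_err, rel=1e-8, abs=1e-10)
        assert table.loc["error", "df"] == (b - 1) * (c - 1) + b * c * (r - 1)
        # partition adds up
        assert table.loc["treatment", "ss"] == pytest.approx(
            table.loc[["checks", "tests", "checks_vs_tests"], "ss"].sum(),
            rel=1e-8)
        # decomposition: total = block + treatment + error
        y = fb.plots["GY"].to_numpy()
        assert ((y - y.mean()) ** 2).sum() == pytest.approx(
            table.loc[["block", "treatment", "error"], "ss"].sum(), rel=1e-10)


def test_anova_requires_two_checks():
    fb = make_fieldbook(block_values={1: {"C1": 10.0}, 2: {"C1": 12.0}},
                        tests_per_block={1: {"T1": 9.0}, 2: {"T2": 11.0}},
                        check_names=("C1",))
    with pytest.raises(DesignError):
        mc.abd_anova(fb, "GY")


# ---------------------------------------------------------------------------
# critical differences and promising accessions
# ---------------------------------------------------------------------------

def make_anova(ve, df, trait="GY"):
    table = pd.DataFrame({"df": [df], "ss": [ve * df], "ms": [ve],
                          "F": [np.nan], "p": [np.nan]}, index=["error"])
    return mc.AnovaTable(trait, table)


def test_cd_formula_arithmetic():
    cd = mc.critical_differences(make_anova(4.0, 1), design=(2, 2), alpha=0.05)
    t = stats.t.ppf(0.975, 1)  # 12.7062
    assert cd.test_test_same_block == pytest.approx(t * math.sqrt(8.0), rel=1e-9)
    assert cd.test_test_same_block == pytest.approx(35.94, abs=0.01)
    assert cd.check_check == pytest.approx(t * math.sqrt(4.0), rel=1e-9)
    assert cd.test_test_diff_block == pytest.approx(t * math.sqrt(12.0), rel=1e-9)
    assert cd.test_check == pytest.approx(t * math.sqrt(4 * 2.25), rel=1e-9)


def test_cd_zero_variance_and_monotonicity():
    zero = mc.critical_differences(make_anova(0.0, 5), (3, 2))
    assert zero.check_check == zero.test_test_same_block == 0.0
    small = mc.critical_differences(make_anova(1.0, 5), (3, 2))
    big = mc.critical_differences(make_anova(4.0, 5), (3, 2))
    for attr in ("check_check", "test_test_same_block",
                 "test_test_diff_block", "test_check"):
        assert getattr(big, attr) > getattr(small, attr) > 0


def test_identify_promising_construction_and_planted_genotype():
    fb = make_fieldbook(
        block_values={1: {"C1": 10.0, "C2": 11.0}, 2: {"C1": 10.0, "C2": 11.0}},
        tests_per_block={1: {"T1": 10.5, "T2": 10.2}, 2: {"T3": 40.0}})
    adj = mc.adjust_means(fb)
    cd = mc.critical_differences(mc.abd_anova(fb, "GY"), (2, 2))
    assert mc.identify_promising(adj, cd, "GY", "lower") == []
    hits = mc.identify_promising(adj, cd, "GY", "higher")
    assert hits and hits[0] == "T3"

    # planted extreme genotype in a synthetic trial is recovered
    cfg = SyntheticConfig(
        n_test=60, n_blocks=3, checks=("C1", "C2"),
        reps_per_check_per_block=2,
        quant_traits=[QuantTraitSpec("Q1", 30.0, vg=1.0, ve=0.5)],
        block_sd=1.0, seed=21)
    coll = mc.generate_collection(cfg)
    fb = coll.fieldbook
    star = fb.tests[0]
    fb.plots.loc[fb.plots["accession"] == star, "Q1"] += 50.0
    adj = mc.adjust_means(fb)
    cd = mc.critical_differences(mc.abd_anova(fb, "Q1"), (3, 2))
    hits = mc.identify_promising(adj, cd, "Q1", "higher")
    assert hits[0] == star


# ---------------------------------------------------------------------------
# Bartlett homogeneity
# ---------------------------------------------------------------------------

def test_bartlett_equal_and_extreme_variances():
    equal = mc.bartlett_homogeneity([2.0, 2.0, 2.0, 2.0], [10, 10, 10, 10])
    assert equal.statistic == pytest.approx(0.0, abs=1e-10)
    assert equal.p == pytest.approx(1.0)
    extreme = mc.bartlett_homogeneity([1.0, 100.0], [50, 50])
    assert extreme.p < 0.001


def test_bartlett_matches_textbook_formula_and_scipy():
    res = mc.bartlett_homogeneity([2.0, 8.0], [10, 10])
    assert res.statistic == pytest.approx(
        bartlett_statistic([2.0, 8.0], [10, 10]), rel=1e-12)
    # scipy on raw samples constructed to have exactly those variances
    rng = np.random.default_rng(3)
    x = sample_with_exact_variance(rng, 11, 2.0)
    y = sample_with_exact_variance(rng, 11, 8.0)
    ref = stats.bartlett(x, y)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_bartlett_input_validation():
    with pytest.raises(ComputationError):
        mc.bartlett_homogeneity([2.0], [10])
    with pytest.raises(ComputationError):
        mc.bartlett_homogeneity([2.0, 0.0], [10, 10])
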