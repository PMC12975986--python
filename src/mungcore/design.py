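"""Federer augmented-block-design analysis.

In an augmented RCBD, replicated check varieties carry all the information
about block effects and experimental error; each unreplicated test entry is
then corrected by its block's effect:

    b_j  = (mean of check plot values in block j) - (grand mean of check
           plot values)
    adjusted test value = observed - b_j
    adjusted check mean = raw across-block mean of that check

The check data also yield the ANOVA error stratum. With ``b`` blocks, ``c``
checks and ``r`` check replicates per block, the additive two-way fit on
check plots leaves ``(b-1)(c-1) + bc(r-1)`` error degrees of freedom (the
classical Federer stratum ``(b-1)(c-1)`` when r = 1); its mean square
estimates the plot-level error variance Ve used by the critical differences
and the variability parameters.

The four Federer critical differences at level alpha (t on the error df):

    check-check                 t * sqrt(2 Ve / b)
    test-test, same block       t * sqrt(2 Ve)
    test-test, different block  t * sqrt(2 Ve (c+1)/c)
    test-check                  t * sqrt(Ve (1 + 1/b + 1/c + 1/(bc)))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .common import TestResult
from .errors import ComputationError, DesignError, SchemaError
from .io import FieldBook, ROLE_CHECK, ROLE_TEST, validate_fieldbook


@dataclass
class AdjustedMeans:
    """Block-adjusted entry means and the quantities they derive from."""

    means: pd.DataFrame          # accession x trait adjusted means (tests+checks)
    block_effects: pd.DataFrame  # block x trait b_j
    check_means: pd.DataFrame    # check x trait raw across-block means
    ve: pd.Series                # per-trait error MS from the check ANOVA
    grand_test_mean: pd.Series   # per-trait mean of adjusted test means
    test_ids: tuple
    n_blocks: int
    n_checks: int
    reps_per_check: int
    error_df: int

    def test_means(self) -> pd.DataFrame:
        return self.means.loc[list(self.test_ids)]


@dataclass
class AnovaTable:
    """Tidy ANOVA for one trait of an augmented RCBD."""

    trait: str
    table: pd.DataFrame  # index: source; columns: df, ss, ms, F, p

    @property
    def ve(self) -> float:
        return float(self.table.loc["error", "ms"])

    @property
    def error_df(self) -> int:
        return int(self.table.loc["error", "df"])


@dataclass(frozen=True)
class CriticalDifferences:
    trait: str
    alpha: float
    check_check: float
    test_test_same_block: float
    test_test_diff_block: float
    test_check: float


def _check_matrix(fb: FieldBook, trait: str):
    """Check plot values as arrays grouped by (block, check)."""
    checks = fb.checks
    blocks = fb.blocks
    sub = fb.plots[fb.plots["role"] == ROLE_CHECK]
    vals = sub.pivot_table(index="block", columns="accession", values=trait,
                           aggfunc="mean").reindex(index=blocks, columns=checks)
    if vals.isna().any().any():
        missing = vals.isna().stack()
        b, c = missing[missing].index[0]
        raise DesignError(f"check {c!r} has no value for {trait!r} in block {b}")
    return vals  # block x check means (reps averaged)


def adjust_means(fb: FieldBook) -> AdjustedMeans:
    """Compute Federer adjusted means for every quantitative trait."""
    validate_fieldbook(fb)
    checks = fb.checks
    if not checks:
        raise DesignError("field book has no check plots")
    blocks = fb.blocks
    tests = fb.tests
    traits = fb.quantitative_traits
    if not traits:
        raise SchemaError("no quantitative traits to adjust")
    r = fb.reps_per_check()

    adj = pd.DataFrame(index=tests + checks, columns=traits, dtype=float)
    bfx = pd.DataFrame(index=blocks, columns=traits, dtype=float)
    cmeans = pd.DataFrame(index=checks, columns=traits, dtype=float)
    ve = {}
    test_plots = fb.plots[fb.plots["role"] == ROLE_TEST]

    for trait in traits:
        cm = _check_matrix(fb, trait)          # block x check (reps averaged)
        block_means = cm.mean(axis=1)
        grand = float(cm.to_numpy().mean())
        b_j = block_means - grand
        bfx[trait] = b_j

        obs = test_plots.set_index("accession")[[trait, "block"]]
        adj.loc[tests, trait] = (obs.loc[tests, trait]
                                 - b_j.loc[obs.loc[tests, "block"]].to_numpy())
        cmeans[trait] = cm.mean(axis=0)
        adj.loc[checks, trait] = cmeans[trait]

        ve[trait] = _check_error_ms(fb, trait)

    b, c = len(blocks), len(checks)
    error_df = (b - 1) * (c - 1) + b * c * (r - 1)
    return AdjustedMeans(
        means=adj, block_effects=bfx, check_means=cmeans,
        ve=pd.Series(ve), grand_test_mean=adj.loc[tests].mean(),
        test_ids=tuple(tests), n_blocks=b, n_checks=c, reps_per_check=r,
        error_df=error_df)


def _check_error_ms(fb: FieldBook, trait: str) -> float:
    """Plot-level error mean square from the additive fit on check plots."""
    sub = fb.plots[fb.plots["role"] == ROLE_CHECK]
    y = sub[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ComputationError(f"missing check values for trait {trait!r}")
    blocks = sub["block"].to_numpy()
    accs = sub["accession"].to_numpy()
    grand = y.mean()
    block_mean = pd.Series(y).groupby(blocks).transform("mean").to_numpy()
    check_mean = pd.Series(y).groupby(accs).transform("mean").to_numpy()
    resid = y - block_mean - check_mean + grand
    b = len(np.unique(blocks))
    c = len(np.unique(accs))
    r = len(y) // (b * c)
    df = (b - 1) * (c - 1) + b * c * (r - 1)
    if df <= 0:
        raise DesignError("error stratum undefined (need >= 2 checks and blocks)")
    return float((resid ** 2).sum() / df)


def abd_anova(fb: FieldBook, trait: str) -> AnovaTable:
    """Sequential ANOVA of the augmented design for one trait.

    Model: value = mean + block + treatment + error, with blocks fitted first
    (ignoring treatments) and the treatment stratum (eliminating blocks)
    partitioned into checks, tests and the checks-vs-tests contrast. The
    error SS comes entirely from check replication.
    """
    validate_fieldbook(fb)
    if len(fb.checks) < 2:
        raise DesignError("ANOVA needs >= 2 checks to define the error stratum")
    plots = fb.plots.dropna(subset=[trait])
    if len(plots) < len(fb.plots):
        warnings.warn(f"{len(fb.plots) - len(plots)} plots with missing "
                      f"{trait!r} dropped from the ANOVA", stacklevel=2)
    y = plots[trait].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    gb = plots.groupby("block")[trait]
    ss_block = float((gb.size() * (gb.mean() - grand) ** 2).sum())
    b = plots["block"].nunique()

    # error from checks (additive two-way fit, plot level)
    checks = plots[plots["role"] == ROLE_CHECK]
    cy = checks[trait].to_numpy(dtype=float)
    cb = checks["block"].to_numpy()
    cc = checks["accession"].to_numpy()
    cgrand = cy.mean()
    block_mean = pd.Series(cy).groupby(cb).transform("mean").to_numpy()
    check_mean = pd.Series(cy).groupby(cc).transform("mean").to_numpy()
    ss_error = float(((cy - block_mean - check_mean + cgrand) ** 2).sum())
    c = len(np.unique(cc))
    r = len(cy) // (b * c)
    df_error = (b - 1) * (c - 1) + b * c * (r - 1)
    if df_error <= 0:
        raise DesignError("error stratum undefined")

    ss_trt = ss_total - ss_block - ss_error
    v = plots[plots["role"] == ROLE_TEST]["accession"].nunique()
    df_trt = c + v - 1

    # partition of the treatment stratum
    gc = pd.Series(cy).groupby(cc)
    ss_checks = float((gc.size() * (gc.mean() - cgrand) ** 2).sum())
    adj = adjust_means(fb).means
    a = adj.loc[list(fb.tests), trait].to_numpy(dtype=float)
    a = a[np.isfinite(a)]
    ss_tests = float(((a - a.mean()) ** 2).sum()) if len(a) > 1 else 0.0
    ss_cvt = ss_trt - ss_checks - ss_tests

    ms_error = ss_error / df_error
    rows = []
    for src, ss, df in [("block", ss_block, b - 1),
                        ("treatment", ss_trt, df_trt),
                        ("checks", ss_checks, c - 1),
                        ("tests", ss_tests, max(v - 1, 0)),
                        ("checks_vs_tests", ss_cvt, 1 if v else 0),
                        ("error", ss_error, df_error)]:
        ms = ss / df if df > 0 else float("nan")
        if src != "error" and df > 0 and ms_error > 0:
            f_val = ms / ms_error
            p = float(stats.f.sf(f_val, df, df_error))
        else:
            f_val, p = float("nan"), float("nan")
        rows.append({"source": src, "df": df, "ss": ss, "ms": ms,
                     "F": f_val, "p": p})
    table = pd.DataFrame(rows).set_index("source")
    return AnovaTable(trait, table)


def abd_anova_all(fb: FieldBook) -> dict:
    return {t: abd_anova(fb, t) for t in fb.quantitative_traits}


def critical_differences(anova: AnovaTable, design: tuple,
                         alpha: float = 0.05) -> CriticalDifferences:
    """Federer critical differences for the four comparison types."""
    if not 0 < alpha < 1:
        raise ComputationError("alpha must be in (0, 1)")
    b, c = design
    ve = anova.ve
    df = anova.error_df
    if df <= 0:
        raise DesignError("error df <= 0")
    if ve < 0:
        raise ComputationError("negative error variance")
    t = float(stats.t.ppf(1 - alpha / 2, df))
    return CriticalDifferences(
        trait=anova.trait, alpha=alpha,
        check_check=t * math.sqrt(2 * ve / b),
        test_test_same_block=t * math.sqrt(2 * ve),
        test_test_diff_block=t * math.sqrt(2 * ve * (c + 1) / c),
        test_check=t * math.sqrt(ve * (1 + 1 / b + 1 / c + 1 / (b * c))),
    )


def identify_promising(adj: AdjustedMeans, cd: CriticalDifferences,
                       trait: str, direction: str = "higher") -> list:
    """Test accessions beating the best check by more than CD(test-check).

    Returns accession ids sorted by decreasing margin.
    """
    if trait not in adj.means.columns:
        raise SchemaError(f"unknown trait {trait!r}")
    if direction not in ("higher", "lower"):
        raise ComputationError("direction must be 'higher' or 'lower'")
    tests = adj.means.loc[list(adj.test_ids), trait]
    if direction == "higher":
        best_check = adj.check_means[trait].max()
        margin = tests - best_check - cd.test_check
    else:
        best_check = adj.check_means[trait].min()
        margin = best_check - tests - cd.test_check
    hits = margin[margin > 0].sort_values(ascending=False)
    return hits.index.tolist()


def bartlett_homogeneity(error_variances, dfs) -> TestResult:
    """Bartlett's chi-square homogeneity test from (variance, df) summaries.

    Used to screen multi-environment error variances before pooling; a small
    p-value means the environments' error variances are heterogeneous and the
    data should not be combined.
    """
    s2 = np.asarray(error_variances, dtype=float)
    df = np.asarray(dfs, dtype=float)
    k = len(s2)
    if k < 2:
        raise ComputationError("need >= 2 environments")
    if (s2 <= 0).any():
        raise ComputationError("error variances must be positive")
    if (df < 1).any():
        raise ComputationError("each environment needs df >= 1")
    n_tot = df.sum()
    sp2 = float((df * s2).sum() / n_tot)
    m = n_tot * math.log(sp2) - float((df * np.log(s2)).sum())
    c = 1.0 + ((1.0 / df).sum() - 1.0 / n_tot) / (3.0 * (k - 1))
    chi2 = m / c
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult("bartlett", float(chi2), p, df=k - 1)
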