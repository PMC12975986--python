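"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: brute-force enumeration, generic least squares, or per-pair loops.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def exhaustive_best_core(d, size, w_en, w_an, normalizer):
    """Global optimum of the weighted EN/AN objective by full enumeration.

    Returns (best_score, list of optimal index tuples).
    """
    best_score = -np.inf
    best = []
    for combo in itertools.combinations(range(d.n), size):
        idx = np.array(combo, dtype=int)
        s = normalizer.score(d.values, idx, w_en, w_an)
        if s > best_score + 1e-12:
            best_score = s
            best = [combo]
        elif abs(s - best_score) <= 1e-12:
            best.append(combo)
    return best_score, best


def gower_pairwise(table: pd.DataFrame, kinds: dict) -> np.ndarray:
    """Per-pair Gower distance with pairwise deletion (plain double loop)."""
    n = len(table)
    cols = list(table.columns)
    ranges = {}
    for c in cols:
        if kinds[c] == "quantitative":
            x = pd.to_numeric(table[c], errors="coerce")
            ranges[c] = float(x.max() - x.min())
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for c in cols:
                a, b = table.iloc[i][c], table.iloc[j][c]
                if pd.isna(a) or pd.isna(b):
                    continue
                if kinds[c] == "quantitative":
                    if ranges[c] <= 0:
                        continue
                    num += abs(float(a) - float(b)) / ranges[c]
                else:
                    num += 0.0 if a == b else 1.0
                den += 1.0
            dij = num / den if den > 0 else 1.0
            out[i, j] = out[j, i] = dij
    return out


def anova_lstsq(fb, trait):
    """Sequential (type-I) sums of squares for value ~ block + treatment via
    generic OLS dummy regression (statsmodels)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = fb.plots[["block", "accession", trait]].dropna().copy()
    df.columns = ["block", "trt", "y"]
    df["block"] = df["block"].astype(str)
    model = ols("y ~ C(block) + C(trt)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    return (float(tab.loc["C(block)", "sum_sq"]),
            float(tab.loc["C(trt)", "sum_sq"]),
            float(tab.loc["Residual", "sum_sq"]))


def sample_with_exact_variance(rng, n, variance):
    """A sample of size n whose ddof=1 variance is exactly `variance`."""
    x = rng.standard_normal(n)
    x = x - x.mean()
    x = x / x.std(ddof=1)
    return x * np.sqrt(variance)


def welch_t(x, y):
    """Welch two-sample t from first principles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def bartlett_statistic(variances, dfs):
    """Textbook Bartlett statistic from summary (variance, df) pairs."""
    s2 = np.asarray(variances, float)
    df = np.asarray(dfs, float)
    k = len(s2)
    n = df.sum()
    sp2 = (df * s2).sum() / n
    m = n * np.log(sp2) - (df * np.log(s2)).sum()
    c = 1 + ((1 / df).sum() - 1 / n) / (3 * (k - 1))
    return m / c
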