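"""Core-vs-collection quality evaluation.

Given the entire collection (EC) and a candidate core (CC), this module
computes the standard battery of quality indices:

* Hu indices over the quantitative traits: MD% (share of traits whose EC/CC
  means differ significantly by t-test), VD% (share with significantly
  different variances, F ratio test), CR% (mean ratio of CC to EC trait
  ranges, in percent), VR% (mean ratio of CC to EC coefficients of
  variation). A good core is conventionally MD% < 20 and CR% > 80.
* class coverage (share of EC trait classes -- Sturges bins for quantitative
  traits, descriptor states for qualitative ones -- present in the core) and
  the ratio of qualitative phenotypes retained;
* Shannon diversity H', evenness J' = H'/H_max and H_max = ln(number of
  descriptor states) per qualitative trait;
* sign tests on the per-trait mean and variance differences;
* a Mantel permutation test between the EC and CC trait-correlation matrices;
* a per-trait distribution-comparison battery (Welch t, two-group
  Newman-Keuls, Brown-Forsythe Levene, Wilcoxon rank-sum, Kolmogorov-Smirnov,
  k-sample Anderson-Darling, symmetrized Kullback-Leibler over shared
  histogram bins) plus Q-Q data for plotting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .common import TestResult
from .errors import ComputationError, SchemaError
from .sampling import ObjectiveValues, sturges_classes, trait_classes
from .traits import qualitative_names, quantitative_names


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    trait: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv: float        # 100 * sd / mean; nan when the mean is zero
    iqr: float
    skewness: float  # adjusted Fisher-Pearson; nan for constant samples
    kurtosis: float  # excess


def summary_stats(values, trait: str = "") -> SummaryStats:
    x = pd.Series(values).dropna().to_numpy(dtype=float)
    if len(x) < 2:
        raise ComputationError("need >= 2 non-missing values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0:
        warnings.warn(f"zero mean for {trait or 'sample'}: CV undefined",
                      stacklevel=2)
        cv = float("nan")
    else:
        cv = 100.0 * sd / mean
    q1, q3 = np.percentile(x, [25, 75])
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return SummaryStats(trait, len(x), float(x.min()), float(x.max()),
                        mean, sd, cv, float(q3 - q1), skew, kurt)


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = {t: summary_stats(table[t], t).__dict__ for t in table.columns}
    return pd.DataFrame(rows).T.drop(columns="trait")


# ---------------------------------------------------------------------------
# Hu indices
# ---------------------------------------------------------------------------

def hu_indices(ec: pd.DataFrame, cc: pd.DataFrame, alpha: float = 0.05):
    """(MD%, VD%, CR%, VR%) over the shared quantitative traits.

    ``cc`` rows must be a subset of ``ec`` rows; traits with zero EC range
    are excluded with a warning.
    """
    if not set(cc.index) <= set(ec.index):
        raise SchemaError("core accessions must be a subset of the collection")
    traits = [t for t in ec.columns if t in cc.columns]
    md_hits = vd_hits = 0
    cr_parts, vr_parts = [], []
    m = 0
    for t in traits:
        x = ec[t].dropna().to_numpy(dtype=float)
        y = cc[t].dropna().to_numpy(dtype=float)
        rng_ec = x.max() - x.min()
        if rng_ec <= 0:
            warnings.warn(f"trait {t!r} has zero collection range; excluded "
                          "from the Hu indices", stacklevel=2)
            continue
        m += 1
        t_res = stats.ttest_ind(y, x, equal_var=False)
        if t_res.pvalue < alpha:
            md_hits += 1
        f = y.var(ddof=1) / x.var(ddof=1)
        p_f = 2.0 * min(stats.f.sf(f, len(y) - 1, len(x) - 1),
                        stats.f.cdf(f, len(y) - 1, len(x) - 1))
        if min(p_f, 1.0) < alpha:
            vd_hits += 1
        cr_parts.append((y.max() - y.min()) / rng_ec)
        cv_ec = 100.0 * x.std(ddof=1) / x.mean() if x.mean() != 0 else np.nan
        cv_cc = 100.0 * y.std(ddof=1) / y.mean() if y.mean() != 0 else np.nan
        if np.isfinite(cv_ec) and cv_ec != 0:
            vr_parts.append(cv_cc / cv_ec)
    if m == 0:
        raise ComputationError("no usable traits for the Hu indices")
    md = 100.0 * md_hits / m
    vd = 100.0 * vd_hits / m
    cr = 100.0 * float(np.mean(cr_parts))
    vr = 100.0 * float(np.mean(vr_parts)) if vr_parts else float("nan")
    return md, vd, cr, vr


def class_coverage(ec: pd.DataFrame, cc: pd.DataFrame, descriptors,
                   subset=None):
    """(coverage %, phenotype-retained ratio) with classes built on the EC."""
    covers, counts = trait_classes(ec, descriptors, subset)
    universe = set(counts)
    hit = set()
    for acc in cc.index:
        hit |= covers[acc]
    coverage = 100.0 * len(hit & universe) / len(universe) if universe else 100.0

    qual = set(qualitative_names(descriptors))
    qual_classes_ec = {c for c in universe if c[0] in qual}
    qual_classes_cc = {c for c in hit if c[0] in qual}
    ratio = (len(qual_classes_cc) / len(qual_classes_ec)
             if qual_classes_ec else 1.0)
    return coverage, ratio


# ---------------------------------------------------------------------------
# Shannon diversity
# ---------------------------------------------------------------------------

def shannon_indices(state_counts, k: int | None = None):
    """(H', J', H_max) from descriptor-state counts.

    ``k`` is the number of *possible* states (from the descriptor); when not
    given it defaults to the length of the count vector. H' uses the natural
    logarithm over observed (positive-count) states; H_max = ln k;
    J' = H'/H_max.
    """
    counts = np.asarray(list(state_counts), dtype=float)
    if k is None:
        k = len(counts)
    if k < 2:
        raise ComputationError("Shannon indices need >= 2 possible states")
    if (counts < 0).any() or counts.sum() <= 0:
        raise ComputationError("counts must be non-negative with positive sum")
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    h_max = math.log(k)
    return h, h / h_max, h_max


def evenness(h: float, h_max: float) -> float:
    """Shannon evenness J' = H'/H_max."""
    if h_max <= 0:
        raise ComputationError("H_max must be positive")
    return h / h_max


def shannon_table(ec_states: pd.DataFrame, cc_states: pd.DataFrame,
                  descriptors) -> pd.DataFrame:
    """Per-qualitative-trait H', J', H_max for collection and core."""
    by_name = {d.name: d for d in descriptors}
    rows = {}
    for name in qualitative_names(descriptors):
        k = len(by_name[name].states)
        ec_counts = ec_states[name].value_counts()
        cc_counts = cc_states[name].value_counts()
        h_ec, j_ec, h_max = shannon_indices(ec_counts.to_numpy(), k)
        h_cc, j_cc, _ = shannon_indices(cc_counts.to_numpy(), k)
        rows[name] = {"n_states": k, "h_max": h_max,
                      "h_ec": h_ec, "j_ec": j_ec,
                      "h_cc": h_cc, "j_cc": j_cc}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# sign tests and Mantel
# ---------------------------------------------------------------------------

def sign_tests(ec_stats: pd.Series, cc_stats: pd.Series) -> TestResult:
    """Exact two-sided sign test on per-trait CC-vs-EC statistic differences."""
    common = ec_stats.index.intersection(cc_stats.index)
    diff = cc_stats[common] - ec_stats[common]
    n_plus = int((diff > 0).sum())
    n_minus = int((diff < 0).sum())
    n = n_plus + n_minus
    if n == 0:
        return TestResult("sign", float("nan"), float("nan"),
                          note="all ties: test undefined")
    p = stats.binomtest(n_plus, n, 0.5).pvalue
    return TestResult("sign", float(n_plus), float(p), df=n)


def sign_test_pair(ec: pd.DataFrame, cc: pd.DataFrame):
    """Sign tests on the trait means and trait variances (mean, variance)."""
    traits = [t for t in ec.columns if t in cc.columns]
    ec_mean = ec[traits].mean()
    cc_mean = cc[traits].mean()
    ec_var = ec[traits].var(ddof=1)
    cc_var = cc[traits].var(ddof=1)
    return sign_tests(ec_mean, cc_mean), sign_tests(ec_var, cc_var)


def mantel_test(m1: pd.DataFrame, m2: pd.DataFrame, permutations: int = 999,
                seed: int = 0) -> TestResult:
    """One-sided Mantel permutation test between two correlation matrices.

    r is the Pearson correlation of the upper off-diagonal elements; the null
    distribution permutes the row/column labels of the second matrix
    simultaneously. p = (1 + #{r_perm >= r_obs}) / (permutations + 1).
    """
    if permutations < 99:
        raise ComputationError("use >= 99 permutations")
    if list(m1.index) != list(m2.index):
        m2 = m2.loc[m1.index, m1.index]
    a = m1.to_numpy(dtype=float)
    b = m2.to_numpy(dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise SchemaError("matrices must be square and aligned")
    iu = np.triu_indices_from(a, k=1)
    x = a[iu]
    if np.std(x) == 0 or np.std(b[iu]) == 0:
        raise ComputationError("constant off-diagonal elements")
    r_obs = float(np.corrcoef(x, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        r = np.corrcoef(x, bp[iu])[0, 1]
        if r >= r_obs - 1e-12:
            hits += 1
    p = (1.0 + hits) / (permutations + 1.0)
    return TestResult("mantel", r_obs, float(p), df=permutations)


# ---------------------------------------------------------------------------
# distribution-comparison battery
# ---------------------------------------------------------------------------

def _newman_keuls_two(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Studentized-range comparison of two means on the pooled variance.

    With exactly two groups the Newman-Keuls procedure reduces to a single
    studentized-range test: q = |m1 - m2| / sqrt(s2p/2 * (1/n1 + 1/n2)).
    """
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    s2p = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    if s2p <= 0:
        return TestResult("newman_keuls", 0.0, 1.0, df=df,
                          note="zero pooled variance")
    se = math.sqrt(s2p / 2.0 * (1.0 / n1 + 1.0 / n2))
    q = abs(x.mean() - y.mean()) / se
    p = float(stats.studentized_range.sf(q, 2, df))
    return TestResult("newman_keuls", float(q), min(max(p, 0.0), 1.0), df=df)


def kl_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetrized discrete Kullback-Leibler distance over shared bins.

    Histograms share Sturges-rule bins built on the pooled sample; both are
    smoothed by adding eps = 1/(2 * n_pooled) to every bin before
    normalization, so the distance is finite and exactly zero for identical
    samples.
    """
    pooled = np.concatenate([x, y])
    nbins = sturges_classes(len(pooled))
    edges = np.histogram_bin_edges(pooled, bins=nbins)
    hx, _ = np.histogram(x, bins=edges)
    hy, _ = np.histogram(y, bins=edges)
    eps = 1.0 / (2.0 * len(pooled))
    p = hx + eps
    q = hy + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(0.5 * (stats.entropy(p, q) + stats.entropy(q, p)))


def distribution_tests(ec_values, cc_values) -> dict:
    """Per-trait EC-vs-CC distribution comparison battery.

    Returns a mapping label -> TestResult for: Welch t, two-group
    Newman-Keuls, Brown-Forsythe Levene, Wilcoxon rank-sum (normal
    approximation with continuity and tie correction), two-sample KS,
    k=2-sample Anderson-Darling, and the symmetrized KL distance (no
    p-value). Samples of fewer than 5 values yield undefined-flagged results.
    """
    x = pd.Series(ec_values).dropna().to_numpy(dtype=float)
    y = pd.Series(cc_values).dropna().to_numpy(dtype=float)
    if min(len(x), len(y)) < 5:
        nan = float("nan")
        return {lab: TestResult(lab, nan, nan, note="sample < 5")
                for lab in ("t", "newman_keuls", "levene", "wilcoxon", "ks",
                            "anderson_darling", "kl")}
    out = {}
    t_res = stats.ttest_ind(y, x, equal_var=False)
    out["t"] = TestResult("t", float(t_res.statistic), float(t_res.pvalue),
                          df=float(t_res.df))
    out["newman_keuls"] = _newman_keuls_two(x, y)
    lev = stats.levene(x, y, center="median")
    out["levene"] = TestResult("levene", float(lev.statistic),
                               float(lev.pvalue), df=(1, len(x) + len(y) - 2))
    mw = stats.mannwhitneyu(y, x, alternative="two-sided",
                            method="asymptotic", use_continuity=True)
    out["wilcoxon"] = TestResult("wilcoxon", float(mw.statistic),
                                 float(mw.pvalue))
    ks = stats.ks_2samp(x, y)
    out["ks"] = TestResult("ks", float(ks.statistic), float(ks.pvalue))
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: AD midrank statistic is at its minimum
        out["anderson_darling"] = TestResult("anderson_darling", 0.0, 1.0,
                                             note="identical samples")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # p capped outside [0.001, 0.25]
            ad = stats.anderson_ksamp([x, y])
        out["anderson_darling"] = TestResult(
            "anderson_darling", float(ad.statistic),
            float(ad.significance_level))
    out["kl"] = TestResult("kl", kl_distance(x, y), None)
    return out


def qq_data(ec_values, cc_values) -> pd.DataFrame:
    """Matched quantile pairs on the plotting grid (i - 0.5)/n, n = min size."""
    x = pd.Series(ec_values).dropna().to_numpy(dtype=float)
    y = pd.Series(cc_values).dropna().to_numpy(dtype=float)
    if min(len(x), len(y)) < 2:
        raise ComputationError("need >= 2 values in each sample")
    n = min(len(x), len(y))
    probs = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "prob": probs,
        "ec_quantile": np.quantile(x, probs, method="linear"),
        "cc_quantile": np.quantile(y, probs, method="linear"),
    })


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """The machine-readable core-quality report for one core set."""

    method: str
    core_size: int
    md: float
    vd: float
    cr: float
    vr: float
    coverage: float
    phenotype_ratio: float
    objectives: ObjectiveValues | None
    sign_mean: TestResult
    sign_variance: TestResult
    mantel: TestResult | None
    shannon: pd.DataFrame
    trait_tests: dict = field(default_factory=dict)  # trait -> {label: TestResult}

    def passes_quality_gate(self, md_limit: float = 20.0,
                            cr_floor: float = 80.0) -> bool:
        """The conventional Hu acceptance rule: MD% < 20 and CR% > 80."""
        return self.md < md_limit and self.cr > cr_floor

    def summary_row(self) -> dict:
        row = {"method": self.method, "size": self.core_size,
               "MD%": self.md, "VD%": self.vd, "CR%": self.cr, "VR%": self.vr,
               "class_coverage%": self.coverage,
               "phenotype_ratio": self.phenotype_ratio,
               "sign_mean_p": self.sign_mean.p,
               "sign_variance_p": self.sign_variance.p}
        if self.objectives is not None:
            row.update({"E-NE": self.objectives.e_ne,
                        "A-NE": self.objectives.a_ne,
                        "E-E": self.objectives.e_e})
        if self.mantel is not None:
            row.update({"mantel_r": self.mantel.statistic,
                        "mantel_p": self.mantel.p})
        return row


def evaluate_core(ec_quant: pd.DataFrame, core_ids, descriptors,
                  ec_qual: pd.DataFrame | None = None,
                  distance=None, method: str = "core", alpha: float = 0.05,
                  permutations: int = 999, seed: int = 0,
                  run_trait_tests: bool = True) -> EvaluationReport:
    """Evaluate one core against the entire collection.

    ``ec_quant`` is the accession x quantitative-trait table (typically the
    adjusted test means); ``ec_qual`` the accession x qualitative-state table.
    """
    core_ids = [a for a in core_ids]
    missing = [a for a in core_ids if a not in ec_quant.index]
    if missing:
        raise SchemaError(f"core ids not in the collection: {missing[:5]}")
    cc_quant = ec_quant.loc[core_ids]

    md, vd, cr, vr = hu_indices(ec_quant, cc_quant, alpha)

    quant_names = [c for c in ec_quant.columns]
    if ec_qual is not None and len(ec_qual.columns):
        full = ec_quant.join(ec_qual, how="left")
    else:
        full = ec_quant
    coverage, ratio = class_coverage(full, full.loc[core_ids], descriptors,
                                     subset=[c for c in full.columns])

    if ec_qual is not None and len(ec_qual.columns):
        shannon = shannon_table(ec_qual, ec_qual.loc[core_ids], descriptors)
    else:
        shannon = pd.DataFrame()

    s_mean, s_var = sign_test_pair(ec_quant, cc_quant)

    mantel = None
    if len(quant_names) >= 3:
        try:
            m1 = ec_quant.corr()
            m2 = cc_quant.corr()
            mantel = mantel_test(m1, m2, permutations, seed)
        except ComputationError:
            mantel = None

    objectives = None
    if distance is not None:
        from .sampling import core_objective
        objectives = core_objective(distance, core_ids)

    trait_tests = {}
    if run_trait_tests:
        for t in quant_names:
            trait_tests[t] = distribution_tests(ec_quant[t], cc_quant[t])

    return EvaluationReport(
        method=method, core_size=len(core_ids), md=md, vd=vd, cr=cr, vr=vr,
        coverage=coverage, phenotype_ratio=ratio, objectives=objectives,
        sign_mean=s_mean, sign_variance=s_var, mantel=mantel,
        shannon=shannon, trait_tests=trait_tests)
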