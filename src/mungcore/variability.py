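"""Genetic variability parameters per quantitative trait.

For each trait, from the adjusted test means and the design's error mean
square:

    Vp  = variance of adjusted test means (phenotypic variance of a
          once-replicated entry; see the correction note below)
    Ve  = error MS
    Vg  = Vp - Ve                      (genotypic variance)
    GCV = 100 * sqrt(Vg) / mean        PCV = 100 * sqrt(Vp) / mean
    h2  = 100 * Vg / Vp                (broad sense, percent)
    GA  = k * sqrt(Vp) * h2/100        (genetic advance at selection
                                        intensity k, default 2.063 = 5%)
    GG  = 100 * GA / mean              (genetic gain, percent of mean)

Correction note: an adjusted test mean carries the plot error once *plus*
the noise of its block-effect estimate, which for c checks with r replicates
per block adds Ve/(r*c). The raw variance of adjusted means therefore
overstates the entry-level phenotypic variance; by default it is deflated by
Ve/(r*c) before the decomposition, which makes both h2 and Vg recovery
unbiased on simulated trials. ``correct_adjustment_variance=False`` keeps the
plain convention (Vp = raw variance of adjusted means) used by most field
reports. Either way Vg is floored at zero (with a flag) when the error MS
exceeds Vp.

Categories follow the usual breeding-literature bands: h2 < 30 Low, 30-60
Medium, > 60 High; GCV/PCV, GA and GG < 10 Low, 10-20 Medium, > 20 High
(boundaries closed on the lower side).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AdjustedMeans
from .errors import ComputationError

#: selection differential at 5% selected fraction (Johnson et al. constant)
DEFAULT_SELECTION_INTENSITY = 2.063

_CATEGORY_BANDS = {
    "h2": (30.0, 60.0),
    "gcv_pcv": (10.0, 20.0),
    "ga": (10.0, 20.0),
    "gg": (10.0, 20.0),
}


def categorize(value: float, parameter: str) -> str:
    """Low/Medium/High label for a variability parameter.

    Boundaries are closed on the lower side: a value exactly at the lower
    band edge is Medium, exactly at the upper edge is High.
    """
    if parameter not in _CATEGORY_BANDS:
        raise ComputationError(f"unknown parameter {parameter!r}")
    if not np.isfinite(value) or value < 0:
        raise ComputationError(f"cannot categorize value {value!r}")
    lo, hi = _CATEGORY_BANDS[parameter]
    if value < lo:
        return "Low"
    if value < hi:
        return "Medium"
    return "High"


@dataclass
class VariabilityResult:
    """Per-trait variability parameters (the 'Table 1' of a trial report)."""

    table: pd.DataFrame
    k: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="trait")


def variability_params(adj: AdjustedMeans,
                       k: float = DEFAULT_SELECTION_INTENSITY,
                       correct_adjustment_variance: bool = True
                       ) -> VariabilityResult:
    """Estimate Vp, Vg, GCV, PCV, h2, GA, GG and their categories per trait."""
    tests = adj.test_means()
    if len(tests) < 3:
        raise ComputationError("need >= 3 test accessions")
    rc = adj.reps_per_check * adj.n_checks
    rows = {}
    for trait in tests.columns:
        x = tests[trait].dropna().to_numpy(dtype=float)
        mean = float(x.mean())
        vp = float(x.var(ddof=1))
        ve = float(adj.ve[trait])
        if correct_adjustment_variance and vp - ve / rc > 0:
            # the adjusted means carry the block-effect estimation noise
            # Ve/(r*c) on top of the entry's own Vg + Ve; remove it from the
            # phenotypic variance before decomposing (skipped when the data
            # are so noisy the correction would exhaust Vp)
            vp = vp - ve / rc
        vg = vp - ve
        floored = vg < 0
        if floored:
            warnings.warn(f"Vg floored at 0 for trait {trait!r} "
                          f"(error MS exceeds Vp)", stacklevel=2)
            vg = 0.0
        if vp <= 0:
            raise ComputationError(f"non-positive Vp for trait {trait!r}")
        h2 = 100.0 * vg / vp
        ga = k * math.sqrt(vp) * h2 / 100.0
        if mean == 0:
            warnings.warn(f"zero mean for trait {trait!r}: CVs undefined",
                          stacklevel=2)
            gcv = pcv = gg = float("nan")
        else:
            gcv = 100.0 * math.sqrt(vg) / mean
            pcv = 100.0 * math.sqrt(vp) / mean
            gg = 100.0 * ga / mean
        rows[trait] = {
            "mean": mean, "vp": vp, "vg": vg, "ve": ve, "vg_floored": floored,
            "gcv": gcv, "pcv": pcv,
            "gcv_category": _safe_cat(gcv, "gcv_pcv"),
            "pcv_category": _safe_cat(pcv, "gcv_pcv"),
            "h2": h2, "h2_category": categorize(h2, "h2"),
            "ga": ga, "ga_category": categorize(ga, "ga"),
            "gg": gg, "gg_category": _safe_cat(gg, "gg"),
        }
    table = pd.DataFrame(rows).T
    return VariabilityResult(table, k)


def _safe_cat(value, parameter):
    if not np.isfinite(value):
        return "Undefined"
    return categorize(value, parameter)


# ---------------------------------------------------------------------------
# identities used to verify the formulas against a printed trial report
# ---------------------------------------------------------------------------

def heritability_from_cv(gcv: float, pcv: float) -> float:
    """h2 (%) from the coefficient-of-variation pair: 100 * (GCV/PCV)**2."""
    if pcv <= 0:
        raise ComputationError("PCV must be positive")
    return 100.0 * (gcv / pcv) ** 2


def genetic_advance(h2_fraction: float, pcv: float, mean: float,
                    k: float = DEFAULT_SELECTION_INTENSITY) -> float:
    """GA = k * h2 * sqrt(Vp), with sqrt(Vp) recovered as PCV*mean/100."""
    return k * h2_fraction * (pcv * mean / 100.0)


def genetic_gain(ga: float, mean: float) -> float:
    """GG (%) = 100 * GA / mean."""
    if mean == 0:
        raise ComputationError("zero mean")
    return 100.0 * ga / mean
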