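"""Core-subset sampling strategies.

Five strategies are provided, mirroring the methods commonly compared when
building a germplasm core collection:

* ``en100`` / ``an100`` / ``en50an50`` -- local-search subset selection under
  the Odong-style nearest-entry objectives:

  - E-NE: mean distance from each core entry to its nearest other entry
    (diversity; larger is better),
  - A-NE: mean distance from each accession of the whole collection to its
    nearest core entry (representativeness; smaller is better),

  combined as ``w_EN * norm(E-NE) - w_AN * norm(A-NE)`` and maximized by
  random-descent swaps;
* ``powercore`` -- greedy class-coverage (an M-strategy approximation):
  quantitative traits are discretized into Sturges classes and accessions are
  added to cover the most still-uncovered classes, then remaining slots are
  filled by farthest-point (E-NE-maximizing) additions;
* ``pcss`` -- principal component score strategy: accessions ranked by their
  contribution to the retained (eigenvalue > 1) principal components.

Because E-NE and A-NE live on different scales, the weighted objective
normalizes each by its range over an ensemble of random cores drawn once per
optimization (the normalization is monotone, so single-objective runs are
unaffected by it).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, gower_matrix
from .errors import ComputationError, ConfigError, InfeasibleError
from .traits import validate_descriptor_set

METHODS = ("powercore", "pcss", "en100", "an100", "en50an50")

#: (w_EN, w_AN) pairs of the three nearest-entry strategies
METHOD_WEIGHTS = {"en100": (1.0, 0.0), "an100": (0.0, 1.0), "en50an50": (0.5, 0.5)}


@dataclass(frozen=True)
class ObjectiveValues:
    """The three Odong core-quality distances."""

    e_ne: float  # mean entry-to-nearest-entry distance
    a_ne: float  # mean accession-to-nearest-entry distance
    e_e: float   # mean pairwise entry distance


@dataclass(frozen=True)
class CoreSet:
    """An ordered core subset with its sampling provenance."""

    ids: tuple
    method: str
    w_en: float = 0.0
    w_an: float = 0.0
    forced: tuple = field(default_factory=tuple)
    groups_covered: tuple = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "forced", tuple(self.forced))
        object.__setattr__(self, "groups_covered", tuple(self.groups_covered))
        if len(set(self.ids)) != len(self.ids):
            raise ConfigError("core contains duplicate accession ids")
        if not set(self.forced) <= set(self.ids):
            raise ConfigError("forced-include ids missing from the core")

    @property
    def size(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# objective evaluation
# ---------------------------------------------------------------------------

def _e_ne(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _a_ne(d: np.ndarray, idx: np.ndarray) -> float:
    return float(d[:, idx].min(axis=1).mean())


def _e_e(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def core_objective(d: DistanceMatrix, core_ids) -> ObjectiveValues:
    """Evaluate E-NE, A-NE and E-E for a core subset.

    Accessions inside the core contribute 0 to A-NE (their nearest entry is
    themselves). E-NE and E-E require at least two entries and are reported
    as ``nan`` for singleton cores.
    """
    core_ids = list(core_ids)
    if not core_ids:
        raise ComputationError("empty core")
    idx = d.index_of(core_ids)
    a = _a_ne(d.values, idx)
    if len(idx) >= 2:
        e = _e_ne(d.values, idx)
        ee = _e_e(d.values, idx)
    else:
        e = float("nan")
        ee = float("nan")
    return ObjectiveValues(e_ne=e, a_ne=a, e_e=ee)


class ObjectiveNormalizer:
    """Range-normalization of E-NE and A-NE over a random-core ensemble.

    ``n_samples`` random cores of the target size are scored once; each
    objective is then rescaled by its observed (min, range). Degenerate
    ranges fall back to 1 so single-objective optimization stays well-defined.
    """

    def __init__(self, d: DistanceMatrix, size: int, seed: int = 0,
                 n_samples: int = 200):
        rng = np.random.default_rng(seed)
        ene, ane = [], []
        for _ in range(n_samples):
            idx = rng.choice(d.n, size=size, replace=False)
            if size >= 2:
                ene.append(_e_ne(d.values, idx))
            ane.append(_a_ne(d.values, idx))
        self.ene_lo, self.ene_range = self._bounds(ene)
        self.ane_lo, self.ane_range = self._bounds(ane)

    @staticmethod
    def _bounds(values):
        if not values:
            return 0.0, 1.0
        lo, hi = min(values), max(values)
        return lo, (hi - lo) if hi > lo else 1.0

    def score(self, d_values: np.ndarray, idx: np.ndarray,
              w_en: float, w_an: float) -> float:
        s = 0.0
        if w_en > 0:
            s += w_en * (_e_ne(d_values, idx) - self.ene_lo) / self.ene_range
        if w_an > 0:
            s -= w_an * (_a_ne(d_values, idx) - self.ane_lo) / self.ane_range
        return s


def weighted_objective(d: DistanceMatrix, core_ids, w_en: float, w_an: float,
                       normalizer: ObjectiveNormalizer) -> float:
    """Normalized weighted EN/AN objective of a core (maximized)."""
    return normalizer.score(d.values, d.index_of(list(core_ids)), w_en, w_an)


# ---------------------------------------------------------------------------
# local-search optimizer (EN100 / AN100 / EN50:AN50)
# ---------------------------------------------------------------------------

def optimize_core(d: DistanceMatrix, size: int, w_en: float = 1.0,
                  w_an: float = 0.0, forced=(), seed: int = 0,
                  budget: int = 50_000, restarts: int = 20,
                  max_proposals: int | None = None,
                  normalizer: ObjectiveNormalizer | None = None,
                  method: str | None = None) -> CoreSet:
    """Random-descent subset selection for the weighted EN/AN objective.

    Starting from a random size-``size`` subset (containing all ``forced``
    ids), single swaps between a non-forced entry and an outside accession
    are proposed uniformly at random and accepted when they strictly improve
    the normalized objective. A restart terminates after ``budget``
    consecutive non-improving proposals (or ``max_proposals`` in total); the
    best core over ``restarts`` restarts is returned. Fully deterministic
    given ``seed``.
    """
    if w_en < 0 or w_an < 0:
        raise ConfigError("objective weights must be non-negative")
    if abs(w_en + w_an - 1.0) > 1e-9:
        raise ConfigError("objective weights must sum to 1")
    if size > d.n:
        raise ConfigError(f"core size {size} exceeds collection size {d.n}")
    if size < 1 or (w_en > 0 and size < 2):
        raise ConfigError("size must be >= 2 when E-NE enters the objective")
    forced = tuple(forced)
    forced_idx = d.index_of(forced)
    if len(forced_idx) > size:
        raise ConfigError("more forced ids than core slots")

    if method is None:
        method = {(1.0, 0.0): "en100", (0.0, 1.0): "an100",
                  (0.5, 0.5): "en50an50"}.get((w_en, w_an), "weighted")

    if size == d.n:
        return CoreSet(d.ids, method, w_en, w_an, forced, seed=seed)

    if normalizer is None:
        normalizer = ObjectiveNormalizer(d, size, seed=seed)

    rng = np.random.default_rng(seed)
    values = d.values
    free_slots = size - len(forced_idx)
    forced_set = set(forced_idx.tolist())
    pool = np.array([i for i in range(d.n) if i not in forced_set], dtype=int)

    best_idx, best_score = None, -np.inf
    for _ in range(max(1, restarts)):
        start = rng.choice(pool, size=free_slots, replace=False)
        core = np.concatenate([forced_idx, start]).astype(int)
        in_core = np.zeros(d.n, dtype=bool)
        in_core[core] = True
        score = normalizer.score(values, core, w_en, w_an)

        stale = 0
        proposals = 0
        n_fixed = len(forced_idx)
        outside = np.array([i for i in range(d.n) if not in_core[i]], dtype=int)
        while stale < budget and len(outside) > 0 and free_slots > 0:
            if max_proposals is not None and proposals >= max_proposals:
                break
            proposals += 1
            pos = n_fixed + int(rng.integers(free_slots))
            j = int(outside[rng.integers(len(outside))])
            old = core[pos]
            core[pos] = j
            cand = normalizer.score(values, core, w_en, w_an)
            if cand > score + 1e-12:
                score = cand
                in_core[old] = False
                in_core[j] = True
                outside[outside == j] = old
                stale = 0
            else:
                core[pos] = old
                stale += 1

        if score > best_score:
            best_score = score
            best_idx = core.copy()

    ids = tuple(sorted((d.ids[i] for i in best_idx), key=str))
    return CoreSet(ids, method, w_en, w_an, forced, seed=seed)


# ---------------------------------------------------------------------------
# PowerCore-style greedy class coverage
# ---------------------------------------------------------------------------

def sturges_classes(n: int) -> int:
    """Sturges' histogram class count, ceil(1 + log2 n)."""
    return int(math.ceil(1.0 + math.log2(max(n, 2))))


def trait_classes(table: pd.DataFrame, descriptors, subset=None):
    """Map each accession to the set of (trait, class) labels it carries.

    Quantitative traits are discretized into Sturges-rule classes over the
    collection's range; qualitative descriptor states are classes as-is.
    Returns ``(classes_per_accession, class_counts)`` where ``class_counts``
    counts carriers per class over the whole table.
    """
    validate_descriptor_set(descriptors)
    by_name = {d.name: d for d in descriptors}
    names = list(subset) if subset is not None else list(table.columns)
    n = len(table)
    nbins = sturges_classes(n)

    covers = {acc: set() for acc in table.index}
    for name in names:
        desc = by_name[name]
        col = table[name]
        if desc.is_quantitative:
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            lo, hi = np.nanmin(x), np.nanmax(x)
            if not np.isfinite(lo) or hi <= lo:
                continue
            edges = np.linspace(lo, hi, nbins + 1)
            bins = np.clip(np.digitize(x, edges[1:-1], right=False), 0, nbins - 1)
            for acc, b, v in zip(table.index, bins, x):
                if np.isfinite(v):
                    covers[acc].add((name, int(b)))
        else:
            for acc, v in col.items():
                if pd.notna(v):
                    covers[acc].add((name, v))

    counts = {}
    for cls_set in covers.values():
        for c in cls_set:
            counts[c] = counts.get(c, 0) + 1
    return covers, counts


def powercore_sample(table: pd.DataFrame, descriptors, size: int,
                     seed: int = 0, subset=None):
    """Greedy maximum-class-coverage core ('advanced M strategy' style).

    Returns ``(CoreSet, coverage_percent)``. Ties in the greedy step are
    broken toward the accession covering the rarest class, then by ascending
    accession id. Once every observed class is covered, remaining slots are
    filled farthest-point style to push up E-NE. Not an error when ``size``
    cannot cover all classes -- the achieved coverage is simply reported.
    """
    if size < 1:
        raise ConfigError("core size must be >= 1")
    covers, counts = trait_classes(table, descriptors, subset)
    universe = set(counts)
    accessions = sorted(table.index, key=str)

    chosen: list = []
    uncovered = set(universe)
    remaining = set(accessions)
    while len(chosen) < size and uncovered and remaining:
        best_key, best_acc = None, None
        for acc in sorted(remaining, key=str):
            new = covers[acc] & uncovered
            if not new:
                continue
            rarest = min(counts[c] for c in new)
            key = (-len(new), rarest)  # most new classes, then rarest class
            if best_key is None or key < best_key:
                best_key, best_acc = key, acc
        if best_acc is None:
            break
        chosen.append(best_acc)
        uncovered -= covers[best_acc]
        remaining.discard(best_acc)

    if len(chosen) < size:
        # farthest-point fill on Gower distance to lift E-NE
        d = gower_matrix(table, descriptors, subset)
        in_core = np.zeros(d.n, dtype=bool)
        in_core[d.index_of(chosen)] = True
        if not chosen:
            first = accessions[np.random.default_rng(seed).integers(len(accessions))]
            chosen.append(first)
            in_core[d.index_of([first])[0]] = True
        nearest = d.values[:, in_core].min(axis=1)
        nearest[in_core] = -np.inf
        while len(chosen) < size:
            i = int(np.argmax(nearest))
            chosen.append(d.ids[i])
            in_core[i] = True
            nearest = np.minimum(nearest, d.values[:, i])
            nearest[i] = -np.inf

    covered = set().union(*(covers[a] for a in chosen)) & universe
    coverage = 100.0 * len(covered) / len(universe) if universe else 100.0
    core = CoreSet(tuple(sorted(chosen, key=str)), "powercore", seed=seed)
    return core, coverage


# ---------------------------------------------------------------------------
# PCSS: principal component score strategy
# ---------------------------------------------------------------------------

def pcss_sample(table: pd.DataFrame, size: int, subset=None) -> CoreSet:
    """Select the ``size`` accessions contributing most to the retained PCs.

    PCA is run on standardized quantitative traits; components with
    eigenvalue > 1 are retained (all components if none exceed 1); an
    accession's contribution is the sum over retained components of its
    squared standardized score weighted by the component's variance share.
    Deterministic; ties broken by ascending accession id.
    """
    if size < 1 or size > len(table):
        raise ConfigError("invalid core size")
    cols = list(subset) if subset is not None else list(table.columns)
    x = table[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    keep = []
    for j, name in enumerate(cols):
        sd = np.nanstd(x[:, j], ddof=1)
        if np.isfinite(sd) and sd > 0:
            keep.append(j)
        else:
            warnings.warn(f"zero-variance trait {name!r} dropped from PCSS",
                          stacklevel=2)
    if len(keep) < 2:
        raise ComputationError("PCSS needs >= 2 non-constant quantitative traits")
    x = x[:, keep]
    if np.isnan(x).any():
        mu = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = mu[idx[1]]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    p = z.shape[1]
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    retained = eigval > 1.0
    if not retained.any():
        retained = np.ones_like(eigval, dtype=bool)
    scores = z @ eigvec[:, retained]
    lam = eigval[retained]
    with np.errstate(divide="ignore", invalid="ignore"):
        std_scores = scores / np.sqrt(np.where(lam > 0, lam, np.inf))
    contribution = (std_scores ** 2 * (lam / p)).sum(axis=1)

    order = sorted(range(len(table)),
                   key=lambda i: (-contribution[i], str(table.index[i])))
    ids = tuple(sorted((table.index[i] for i in order[:size]), key=str))
    return CoreSet(ids, "pcss")


# ---------------------------------------------------------------------------
# geographic-coverage repair
# ---------------------------------------------------------------------------

def enforce_geography(core: CoreSet, passport, d: DistanceMatrix,
                      normalizer: ObjectiveNormalizer | None = None) -> CoreSet:
    """Swap accessions into the core until every geographic group is covered.

    For each group absent from the core, every (group member, removable
    entry) swap is scored under the core's own weighted objective and the
    least-degrading one applied; entries that are forced, or that are the
    sole core representative of an already covered group, are never removed.
    The result has the same size and covers all groups.
    """
    group_of = {p.accession: p.group for p in passport}
    groups = sorted({g for g in group_of.values() if g})
    members = {g: sorted((a for a, gg in group_of.items() if gg == g), key=str)
               for g in groups}
    if len(groups) > core.size:
        raise InfeasibleError(
            f"{len(groups)} groups cannot be covered by a core of {core.size}")
    for g in groups:
        if not any(a in d._pos for a in members[g]):
            raise InfeasibleError(f"group {g!r} has no member in the collection")

    w_en, w_an = core.w_en, core.w_an
    if w_en == 0 and w_an == 0:
        w_en = 1.0  # coverage repair for non-EN/AN cores keeps diversity
    if normalizer is None:
        normalizer = ObjectiveNormalizer(d, core.size, seed=core.seed or 0)

    ids = list(core.ids)
    covered = {group_of.get(a) for a in ids}
    missing = [g for g in groups if g not in covered]

    for g in missing:
        current_groups = [group_of.get(a) for a in ids]
        counts = {}
        for gg in current_groups:
            if gg:
                counts[gg] = counts.get(gg, 0) + 1
        removable = [a for a in ids
                     if a not in core.forced
                     and (group_of.get(a) is None
                          or counts.get(group_of.get(a), 0) > 1
                          or group_of.get(a) not in groups)]
        candidates = [a for a in members[g] if a not in ids and a in d._pos]
        if not candidates or not removable:
            raise InfeasibleError(f"cannot cover group {g!r}")
        best = None
        for cand in candidates:
            for victim in removable:
                trial = [cand if a == victim else a for a in ids]
                s = normalizer.score(d.values, d.index_of(trial), w_en, w_an)
                key = (-s, str(cand), str(victim))
                if best is None or key < best[0]:
                    best = (key, cand, victim)
        _, cand, victim = best
        ids = [cand if a == victim else a for a in ids]

    covered = tuple(sorted({group_of.get(a) for a in ids if group_of.get(a)}))
    return CoreSet(tuple(sorted(ids, key=str)), core.method, core.w_en,
                   core.w_an, core.forced, groups_covered=covered,
                   seed=core.seed)
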