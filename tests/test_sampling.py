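"""Core sampling: objectives, local search vs exhaustive oracle, PowerCore,
PCSS and geographic-coverage repair."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mungcore as mc
from mungcore.distance import DistanceMatrix
from mungcore.errors import ComputationError, ConfigError, InfeasibleError
from mungcore.io import PassportRecord
from mungcore.sampling import ObjectiveNormalizer, weighted_objective
from mungcore.traits import TraitDescriptor

from oracles import exhaustive_best_core


def line_distance(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"A{i}" for i in range(len(pts))]
    return DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids, "abs")


def test_core_objective_hand_enumeration():
    d = line_distance([0.0, 1.0, 3.0])
    obj = mc.core_objective(d, ["A0", "A2"])
    assert obj.e_ne == pytest.approx(3.0)
    assert obj.a_ne == pytest.approx(1.0 / 3.0)
    assert obj.e_e == pytest.approx(3.0)


def test_core_equal_to_collection_has_zero_a_ne():
    d = line_distance([0.0, 2.0, 5.0, 9.0])
    obj = mc.core_objective(d, d.ids)
    assert obj.a_ne == 0.0


def test_pair_core_e_ne_equals_e_e():
    d = line_distance([0.0, 4.0, 10.0])
    obj = mc.core_objective(d, ["A0", "A2"])
    assert obj.e_ne == obj.e_e == pytest.approx(10.0)
    with pytest.raises(ComputationError):
        mc.core_objective(d, [])


def test_en100_finds_extreme_pair():
    d = line_distance([0.0, 1.0, 2.0, 10.0, 11.0])
    core = mc.optimize_core(d, 2, w_en=1.0, w_an=0.0, seed=0, restarts=5,
                            budget=200)
    assert set(core.ids) == {"A0", "A4"}  # E-NE = 11, the max pairwise
    assert core.method == "en100"


def test_an100_size_one_selects_medoid():
    d = line_distance([0.0, 1.0, 2.0, 10.0, 11.0])
    core = mc.optimize_core(d, 1, w_en=0.0, w_an=1.0, seed=0, restarts=5,
                            budget=200)
    assert core.ids == ("A2",)  # mean distance 4.0, all others >= 4.2


def test_size_equals_collection_and_forced_constraint():
    d = line_distance([0.0, 1.0, 5.0])
    core = mc.optimize_core(d, 3, 1.0, 0.0, seed=1)
    assert set(core.ids) == set(d.ids)
    for seed in range(4):
        core = mc.optimize_core(d, 2, 1.0, 0.0, forced=("A1",), seed=seed,
                                restarts=3, budget=100)
        assert "A1" in core.ids


def test_optimizer_determinism():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(30, 3))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) ** 0.5
    d = DistanceMatrix(d2, [f"A{i}" for i in range(30)], "euclid")
    a = mc.optimize_core(d, 6, 0.5, 0.5, seed=99, restarts=3, budget=500)
    b = mc.optimize_core(d, 6, 0.5, 0.5, seed=99, restarts=3, budget=500)
    assert a.ids == b.ids


def test_optimizer_weight_validation():
    d = line_distance([0.0, 1.0, 2.0])
    with pytest.raises(ConfigError):
        mc.optimize_core(d, 2, -0.2, 1.2)
    with pytest.raises(ConfigError):
        mc.optimize_core(d, 2, 0.7, 0.7)
    with pytest.raises(ConfigError):
        mc.optimize_core(d, 9, 1.0, 0.0)


def test_local_search_attains_exhaustive_optimum_small_instances():
    """Spot check of oracle equivalence (the full 100-instance sweep runs in
    the acceptance suite)."""
    rng = np.random.default_rng(5)
    for k, (w_en, w_an) in enumerate([(1.0, 0.0), (0.0, 1.0), (0.5, 0.5)]):
        pts = rng.normal(size=(10, 2))
        dv = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) ** 0.5
        d = DistanceMatrix(dv, [f"A{i}" for i in range(10)], "euclid")
        norm = ObjectiveNormalizer(d, 3, seed=k, n_samples=50)
        best_score, _ = exhaustive_best_core(d, 3, w_en, w_an, norm)
        core = mc.optimize_core(d, 3, w_en, w_an, seed=k, restarts=20,
                                budget=150, normalizer=norm)
        got = weighted_objective(d, core.ids, w_en, w_an, norm)
        assert got == pytest.approx(best_score, abs=1e-9)


def test_en_an_tradeoff_monotone_in_weight():
    rng = np.random.default_rng(17)
    pts = rng.normal(size=(60, 4))
    dv = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) ** 0.5
    d = DistanceMatrix(dv / dv.max(), [f"A{i:02d}" for i in range(60)], "euclid")
    norm = ObjectiveNormalizer(d, 8, seed=17)
    enes, anes = [], []
    for w in (0.0, 0.25, 0.5, 0.75, 1.0):
        core = mc.optimize_core(d, 8, w, 1.0 - w, seed=17, restarts=10,
                                budget=1500, normalizer=norm)
        obj = mc.core_objective(d, core.ids)
        enes.append(obj.e_ne)
        anes.append(obj.a_ne)
    # diversity rises with the EN weight, representativeness degrades
    assert all(b >= a - 1e-9 for a, b in zip(enes, enes[1:]))
    assert all(b >= a - 1e-9 for a, b in zip(anes, anes[1:]))


# ---------------------------------------------------------------------------
# PowerCore
# ---------------------------------------------------------------------------

QUAL = TraitDescriptor("c", "qualitative", "", ("A", "B", "C"))


def test_powercore_covers_all_states():
    table = pd.DataFrame({"c": ["A", "A", "B", "B", "C", "C"]},
                         index=[f"G{i}" for i in range(6)])
    core, coverage = mc.powercore_sample(table, [QUAL], size=3, seed=0)
    assert coverage == 100.0
    states = set(table.loc[list(core.ids), "c"])
    assert states == {"A", "B", "C"}


def test_powercore_greedy_prefers_widest_coverage():
    # G0 carries three rare states at once; specialists carry one each
    table = pd.DataFrame({
        "c1": ["A", "A", "B", "B", "B"],
        "c2": ["X", "X", "Y", "Y", "Y"],
        "c3": ["P", "P", "Q", "Q", "Q"],
    }, index=["G0", "G1", "G2", "G3", "G4"])
    desc = [TraitDescriptor("c1", "qualitative", "", ("A", "B")),
            TraitDescriptor("c2", "qualitative", "", ("X", "Y")),
            TraitDescriptor("c3", "qualitative", "", ("P", "Q"))]
    core, coverage = mc.powercore_sample(table, desc, size=2, seed=0)
    assert "G0" in core.ids or "G1" in core.ids
    assert coverage == 100.0


def test_powercore_greedy_hand_trace_suboptimal_cover():
    """Classic greedy set-cover trap: the optimal 2-accession cover exists
    but greedy needs 3; the documented greedy behavior is what we assert."""
    # universe of 6 states across three traits; greedy grabs the 4-state
    # accession first, then needs two more; the optimal pair covers 3+3.
    rows = {
        "g_greedy": ["s1", "t1", "u1", "v1"],
        "g_left": ["s1", "t1", "u2", "v2"],
        "g_right": ["s2", "t2", "u1", "v1"],
        "g_pad": ["s2", "t2", "u2", "v2"],
    }
    table = pd.DataFrame(rows, index=["c1", "c2", "c3", "c4"]).T
    desc = [TraitDescriptor(c, "qualitative", "", ("s1", "s2", "t1", "t2",
                                                   "u1", "u2", "v1", "v2"))
            for c in ["c1", "c2", "c3", "c4"]]
    covers = {"g_greedy": 4, "g_left": 4, "g_right": 4, "g_pad": 4}
    core, coverage = mc.powercore_sample(table, desc, size=2, seed=0)
    # 8 distinct (trait, state) classes; any two accessions cover exactly
    # 4 + 2 = 6 or 4 + 4 = 8 of them; greedy's tie rules pick g_greedy then
    # its complement g_pad
    assert core.ids == ("g_greedy", "g_pad")
    assert coverage == 100.0


def test_powercore_determinism_and_fill():
    rng = np.random.default_rng(2)
    table = pd.DataFrame({
        "q": rng.normal(size=30),
        "c": rng.choice(["A", "B"], 30),
    }, index=[f"G{i:02d}" for i in range(30)])
    desc = [TraitDescriptor("q", "quantitative"),
            TraitDescriptor("c", "qualitative", "", ("A", "B"))]
    a, cov_a = mc.powercore_sample(table, desc, size=12, seed=3)
    b, cov_b = mc.powercore_sample(table, desc, size=12, seed=3)
    assert a.ids == b.ids and cov_a == cov_b
    assert a.size == 12


# ---------------------------------------------------------------------------
# PCSS
# ---------------------------------------------------------------------------

def test_pcss_centroid_never_beats_off_center():
    table = pd.DataFrame({
        "q1": [0.0, 1.0, -1.0, 2.0, -2.0],
        "q2": [0.0, 1.0, -1.0, -2.0, 2.0],
    }, index=["center", "a", "b", "c", "d"])
    core = mc.pcss_sample(table, size=4)
    assert "center" not in core.ids


def test_pcss_outlier_selected_first():
    rng = np.random.default_rng(1)
    cluster1 = rng.normal(0, 0.2, size=(10, 3))
    cluster2 = rng.normal(1, 0.2, size=(10, 3))
    outlier = np.array([[8.0, -8.0, 8.0]])
    x = np.vstack([cluster1, cluster2, outlier])
    table = pd.DataFrame(x, columns=["q1", "q2", "q3"],
                         index=[f"G{i:02d}" for i in range(21)])
    core = mc.pcss_sample(table, size=1)
    assert core.ids == ("G20",)


def test_pcss_duplicates_tie_broken_by_id():
    table = pd.DataFrame({
        "q1": [5.0, 5.0, 0.0, 0.1, -0.3],
        "q2": [5.0, 5.0, 0.1, -0.2, 0.0],
    }, index=["dupB", "dupA", "m1", "m2", "m3"])
    core = mc.pcss_sample(table, size=1)
    assert core.ids == ("dupA",)  # equal contribution, ascending id wins


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def test_enforce_geography_noop_and_single_member_insertion():
    d = line_distance([0.0, 1.0, 2.0, 3.0, 10.0],
                      ids=["a", "b", "c", "d", "e"])
    passport = [PassportRecord("a", "g1"), PassportRecord("b", "g1"),
                PassportRecord("c", "g2"), PassportRecord("d", "g2"),
                PassportRecord("e", "g3")]
    core = mc.CoreSet(("a", "c", "e"), "en100", 1.0, 0.0, seed=0)
    fixed = mc.enforce_geography(core, passport, d)
    assert set(fixed.ids) == {"a", "c", "e"}  # already covered

    core2 = mc.CoreSet(("a", "b", "c"), "en100", 1.0, 0.0, seed=0)
    fixed2 = mc.enforce_geography(core2, passport, d)
    assert "e" in fixed2.ids  # sole member of the missing group
    assert fixed2.size == 3
    assert set(fixed2.groups_covered) == {"g1", "g2", "g3"}


def test_enforce_geography_matches_exhaustive_best_triple():
    # adversarial 6-accession instance: one swap must land on the best
    # group-covering triple
    pts = [0.0, 0.05, 5.0, 5.05, 10.0, 10.05]
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    d = line_distance(pts, ids=ids)
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
              "c1": "C", "c2": "C"}
    passport = [PassportRecord(k, v) for k, v in groups.items()]
    norm = ObjectiveNormalizer(d, 3, seed=0)

    best_score, best_sets = None, []
    for combo in itertools.combinations(ids, 3):
        if {groups[x] for x in combo} != {"A", "B", "C"}:
            continue
        s = weighted_objective(d, combo, 1.0, 0.0, norm)
        if best_score is None or s > best_score + 1e-12:
            best_score, best_sets = s, [set(combo)]
        elif abs(s - best_score) <= 1e-12:
            best_sets.append(set(combo))

    core = mc.CoreSet(("a1", "a2", "c2"), "en100", 1.0, 0.0, seed=0)
    fixed = mc.enforce_geography(core, passport, d, normalizer=norm)
    got = weighted_objective(d, fixed.ids, 1.0, 0.0, norm)
    assert got == pytest.approx(best_score, abs=1e-9)


def test_enforce_geography_infeasible_when_groups_exceed_size():
    d = line_distance([0.0, 1.0, 2.0], ids=["a", "b", "c"])
    passport = [PassportRecord("a", "g1"), PassportRecord("b", "g2"),
                PassportRecord("c", "g3")]
    core = mc.CoreSet(("a", "b"), "en100", 1.0, 0.0, seed=0)
    with pytest.raises(InfeasibleError):
        mc.enforce_geography(core, passport, d)
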