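"""Shared fixtures: hand-sized field books and a mid-sized synthetic
collection reused by the slower evaluation/trade-off tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mungcore as mc
from mungcore.io import FieldBook
from mungcore.traits import TraitDescriptor


def make_fieldbook(block_values, tests_per_block=None, qual=None,
                   trait="GY", check_names=("C1", "C2")):
    """Build a small field book by hand.

    ``block_values`` maps block -> {check name: value or list of replicate
    values}; ``tests_per_block`` maps block -> {test accession: value}.
    """
    rows = []
    plot = 1
    for block, checks in block_values.items():
        for name, vals in checks.items():
            vals = vals if isinstance(vals, (list, tuple)) else [vals]
            for v in vals:
                rows.append({"plot": plot, "block": block, "accession": name,
                             "role": "check", trait: v})
                plot += 1
        for name, v in (tests_per_block or {}).get(block, {}).items():
            rows.append({"plot": plot, "block": block, "accession": name,
                         "role": "test", trait: v})
            plot += 1
    plots = pd.DataFrame(rows)
    descriptors = [TraitDescriptor(trait, "quantitative", "g")]
    if qual:
        for name, states in qual.items():
            descriptors.append(TraitDescriptor(name, "qualitative", "",
                                               tuple(sorted(set(states.values())))))
            plots[name] = plots["accession"].map(states)
    return FieldBook(plots, descriptors)


@pytest.fixture
def worked_example_fieldbook():
    """Two blocks whose check means are 11 and 14; one test plot of 20 in
    block 2 (adjusted value must be 18.5)."""
    return make_fieldbook(
        block_values={1: {"C1": 10.0, "C2": 12.0}, 2: {"C1": 12.0, "C2": 16.0}},
        tests_per_block={1: {"T1": 15.0, "T2": 9.0}, 2: {"T3": 20.0}},
    )


def random_fieldbook(rng, n_blocks=3, n_checks=2, reps=1, n_tests=8,
                     trait="GY"):
    """A random augmented-design field book for oracle comparisons."""
    block_values = {}
    for b in range(1, n_blocks + 1):
        block_values[b] = {f"C{k+1}": [float(rng.normal(10, 2))
                                       for _ in range(reps)]
                           for k in range(n_checks)}
    tests = {b: {} for b in range(1, n_blocks + 1)}
    for t in range(n_tests):
        b = 1 + t % n_blocks
        tests[b][f"T{t+1:02d}"] = float(rng.normal(10, 3))
    return make_fieldbook(block_values, tests, trait=trait)


# ---------------------------------------------------------------------------
# mid-sized synthetic collection (shared across the slow tests)
# ---------------------------------------------------------------------------

COLLECTION_SEED = 11
CORE_SIZE = 100  # 10% of the collection


@pytest.fixture(scope="session")
def collection1000():
    cfg = mc.default_config(n_test=1000, seed=COLLECTION_SEED)
    return mc.generate_collection(cfg)


@pytest.fixture(scope="session")
def adjusted1000(collection1000):
    return mc.adjust_means(collection1000.fieldbook)


@pytest.fixture(scope="session")
def ec_quant1000(adjusted1000):
    return adjusted1000.test_means()


@pytest.fixture(scope="session")
def gower1000(collection1000, ec_quant1000):
    return mc.gower_matrix(ec_quant1000, collection1000.fieldbook.descriptors)


@pytest.fixture(scope="session")
def normalizer1000(gower1000):
    from mungcore.sampling import ObjectiveNormalizer
    return ObjectiveNormalizer(gower1000, CORE_SIZE, seed=COLLECTION_SEED)


def _optimize(d, normalizer, w_en, w_an):
    return mc.optimize_core(d, CORE_SIZE, w_en, w_an, seed=COLLECTION_SEED,
                            budget=1500, restarts=1, max_proposals=12_000,
                            normalizer=normalizer)


@pytest.fixture(scope="session")
def en100_core(gower1000, normalizer1000):
    return _optimize(gower1000, normalizer1000, 1.0, 0.0)


@pytest.fixture(scope="session")
def an100_core(gower1000, normalizer1000):
    return _optimize(gower1000, normalizer1000, 0.0, 1.0)
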