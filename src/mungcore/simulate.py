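"""Synthetic germplasm collections with augmented-block-design structure.

The generator emulates a genebank characterization trial: unreplicated test
accessions laid out across blocks, plus a small set of check varieties
replicated a fixed number of times in every block. The observation model for
a quantitative trait t on a plot in block j is

    y = mean_t + g (genotypic value, MVN across traits with the configured
        correlation matrix and variance Vg_t; identical across a check's
        replicate plots) + b_j (block effect, one standard-normal draw per
        block scaled per trait) + e (independent error, variance Ve_t)

so the phenotypic variance of a once-replicated test entry decomposes as
Vp = Vg + Ve, which is exactly the algebra the variability module estimates.
Qualitative descriptor states are attributes of the accession (drawn once
from the configured state-probability vector, constant across plots).

The default configuration reproduces the study conditions of the mungbean
characterization this package replicates: 3,903 tests, 50 blocks, 5 checks
sown twice per block, 21 quantitative traits (means/SD from the published
summary, Vg/Ve split from the published heritability), and 7 qualitative
traits with 29 states whose frequencies are calibrated so the collection's
Shannon H' matches the published values.

A truth record (genotypic values and block effects actually drawn) is
returned alongside the field book so downstream estimators can be tested for
parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference
from .errors import ConfigError, DesignError
from .io import FieldBook, PassportRecord, ROLE_CHECK, ROLE_TEST
from .traits import TraitDescriptor


@dataclass(frozen=True)
class QuantTraitSpec:
    name: str
    mean: float
    vg: float  # genotypic variance
    ve: float  # plot-level error variance
    unit: str = ""
    lognormal: bool = False  # skewed-trait option (latent-normal genotype)

    def __post_init__(self):
        if self.vg < 0 or self.ve < 0:
            raise ConfigError(f"negative variance for trait {self.name!r}")


@dataclass(frozen=True)
class QualTraitSpec:
    name: str
    states: tuple
    probs: tuple

    def __post_init__(self):
        if len(self.states) != len(self.probs) or len(self.states) < 2:
            raise ConfigError(f"bad state/probability spec for {self.name!r}")
        if abs(sum(self.probs) - 1.0) > 1e-8 or min(self.probs) < 0:
            raise ConfigError(f"state probabilities of {self.name!r} must "
                              "be non-negative and sum to 1")


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic collection."""

    n_test: int
    n_blocks: int
    checks: tuple
    reps_per_check_per_block: int
    quant_traits: list
    qual_traits: list = field(default_factory=list)
    corr: np.ndarray | None = None  # genotypic trait correlations
    block_sd: dict | float = 0.0    # per-trait sd of the block effect
    groups: dict = field(default_factory=dict)  # geographic label -> prob
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 2:
            raise ConfigError("need at least 2 blocks")
        if self.n_test < self.n_blocks:
            raise ConfigError("need at least one test accession per block")
        if not self.checks:
            raise DesignError("at least one check variety is required")
        if self.reps_per_check_per_block < 1:
            raise ConfigError("checks must appear at least once per block")
        p = len(self.quant_traits)
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (p, p):
                raise ConfigError("correlation matrix shape mismatch")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ConfigError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-10):
                raise ConfigError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ConfigError("correlation matrix is not positive semi-definite")
        if self.groups:
            tot = sum(self.groups.values())
            if abs(tot - 1.0) > 1e-8:
                raise ConfigError("group probabilities must sum to 1")

    def block_sd_for(self, name: str) -> float:
        if isinstance(self.block_sd, dict):
            return float(self.block_sd.get(name, 0.0))
        return float(self.block_sd)

    def descriptors(self) -> list:
        out = [TraitDescriptor(t.name, "quantitative", t.unit)
               for t in self.quant_traits]
        out += [TraitDescriptor(t.name, "qualitative", "", t.states)
                for t in self.qual_traits]
        return out


@dataclass
class TruthRecord:
    """What the generator actually drew, for recovery tests."""

    genotypic: pd.DataFrame      # accession x trait genotypic deviations g
    block_effects: pd.DataFrame  # block x trait effects b_j
    trait_means: pd.Series
    groups: dict                 # accession -> geographic group label

    def true_entry_mean(self, trait: str) -> pd.Series:
        """mean_t + g: the noiseless adjusted mean the pipeline should recover."""
        return self.trait_means[trait] + self.genotypic[trait]


@dataclass
class SyntheticCollection:
    fieldbook: FieldBook
    truth: TruthRecord
    passport: list


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def plan_abd_layout(n_test: int, n_blocks: int, checks, reps: int,
                    seed: int = 0) -> pd.DataFrame:
    """Assign test and check plots to blocks.

    Tests are split across blocks as evenly as possible (sizes differ by at
    most one) and the plot order within each block is randomized by ``seed``;
    every block receives every check exactly ``reps`` times.
    """
    checks = tuple(checks)
    if not checks:
        raise DesignError("at least one check variety is required")
    if n_test < n_blocks:
        raise DesignError("fewer test accessions than blocks")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    width = len(str(n_test))
    tests = [f"MB{str(i + 1).zfill(width)}" for i in range(n_test)]
    shuffled = list(rng.permutation(tests))
    base, extra = divmod(n_test, n_blocks)
    rows = []
    plot = 1
    start = 0
    for j in range(n_blocks):
        size = base + (1 if j < extra else 0)
        entries = [(t, ROLE_TEST) for t in shuffled[start:start + size]]
        start += size
        entries += [(c, ROLE_CHECK) for c in checks for _ in range(reps)]
        order = rng.permutation(len(entries))
        for k in order:
            acc, role = entries[k]
            rows.append({"plot": plot, "block": j + 1,
                         "accession": acc, "role": role})
            plot += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _mvn_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L L' = corr, robust to semi-definite matrices."""
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_collection(config: SyntheticConfig) -> SyntheticCollection:
    """Draw a field book (plus truth record and passport) from the config."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_geno = np.random.default_rng(streams[1])
    rng_qual = np.random.default_rng(streams[2])
    rng_block = np.random.default_rng(streams[3])
    rng_err = np.random.default_rng(streams[4])

    layout = plan_abd_layout(config.n_test, config.n_blocks, config.checks,
                             config.reps_per_check_per_block, config.seed)
    tests = sorted(layout.loc[layout["role"] == ROLE_TEST, "accession"].unique())
    accessions = list(config.checks) + tests
    n_acc = len(accessions)
    qnames = [t.name for t in config.quant_traits]
    p = len(qnames)

    corr = np.eye(p) if config.corr is None else np.asarray(config.corr, float)
    z = rng_geno.standard_normal((n_acc, p)) @ _mvn_factor(corr).T
    g = np.empty_like(z)
    for k, t in enumerate(config.quant_traits):
        sd = math.sqrt(t.vg)
        if t.lognormal and t.vg > 0 and t.mean > 0:
            # match the first two genotypic moments on the observed scale
            sigma2 = math.log(1.0 + t.vg / t.mean ** 2)
            mu = math.log(t.mean) - sigma2 / 2.0
            g[:, k] = np.exp(mu + math.sqrt(sigma2) * z[:, k]) - t.mean
        else:
            g[:, k] = sd * z[:, k]
    genotypic = pd.DataFrame(g, index=accessions, columns=qnames)

    # shared latent block draw, centered: block effects are identifiable only
    # up to a constant, so the generator keeps them sum-to-zero like the
    # adjustment model assumes
    u = rng_block.standard_normal(config.n_blocks)
    u = u - u.mean()
    block_fx = pd.DataFrame(
        {name: config.block_sd_for(name) * u for name in qnames},
        index=range(1, config.n_blocks + 1))

    states = {}
    for t in config.qual_traits:
        states[t.name] = rng_qual.choice(t.states, size=n_acc, p=t.probs)
    qual = pd.DataFrame(states, index=accessions)

    means = pd.Series({t.name: t.mean for t in config.quant_traits})
    acc_idx = layout["accession"].map({a: i for i, a in enumerate(accessions)})
    blk = layout["block"].to_numpy()
    obs = {}
    for k, t in enumerate(config.quant_traits):
        e = rng_err.standard_normal(len(layout)) * math.sqrt(t.ve)
        obs[t.name] = (t.mean + g[acc_idx, k]
                       + block_fx[t.name].to_numpy()[blk - 1] + e)
    plots = layout.copy()
    for name in qnames:
        plots[name] = obs[name]
    for t in config.qual_traits:
        plots[t.name] = qual[t.name].to_numpy()[acc_idx]

    fb = FieldBook(plots, config.descriptors(), ("synthetic", config.seed))

    if config.groups:
        labels = sorted(config.groups)
        probs = np.array([config.groups[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        draw = rng_qual.choice(labels, size=len(tests), p=probs)
        # every group gets at least one representative where feasible
        group_map = dict(zip(tests, draw))
        present = set(draw)
        missing = [lab for lab in labels if lab not in present]
        for i, lab in enumerate(missing):
            if i < len(tests):
                group_map[tests[i]] = lab
        passport = [PassportRecord(a, group_map[a]) for a in tests]
        groups = group_map
    else:
        passport = []
        groups = {}

    truth = TruthRecord(genotypic, block_fx, means, groups)
    return SyntheticCollection(fb, truth, passport)


# ---------------------------------------------------------------------------
# default (study-scale) configuration
# ---------------------------------------------------------------------------

def _geometric_probs_for_entropy(k: int, target_h: float) -> tuple:
    """Geometric state frequencies p_i ~ q**i with Shannon entropy target_h.

    The entropy of the normalized geometric vector increases monotonically
    from 0 (q -> 0) to ln k (q = 1), so a unique ratio exists for any
    achievable target.
    """
    if not 0 < target_h <= math.log(k) + 1e-9:
        raise ConfigError(f"entropy {target_h} not achievable with {k} states")

    def entropy(q):
        w = np.array([q ** i for i in range(k)], dtype=float)
        pvec = w / w.sum()
        return float(-(pvec * np.log(pvec)).sum())

    if target_h >= math.log(k) - 1e-9:
        q = 1.0
    else:
        q = brentq(lambda x: entropy(x) - target_h, 1e-9, 1.0 - 1e-12)
    w = np.array([q ** i for i in range(k)], dtype=float)
    pvec = w / w.sum()
    return tuple(float(x) for x in pvec)


# moderate genotypic correlations between biologically linked trait groups
_CORR_GROUPS = [
    (("SW", "SA", "SL", "SB", "PL"), 0.6),
    (("DFF", "DM"), 0.8),
    (("NPPP", "PWPP", "GY"), 0.7),
    (("TLL", "TLW", "PTL"), 0.6),
    (("PH", "PB"), 0.5),
    (("NPB", "NPPC"), 0.4),
]
_CORR_CROSS = [
    (("DFF", "DM"), ("SW", "SA", "SL", "SB", "PL"), -0.3),
    (("NPPP", "PWPP", "GY"), ("PB",), 0.35),
    (("SR",), ("SB",), 0.3),
]


def _nearest_psd_correlation(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    if w.min() >= 1e-10:
        return c
    w = np.clip(w, 1e-8, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def default_trait_correlation(names) -> np.ndarray:
    p = len(names)
    pos = {n: i for i, n in enumerate(names)}
    c = np.eye(p)
    for group, r in _CORR_GROUPS:
        members = [pos[n] for n in group if n in pos]
        for i in members:
            for j in members:
                if i != j:
                    c[i, j] = r
    for g1, g2, r in _CORR_CROSS:
        for n1 in g1:
            for n2 in g2:
                if n1 in pos and n2 in pos:
                    c[pos[n1], pos[n2]] = r
                    c[pos[n2], pos[n1]] = r
    return _nearest_psd_correlation(c)


def default_config(n_test: int = reference.N_TEST,
                   n_blocks: int | None = None,
                   seed: int = 0,
                   block_sd_frac: float = 0.5) -> SyntheticConfig:
    """Study-condition synthetic configuration.

    Trait means and phenotypic SDs come from the published entire-collection
    summary; the Vg/Ve split per trait comes from the published broad-sense
    heritability (Vg = h2 * SD^2). Qualitative state frequencies are
    geometric vectors calibrated so the collection-level Shannon H' matches
    the published diversity table. ``block_sd_frac`` scales the block-effect
    sd as a fraction of each trait's phenotypic SD.

    When ``n_test`` is scaled down from the study size, the block count is
    scaled proportionally (keeping roughly 78 tests per block) unless given.
    """
    if n_blocks is None:
        n_blocks = max(2, round(n_test * reference.N_BLOCKS / reference.N_TEST))
    names = list(reference.SUMMARY_TABLE)
    quant = []
    for name in names:
        mean, sd, unit, _ = reference.SUMMARY_TABLE[name]
        h2 = reference.VARIABILITY_TABLE[name][2] / 100.0
        vp = sd ** 2
        quant.append(QuantTraitSpec(name, mean, vg=h2 * vp,
                                    ve=(1.0 - h2) * vp, unit=unit))
    qual = []
    for name, (k, h_ec, _) in reference.SHANNON_TABLE.items():
        states = tuple(f"{name}_s{i + 1}" for i in range(k))
        qual.append(QualTraitSpec(name, states,
                                  _geometric_probs_for_entropy(k, h_ec)))
    total = sum(reference.ORIGIN_COUNTS.values())
    groups = {k: v / total for k, v in reference.ORIGIN_COUNTS.items()}
    block_sd = {name: block_sd_frac * reference.SUMMARY_TABLE[name][1]
                for name in names}
    return SyntheticConfig(
        n_test=n_test, n_blocks=n_blocks, checks=reference.CHECKS,
        reps_per_check_per_block=reference.REPS_PER_CHECK,
        quant_traits=quant, qual_traits=qual,
        corr=default_trait_correlation(names),
        block_sd=block_sd, groups=groups, seed=seed)
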