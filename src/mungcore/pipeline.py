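"""End-to-end pipeline: data -> adjusted means -> variability -> cores ->
evaluation -> best-core verdict -> report.

The "best core" rule formalizes the usual narrative choice: among the cores
passing the Hu quality gate (MD% < 20 and CR% > 80), pick the one with the
highest E-NE (diversity), breaking ties by higher class coverage and then
higher VR%. When no core passes the gate the highest-E-NE core is returned
with a flag. All stages are deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .design import AdjustedMeans, adjust_means
from .distance import DistanceMatrix, gower_matrix
from .errors import ConfigError, MungcoreError
from .evaluation import EvaluationReport, evaluate_core
from .io import (FieldBook, load_collection, load_passport, save_collection,
                 save_core_list, save_passport)
from .sampling import (CoreSet, METHOD_WEIGHTS, METHODS, ObjectiveNormalizer,
                       enforce_geography, optimize_core, pcss_sample,
                       powercore_sample)
from .variability import VariabilityResult, variability_params

log = logging.getLogger("mungcore")


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    mode: str = "synthetic"               # "synthetic" | "files"
    synthetic: simulate.SyntheticConfig | None = None
    fieldbook_path: str | None = None
    descriptor_path: str | None = None
    passport_path: str | None = None
    core_fraction: float = 0.10           # the conventional 10% threshold
    core_size: int | None = None          # overrides core_fraction when set
    methods: tuple = METHODS
    alpha: float = 0.05
    permutations: int = 999
    seed: int = 0
    forced: tuple = ()
    enforce_groups: bool = False
    budget: int = 50_000
    restarts: int = 20
    max_proposals: int | None = None
    out_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not (self.fieldbook_path
                                         and self.descriptor_path):
            raise ConfigError("files mode needs fieldbook and descriptor paths")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")
        if self.core_size is not None and self.core_size < 2:
            raise ConfigError("core size must be >= 2")

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "synthetic"}
        if self.synthetic is not None:
            payload["synthetic_seed"] = self.synthetic.seed
            payload["n_test"] = self.synthetic.n_test
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = None
        if "synthetic" in raw:
            s = raw.pop("synthetic")
            syn = simulate.default_config(
                n_test=int(s.get("n_test", 1000)),
                n_blocks=s.get("n_blocks"),
                seed=int(s.get("seed", raw.get("seed", 0))))
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(synthetic=syn, **raw)
        if isinstance(cfg.methods, list):
            cfg.methods = tuple(cfg.methods)
        cfg.validate()
        return cfg


@dataclass
class RunBundle:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    fieldbook: FieldBook
    truth: simulate.TruthRecord | None
    passport: list
    adjusted: AdjustedMeans
    variability: VariabilityResult
    distance: DistanceMatrix
    cores: dict                 # method -> CoreSet
    evaluations: dict           # method -> EvaluationReport
    best_method: str
    best_passed_gate: bool
    warnings: list = field(default_factory=list)

    def comparison_table(self) -> pd.DataFrame:
        """Evaluation indices side by side, one column per core set."""
        rows = {m: ev.summary_row() for m, ev in self.evaluations.items()}
        return pd.DataFrame(rows)


def _select_best(evaluations: dict):
    """Highest E-NE among gate-passing cores; coverage then VR tie-breaks."""
    def key(method):
        ev = evaluations[method]
        ene = ev.objectives.e_ne if ev.objectives else float("-inf")
        return (ene, ev.coverage, ev.vr, method)

    passing = [m for m, ev in evaluations.items() if ev.passes_quality_gate()]
    pool = passing if passing else list(evaluations)
    best = max(pool, key=key)
    return best, bool(passing)


def run_pipeline(config: PipelineConfig) -> RunBundle:
    config.validate()
    log.info("pipeline start (config %s, seed %d)", config.digest(), config.seed)

    truth = None
    passport = []
    if config.mode == "synthetic":
        syn = config.synthetic or simulate.default_config(seed=config.seed)
        coll = simulate.generate_collection(syn)
        fb, truth, passport = coll.fieldbook, coll.truth, coll.passport
    else:
        fb = load_collection(config.fieldbook_path, config.descriptor_path)
        if config.passport_path:
            passport = load_passport(config.passport_path)
    log.info("collection: %d tests, %d blocks, %d checks",
             len(fb.tests), len(fb.blocks), len(fb.checks))

    adjusted = adjust_means(fb)
    variability = variability_params(adjusted)

    ec_quant = adjusted.test_means()
    qual_all = fb.qualitative_table()
    ec_qual = qual_all.loc[list(adjusted.test_ids)] if len(qual_all.columns) \
        else qual_all.reindex(list(adjusted.test_ids))
    descriptors = fb.descriptors

    d = gower_matrix(ec_quant, descriptors)
    size = config.core_size or max(2, round(config.core_fraction * d.n))
    log.info("distance matrix %dx%d; core size %d", d.n, d.n, size)

    normalizer = ObjectiveNormalizer(d, size, seed=config.seed)
    cores = {}
    for method in config.methods:
        if method in METHOD_WEIGHTS:
            w_en, w_an = METHOD_WEIGHTS[method]
            core = optimize_core(d, size, w_en, w_an, forced=config.forced,
                                 seed=config.seed, budget=config.budget,
                                 restarts=config.restarts,
                                 max_proposals=config.max_proposals,
                                 normalizer=normalizer, method=method)
        elif method == "powercore":
            core, cov = powercore_sample(ec_quant.join(ec_qual), descriptors,
                                         size, seed=config.seed)
            log.info("powercore class coverage at build: %.2f%%", cov)
        else:  # pcss
            core = pcss_sample(ec_quant, size)
        if config.enforce_groups and passport:
            core = enforce_geography(core, passport, d, normalizer)
        cores[method] = core
        log.info("core %s built (%d entries)", method, core.size)

    evaluations = {}
    for method, core in cores.items():
        evaluations[method] = evaluate_core(
            ec_quant, core.ids, descriptors, ec_qual=ec_qual, distance=d,
            method=method, alpha=config.alpha,
            permutations=config.permutations, seed=config.seed)

    best, passed = _select_best(evaluations)
    log.info("best core: %s (quality gate %s)", best,
             "passed" if passed else "NOT passed by any core")
    return RunBundle(config, fb, truth, passport, adjusted, variability, d,
                     cores, evaluations, best, passed)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _header(config: PipelineConfig) -> str:
    return f"# mungcore config={config.digest()} seed={config.seed}\n"


def write_report(bundle: RunBundle, out_dir) -> Path:
    """Emit the run's tables as CSV plus a machine-readable summary.

    Layout: adjusted_means.csv, variability.csv, comparison.csv,
    shannon_<method>.csv, cores/<method>.csv, trait_tests_<method>.csv,
    summary.json, run.log-style provenance headers in every CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cores").mkdir(exist_ok=True)
    cfg = bundle.config
    head = _header(cfg)

    def dump(df: pd.DataFrame, name: str, **kw):
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(head)
            df.to_csv(fh, **kw)
        return path

    dump(bundle.adjusted.means, "adjusted_means.csv", index_label="accession")
    dump(bundle.adjusted.block_effects, "block_effects.csv",
         index_label="block")
    dump(bundle.variability.table, "variability.csv", index_label="trait")
    dump(bundle.comparison_table(), "comparison.csv", index_label="index")

    for method, core in bundle.cores.items():
        save_core_list(core, out / "cores" / f"{method}.csv")
    for method, ev in bundle.evaluations.items():
        if len(ev.shannon):
            dump(ev.shannon, f"shannon_{method}.csv", index_label="trait")
        if ev.trait_tests:
            rows = {}
            for trait, tests in ev.trait_tests.items():
                rows[trait] = {}
                for lab, tr in tests.items():
                    rows[trait][f"{lab}_stat"] = tr.statistic
                    rows[trait][f"{lab}_p"] = tr.p
            dump(pd.DataFrame(rows).T, f"trait_tests_{method}.csv",
                 index_label="trait")

    floored = bundle.variability.table.index[
        bundle.variability.table["vg_floored"].astype(bool)].tolist()
    summary = {
        "config": cfg.digest(),
        "seed": cfg.seed,
        "n_collection": len(bundle.adjusted.test_ids),
        "core_methods": list(bundle.cores),
        "best_method": bundle.best_method,
        "best_passed_quality_gate": bundle.best_passed_gate,
        "selection_rule": ("max E-NE subject to MD%<20 and CR%>80; "
                           "ties: class coverage, then VR% (codified rule)"),
        "warnings": bundle.warnings + (
            [f"Vg floored at 0 for traits: {floored}"] if floored else []),
        "comparison": json.loads(
            bundle.comparison_table().to_json(orient="columns")),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("report written to %s", out)
    return out


def save_synthetic_inputs(coll: simulate.SyntheticCollection, out_dir) -> None:
    """Write the generated field book, descriptors, truth and passport."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_collection(coll.fieldbook, out / "fieldbook.csv",
                    out / "descriptors.csv")
    coll.truth.genotypic.to_csv(out / "truth_genotypic.csv",
                                index_label="accession")
    coll.truth.block_effects.to_csv(out / "truth_block_effects.csv",
                                    index_label="block")
    if coll.passport:
        save_passport(coll.passport, out / "passport.csv")
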