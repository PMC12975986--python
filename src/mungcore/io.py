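"""Reading, validating and writing trial data.

File dialect: comma-separated UTF-8 with a mandatory header row and ``NA``
as the missing-value token.

* field book: columns ``plot, block, accession, role`` plus one column per
  trait; ``role`` is ``check`` or ``test``. A plot id may appear on several
  rows -- these are replicate intra-plot measurements and are averaged at
  load (``average_replicates=False`` keeps them).
* descriptor table: columns ``trait, kind, unit, states`` with descriptor
  states separated by ``|``.
* passport table: columns ``accession, group[, origin]``.
* core list: a ``#``-commented provenance header followed by one accession
  id per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError, SchemaError, UniquenessError
from .sampling import CoreSet
from .traits import (QUALITATIVE, QUANTITATIVE, TraitDescriptor,
                     qualitative_names, quantitative_names,
                     validate_descriptor_set)

NA_TOKEN = "NA"
_META_COLS = ("plot", "block", "accession", "role")
ROLE_CHECK = "check"
ROLE_TEST = "test"


@dataclass(frozen=True)
class PassportRecord:
    accession: str
    group: str
    origin: str | None = None


@dataclass
class FieldBook:
    """Plot-level observations of one augmented-block-design trial.

    ``plots`` is a wide DataFrame with the meta columns ``plot, block,
    accession, role`` followed by one column per trait; ``descriptors`` is
    the trait schema; ``environment`` a (location, year) label pair.
    """

    plots: pd.DataFrame
    descriptors: list
    environment: tuple = ("synthetic", 0)

    def __post_init__(self):
        validate_descriptor_set(self.descriptors)

    @property
    def blocks(self) -> list:
        return sorted(self.plots["block"].unique().tolist())

    @property
    def checks(self) -> list:
        mask = self.plots["role"] == ROLE_CHECK
        return sorted(self.plots.loc[mask, "accession"].unique().tolist(), key=str)

    @property
    def tests(self) -> list:
        mask = self.plots["role"] == ROLE_TEST
        return sorted(self.plots.loc[mask, "accession"].unique().tolist(), key=str)

    @property
    def quantitative_traits(self) -> list:
        return quantitative_names(self.descriptors)

    @property
    def qualitative_traits(self) -> list:
        return qualitative_names(self.descriptors)

    def reps_per_check(self) -> int:
        """Replicates of each check per block (validated to be constant)."""
        checks = self.plots[self.plots["role"] == ROLE_CHECK]
        counts = checks.groupby(["block", "accession"]).size()
        return int(counts.iloc[0]) if len(counts) else 0

    def qualitative_table(self) -> pd.DataFrame:
        """Per-accession qualitative states (first observed per accession)."""
        cols = self.qualitative_traits
        if not cols:
            return pd.DataFrame(index=sorted(self.plots["accession"].unique(),
                                             key=str))
        grp = self.plots.groupby("accession")[cols].first()
        return grp.sort_index(key=lambda ix: ix.map(str))

    def quantitative_table(self, roles=(ROLE_TEST,)) -> pd.DataFrame:
        """Per-accession raw plot means of the quantitative traits."""
        sub = self.plots[self.plots["role"].isin(roles)]
        tab = sub.groupby("accession")[self.quantitative_traits].mean()
        return tab.sort_index(key=lambda ix: ix.map(str))


def validate_fieldbook(fb: FieldBook) -> None:
    """Structural validation of an augmented-design field book.

    Checks must appear the same number of times in every block; tests appear
    exactly once; block ids form a contiguous integer set; trait values
    conform to their descriptor kind.
    """
    plots = fb.plots
    for col in _META_COLS:
        if col not in plots.columns:
            raise SchemaError(f"field book lacks required column {col!r}")
    bad_roles = set(plots["role"].unique()) - {ROLE_CHECK, ROLE_TEST}
    if bad_roles:
        raise SchemaError(f"unknown role labels: {sorted(map(str, bad_roles))}")

    blocks = sorted(plots["block"].unique().tolist())
    if blocks != list(range(min(blocks), min(blocks) + len(blocks))):
        raise DesignError(f"block ids are not contiguous: {blocks}")

    checks = fb.checks
    if checks:
        counts = (plots[plots["role"] == ROLE_CHECK]
                  .groupby(["block", "accession"]).size()
                  .unstack(fill_value=0)
                  .reindex(index=blocks, columns=checks, fill_value=0))
        reps = counts.to_numpy()
        expected = reps.max() if reps.size else 0
        for b in blocks:
            for c in checks:
                if counts.loc[b, c] != expected:
                    raise DesignError(
                        f"check {c!r} appears {counts.loc[b, c]} time(s) in "
                        f"block {b}, expected {expected}")

    test_counts = plots[plots["role"] == ROLE_TEST].groupby("accession").size()
    multi = test_counts[test_counts > 1]
    if len(multi):
        raise DesignError(
            f"test accessions replicated: {sorted(map(str, multi.index[:5]))}")
    overlap = set(fb.checks) & set(fb.tests)
    if overlap:
        raise DesignError(f"accessions appear as both check and test: {overlap}")

    for name in fb.quantitative_traits:
        col = plots[name]
        coerced = pd.to_numeric(col, errors="coerce")
        bad = col.notna() & coerced.isna()
        if bad.any():
            plot_id = plots.loc[bad, "plot"].iloc[0]
            raise ParseError(
                f"non-numeric value {col[bad].iloc[0]!r} in quantitative "
                f"trait {name!r} at plot {plot_id}")
    for d in fb.descriptors:
        if d.kind == QUALITATIVE and d.states:
            col = plots[d.name].dropna()
            bad = ~col.isin(d.states)
            if bad.any():
                plot_id = plots.loc[col[bad].index[0], "plot"]
                raise ParseError(
                    f"unknown state {col[bad].iloc[0]!r} for trait "
                    f"{d.name!r} at plot {plot_id}")


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def load_descriptors(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"trait", "kind"}
    if not required <= set(df.columns):
        raise SchemaError(f"descriptor table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        states = tuple(s for s in str(row.get("states", "")).split("|") if s)
        out.append(TraitDescriptor(row["trait"], row["kind"],
                                   row.get("unit", ""), states))
    validate_descriptor_set(out)
    return out


def save_descriptors(descriptors, path) -> None:
    rows = [{"trait": d.name, "kind": d.kind, "unit": d.unit,
             "states": "|".join(d.states)} for d in descriptors]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# field book
# ---------------------------------------------------------------------------

def load_collection(fieldbook_path, descriptor_path,
                    average_replicates: bool = True,
                    environment: tuple = ("", 0)) -> FieldBook:
    """Read and validate a field book against its descriptor table.

    Replicate rows for a plot (repeated intra-plot measurements) are averaged
    for quantitative traits unless ``average_replicates`` is False; the
    qualitative state of a plot must be consistent across its rows.
    """
    descriptors = load_descriptors(descriptor_path)
    df = pd.read_csv(fieldbook_path, na_values=[NA_TOKEN], keep_default_na=True)
    for col in _META_COLS:
        if col not in df.columns:
            raise SchemaError(f"field book lacks required column {col!r}")

    known = set(_META_COLS) | {d.name for d in descriptors}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"field book column {unknown[0]!r} has no descriptor")
    missing = [d.name for d in descriptors if d.name not in df.columns]
    if missing:
        raise SchemaError(f"trait {missing[0]!r} declared but absent from field book")

    df["role"] = df["role"].astype(str).str.strip().str.lower()
    df["accession"] = df["accession"].astype(str)
    df["block"] = pd.to_numeric(df["block"], errors="raise")

    quant = quantitative_names(descriptors)
    for name in quant:
        coerced = pd.to_numeric(df[name], errors="coerce")
        bad = df[name].notna() & coerced.isna()
        if bad.any():
            raise ParseError(
                f"non-numeric value {df.loc[bad, name].iloc[0]!r} in "
                f"quantitative trait {name!r} at plot {df.loc[bad, 'plot'].iloc[0]}")
        df[name] = coerced

    if average_replicates and df["plot"].duplicated().any():
        qual = qualitative_names(descriptors)
        agg = {name: "mean" for name in quant}
        agg.update({name: "first" for name in qual})
        agg.update({"block": "first", "accession": "first", "role": "first"})
        df = df.groupby("plot", as_index=False).agg(agg)
        df = df[list(_META_COLS) + quant + qual]

    fb = FieldBook(df.reset_index(drop=True), descriptors, environment)
    validate_fieldbook(fb)
    return fb


def save_collection(fb: FieldBook, fieldbook_path, descriptor_path=None) -> None:
    cols = list(_META_COLS) + [d.name for d in fb.descriptors]
    fb.plots[cols].to_csv(fieldbook_path, index=False, na_rep=NA_TOKEN)
    if descriptor_path is not None:
        save_descriptors(fb.descriptors, descriptor_path)


# ---------------------------------------------------------------------------
# passport
# ---------------------------------------------------------------------------

def load_passport(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise SchemaError("passport table needs an 'accession' column")
    if df["accession"].duplicated().any():
        dup = df.loc[df["accession"].duplicated(), "accession"].iloc[0]
        raise UniquenessError(f"duplicate accession id {dup!r} in passport table")
    records = []
    for _, row in df.iterrows():
        group = row.get("group", "") or ""
        origin = row.get("origin", "") or None
        records.append(PassportRecord(row["accession"], group, origin))
    return records


def save_passport(records, path) -> None:
    pd.DataFrame([{"accession": r.accession, "group": r.group,
                   "origin": r.origin or ""} for r in records]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# core lists
# ---------------------------------------------------------------------------

def save_core_list(core: CoreSet, path) -> None:
    """Write a core membership list with a provenance comment header."""
    if core.size == 0:
        raise SchemaError("refusing to write an empty core")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={core.method} w_en={core.w_en} w_an={core.w_an} "
                 f"size={core.size} seed={core.seed}\n")
        if core.forced:
            fh.write("# forced=" + ",".join(map(str, core.forced)) + "\n")
        if core.groups_covered:
            fh.write("# groups=" + ",".join(map(str, core.groups_covered)) + "\n")
        fh.write("accession\n")
        for a in core.ids:
            fh.write(f"{a}\n")


def load_core_list(path) -> CoreSet:
    meta = {"method": "unknown", "w_en": 0.0, "w_an": 0.0, "seed": None}
    forced, groups = (), ()
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" not in tok:
                        continue
                    key, val = tok.split("=", 1)
                    if key in ("w_en", "w_an"):
                        meta[key] = float(val)
                    elif key == "seed":
                        meta[key] = None if val == "None" else int(val)
                    elif key == "method":
                        meta[key] = val
                    elif key == "forced":
                        forced = tuple(val.split(","))
                    elif key == "groups":
                        groups = tuple(val.split(","))
            elif line != "accession":
                ids.append(line)
    if not ids:
        raise SchemaError(f"no accession ids in core list {path}")
    return CoreSet(tuple(ids), meta["method"], meta["w_en"], meta["w_an"],
                   forced, groups, meta["seed"])
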