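"""Trait descriptors for germplasm characterization data.

A characterization trial records two kinds of traits per accession:

* quantitative traits -- continuous measurements (lengths, weights, counts
  treated as continuous), carrying a unit;
* qualitative traits -- categorical characterization descriptors whose levels
  ("descriptor states", e.g. seed-coat color classes) come from a fixed,
  ordered list.

The descriptor set is the schema every field book is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


@dataclass(frozen=True)
class TraitDescriptor:
    """Schema entry for one trait.

    Parameters
    ----------
    name : str
        Column label, unique within a descriptor set.
    kind : str
        ``"quantitative"`` or ``"qualitative"``.
    unit : str
        Measurement unit; may be empty (and is empty for qualitative traits).
    states : tuple of str
        Ordered descriptor-state labels. Required (>= 2) for qualitative
        traits, must be empty for quantitative ones.
    """

    name: str
    kind: str
    unit: str = ""
    states: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.name:
            raise SchemaError("trait name must be non-empty")
        if self.kind not in (QUANTITATIVE, QUALITATIVE):
            raise SchemaError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "states", tuple(self.states))
        if self.kind == QUALITATIVE and len(self.states) < 2:
            raise SchemaError(
                f"qualitative trait {self.name!r} needs >= 2 descriptor states"
            )
        if self.kind == QUANTITATIVE and self.states:
            raise SchemaError(
                f"quantitative trait {self.name!r} must not declare states"
            )

    @property
    def is_quantitative(self) -> bool:
        return self.kind == QUANTITATIVE

    @property
    def is_qualitative(self) -> bool:
        return self.kind == QUALITATIVE


def validate_descriptor_set(descriptors) -> None:
    """Reject duplicate trait names."""
    names = [d.name for d in descriptors]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate trait names in descriptor set: {dupes}")


def quantitative_names(descriptors) -> list:
    return [d.name for d in descriptors if d.is_quantitative]


def qualitative_names(descriptors) -> list:
    return [d.name for d in descriptors if d.is_qualitative]
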