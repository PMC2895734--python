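"""Label-space mappings (class schemes) for the merging experiments.

A :class:`ClassScheme` maps every source label to a target label or to
deletion.  The registered series mirrors a progressive-coarsening design:
start from the full catalog, merge conceptually similar classes step by
step, and end with a single generic ``PHI`` class.  The manual-consensus
scheme keeps the refined working set (generic first/last names, one Age,
both date classes, ``Location``, ``Health_Care_Unit``, ``Phone_Number``)
and deletes the abandoned classes.

The intermediate memberships are this package's defaults, built from the
stated merging principles (name refinements -> generic names -> ``Name``;
street/town/municipality/country/organization -> ``Location``; ages ->
``Age``; the ``Date_Part`` / ``Full_Date`` division is never collapsed);
they are configurable, not canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .corpus_model import Annotation, AnnotationSet, DEFAULT_CATALOG

__all__ = [
    "ClassScheme",
    "get_scheme",
    "available_schemes",
    "apply_scheme",
    "compose",
    "load_scheme",
    "save_scheme",
    "EXPERIMENT_SERIES",
]

#: Sentinel target meaning "drop annotations with this source label".
DELETE = None


@dataclass(frozen=True)
class ClassScheme:
    """A total mapping from a source label set to a coarser label set
    (``None`` target = delete)."""

    name: str
    mapping: Mapping[str, str | None]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def source_labels(self) -> frozenset[str]:
        return frozenset(self.mapping)

    @property
    def target_labels(self) -> frozenset[str]:
        return frozenset(v for v in self.mapping.values() if v is not None)

    @property
    def deletes(self) -> bool:
        return any(v is None for v in self.mapping.values())

    def __getitem__(self, label: str) -> str | None:
        try:
            return self.mapping[label]
        except KeyError:
            raise KeyError(
                f"label {label!r} is not mapped by scheme {self.name!r}"
            ) from None


def apply_scheme(aset: AnnotationSet, scheme: ClassScheme) -> AnnotationSet:
    """Relabel (and possibly delete) annotations; spans never change.

    Every label in the set must be mapped; an unmapped label raises
    ``KeyError``.  Count is conserved minus deletions.
    """
    out = []
    for a in aset:
        target = scheme[a.label]
        if target is None:
            continue
        out.append(Annotation(a.doc_id, a.start, a.end, target, a.source))
    return AnnotationSet(aset.source, out)


def compose(outer: ClassScheme, inner: ClassScheme) -> ClassScheme:
    """``compose(B, A)`` applies A then B; deletion propagates."""
    mapping: dict[str, str | None] = {}
    for src, mid in inner.mapping.items():
        mapping[src] = None if mid is None else outer[mid]
    return ClassScheme(f"{outer.name}∘{inner.name}", mapping)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _identity(labels) -> dict[str, str]:
    return {l: l for l in sorted(labels)}

_ALL = sorted(DEFAULT_CATALOG.labels)

_NAME_REFINEMENTS = {
    "Clinician_First_Name": "First_Name",
    "Patient_First_Name": "First_Name",
    "Relative_First_Name": "First_Name",
    "Clinician_Last_Name": "Last_Name",
    "Patient_Last_Name": "Last_Name",
    "Relative_Last_Name": "Last_Name",
}
_LOCATION_MERGE = {
    "Street_Address": "Location",
    "Town": "Location",
    "Municipality": "Location",
    "Country": "Location",
    "Organization": "Location",
}
_INFREQUENT = ("Social_Security_Number", "E-mail_Address",
               "Relation", "Ethnicity")


def _build_registry() -> dict[str, ClassScheme]:
    reg: dict[str, ClassScheme] = {}

    exp1 = _identity(_ALL)
    reg["exp1_full"] = ClassScheme("exp1_full", exp1)

    exp2 = dict(exp1, **_NAME_REFINEMENTS)
    reg["exp2_names"] = ClassScheme("exp2_names", exp2)

    exp3 = dict(exp2, Age_Over_89="Age")
    reg["exp3_ages"] = ClassScheme("exp3_ages", exp3)

    exp4 = dict(exp3, **_LOCATION_MERGE)
    reg["exp4_locations"] = ClassScheme("exp4_locations", exp4)

    exp5 = dict(exp4, First_Name="Name", Last_Name="Name")
    for src, tgt in list(exp5.items()):
        if tgt in ("First_Name", "Last_Name"):
            exp5[src] = "Name"
    reg["exp5_name_generic"] = ClassScheme("exp5_name_generic", exp5)

    exp6 = dict(exp5)
    for lab in _INFREQUENT:
        exp6[lab] = None
    reg["exp6_pruned"] = ClassScheme("exp6_pruned", exp6)

    reg["phi_1"] = ClassScheme("phi_1", {l: "PHI" for l in _ALL})

    manual = dict(_identity(_ALL), **_NAME_REFINEMENTS, **_LOCATION_MERGE,
                  Age_Over_89="Age", Relation=None, Ethnicity=None)
    reg["manual_gs"] = ClassScheme("manual_gs", manual)

    reg["full"] = reg["exp1_full"]
    return reg


_REGISTRY = _build_registry()

#: The seven-step coarsening series, in experiment order.
EXPERIMENT_SERIES = ("exp1_full", "exp2_names", "exp3_ages",
                     "exp4_locations", "exp5_name_generic", "exp6_pruned",
                     "phi_1")


def available_schemes() -> list[str]:
    return sorted(_REGISTRY)


def get_scheme(name: str) -> ClassScheme:
    """Look up a registered scheme; an unknown name lists what exists."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; available: {available_schemes()}"
        ) from None


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_scheme(scheme: ClassScheme, path: str | Path) -> None:
    payload = {"name": scheme.name,
               "mapping": {k: (v if v is not None else "DELETE")
                           for k, v in sorted(scheme.mapping.items())}}
    Path(path).write_text(yaml.safe_dump(payload, allow_unicode=True),
                          encoding="utf-8")


def load_scheme(path: str | Path) -> ClassScheme:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    mapping = {k: (None if v == "DELETE" else v)
               for k, v in payload["mapping"].items()}
    return ClassScheme(payload["name"], mapping)
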