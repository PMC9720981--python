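"""Data model and derived measures for gated cell-subset frequency panels.

Frequencies are stored the way they come off the gating hierarchy: percent of
the *stated parent gate*, never percent of lymphocytes.  The canonical subset
dictionary (names, marker definitions, parent paths) ships as JSON in
``immflow/schema/subsets.json``; absolute counts are obtained by chaining the
parent-relative fractions down from the haematology lymphocyte count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "SUBSETS",
    "SUBSET_NAMES",
    "SubjectRecord",
    "PhenotypePanel",
    "Violation",
    "SchemaError",
    "MissingDataError",
    "UndefinedRatioError",
    "load_schema",
    "parent_path",
    "validate_panel",
    "absolute_counts",
    "naive_memory_ratio",
]

#: tolerance (percentage points) on sum / intersection invariants; gated real
#: data are rounded, so exact equality is not enforced.
SUM_TOLERANCE = 0.5


class SchemaError(ValueError):
    """Unknown or missing subset/column names."""


class MissingDataError(ValueError):
    """A required measurement is absent (never silently treated as zero)."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio denominator is zero."""


def load_schema() -> dict:
    """Return the canonical subset schema shipped with the package."""
    with resources.files("immflow.schema").joinpath("subsets.json").open("r") as fh:
        return json.load(fh)


_SCHEMA = load_schema()
SUBSETS: dict[str, dict] = _SCHEMA["subsets"]
SUBSET_NAMES: tuple[str, ...] = tuple(SUBSETS)


def parent_path(subset: str) -> list[str]:
    """Gating chain from the lymphocyte root down to ``subset`` (inclusive)."""
    if subset not in SUBSETS:
        raise SchemaError(f"unknown subset name: {subset!r}")
    chain = [subset]
    while SUBSETS[chain[0]]["parent"] != "lymphocytes":
        chain.insert(0, SUBSETS[chain[0]]["parent"])
    return chain


@dataclass
class SubjectRecord:
    """One sampled individual at one timepoint (HC subjects have one sample)."""

    subject_id: str
    group: str  # "HC" or "trauma"
    timepoint_day: int | None = None
    age: float | None = None
    sex: str | None = None
    iss: float | None = None
    niss: float | None = None
    apache2: float | None = None
    sofa: float | None = None
    saps2: float | None = None
    sepsis: bool | None = None
    icu_los: float | None = None
    hospital_los: float | None = None
    ventilator_days: float | None = None
    lymphocyte_count: float | None = None  # 1e9 cells/L
    cytokines: dict[str, float] = field(default_factory=dict)  # pg/ml; CRP mg/ml


@dataclass
class PhenotypePanel:
    """Parent-relative subset frequencies (percent) for one sample."""

    subject_id: str
    frequencies: dict[str, float] = field(default_factory=dict)

    def get(self, subset: str) -> float | None:
        v = self.frequencies.get(subset)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)


@dataclass(frozen=True)
class Violation:
    subset: str
    rule: str
    observed: float
    message: str


def _check_known(names: Iterable[str]) -> None:
    unknown = sorted(set(names) - set(SUBSET_NAMES))
    if unknown:
        raise SchemaError(f"unknown subset names: {unknown}")


def validate_panel(panel: PhenotypePanel) -> list[Violation]:
    """Check a panel against the gating-hierarchy invariants.

    Returns an empty list iff every invariant holds on the non-missing values:
    each frequency in [0, 100]; the CD45RA/CCR7 quartets sum to 100 within
    ``SUM_TOLERANCE``; an intersection gate (e.g. CD28-CD57+) cannot exceed
    either of its parent single-marker gates; bounded sibling groups sum to
    at most 100.  Rules touching a missing value are skipped.
    """
    _check_known(panel.frequencies)
    out: list[Violation] = []

    for name in panel.frequencies:
        v = panel.get(name)
        if v is not None and not (0.0 <= v <= 100.0):
            out.append(Violation(name, "range", v, f"{name}={v} outside [0, 100]"))

    for group in _SCHEMA["exhaustive_groups"]:
        members = [n for n, s in SUBSETS.items() if s.get("group") == group]
        vals = [panel.get(n) for n in members]
        if any(v is None for v in vals):
            continue
        total = sum(vals)  # type: ignore[arg-type]
        if abs(total - 100.0) > SUM_TOLERANCE:
            out.append(
                Violation(group, "exhaustive_sum", total,
                          f"{group} sums to {total:.3f}, expected 100 ± {SUM_TOLERANCE}")
            )

    for members in _SCHEMA["bounded_sibling_groups"].values():
        vals = [panel.get(n) for n in members]
        if any(v is None for v in vals):
            continue
        total = sum(vals)  # type: ignore[arg-type]
        if total > 100.0 + SUM_TOLERANCE:
            out.append(
                Violation("+".join(members), "sibling_sum", total,
                          f"sibling subsets sum to {total:.3f} > 100")
            )

    for name, spec in SUBSETS.items():
        parents = spec.get("intersection_of")
        if not parents:
            continue
        v = panel.get(name)
        bounds = [panel.get(p) for p in parents]
        if v is None or any(b is None for b in bounds):
            continue
        bound = min(bounds)  # type: ignore[type-var]
        if v > bound + SUM_TOLERANCE:
            out.append(
                Violation(name, "intersection_bound", v,
                          f"{name}={v} exceeds min({', '.join(parents)})={bound}")
            )
    return out


def absolute_counts(panel: PhenotypePanel, record: SubjectRecord) -> dict[str, float]:
    """Absolute subset counts (1e9 cells/L) from the lymphocyte count.

    Each count is the chained product of parent-relative fractions, e.g.
    naive CD8 = lymphocytes x T/100 x CD8_of_T/100 x naive/100.  Subsets whose
    chain contains a missing frequency are omitted from the result.
    """
    if record.lymphocyte_count is None or (
        isinstance(record.lymphocyte_count, float) and math.isnan(record.lymphocyte_count)
    ):
        raise MissingDataError(f"lymphocyte count missing for {record.subject_id}")
    if record.lymphocyte_count <= 0:
        raise MissingDataError(
            f"lymphocyte count must be > 0, got {record.lymphocyte_count}"
        )
    _check_known(panel.frequencies)
    out: dict[str, float] = {}
    for name in panel.frequencies:
        chain = parent_path(name)
        fracs = [panel.get(step) for step in chain]
        if any(f is None for f in fracs):
            continue
        count = float(record.lymphocyte_count)
        for f in fracs:
            count *= f / 100.0  # type: ignore[operator]
        out[name] = count
    return out


def naive_memory_ratio(panel: PhenotypePanel, lineage: str) -> float:
    """Naive : memory T cell ratio for one lineage ("CD4" or "CD8").

    Memory is the quartet complement of naive (cm + em + emra).
    """
    lin = lineage.lower()
    if lin not in ("cd4", "cd8"):
        raise ValueError(f"lineage must be 'CD4' or 'CD8', got {lineage!r}")
    naive = panel.get(f"{lin}_naive")
    mem_parts = [panel.get(f"{lin}_{s}") for s in ("cm", "em", "emra")]
    if naive is None or any(m is None for m in mem_parts):
        raise MissingDataError(f"{lineage} quartet incomplete for {panel.subject_id}")
    memory = sum(mem_parts)  # type: ignore[arg-type]
    if memory == 0:
        raise UndefinedRatioError(
            f"memory {lineage} total is zero for {panel.subject_id}"
        )
    return naive / memory
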