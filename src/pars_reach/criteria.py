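"""Inclusion/exclusion criteria as declarative, versioned data.

A :class:`CriteriaSet` carries an ordered list of criteria, each tying an
ICD-10-CM code pattern to a direction (inclusion or exclusion), a clinical
category, and a provenance tag. The package bundles two fixture sets for a
physical-activity referral scheme targeting adults with five chronic
conditions (physical inactivity, obesity, dyslipidemia, diabetes,
hypertension):

* ``inclusion_criteria.csv`` — 30 exact codes across the five target
  conditions (3 / 17 / 4 / 5 / 1 per category);
* ``exclusion_criteria.csv`` — 78 exact or truncated patterns for
  contraindicating conditions (recent myocardial infarction, embolism,
  aortic stenosis, atrial fibrillation, fractures, chronic kidney disease,
  moderate/severe asthma, acute illness, ...).

Both fixtures are *reconstructions*: the study's exact supplementary code
spreadsheets are not publicly deposited, so the bundled lists were rebuilt
to satisfy every published per-category count and condition description.
Every row is tagged ``source=reconstruction`` to make that status explicit.
Conditions the clinical consensus process explicitly rejected as
contraindications (coronary artery disease, diabetes, osteoporosis, back
problems/acute back injury) are deliberately absent from the exclusion set.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from .icd10 import CodePattern, DxCode, matches, parse_pattern

__all__ = [
    "Criterion",
    "CriteriaSet",
    "ValidationReport",
    "CriteriaLoadError",
    "load_criteria",
    "write_criteria",
    "validate_criteria",
    "classify_code",
    "bundled_inclusion",
    "bundled_exclusion",
    "bundled_criteria",
]

Direction = Literal["inclusion", "exclusion"]

_DIRECTIONS = {"inclusion", "exclusion"}
_SOURCES = {"program-definition", "ACSM-GETP", "PAR-Q+", "expert", "consensus", "reconstruction"}
_CSV_COLUMNS = ["id", "direction", "category", "pattern", "description", "source"]

INCLUSION_CATEGORIES = (
    "physical inactivity",
    "obesity",
    "dyslipidemia",
    "diabetes",
    "hypertension",
)


class CriteriaLoadError(ValueError):
    """Malformed criteria file: names the offending row and field."""


@dataclass(frozen=True)
class Criterion:
    id: str
    direction: Direction
    category: str
    pattern: CodePattern
    description: str = ""
    source: str = "consensus"


@dataclass
class CriteriaSet:
    """An ordered, versioned list of criteria. Order is significant:
    classification hit lists follow file order for deterministic reports."""

    name: str
    version: str
    criteria: list[Criterion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CriteriaLoadError(f"duplicate criterion ids: {sorted(dupes)}")

    def by_direction(self, direction: Direction) -> list[Criterion]:
        return [c for c in self.criteria if c.direction == direction]

    @property
    def inclusion(self) -> list[Criterion]:
        return self.by_direction("inclusion")

    @property
    def exclusion(self) -> list[Criterion]:
        return self.by_direction("exclusion")

    def categories(self, direction: Direction | None = None) -> list[str]:
        """Distinct categories in file order, optionally for one direction."""
        seen: dict[str, None] = {}
        for c in self.criteria:
            if direction is None or c.direction == direction:
                seen.setdefault(c.category)
        return list(seen)

    def __len__(self) -> int:
        return len(self.criteria)


@dataclass
class ValidationReport:
    duplicate_ids: list[str] = field(default_factory=list)
    overlaps: list[tuple[str, str]] = field(default_factory=list)  # (inclusion id, exclusion id)
    unmatched_wildcards: list[str] = field(default_factory=list)  # criterion ids
    category_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.duplicate_ids and not self.overlaps


def _build_criterion(row: dict, where: str) -> Criterion:
    for col in _CSV_COLUMNS[:4]:
        if not (row.get(col) or "").strip():
            raise CriteriaLoadError(f"{where}: missing required field {col!r}")
    direction = row["direction"].strip()
    if direction not in _DIRECTIONS:
        raise CriteriaLoadError(f"{where}: field 'direction' must be inclusion|exclusion, got {direction!r}")
    source = (row.get("source") or "consensus").strip()
    if source not in _SOURCES:
        raise CriteriaLoadError(f"{where}: field 'source' not one of {sorted(_SOURCES)}: {source!r}")
    try:
        pattern = parse_pattern(row["pattern"])
    except ValueError as exc:
        raise CriteriaLoadError(f"{where}: field 'pattern': {exc}") from exc
    return Criterion(
        id=row["id"].strip(),
        direction=direction,  # type: ignore[arg-type]
        category=row["category"].strip(),
        pattern=pattern,
        description=(row.get("description") or "").strip(),
        source=source,
    )


def load_criteria(path: str | Path, format: str | None = None,
                  name: str | None = None, version: str = "1") -> CriteriaSet:
    """Load a criteria file (CSV or JSON; inferred from the suffix).

    CSV schema (header required): ``id,direction,category,pattern,description,source``.
    JSON schema: ``{"name":..., "version":..., "criteria":[{...}, ...]}``.

    Raises :class:`CriteriaLoadError` naming the row and field for any
    schema violation, duplicate id, or unparsable pattern.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CriteriaLoadError(f"{path}: empty criteria file")
            missing = [c for c in _CSV_COLUMNS[:4] if c not in reader.fieldnames]
            if missing:
                raise CriteriaLoadError(f"{path}: header missing columns {missing}")
            rows = [_build_criterion(row, f"{path} row {i}") for i, row in enumerate(reader, start=2)]
        if not rows:
            raise CriteriaLoadError(f"{path}: no criteria rows")
        return CriteriaSet(name=name or path.stem, version=version, criteria=rows)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        raw = doc.get("criteria", [])
        if not raw:
            raise CriteriaLoadError(f"{path}: no criteria rows")
        rows = [_build_criterion(row, f"{path} criteria[{i}]") for i, row in enumerate(raw)]
        return CriteriaSet(name=doc.get("name", path.stem), version=str(doc.get("version", version)), criteria=rows)
    raise CriteriaLoadError(f"unsupported criteria format: {fmt!r} (expected csv or json)")


def write_criteria(cset: CriteriaSet, path: str | Path, format: str | None = None) -> None:
    """Write a CriteriaSet back out (round-trips with :func:`load_criteria`)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records = [
        {"id": c.id, "direction": c.direction, "category": c.category,
         "pattern": c.pattern.raw, "description": c.description, "source": c.source}
        for c in cset.criteria
    ]
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(records)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"name": cset.name, "version": cset.version, "criteria": records}, fh, indent=2)
    else:
        raise CriteriaLoadError(f"unsupported criteria format: {fmt!r} (expected csv or json)")


def _stems_overlap(a: CodePattern, b: CodePattern) -> bool:
    # two patterns can hit the same code iff one stem prefixes the other
    # and the longer-stemmed side reaches the shorter stem via a wildcard
    if a.stem == b.stem:
        return True
    shorter, longer = (a, b) if len(a.stem) < len(b.stem) else (b, a)
    return longer.stem.startswith(shorter.stem) and shorter.wildcard


def validate_criteria(cset: CriteriaSet, universe: Iterable[DxCode] | None = None) -> ValidationReport:
    """Audit a criteria set: duplicate ids, inclusion/exclusion stem
    overlaps (a code must never be simultaneously qualifying and
    disqualifying), wildcards matching nothing in an optional code
    universe, and per-direction per-category pattern counts."""
    report = ValidationReport()
    ids = [c.id for c in cset.criteria]
    report.duplicate_ids = sorted({i for i in ids if ids.count(i) > 1})
    for inc in cset.inclusion:
        for exc in cset.exclusion:
            if _stems_overlap(inc.pattern, exc.pattern):
                report.overlaps.append((inc.id, exc.id))
    if universe is not None:
        pool = set(universe)
        for c in cset.criteria:
            if c.pattern.wildcard and not any(matches(c.pattern, code) for code in pool):
                report.unmatched_wildcards.append(c.id)
    for direction in ("inclusion", "exclusion"):
        counts: dict[str, int] = {}
        for c in cset.by_direction(direction):  # type: ignore[arg-type]
            counts[c.category] = counts.get(c.category, 0) + 1
        report.category_counts[direction] = counts
    return report


def classify_code(code: DxCode, cset: CriteriaSet) -> list[Criterion]:
    """All criteria (either direction) whose pattern matches ``code``,
    in criteria-file order."""
    return [c for c in cset.criteria if matches(c.pattern, code)]


def _bundled(fname: str, name: str) -> CriteriaSet:
    with resources.as_file(resources.files("pars_reach.data").joinpath(fname)) as p:
        return load_criteria(p, format="csv", name=name)


def bundled_inclusion() -> CriteriaSet:
    """The bundled 30-code inclusion set (five chronic conditions)."""
    return _bundled("inclusion_criteria.csv", "pars-inclusion")


def bundled_exclusion() -> CriteriaSet:
    """The bundled 78-pattern exclusion set (exercise contraindications)."""
    return _bundled("exclusion_criteria.csv", "pars-exclusion")


def bundled_criteria() -> CriteriaSet:
    """Inclusion + exclusion fixtures merged into one ordered set."""
    inc, exc = bundled_inclusion(), bundled_exclusion()
    return CriteriaSet(name="pars-criteria", version=inc.version, criteria=inc.criteria + exc.criteria)
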