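"""Visit-level eligibility classification, attrition, and reach estimation.

The procedure mirrors how a physical-activity referral scheme (PARS) is
evaluated retrospectively from an EHR extract:

1. **Scope** — keep visits inside the study window, age bounds (18-80,
   inclusive at both ends) and, optionally, an allow-list of clinics.
2. **Inclusion** — a visit qualifies if any of its diagnosis codes matches
   an inclusion criterion (one of the five target chronic conditions).
3. **Exclusion** — a qualifying visit is removed if any code matches an
   exclusion criterion (an exercise contraindication or acute illness that
   makes a referral inappropriate at that encounter).
4. **Reach** — referrals placed on in-scope, inclusion-qualifying visits
   form the numerator; eligible visits (or unique patients) the denominator.

Inclusion and exclusion are per-visit predicates, so the final eligible set
is order-invariant; only the staged attrition counts depend on the order,
which is fixed as inclusion-then-exclusion to match how such flow diagrams
are conventionally reported.

By default the numerator does *not* re-apply the exclusion criteria to
referred visits (a clinician who placed a referral has already judged it
appropriate); ``strict_numerator=True`` additionally intersects the
numerator with the denominator set so the reach proportion is a true
subset ratio.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import CriteriaSet, classify_code
from .extract import DX_SOURCES
from .icd10 import DxCode, MalformedCodeError, normalize_code

logger = logging.getLogger(__name__)

__all__ = [
    "Visit",
    "ScopeConfig",
    "EligibilityResult",
    "ReachEstimate",
    "AttritionStage",
    "AttritionReport",
    "UnclassifiableVisitError",
    "classify_visit",
    "classify_visits",
    "count_referred",
    "build_attrition",
    "attrition_from_classification",
    "compute_reach",
    "unique_patient_counts",
    "round_half_away",
]

DEFAULT_REFERRAL_CODE = "REF201"


class UnclassifiableVisitError(ValueError):
    """Visit record with an invalid service date or negative age."""


@dataclass(frozen=True)
class Visit:
    """One clinical encounter with its diagnosis codes.

    ``dx`` pairs each code with its EHR source field: ``problem_list``
    (persistent/chronic diagnoses) or ``encounter`` (per-visit diagnoses).
    """

    visit_id: str
    patient_id: str
    clinic_id: str
    provider_id: str
    service_date: dt.date
    age_at_visit: int
    dx: tuple[tuple[DxCode, str], ...] = ()


@dataclass(frozen=True)
class ScopeConfig:
    """Extract boundaries: who counts as an encounter at all.

    Ages and the date window are inclusive at both ends. ``clinic_ids``
    of ``None`` means no clinic restriction.
    """

    age_min: int = 18
    age_max: int = 80
    window_start: dt.date = dt.date(2021, 3, 15)
    window_end: dt.date = dt.date(2022, 9, 30)
    clinic_ids: frozenset[str] | None = None
    referral_code: str = DEFAULT_REFERRAL_CODE

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")

    def contains(self, age: int, date: dt.date, clinic_id: str) -> bool:
        return (
            self.age_min <= age <= self.age_max
            and self.window_start <= date <= self.window_end
            and (self.clinic_ids is None or clinic_id in self.clinic_ids)
        )


@dataclass(frozen=True)
class EligibilityResult:
    visit_id: str
    in_scope: bool
    inclusion_hits: tuple[str, ...]  # distinct categories, criteria-file order
    exclusion_hits: tuple[str, ...]  # criterion ids, criteria-file order
    eligible: bool


@dataclass(frozen=True)
class ReachEstimate:
    """Numerator / denominator / proportion at a chosen unit.

    ``proportion`` is ``None`` (undefined) when the denominator is zero —
    never reported as 0, which would mean something different.
    """

    unit: str  # "visits" | "unique_patients"
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "proportion": self.proportion,
        }


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (the convention
    that reproduces conventionally reported flow-diagram percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class AttritionStage:
    label: str
    entering: int
    removed: int

    @property
    def remaining(self) -> int:
        return self.entering - self.removed


@dataclass
class AttritionReport:
    """Ordered stage counts with integer percent reductions."""

    initial: int
    stages: list[AttritionStage] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.stages[-1].remaining if self.stages else self.initial

    def pct_removed_of_entering(self, i: int) -> int:
        s = self.stages[i]
        return round_half_away(100.0 * s.removed / s.entering) if s.entering else 0

    def pct_remaining_of_initial(self, i: int) -> int:
        s = self.stages[i]
        return round_half_away(100.0 * s.remaining / self.initial) if self.initial else 0

    @property
    def pct_reduction_from_initial(self) -> int:
        if self.initial == 0:
            return 0
        return round_half_away(100.0 * (self.initial - self.final) / self.initial)

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "final": self.final,
            "pct_reduction_from_initial": self.pct_reduction_from_initial,
            "stages": [
                {
                    "label": s.label,
                    "entering": s.entering,
                    "removed": s.removed,
                    "remaining": s.remaining,
                    "pct_removed_of_entering": self.pct_removed_of_entering(i),
                    "pct_remaining_of_initial": self.pct_remaining_of_initial(i),
                }
                for i, s in enumerate(self.stages)
            ],
        }

    def flow_text(self, unit: str = "visits") -> str:
        """Plain-text flow diagram: initial -> stage -> ... -> final."""
        lines = [f"initial {unit}: n={self.initial:,}"]
        for i, s in enumerate(self.stages):
            lines.append(
                f"  |- {s.label}: removed n={s.removed:,} "
                f"({self.pct_removed_of_entering(i)}% of entering)"
            )
            lines.append(
                f"  v  remaining n={s.remaining:,} "
                f"({self.pct_remaining_of_initial(i)}% of initial)"
            )
        lines.append(
            f"final {unit}: n={self.final:,} "
            f"({self.pct_reduction_from_initial}% reduction from initial)"
        )
        return "\n".join(lines)


def build_attrition(initial: int, stages: list[tuple[str, int]]) -> AttritionReport:
    """Chain staged removals from an initial count.

    ``stages`` is an ordered list of (label, removed_count); each stage
    enters with the previous stage's remaining count. Raises ``ValueError``
    if any removal is negative or exceeds its entering count.
    """
    if initial < 0:
        raise ValueError("initial count must be non-negative")
    report = AttritionReport(initial=initial)
    entering = initial
    for label, removed in stages:
        if removed < 0:
            raise ValueError(f"stage {label!r}: negative removal {removed}")
        if removed > entering:
            raise ValueError(f"stage {label!r}: removal {removed} exceeds entering count {entering}")
        stage = AttritionStage(label=label, entering=entering, removed=removed)
        report.stages.append(stage)
        entering = stage.remaining
    return report


# ---------------------------------------------------------------------------
# classification


def _hit_maps(raw_codes: "pd.Series | list[str]", criteria: CriteriaSet
              ) -> tuple[dict[str, tuple[str, ...]], dict[str, tuple[str, ...]], int]:
    """Map each distinct raw code string to its inclusion categories and
    exclusion criterion ids (criteria-file order). Returns the two maps and
    the number of distinct malformed/invalid code strings encountered."""
    inc_map: dict[str, tuple[str, ...]] = {}
    exc_map: dict[str, tuple[str, ...]] = {}
    n_bad = 0
    for raw in pd.unique(pd.Series(raw_codes, dtype=str)):
        try:
            dx = normalize_code(raw)
        except MalformedCodeError:
            n_bad += 1
            continue
        if not dx.valid:
            n_bad += 1
            continue
        hits = classify_code(dx, criteria)
        cats: list[str] = []
        for h in hits:
            if h.direction == "inclusion" and h.category not in cats:
                cats.append(h.category)
        ids = [h.id for h in hits if h.direction == "exclusion"]
        if cats:
            inc_map[raw] = tuple(cats)
        if ids:
            exc_map[raw] = tuple(ids)
    return inc_map, exc_map, n_bad


def classify_visit(visit: Visit, scope: ScopeConfig, criteria: CriteriaSet,
                   dx_sources: tuple[str, ...] = DX_SOURCES) -> EligibilityResult:
    """Classify a single visit.

    All hits are recorded even when the visit is out of scope (nothing is
    short-circuited), so reports can show why a visit failed. Raises
    :class:`UnclassifiableVisitError` for a negative age.
    """
    if visit.age_at_visit < 0:
        raise UnclassifiableVisitError(f"visit {visit.visit_id}: negative age {visit.age_at_visit}")
    if not dx_sources:
        raise ValueError("dx_sources must be non-empty")
    in_scope = scope.contains(visit.age_at_visit, visit.service_date, visit.clinic_id)
    inc_cats: list[str] = []
    exc_ids: list[str] = []
    seen: set[tuple[str, str]] = set()
    for code_obj, source in visit.dx:
        if source not in dx_sources or (code_obj.normalized, source) in seen:
            continue
        seen.add((code_obj.normalized, source))
        if not code_obj.valid:
            continue
        for hit in classify_code(code_obj, criteria):
            if hit.direction == "inclusion" and hit.category not in inc_cats:
                inc_cats.append(hit.category)
            elif hit.direction == "exclusion" and hit.id not in exc_ids:
                exc_ids.append(hit.id)
    # keep deterministic criteria-file order for categories/ids
    cat_order = {c: i for i, c in enumerate(criteria.categories("inclusion"))}
    id_order = {c.id: i for i, c in enumerate(criteria.criteria)}
    inc_cats.sort(key=cat_order.__getitem__)
    exc_ids.sort(key=id_order.__getitem__)
    eligible = in_scope and bool(inc_cats) and not exc_ids
    return EligibilityResult(
        visit_id=visit.visit_id,
        in_scope=in_scope,
        inclusion_hits=tuple(inc_cats),
        exclusion_hits=tuple(exc_ids),
        eligible=eligible,
    )


def classify_visits(visits: pd.DataFrame, diagnoses: pd.DataFrame,
                    scope: ScopeConfig, criteria: CriteriaSet,
                    inclusion_sources: tuple[str, ...] = DX_SOURCES,
                    exclusion_sources: tuple[str, ...] = DX_SOURCES) -> pd.DataFrame:
    """Classify every visit in an extract.

    Inclusion and exclusion criteria each evaluate the union of the
    diagnosis sources given for their direction (both sources by default).

    Returns a DataFrame with one row per visit: ``visit_id, patient_id,
    clinic_id, unclassifiable, in_scope, inclusion_hits, exclusion_hits,
    eligible, referred`` (``referred`` is filled by :func:`compute_reach`
    callers; here it is absent). Visits with an unparsable service date or
    a negative/missing age are flagged ``unclassifiable`` and take part in
    no counts; they are logged, never silently dropped.
    """
    if not inclusion_sources or not exclusion_sources:
        raise ValueError("diagnosis source selections must be non-empty")
    v = visits.copy()
    dates = pd.to_datetime(v["service_date"], errors="coerce", format="mixed").dt.date
    ages = pd.to_numeric(v["age_at_visit"], errors="coerce")
    unclassifiable = dates.isna() | ages.isna() | (ages < 0)
    n_bad_visits = int(unclassifiable.sum())
    if n_bad_visits:
        logger.warning("%d visit(s) unclassifiable (invalid service_date or age); "
                       "excluded from all counts", n_bad_visits)
    in_scope = np.zeros(len(v), dtype=bool)
    ok = ~unclassifiable
    if ok.any():
        age_ok = (ages >= scope.age_min) & (ages <= scope.age_max)
        date_ok = (dates >= scope.window_start) & (dates <= scope.window_end)
        clinic_ok = (
            v["clinic_id"].isin(scope.clinic_ids)
            if scope.clinic_ids is not None
            else pd.Series(True, index=v.index)
        )
        in_scope = (ok & age_ok & date_ok & clinic_ok).to_numpy()

    inc_map, exc_map, n_bad_codes = _hit_maps(diagnoses["code"], criteria)
    if n_bad_codes:
        logger.warning("%d distinct malformed/invalid diagnosis code string(s) "
                       "matched no criteria", n_bad_codes)

    def visit_hits(sources: tuple[str, ...], hit_map: dict[str, tuple[str, ...]],
                   order: dict[str, int]) -> dict[str, tuple[str, ...]]:
        dxs = diagnoses[diagnoses["source"].isin(sources)]
        dxs = dxs[dxs["code"].isin(hit_map)]
        out: dict[str, tuple[str, ...]] = {}
        for vid, grp in dxs.groupby("visit_id", sort=False)["code"]:
            items: set[str] = set()
            for raw in grp:
                items.update(hit_map[raw])
            out[vid] = tuple(sorted(items, key=order.__getitem__))
        return out

    cat_order = {c: i for i, c in enumerate(criteria.categories("inclusion"))}
    id_order = {c.id: i for i, c in enumerate(criteria.criteria)}
    inc_by_visit = visit_hits(inclusion_sources, inc_map, cat_order)
    exc_by_visit = visit_hits(exclusion_sources, exc_map, id_order)

    result = pd.DataFrame({
        "visit_id": v["visit_id"].to_numpy(),
        "patient_id": v["patient_id"].to_numpy(),
        "clinic_id": v["clinic_id"].to_numpy(),
        "unclassifiable": unclassifiable.to_numpy(),
        "in_scope": in_scope & ~unclassifiable.to_numpy(),
    })
    result["inclusion_hits"] = [inc_by_visit.get(vid, ()) for vid in result["visit_id"]]
    result["exclusion_hits"] = [exc_by_visit.get(vid, ()) for vid in result["visit_id"]]
    has_inc = result["inclusion_hits"].map(bool)
    has_exc = result["exclusion_hits"].map(bool)
    result["eligible"] = result["in_scope"] & has_inc & ~has_exc
    return result


def _referred_visit_ids(classified: pd.DataFrame, referrals: pd.DataFrame,
                        scope: ScopeConfig, strict: bool = False) -> tuple[pd.Index, int]:
    """Visit ids counted in the numerator, plus the orphan-referral count."""
    refs = referrals[referrals["referral_code"] == scope.referral_code]
    known = classified.set_index("visit_id")
    orphan = ~refs["visit_id"].isin(known.index)
    n_orphans = int(orphan.sum())
    if n_orphans:
        logger.warning("%d referral row(s) reference unknown visit_ids; ignored", n_orphans)
    hit_visits = known.loc[refs.loc[~orphan, "visit_id"].unique()]
    mask = hit_visits["in_scope"] & hit_visits["inclusion_hits"].map(bool)
    if strict:
        mask &= ~hit_visits["exclusion_hits"].map(bool)
    return hit_visits.index[mask], n_orphans


def count_referred(classified: pd.DataFrame, referrals: pd.DataFrame,
                   scope: ScopeConfig, strict: bool = False) -> int:
    """Numerator: visits carrying the referral code that are in scope and
    meet the inclusion criteria. Exclusion criteria are not applied unless
    ``strict`` (which restricts the numerator to denominator-eligible
    visits). Referrals pointing at unknown visits are warned about,
    ignored, and never counted."""
    ids, _ = _referred_visit_ids(classified, referrals, scope, strict=strict)
    return len(ids)


def compute_reach(classified: pd.DataFrame, referrals: pd.DataFrame,
                  scope: ScopeConfig, unit: str = "visits",
                  strict_numerator: bool = False) -> ReachEstimate:
    """Reach at the chosen unit.

    ``visits``: denominator is the eligible-visit count, numerator per
    :func:`count_referred`. ``unique_patients``: denominator is the number
    of distinct patients with >=1 eligible visit; numerator the number of
    distinct patients with >=1 counted referral visit.
    """
    if unit not in ("visits", "unique_patients"):
        raise ValueError(f"unknown unit {unit!r}")
    num_ids, _ = _referred_visit_ids(classified, referrals, scope, strict=strict_numerator)
    eligible = classified[classified["eligible"]]
    if unit == "visits":
        return ReachEstimate(unit=unit, numerator=len(num_ids), denominator=len(eligible))
    num_patients = classified.set_index("visit_id").loc[num_ids, "patient_id"].nunique()
    den_patients = eligible["patient_id"].nunique()
    return ReachEstimate(unit=unit, numerator=int(num_patients), denominator=int(den_patients))


def attrition_from_classification(classified: pd.DataFrame,
                                  unit: str = "visits") -> AttritionReport:
    """Staged attrition (inclusion then exclusion) over in-scope records.

    At unit ``visits`` the counts are visits; at ``unique_patients`` each
    stage counts distinct patients whose record set survives that stage.
    """
    if unit not in ("visits", "unique_patients"):
        raise ValueError(f"unknown unit {unit!r}")
    scoped = classified[classified["in_scope"]]
    has_inc = scoped["inclusion_hits"].map(bool)
    has_exc = scoped["exclusion_hits"].map(bool)
    if unit == "visits":
        initial = len(scoped)
        after_inc = int(has_inc.sum())
        final = int((has_inc & ~has_exc).sum())
    else:
        initial = scoped["patient_id"].nunique()
        after_inc = scoped.loc[has_inc, "patient_id"].nunique()
        final = scoped.loc[has_inc & ~has_exc, "patient_id"].nunique()
    return build_attrition(initial, [
        ("inclusion criteria", initial - after_inc),
        ("exclusion criteria", after_inc - final),
    ])


def unique_patient_counts(visits: pd.DataFrame, level: str = "system") -> int:
    """Distinct-patient count at system level or summed per clinic.

    ``per_clinic_sum`` deliberately double-counts patients who attend more
    than one clinic — the figure a per-clinic aggregation would report.
    """
    if level == "system":
        return int(visits["patient_id"].nunique())
    if level == "per_clinic_sum":
        return int(visits.groupby("clinic_id")["patient_id"].nunique().sum())
    raise ValueError(f"unknown level {level!r}")


def classification_to_frame(results: list[EligibilityResult]) -> pd.DataFrame:
    """Convenience: EligibilityResult objects -> the tabular layout used by
    the frame-level pipeline (without patient/clinic columns)."""
    return pd.DataFrame(
        {
            "visit_id": r.visit_id,
            "in_scope": r.in_scope,
            "inclusion_hits": r.inclusion_hits,
            "exclusion_hits": r.exclusion_hits,
            "eligible": r.eligible,
        }
        for r in results
    )
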