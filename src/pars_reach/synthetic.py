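"""Seeded synthetic EHR extract generator.

Emulates the statistical structure the eligibility pipeline assumes for a
primary-care physical-activity referral scheme: adult patients spread over
several clinics, each with a Poisson number of visits in a fixed study
window; persistent chronic conditions carried on the *problem list* layer
(the same codes repeat on every visit of an affected patient); acute
conditions appearing as one-off *encounter* diagnoses; and referral events
(code REF201) placed preferentially on eligible visits, with a small noise
rate on ineligible ones to exercise numerator filtering.

Default parameters reproduce the visit-attrition profile of a large
US-health-system evaluation: five chronic target conditions whose joint
prevalence leaves ~58% of visits inclusion-qualifying, and exclusionary
conditions (chronic patient-level plus acute visit-level) that remove ~23%
of those, with ~4.3 visits per patient over an 18.5-month window.

Random streams are partitioned per patient (one child seed per patient
index), so enlarging ``n_patients`` extends the population without
reshuffling existing patients, and every per-patient/per-visit decision
consumes its draws unconditionally, so changing one probability flips only
the decisions it governs.

The generator also emits its own ground-truth labels
(:func:`true_labels`): which visits it made in-scope / inclusion-qualifying
/ excluded / referred. The eligibility pipeline must reproduce these labels
exactly; that is the package's strongest correctness oracle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .criteria import CriteriaSet, classify_code
from .eligibility import ScopeConfig
from .extract import Extract
from .icd10 import normalize_code

__all__ = ["SyntheticConfig", "SyntheticExtract", "generate_extract", "true_labels",
           "FILLER_CODES", "STUDY_PROFILE"]

# neutral per-visit encounter codes that match no bundled criterion
FILLER_CODES = (
    "Z00.00",   # general adult medical examination
    "J06.9",    # acute upper respiratory infection
    "K21.9",    # gastro-esophageal reflux disease
    "F41.9",    # anxiety disorder, unspecified
    "M54.50",   # low back pain, unspecified
    "R51.9",    # headache, unspecified
    "E03.9",    # hypothyroidism, unspecified
    "L70.0",    # acne vulgaris
    "H52.4",    # presbyopia
    "N39.0",    # urinary tract infection
)

_DEFAULT_P_CHRONIC = {
    "physical inactivity": 0.05,
    "obesity": 0.25,
    "dyslipidemia": 0.15,
    "diabetes": 0.08,
    "hypertension": 0.25,
}


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the study-profile conditions.

    ``p_chronic`` gives patient-level prevalences of the five target
    chronic conditions (persistent on the problem list);
    ``p_chronic_exclusion`` the patient-level prevalence of a persistent
    exclusionary condition; ``p_acute_exclusion`` the per-visit probability
    of an acute exclusionary encounter diagnosis. With the defaults the
    expected inclusion-pass fraction is 1 - prod(1 - p_c) ~= 0.58 and the
    expected exclusion removal among included visits is
    1 - (1 - 0.12)(1 - 0.125) = 0.23.
    """

    n_patients: int = 5000
    n_clinics: int = 12
    window_start: dt.date = dt.date(2021, 3, 15)
    window_end: dt.date = dt.date(2022, 9, 30)
    mean_visits_per_patient: float = 4.3
    age_range: tuple[int, int] = (18, 80)
    p_chronic: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_P_CHRONIC))
    p_acute_exclusion: float = 0.125
    p_chronic_exclusion: float = 0.12
    p_refer_given_eligible: float = 0.0016
    p_refer_noise: float = 0.0002
    p_clinic_switch: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_clinics <= 0:
            raise SyntheticConfigError("n_patients and n_clinics must be positive")
        if self.mean_visits_per_patient < 1:
            raise SyntheticConfigError("mean_visits_per_patient must be >= 1")
        if self.window_start > self.window_end:
            raise SyntheticConfigError("window_start must be <= window_end")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise SyntheticConfigError("invalid age_range")
        probs = [self.p_acute_exclusion, self.p_chronic_exclusion,
                 self.p_refer_given_eligible, self.p_refer_noise,
                 self.p_clinic_switch, *self.p_chronic.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SyntheticConfigError("all probabilities must be in [0, 1]")
        if self.p_clinic_switch > 0 and self.n_clinics < 2:
            raise SyntheticConfigError("clinic switching requires n_clinics >= 2")

    def scope(self) -> ScopeConfig:
        """The scope the generator labels against: 18-80 inclusive, its
        own window, all clinics."""
        return ScopeConfig(window_start=self.window_start, window_end=self.window_end)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticExtract(Extract):
    """The three extract tables plus the generator's ground truth."""

    labels: pd.DataFrame = None  # type: ignore[assignment]
    n_switchers: int = 0
    config: SyntheticConfig = None  # type: ignore[assignment]


def _materialize(pattern, rng: np.random.Generator) -> str:
    """Turn a criteria pattern into a concrete sampled code: wildcards get a
    random digit suffix so generated data exercises prefix matching."""
    digit = int(rng.integers(0, 10))  # drawn unconditionally by callers
    if not pattern.wildcard:
        return pattern.stem
    if len(pattern.stem) >= 7:
        return pattern.stem[:7]
    return pattern.stem + str(digit)


def _code_pools(criteria: CriteriaSet, p_chronic: dict[str, float]):
    inc_by_cat: dict[str, list] = {}
    for c in criteria.inclusion:
        inc_by_cat.setdefault(c.category, []).append(c.pattern)
    missing = [cat for cat in p_chronic if cat not in inc_by_cat]
    if missing:
        raise SyntheticConfigError(f"p_chronic categories with no inclusion criteria: {missing}")
    exc_patterns = [c.pattern for c in criteria.exclusion]
    if not criteria.inclusion or not exc_patterns:
        raise SyntheticConfigError("criteria must provide non-empty inclusion and exclusion pools")
    for raw in FILLER_CODES:
        if classify_code(normalize_code(raw), criteria):
            raise SyntheticConfigError(f"filler code {raw} collides with a criterion")
    return inc_by_cat, exc_patterns


def generate_extract(config: SyntheticConfig, criteria: CriteriaSet) -> SyntheticExtract:
    """Generate a seeded synthetic extract with ground-truth labels.

    Identical (config, seed) pairs produce identical tables. The returned
    object carries ``visits``, ``diagnoses``, ``referrals`` (string-typed
    DataFrames in the documented CSV schemas), ``labels`` (per-visit ground
    truth) and ``n_switchers`` (patients with visits at two clinics).
    """
    inc_by_cat, exc_patterns = _code_pools(criteria, config.p_chronic)
    categories = list(config.p_chronic)  # fixed draw order
    scope = config.scope()
    n_days = (config.window_end - config.window_start).days + 1

    visit_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    ref_rows: list[tuple] = []
    label_rows: list[tuple] = []
    n_switchers = 0

    root = np.random.SeedSequence(config.seed)
    for i in range(config.n_patients):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))))
        pid = f"P{i:06d}"
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        n_visits = 1 + int(rng.poisson(config.mean_visits_per_patient - 1.0))

        # chronic inclusion conditions: all draws happen regardless of outcome
        chronic_codes: list[str] = []
        for cat in categories:
            u = rng.random()
            pool = inc_by_cat[cat]
            idx = int(rng.integers(0, len(pool)))
            if u < config.p_chronic[cat]:
                chronic_codes.append(_materialize(pool[idx], rng))
            else:
                _materialize(pool[idx], rng)  # burn the suffix draw

        u_chronic_exc = rng.random()
        exc_idx = int(rng.integers(0, len(exc_patterns)))
        chronic_exc_code = _materialize(exc_patterns[exc_idx], rng)
        has_chronic_exc = u_chronic_exc < config.p_chronic_exclusion

        home_clinic = int(rng.integers(0, config.n_clinics))
        u_switch = rng.random()
        other = int(rng.integers(0, config.n_clinics - 1)) if config.n_clinics > 1 else 0
        target_clinic = other if other < home_clinic else other + 1
        switch_frac = rng.random()
        switches = u_switch < config.p_clinic_switch and n_visits >= 2
        switch_at = 1 + int(switch_frac * (n_visits - 1)) if switches else n_visits
        if switches:
            n_switchers += 1

        offsets = np.sort(rng.integers(0, n_days, size=n_visits))
        for v in range(n_visits):
            vid = f"V{i:06d}-{v:02d}"
            date = config.window_start + dt.timedelta(days=int(offsets[v]))
            clinic = target_clinic if v >= switch_at else home_clinic
            provider = f"DR{clinic:02d}{int(rng.integers(0, 5)):01d}"
            visit_rows.append((vid, pid, f"C{clinic:02d}", provider, date.isoformat(), age))

            for code in chronic_codes:
                dx_rows.append((vid, "problem_list", code))
            if has_chronic_exc:
                dx_rows.append((vid, "problem_list", chronic_exc_code))

            u_acute = rng.random()
            acute_idx = int(rng.integers(0, len(exc_patterns)))
            acute_code = _materialize(exc_patterns[acute_idx], rng)
            has_acute = u_acute < config.p_acute_exclusion
            if has_acute:
                dx_rows.append((vid, "encounter", acute_code))

            n_filler = int(rng.integers(1, 4))
            for k in range(n_filler):
                dx_rows.append((vid, "encounter", FILLER_CODES[int(rng.integers(0, len(FILLER_CODES)))]))

            in_scope = scope.contains(age, date, f"C{clinic:02d}")
            has_inclusion = bool(chronic_codes)
            has_exclusion = has_chronic_exc or has_acute
            eligible = in_scope and has_inclusion and not has_exclusion

            u_ref = rng.random()
            p_ref = config.p_refer_given_eligible if eligible else config.p_refer_noise
            referred = u_ref < p_ref
            if referred:
                ref_rows.append((vid, scope.referral_code))

            label_rows.append((vid, pid, in_scope, has_inclusion, has_exclusion,
                               eligible, referred))

    visits = pd.DataFrame(visit_rows, columns=["visit_id", "patient_id", "clinic_id",
                                               "provider_id", "service_date", "age_at_visit"])
    visits["age_at_visit"] = visits["age_at_visit"].astype(str)
    diagnoses = pd.DataFrame(dx_rows, columns=["visit_id", "source", "code"])
    referrals = pd.DataFrame(ref_rows, columns=["visit_id", "referral_code"])
    labels = pd.DataFrame(label_rows, columns=["visit_id", "patient_id", "in_scope",
                                               "has_inclusion", "has_exclusion",
                                               "eligible", "referred"])
    return SyntheticExtract(visits=visits, diagnoses=diagnoses, referrals=referrals,
                            labels=labels, n_switchers=n_switchers, config=config)


def true_labels(extract: SyntheticExtract) -> pd.DataFrame:
    """The generator's own per-visit eligibility record. The pipeline run
    on the same extract must reproduce these labels exactly."""
    return extract.labels.copy()


# canonical study-profile configuration (the generator defaults)
STUDY_PROFILE = SyntheticConfig()
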