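"""Two-center synthetic EHR generator with known ground truth.

Real RPL case-control extracts live in access-restricted clinical databases,
so every downstream stage here is exercised on synthetic bundles that emulate
the structure the study depends on:

* two centers whose case/control visit-count gap differs (one center with a
  near-equal gap, one with a large gap — the pattern that drives the
  utilization sensitivity analysis),
* a nonlinear maternal-age effect on case status that accelerates after 35,
* race/ethnicity category mixes,
* per-diagnosis baseline prevalence and planted case odds ratios,
* optional visit-count-linked diagnosis intensity,
* duplicate loss records inside the 90-day window, history-of-loss
  qualifiers, and exclusion-triggering records for would-be controls.

Case status is generated first and records are synthesized to be consistent
with it: the generator plants marginal structure for parameter-recovery
testing, it does not simulate pregnancy biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_io import ConceptSet, EhrBundle

# ---------------------------------------------------------------------------
# concept vocabulary

LOSS_CONCEPTS = ("PL_CHEMICAL", "PL_MISCARRIAGE", "PL_FETAL_DEATH", "PL_STILLBIRTH")
BIRTH_CONCEPTS = ("LB_UNCOMPLICATED", "LB_NORMAL_DELIVERY", "LB_FULL_TERM")
RPL_DX_CONCEPT = "RPL_DIAGNOSIS"
HISTORY_CONCEPT = "HX_PREGNANCY_LOSS"
EXCLUSION_CONCEPTS = (
    "EX_PRETERM_BIRTH",
    "EX_PRETERM_LABOR",
    "EX_PRETERM_ROM",
    "EX_MULTI_GESTATION_LOSS",
    "EX_MOLAR_PREGNANCY",
    "EX_EXTRAUTERINE_PREGNANCY",
)
INCIDENT_PREGNANCY_EXTRA = ("IP_PREGNANT_STATE",)


def default_concept_sets() -> dict[str, ConceptSet]:
    """Outcome concept sets used by the generator and fixtures.

    Pregnancy-loss concepts are a subset of the control exclusions, and loss
    and birth concepts count as incident-pregnancy evidence.
    """
    loss = frozenset(LOSS_CONCEPTS)
    birth = frozenset(BIRTH_CONCEPTS)
    return {
        "rpl_diagnosis": ConceptSet("rpl_diagnosis", frozenset({RPL_DX_CONCEPT})),
        "pregnancy_loss": ConceptSet("pregnancy_loss", loss),
        "history_of_loss": ConceptSet("history_of_loss", frozenset({HISTORY_CONCEPT})),
        "live_birth": ConceptSet("live_birth", birth),
        "control_exclusion": ConceptSet(
            "control_exclusion", loss | frozenset(EXCLUSION_CONCEPTS)
        ),
        "incident_pregnancy": ConceptSet(
            "incident_pregnancy", loss | birth | frozenset(INCIDENT_PREGNANCY_EXTRA)
        ),
    }


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DiagnosisSpec:
    """One planted exposure diagnosis.

    ``planted_or`` is the conditional case odds ratio given the other
    generator inputs (age modifier, utilization link); with those switched
    off it is also the marginal 2x2 odds ratio.
    """

    phecode: str
    icd9: str
    icd10: str
    category: str
    baseline_prevalence: float
    planted_or: float
    age_modifier: float = 0.0  # log-odds of presence per ~1 SD of age

    def validate(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError(
                f"{self.phecode}: baseline_prevalence must be in (0, 1), "
                f"got {self.baseline_prevalence}"
            )
        if self.planted_or <= 0:
            raise ValueError(f"{self.phecode}: planted_or must be > 0")


#: Category mix loosely following a diverse US academic-center population.
DEFAULT_RACE_PROBS = {
    "White": 0.46,
    "Asian": 0.22,
    "Other Race": 0.19,
    "Black or African American": 0.05,
    "Unknown": 0.066,
    "Native Hawaiian or Other Pacific Islander": 0.008,
    "American Indian or Alaska Native": 0.006,
}
DEFAULT_ETHNICITY_PROBS = {
    "Not Hispanic or Latino": 0.772,
    "Hispanic or Latino": 0.157,
    "Unknown": 0.071,
}


def default_diagnosis_panel() -> list[DiagnosisSpec]:
    """Planted panel mirroring the effect-size range the study reports.

    Menstrual/infertility diagnoses get positive odds ratios of ~1.7-5,
    pregnancy-complication codes get strongly negative ones (they mark the
    control-defining deliveries), and a block of null diagnoses (OR = 1)
    anchors error-control checks.
    """
    d = DiagnosisSpec
    return [
        d("626.4", "626.4", "N92.6", "genitourinary", 0.08, 2.67),
        d("626.1", "626.0", "N91.1", "genitourinary", 0.05, 1.67),
        d("626.2", "626.2", "N92.0", "genitourinary", 0.05, 1.94),
        d("625.1", "625.3", "N94.6", "genitourinary", 0.06, 1.96),
        d("628", "628.9", "N97.9", "genitourinary", 0.06, 5.0),
        d("615", "617.9", "N80.9", "genitourinary", 0.04, 3.13),
        d("256.4", "256.4", "E28.2", "endocrine/metabolic", 0.05, 2.15),
        d("256.3", "256.9", "E28.9", "endocrine/metabolic", 0.03, 3.17),
        d("256.2", "256.31", "E28.3", "endocrine/metabolic", 0.02, 3.75),
        d("244", "244.9", "E03.9", "endocrine/metabolic", 0.08, 1.3, age_modifier=0.3),
        d("245.21", "245.2", "E06.3", "endocrine/metabolic", 0.02, 1.59),
        d("286.81", "289.81", "D68.59", "hematopoietic", 0.01, 4.2),
        d("250.2", "250.00", "E11.9", "endocrine/metabolic", 0.04, 1.0, age_modifier=0.5),
        d("401", "401.9", "I10", "circulatory system", 0.07, 1.0, age_modifier=0.6),
        d("278.1", "278.00", "E66.9", "endocrine/metabolic", 0.10, 1.0),
        d("300", "300.00", "F41.9", "mental disorders", 0.12, 1.0),
        d("296.2", "311", "F32.9", "mental disorders", 0.10, 1.0),
        d("465", "465.9", "J06.9", "respiratory", 0.15, 1.44),
        d("619", "616.10", "N76.0", "genitourinary", 0.08, 1.48),
        d("614", "614.9", "N73.9", "genitourinary", 0.01, 4.29),
        d("218", "218.9", "D25.9", "genitourinary", 0.05, 1.0, age_modifier=0.4),
        d("621.3", "621.0", "N84.0", "genitourinary", 0.015, 4.09),
        d("277.7", "277.7", "E88.81", "endocrine/metabolic", 0.005, 9.5),
        d("285", "285.9", "D64.9", "hematopoietic", 0.08, 0.42),
        d("563", "564.00", "K59.00", "digestive", 0.06, 1.0),
        d("650", "650", "O80", "pregnancy complications", 0.55, 0.14),
        d("642", "642.40", "O14.90", "pregnancy complications", 0.05, 0.25),
        d("649", "646.90", "O26.90", "pregnancy complications", 0.15, 0.44),
        d("008", "008.8", "A09", "infectious diseases", 0.05, 1.0),
        d("079", "079.99", "B34.9", "infectious diseases", 0.04, 1.0),
        d("339", "784.0", "R51", "neurological", 0.09, 1.0),
        d("495", "493.90", "J45.909", "respiratory", 0.07, 1.0),
        d("530.11", "530.81", "K21.9", "digestive", 0.06, 1.0),
    ]


@dataclass
class SynthConfig:
    """Generator configuration for one synthetic center."""

    seed: int = 0
    center_label: str = "center-A"
    n_rpl: int = 1000
    n_control: int = 3000
    age_case_shift_years: float = 3.0
    age_range: tuple[float, float] = (15.0, 44.0)
    age_control_mean: float = 32.5
    age_control_sd: float = 5.0
    race_probs: dict = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    ethnicity_probs: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS))
    visit_mean_control: float = 50.0
    visit_case_multiplier: float = 1.25
    visit_dispersion: float = 1.2  # negative-binomial size; visit counts are overdispersed
    diagnoses: list[DiagnosisSpec] = field(default_factory=default_diagnosis_panel)
    utilization_link_strength: float = 0.0
    record_span_years: float = 5.0
    dup_loss_prob: float = 0.30
    history_record_prob: float = 0.20
    rpl_dx_record_prob: float = 0.15
    history_only_prob: float = 0.10  # cases qualifying only via history-then-loss
    next_outcome_prob: float = 0.55  # cases with a birth/loss after the index
    next_birth_frac: float = 0.5
    routine_exam_prob: float = 0.98
    unmapped_code_prob: float = 0.05
    icd10_prob: float = 0.65

    def validate(self) -> None:
        if self.n_rpl <= 0 or self.n_control <= 0:
            raise ValueError("n_rpl and n_control must be positive")
        if self.visit_case_multiplier <= 0 or self.visit_mean_control <= 0:
            raise ValueError("visit parameters must be positive")
        if self.utilization_link_strength < 0:
            raise ValueError("utilization_link_strength must be >= 0")
        for probs, label in (
            (self.race_probs, "race_probs"),
            (self.ethnicity_probs, "ethnicity_probs"),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-8:
                raise ValueError(f"{label} must sum to 1")
        lo, hi = self.age_range
        if not 0 < lo < hi:
            raise ValueError("age_range must be an increasing positive pair")
        for spec in self.diagnoses:
            spec.validate()


def ucsf_like_config(seed: int = 0, **overrides) -> SynthConfig:
    """Center with a near-equal case/control visit gap (median ~42 vs ~41)."""
    cfg = SynthConfig(
        seed=seed, center_label="center-A", visit_mean_control=50.0,
        visit_case_multiplier=1.25,
    )
    return _override(cfg, overrides)


def stanford_like_config(seed: int = 1, **overrides) -> SynthConfig:
    """Center with a large case/control visit gap (median ~31 vs ~14)."""
    cfg = SynthConfig(
        seed=seed, center_label="center-B", visit_mean_control=18.0,
        visit_case_multiplier=2.2,
    )
    return _override(cfg, overrides)


def _override(cfg: SynthConfig, overrides: dict) -> SynthConfig:
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown SynthConfig field '{key}'")
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Planted parameters exported alongside every generated bundle."""

    center_label: str
    seed: int
    planted_or: dict[str, float]
    baseline_prevalence: dict[str, float]
    visit_mean_control: float
    visit_case_multiplier: float
    utilization_link_strength: float
    patients: pd.DataFrame  # person_id, group, age_at_index, n_visits, index_date

    def to_json(self, path) -> None:
        payload = {
            "center_label": self.center_label,
            "seed": self.seed,
            "planted_or": self.planted_or,
            "baseline_prevalence": self.baseline_prevalence,
            "visit_mean_control": self.visit_mean_control,
            "visit_case_multiplier": self.visit_case_multiplier,
            "utilization_link_strength": self.utilization_link_strength,
            "n_rpl": int((self.patients["group"] == "rpl").sum()),
            "n_control": int((self.patients["group"] == "control").sum()),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# sampling helpers

def _age_tilt(age: np.ndarray) -> np.ndarray:
    # Piecewise-smooth log-weight: gentle rise through the 20s, accelerating
    # quadratically after 35 (the documented risk pattern).
    base = (age - 15.0) / 29.0
    late = np.clip(age - 35.0, 0.0, None) / 9.0
    return base + 3.0 * late**2


def _control_age_grid(cfg: SynthConfig):
    lo, hi = cfg.age_range
    grid = np.arange(lo, hi, 0.05) + 0.025
    dens = np.exp(-0.5 * ((grid - cfg.age_control_mean) / cfg.age_control_sd) ** 2)
    return grid, dens / dens.sum()


def _case_age_probs(cfg: SynthConfig):
    """Tilt the control age density so the case mean exceeds it by the
    configured shift; the tilt strength is solved by bisection."""
    grid, p0 = _control_age_grid(cfg)
    target = (grid * p0).sum() + cfg.age_case_shift_years
    tilt = _age_tilt(grid)

    def mean_at(k: float) -> float:
        w = p0 * np.exp(k * tilt)
        w /= w.sum()
        return float((grid * w).sum())

    lo_k, hi_k = 0.0, 50.0
    if target >= mean_at(hi_k):
        k = hi_k
    else:
        for _ in range(80):
            mid = 0.5 * (lo_k + hi_k)
            if mean_at(mid) < target:
                lo_k = mid
            else:
                hi_k = mid
        k = 0.5 * (lo_k + hi_k)
    w = p0 * np.exp(k * tilt)
    return grid, w / w.sum()


def _sample_ages(rng: np.random.Generator, n: int, case: bool, cfg: SynthConfig):
    grid, probs = _case_age_probs(cfg) if case else _control_age_grid(cfg)
    ages = rng.choice(grid, size=n, p=probs) + rng.uniform(-0.025, 0.025, size=n)
    return np.clip(ages, cfg.age_range[0], cfg.age_range[1] - 1e-6)


def _sample_visits_vec(rng: np.random.Generator, means, cfg: SynthConfig) -> np.ndarray:
    # negative binomial, shifted so everyone has >= 1 visit; capped at the
    # heaviest utilization seen in real extracts
    r = cfg.visit_dispersion
    p = r / (r + np.asarray(means, dtype=float))
    return np.minimum(rng.negative_binomial(r, p) + 1, 1700)


def _presence_probs(
    spec: DiagnosisSpec,
    case: np.ndarray,
    age: np.ndarray,
    visits: np.ndarray,
    cfg: SynthConfig,
) -> np.ndarray:
    logit = np.log(spec.baseline_prevalence / (1 - spec.baseline_prevalence))
    eta = logit + case * np.log(spec.planted_or)
    if spec.age_modifier:
        eta = eta + spec.age_modifier * (age - cfg.age_control_mean) / 5.0
    if cfg.utilization_link_strength:
        eta = eta + cfg.utilization_link_strength * (
            np.log(visits) - np.log(cfg.visit_mean_control)
        )
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# main generator

def generate_center(config: SynthConfig) -> tuple[EhrBundle, GroundTruth]:
    """Generate one center's bundle plus its ground truth.

    Per RPL patient the bundle contains at least two pregnancy-loss records
    >= 90 days apart (or a history-of-loss followed by a loss), optional
    sub-90-day duplicate loss records, and optional explicit RPL-diagnosis
    records; per control patient at least one live-birth record and no
    loss/exclusion records. Diagnosis presence follows the configured
    logit-additive model; visit counts are negative-binomial with a
    center-specific case multiplier. Fully reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rpl, n_ctl = config.n_rpl, config.n_control
    n = n_rpl + n_ctl
    case = np.concatenate([np.ones(n_rpl, bool), np.zeros(n_ctl, bool)])
    person_ids = np.array(
        [f"{config.center_label}-P{i:06d}" for i in range(n)], dtype=object
    )

    ages = np.empty(n)
    ages[:n_rpl] = _sample_ages(rng, n_rpl, True, config)
    ages[n_rpl:] = _sample_ages(rng, n_ctl, False, config)
    races = rng.choice(
        list(config.race_probs), size=n, p=list(config.race_probs.values())
    )
    eths = rng.choice(
        list(config.ethnicity_probs), size=n, p=list(config.ethnicity_probs.values())
    )
    visit_means = np.where(
        case,
        config.visit_mean_control * config.visit_case_multiplier,
        config.visit_mean_control,
    )
    visits = _sample_visits_vec(rng, visit_means, config)

    # calendar anchors: index dates spread across ~8 years
    index_offset = rng.integers(-1500, 1501, size=n)
    index_dates = pd.Timestamp("2016-01-01") + pd.to_timedelta(index_offset, unit="D")

    span_scale = config.record_span_years * 365.25
    pre_extra = rng.exponential(span_scale * 0.5, size=n)
    post_days = 30 + rng.exponential(span_scale * 0.35, size=n)

    persons = []
    cond_pid, cond_code, cond_day = [], [], []

    def add_record(pid, code, date):
        cond_pid.append(pid)
        cond_code.append(code)
        cond_day.append(date)

    first_record = np.empty(n, dtype="datetime64[ns]")
    last_record = np.empty(n, dtype="datetime64[ns]")

    day = pd.Timedelta(days=1)
    for i in range(n):
        pid = person_ids[i]
        idx = index_dates[i]
        if case[i]:
            qualifies_via_history_only = rng.random() < config.history_only_prob
            if qualifies_via_history_only:
                # single loss preceded by a history-of-loss record
                h_gap = int(rng.integers(40, 500))
                add_record(pid, HISTORY_CONCEPT, idx - h_gap * day)
                add_record(pid, rng.choice(LOSS_CONCEPTS), idx)
                pre_days = h_gap + pre_extra[i]
            else:
                d2 = int(rng.integers(90, 540))
                first_loss = idx - d2 * day
                add_record(pid, rng.choice(LOSS_CONCEPTS), first_loss)
                add_record(pid, rng.choice(LOSS_CONCEPTS), idx)
                if rng.random() < config.dup_loss_prob:
                    # duplicate record for the first loss, inside 90 days
                    add_record(
                        pid,
                        rng.choice(LOSS_CONCEPTS),
                        first_loss + int(rng.integers(1, min(89, d2 - 1) + 1)) * day,
                    )
                if rng.random() < config.history_record_prob and d2 > 60:
                    # history noted between the two losses: criterion dates
                    # cannot precede the planned index
                    add_record(
                        pid,
                        HISTORY_CONCEPT,
                        first_loss + int(rng.integers(30, d2 - 29)) * day,
                    )
                pre_days = d2 + pre_extra[i]
            if rng.random() < config.rpl_dx_record_prob:
                add_record(pid, RPL_DX_CONCEPT, idx + int(rng.integers(0, 60)) * day)
            if rng.random() < config.next_outcome_prob:
                # subsequent pregnancy outcome; post-index losses also create
                # third distinct events (the severe-RPL subgroup) without
                # moving the main index date
                gap_next = int(rng.integers(60, 700))
                next_code = (
                    rng.choice(BIRTH_CONCEPTS)
                    if rng.random() < config.next_birth_frac
                    else rng.choice(LOSS_CONCEPTS)
                )
                add_record(pid, next_code, idx + gap_next * day)
        else:
            add_record(pid, rng.choice(BIRTH_CONCEPTS), idx)
            if rng.random() < 0.3:
                add_record(
                    pid, rng.choice(BIRTH_CONCEPTS), idx + int(rng.integers(400, 1200)) * day
                )
            pre_days = 30 + pre_extra[i]

        start = idx - int(pre_days) * day
        end = idx + int(post_days[i]) * day
        first_record[i] = start
        last_record[i] = end
        birth = idx - pd.Timedelta(days=round(ages[i] * 365.25))
        persons.append(
            {
                "person_id": pid,
                "birth_date": birth,
                "gender": "female",
                "race": races[i],
                "ethnicity": eths[i],
            }
        )

    # exposure diagnoses, vectorized per diagnosis
    window_end = index_dates + pd.Timedelta(days=365)
    dx_presence = {}
    for spec in config.diagnoses:
        probs = _presence_probs(spec, case.astype(float), ages, visits, config)
        present = rng.random(n) < probs
        dx_presence[spec.phecode] = present
        idx_present = np.flatnonzero(present)
        if len(idx_present) == 0:
            continue
        rec_end = np.minimum(window_end.values[idx_present], last_record[idx_present])
        rec_start = first_record[idx_present]
        span = np.maximum(
            (rec_end - rec_start) / np.timedelta64(1, "D"), 1.0
        )
        offsets = (rng.random(len(idx_present)) * span).astype(int)
        use_icd10 = rng.random(len(idx_present)) < config.icd10_prob
        for j, patient, off, ten in zip(
            range(len(idx_present)), idx_present, offsets, use_icd10
        ):
            code = spec.icd10 if ten else spec.icd9
            add_record(
                person_ids[patient], code, pd.Timestamp(rec_start[j]) + int(off) * day
            )

    # routine-exam code keeps nearly every patient past the no-diagnosis
    # exclusion; a small share of junk codes exercises the coverage report
    routine = rng.random(n) < config.routine_exam_prob
    junk = rng.random(n) < config.unmapped_code_prob
    for i in range(n):
        if routine[i]:
            code = "Z00.00" if rng.random() < config.icd10_prob else "V70.0"
            add_record(person_ids[i], code, index_dates[i] - int(rng.integers(0, 30)) * day)
        if junk[i]:
            add_record(person_ids[i], "Q99.99", index_dates[i] - int(rng.integers(0, 30)) * day)

    # visit records
    visit_pid, visit_date = [], []
    for i in range(n):
        span_days = max(
            int((last_record[i] - first_record[i]) / np.timedelta64(1, "D")), 1
        )
        offs = rng.integers(0, span_days + 1, size=int(visits[i]))
        start = pd.Timestamp(first_record[i])
        for off in offs:
            visit_pid.append(person_ids[i])
            visit_date.append(start + int(off) * day)

    bundle = EhrBundle(
        center_label=config.center_label,
        persons=pd.DataFrame(persons),
        conditions=pd.DataFrame(
            {"person_id": cond_pid, "concept_id": cond_code, "start_date": cond_day}
        ),
        visits=pd.DataFrame({"person_id": visit_pid, "visit_date": visit_date}),
    )
    bundle.validate()

    truth = GroundTruth(
        center_label=config.center_label,
        seed=config.seed,
        planted_or={s.phecode: s.planted_or for s in config.diagnoses},
        baseline_prevalence={s.phecode: s.baseline_prevalence for s in config.diagnoses},
        visit_mean_control=config.visit_mean_control,
        visit_case_multiplier=config.visit_case_multiplier,
        utilization_link_strength=config.utilization_link_strength,
        patients=pd.DataFrame(
            {
                "person_id": person_ids,
                "group": np.where(case, "rpl", "control"),
                "age_at_index": ages,
                "n_visits": visits,
                "index_date": index_dates,
                **{f"dx_{k}": v for k, v in dx_presence.items()},
            }
        ),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# edge-case injection

def inject_edge_cases(bundle: EhrBundle, base_date: str = "2015-01-01") -> EhrBundle:
    """Append named fixture patients exercising every exclusion arm.

    Patients added (all dates relative to ``base_date``):

    ======================  ==================================================
    edge_gap89              losses on day 0/89 -> one distinct event, not RPL
    edge_gap90              losses on day 0/90 -> RPL, index day 90
    edge_gap91              losses on day 0/91 -> RPL, index day 91
    edge_under15            RPL but aged 14.9 at index -> age exclusion
    edge_over44             RPL but aged 44.9 at index -> age exclusion
    edge_span101y           RPL with a record 101 years after index -> span
    edge_nodx               RPL with zero in-window ICD diagnoses -> no-dx
    edge_preterm_ctrl       live birth plus preterm record -> not a control
    edge_male_nopreg        male, RPL-diagnosis record, no pregnancy evidence
    ======================  ==================================================
    """
    base = pd.Timestamp(base_date)
    day = pd.Timedelta(days=1)
    default_birth = base - pd.Timedelta(days=round(30 * 365.25))

    persons, conds = [], []

    def person(pid, birth=default_birth, gender="female"):
        persons.append(
            {
                "person_id": pid,
                "birth_date": birth,
                "gender": gender,
                "race": "White",
                "ethnicity": "Not Hispanic or Latino",
            }
        )

    def cond(pid, code, d):
        conds.append(
            {"person_id": pid, "concept_id": code, "start_date": base + d * day}
        )

    loss = LOSS_CONCEPTS[1]
    for pid, gap in (("edge_gap89", 89), ("edge_gap90", 90), ("edge_gap91", 91)):
        person(pid)
        cond(pid, loss, 0)
        cond(pid, loss, gap)
        cond(pid, "J06.9", 10)

    person("edge_under15", birth=base + 90 * day - pd.Timedelta(days=round(14.9 * 365.25)))
    cond("edge_under15", loss, 0)
    cond("edge_under15", loss, 90)
    cond("edge_under15", "J06.9", 10)

    person("edge_over44", birth=base + 90 * day - pd.Timedelta(days=round(44.9 * 365.25)))
    cond("edge_over44", loss, 0)
    cond("edge_over44", loss, 90)
    cond("edge_over44", "J06.9", 10)

    person("edge_span101y")
    cond("edge_span101y", loss, 0)
    cond("edge_span101y", loss, 90)
    cond("edge_span101y", "J06.9", 10)
    cond("edge_span101y", "J06.9", 90 + round(101 * 365.25))  # 101 years later

    person("edge_nodx")
    cond("edge_nodx", loss, 0)
    cond("edge_nodx", loss, 90)

    person("edge_preterm_ctrl")
    cond("edge_preterm_ctrl", BIRTH_CONCEPTS[0], 200)
    cond("edge_preterm_ctrl", "EX_PRETERM_BIRTH", 600)
    cond("edge_preterm_ctrl", "J06.9", 180)

    person("edge_male_nopreg", gender="male")
    cond("edge_male_nopreg", RPL_DX_CONCEPT, 0)
    cond("edge_male_nopreg", "E11.9", -10)

    out = EhrBundle(
        center_label=bundle.center_label,
        persons=pd.concat(
            [bundle.persons, pd.DataFrame(persons)], ignore_index=True
        ),
        conditions=pd.concat(
            [bundle.conditions, pd.DataFrame(conds)], ignore_index=True
        ),
        visits=bundle.visits.copy(),
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# hand-built 25-patient fixture

def handcrafted_fixture() -> tuple[EhrBundle, dict[str, ConceptSet]]:
    """A fully hand-enumerated 25-patient bundle.

    Covers the 89/90/91-day loss-gap boundary, history-of-loss qualifiers,
    same-day history+loss, index-date minimization across criteria,
    duplicate loss records, control exclusions (preterm, molar, prior loss),
    the age/gender/span/no-diagnosis exclusion arms, the window endpoint at
    index+365 vs +366 days, and a patient qualifying for both groups.
    Expected memberships are asserted record-by-record in the test suite.
    """
    base = pd.Timestamp("2015-01-01")
    day = pd.Timedelta(days=1)
    default_birth = pd.Timestamp("1985-06-15")
    loss = LOSS_CONCEPTS[1]
    birth_code = BIRTH_CONCEPTS[1]

    persons, conds = [], []

    def person(pid, birth=default_birth, gender="female"):
        persons.append(
            {
                "person_id": pid,
                "birth_date": birth,
                "gender": gender,
                "race": "White",
                "ethnicity": "Not Hispanic or Latino",
            }
        )

    def cond(pid, code, d):
        conds.append(
            {"person_id": pid, "concept_id": code, "start_date": base + d * day}
        )

    def with_filler(pid, d=10):
        cond(pid, "J06.9", d)

    # loss-gap boundary trio
    person("P01"); cond("P01", loss, 0); cond("P01", loss, 89); with_filler("P01")
    person("P02"); cond("P02", loss, 0); cond("P02", loss, 90); with_filler("P02")
    person("P03"); cond("P03", loss, 0); cond("P03", loss, 91); with_filler("P03")
    # greedy event scan: events at 0, 95, 200 -> severe RPL
    person("P04")
    for d in (0, 50, 95, 200):
        cond("P04", loss, d)
    with_filler("P04")
    # history-then-loss qualifier
    person("P05"); cond("P05", HISTORY_CONCEPT, 100); cond("P05", loss, 300)
    cond("P05", "J06.9", 250)
    # same-day history+loss does not qualify
    person("P06"); cond("P06", HISTORY_CONCEPT, 100); cond("P06", loss, 100)
    cond("P06", "J06.9", 50)
    # index = min over qualifying dates (RPL dx at 50 beats second loss at 90)
    person("P07"); cond("P07", RPL_DX_CONCEPT, 50); cond("P07", loss, 0)
    cond("P07", loss, 90); with_filler("P07")
    # single loss only
    person("P08"); cond("P08", loss, 0); with_filler("P08")
    # controls
    person("P09"); cond("P09", birth_code, 500); cond("P09", "J06.9", 480)
    person("P10"); cond("P10", birth_code, 400); cond("P10", birth_code, 800)
    cond("P10", "J06.9", 380)
    person("P11"); cond("P11", birth_code, 500); cond("P11", "EX_PRETERM_BIRTH", 900)
    cond("P11", "J06.9", 480)
    person("P12"); cond("P12", birth_code, 500); cond("P12", loss, 900)
    cond("P12", "J06.9", 480)
    person("P13"); cond("P13", birth_code, 300); cond("P13", "EX_MOLAR_PREGNANCY", 100)
    cond("P13", "J06.9", 280)
    # age-arm cases
    person("P14", birth=base + 90 * day - pd.Timedelta(days=round(14.9 * 365.25)))
    cond("P14", loss, 0); cond("P14", loss, 90); with_filler("P14")
    person("P15", birth=base + 500 * day - pd.Timedelta(days=round(43.9 * 365.25)))
    cond("P15", birth_code, 500); cond("P15", "J06.9", 480)
    person("P16", birth=base + 90 * day - pd.Timedelta(days=round(44.9 * 365.25)))
    cond("P16", loss, 0); cond("P16", loss, 90); with_filler("P16")
    # 101-year record span
    person("P17"); cond("P17", loss, 0); cond("P17", loss, 90); with_filler("P17")
    cond("P17", "J06.9", 90 + round(101 * 365.25))
    # no in-window ICD diagnoses
    person("P18"); cond("P18", loss, 0); cond("P18", loss, 90)
    # male via RPL diagnosis, no incident-pregnancy evidence
    person("P19", gender="male"); cond("P19", RPL_DX_CONCEPT, 0)
    cond("P19", "E11.9", -10)
    # non-female with pregnancy evidence is retained
    person("P20", gender="other"); cond("P20", loss, 0); cond("P20", loss, 90)
    with_filler("P20")
    # window endpoint: +365 in, +366 out
    person("P21"); cond("P21", birth_code, 500); cond("P21", "J06.9", 865)
    person("P22"); cond("P22", birth_code, 500); cond("P22", "J06.9", 866)
    # duplicate loss inside 90 days
    person("P23"); cond("P23", loss, 0); cond("P23", loss, 45); cond("P23", loss, 90)
    with_filler("P23")
    # history-of-loss alone does not exclude a control
    person("P24"); cond("P24", birth_code, 200); cond("P24", HISTORY_CONCEPT, 100)
    cond("P24", "J06.9", 190)
    # qualifies for both groups -> RPL only (loss records bar the control arm)
    person("P25"); cond("P25", loss, 0); cond("P25", loss, 90)
    cond("P25", birth_code, 400); with_filler("P25")

    bundle = EhrBundle(
        center_label="fixture",
        persons=pd.DataFrame(persons),
        conditions=pd.DataFrame(conds),
        visits=pd.DataFrame({"person_id": pd.Series(dtype=str),
                             "visit_date": pd.Series(dtype="datetime64[ns]")}),
    )
    bundle.validate()
    return bundle, default_concept_sets()


# ---------------------------------------------------------------------------
# analysis-frame simulator (no record materialization)

def simulate_case_control(
    rng: np.random.Generator,
    n_rpl: int,
    n_control: int,
    diagnoses: list[DiagnosisSpec],
    config: SynthConfig | None = None,
) -> pd.DataFrame:
    """Draw an analysis-ready case-control frame directly.

    Produces the same covariate and diagnosis-presence distributions as
    :func:`generate_center` without materializing condition/visit records —
    the tool for calibration experiments (parameter recovery, error control)
    where thousands of replicates are fitted.

    Columns: ``y`` (1 = RPL), ``age``, ``race``, ``ethnicity``, ``visits``,
    and one ``dx_<phecode>`` indicator per diagnosis.
    """
    config = config or SynthConfig()
    n = n_rpl + n_control
    case = np.concatenate([np.ones(n_rpl), np.zeros(n_control)])
    ages = np.empty(n)
    ages[:n_rpl] = _sample_ages(rng, n_rpl, True, config)
    ages[n_rpl:] = _sample_ages(rng, n_control, False, config)
    races = rng.choice(list(config.race_probs), size=n, p=list(config.race_probs.values()))
    eths = rng.choice(
        list(config.ethnicity_probs), size=n, p=list(config.ethnicity_probs.values())
    )
    means = np.where(
        case > 0,
        config.visit_mean_control * config.visit_case_multiplier,
        config.visit_mean_control,
    )
    visits = _sample_visits_vec(rng, means, config)
    out = pd.DataFrame(
        {"y": case.astype(int), "age": ages, "race": races, "ethnicity": eths,
         "visits": visits}
    )
    for spec in diagnoses:
        probs = _presence_probs(spec, case, ages, visits, config)
        out[f"dx_{spec.phecode}"] = (rng.random(n) < probs).astype(int)
    return out
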