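"""Synthetic primary-care EMR cohort generator with known smoking truth.

Emulates the structure of a hypertensive primary-care extract: patient
demographics and clinical marginals shaped like the study population
(age ~65 (14), ~51% female, BMI ~31 (7), systolic BP ~133, diabetes
~27%, COPD ~10%, ~76% urban), five EMR-vendor labels with very different
smoking-recording completeness, free-text smoking records in per-vendor
dialects, distractor records (kinship text such as "father smokes",
conflicting Status/Value pairs, multi-risk-factor strings, non-smoking
strings), and configurable MCAR / covariate-MAR / status-MNAR
missingness mechanisms.  Every draw is reproducible from the scenario
seed, and every generated record carries a 7-level truth label so the
evaluation harness can build a reference-standard confusion matrix.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import Tables
from .types import IMPUTABLE_CATEGORIES

#: 7-level per-record truth labels mirroring a reference-standard review
RECORD_TRUTH_LEVELS = (
    "current", "past", "never", "not_current", "unknown",
    "conflicting", "not_smoking_related",
)

_WINDOW_START = dt.date(2016, 7, 1)
_WINDOW_END = dt.date(2018, 6, 30)
_HISTORY_START = dt.date(2009, 1, 1)

VENDORS = ("Wolf", "MedAccess", "PracticeSolutions", "Telin", "Healthquest")


def _default_vendor_mix() -> dict:
    # shares of the study population by vendor
    return {
        "Wolf": 0.5446, "MedAccess": 0.4256, "PracticeSolutions": 0.0096,
        "Telin": 0.0070, "Healthquest": 0.0132,
    }


def _default_record_prob() -> dict:
    # probability a patient on each vendor has any usable smoking record
    return {
        "Wolf": 0.777, "MedAccess": 0.363, "PracticeSolutions": 0.970,
        "Telin": 0.255, "Healthquest": 0.230,
    }


def _default_effects() -> dict:
    # log-odds (reference category: never) on standardized covariates;
    # modest, epidemiologically plausible defaults
    return {
        "current": {"male": 0.5, "age10": -0.3, "copd": 0.8},
        "past": {"male": 0.3, "age10": 0.3, "copd": 0.5},
    }


def _default_distractors() -> dict:
    return {
        "relationship": 0.02,
        "conflicting": 0.005,
        "multi_risk": 0.03,
        "non_smoking": 0.01,
        "not_current": 0.01,
    }


@dataclass
class SimulationScenario:
    """A stated synthetic world; defaults mirror the study population."""

    n_patients: int = 5000
    truth_proportions: dict = field(
        default_factory=lambda: {"current": 0.212, "past": 0.227, "never": 0.561}
    )
    covariate_effects: dict = field(default_factory=_default_effects)
    vendor_mix: dict = field(default_factory=_default_vendor_mix)
    vendor_record_prob: dict = field(default_factory=_default_record_prob)
    distractor_rates: dict = field(default_factory=_default_distractors)
    # missingness mechanism for inject_missingness convenience runs
    missing_mechanism: str = "mcar"  # mcar | mar_covariate | mnar_status
    missing_rate: float = 0.408
    # demographics / clinical marginals
    female_frac: float = 0.51
    age_mean: float = 65.0
    age_sd: float = 14.0
    bmi_mean: float = 31.0
    bmi_sd: float = 7.0
    sbp_mean: float = 133.0
    sbp_sd: float = 16.0
    dbp_mean: float = 79.0
    dbp_sd: float = 11.0
    diabetes_rate: float = 0.27
    copd_rate: float = 0.10
    rural_frac: float = 0.24
    postal_missing_rate: float = 0.018
    bmi_missing_rate: float = 0.10
    bp_missing_rate: float = 0.01
    deceased_rate: float = 0.02
    inactive_rate: float = 0.03
    no_window_visit_rate: float = 0.04
    multi_record_frac: float = 0.20  # patients with >1 smoking record
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        tot = sum(self.truth_proportions.get(c, 0.0) for c in IMPUTABLE_CATEGORIES)
        if tot <= 0:
            raise ValueError("truth proportions must be positive")
        self.truth_proportions = {
            c: self.truth_proportions[c] / tot for c in IMPUTABLE_CATEGORIES
        }
        for name, rates in (
            ("distractor_rates", self.distractor_rates),
            ("vendor_record_prob", self.vendor_record_prob),
        ):
            for k, v in rates.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{name}[{k}] must be in [0, 1]")
        mix_tot = sum(self.vendor_mix.values())
        self.vendor_mix = {k: v / mix_tot for k, v in self.vendor_mix.items()}

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# population


def _truth_smoking(scenario, male, age, copd, rng) -> np.ndarray:
    """Covariate-dependent multinomial truth with intercepts calibrated so
    the marginal proportions equal the scenario targets."""
    age10 = (age - 65.0) / 10.0
    eff = scenario.covariate_effects
    eta = {}
    for cat in ("current", "past"):
        e = eff.get(cat, {})
        eta[cat] = (
            e.get("male", 0.0) * male
            + e.get("age10", 0.0) * age10
            + e.get("copd", 0.0) * copd
        )
    a = {"current": 0.0, "past": 0.0}
    target = scenario.truth_proportions
    for _ in range(60):
        ec = np.exp(a["current"] + eta["current"])
        ep = np.exp(a["past"] + eta["past"])
        denom = 1.0 + ec + ep
        pc, pp = (ec / denom).mean(), (ep / denom).mean()
        a["current"] += np.log(target["current"] / max(pc, 1e-12))
        a["past"] += np.log(target["past"] / max(pp, 1e-12))
    ec = np.exp(a["current"] + eta["current"])
    ep = np.exp(a["past"] + eta["past"])
    denom = 1.0 + ec + ep
    P = np.column_stack([ec / denom, ep / denom, 1.0 / denom])
    u = rng.random(len(P))
    cum = np.cumsum(P, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(["current", "past", "never"], dtype=object)[idx]


def _postal_codes(n, scenario, rng) -> np.ndarray:
    letters = np.array(list("ABCEGHJKLMNPRSTVXY"))
    digits = np.array(list("0123456789"))
    second = np.where(
        rng.random(n) < scenario.rural_frac,
        "0",
        digits[rng.integers(1, 10, n)],
    )
    parts = [
        letters[rng.integers(0, len(letters), n)],
        second,
        letters[rng.integers(0, len(letters), n)],
        digits[rng.integers(0, 10, n)],
        letters[rng.integers(0, len(letters), n)],
        digits[rng.integers(0, 10, n)],
    ]
    codes = np.array(["".join(p) for p in zip(*parts)], dtype=object)
    codes[rng.random(n) < scenario.postal_missing_rate] = ""
    return codes


def _random_dates(n, start: dt.date, end: dt.date, rng) -> list[dt.date]:
    span = (end - start).days
    return [start + dt.timedelta(days=int(d)) for d in rng.integers(0, span + 1, n)]


def generate_population(
    scenario: SimulationScenario, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Generate patients/encounters/measurements/conditions plus the
    patient-level truth table.  Fully reproducible from the seed."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_patients
    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)

    sex = np.where(rng.random(n) < scenario.female_frac, "F", "M")
    age = np.clip(rng.normal(scenario.age_mean, scenario.age_sd, n), 18, 100)
    birth_year = (_WINDOW_END.year - age).astype(int)
    vendors = rng.choice(
        list(scenario.vendor_mix), p=list(scenario.vendor_mix.values()), size=n
    )
    deceased = rng.random(n) < scenario.deceased_rate
    inactive = rng.random(n) < scenario.inactive_rate
    diabetes = rng.random(n) < scenario.diabetes_rate
    copd = rng.random(n) < scenario.copd_rate
    truth = _truth_smoking(scenario, (sex == "M").astype(float), age,
                           copd.astype(float), rng)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "birth_year": birth_year,
            "postal_code": _postal_codes(n, scenario, rng),
            "emr_system": vendors,
            "deceased": deceased,
            "inactive": inactive,
        }
    )
    conditions = pd.DataFrame(
        {
            "patient_id": pid,
            "hypertension": np.ones(n, dtype=bool),
            "diabetes": diabetes,
            "copd": copd,
        }
    )

    # encounters: total count ~ 1 + NegBin, spread over the patient history;
    # most patients get at least one in-window visit (the activity filter)
    n_enc = 1 + rng.negative_binomial(2, 2 / (2 + 30), n)
    enc_pid, enc_dates = [], []
    has_window = rng.random(n) >= scenario.no_window_visit_rate
    for i in range(n):
        k = int(n_enc[i])
        dates = _random_dates(k, _HISTORY_START, _WINDOW_END, rng)
        if has_window[i]:
            dates[0] = _random_dates(1, _WINDOW_START, _WINDOW_END, rng)[0]
        else:
            dates = _random_dates(k, _HISTORY_START,
                                  _WINDOW_START - dt.timedelta(days=1), rng)
        enc_pid.extend([pid[i]] * k)
        enc_dates.extend(dates)
    encounters = pd.DataFrame(
        {"patient_id": enc_pid, "encounter_date": enc_dates}
    )

    # measurements: a short BMI series per patient (with rare implausible
    # values and jumps, to exercise the cleaning rules) plus latest BPs
    m_pid, m_kind, m_val, m_date = [], [], [], []
    bmi_base = np.clip(rng.normal(scenario.bmi_mean, scenario.bmi_sd, n), 14, 65)
    has_bmi = rng.random(n) >= scenario.bmi_missing_rate
    has_bp = rng.random(n) >= scenario.bp_missing_rate
    sbp = rng.normal(scenario.sbp_mean, scenario.sbp_sd, n)
    dbp = rng.normal(scenario.dbp_mean, scenario.dbp_sd, n)
    for i in range(n):
        if has_bmi[i]:
            k = int(rng.integers(1, 4))
            dates = sorted(_random_dates(k, _HISTORY_START, _WINDOW_END, rng))
            for d in dates:
                v = float(bmi_base[i] + rng.normal(0, 1.5))
                u = rng.random()
                if u < 0.01:
                    v = float(rng.uniform(71, 90))  # implausible
                elif u < 0.02:
                    v = v + 15.0  # jump outlier
                m_pid.append(pid[i]); m_kind.append("bmi")
                m_val.append(round(v, 1)); m_date.append(d)
        if has_bp[i]:
            d = _random_dates(1, _WINDOW_START, _WINDOW_END, rng)[0]
            m_pid.extend([pid[i], pid[i]])
            m_kind.extend(["sbp", "dbp"])
            m_val.extend([round(float(sbp[i]), 0), round(float(dbp[i]), 0)])
            m_date.extend([d, d])
    measurements = pd.DataFrame(
        {"patient_id": m_pid, "kind": m_kind, "value": m_val,
         "measure_date": m_date}
    )

    truth_df = pd.DataFrame({"patient_id": pid, "smoking": truth})
    return {
        "patients": patients,
        "encounters": encounters,
        "measurements": measurements,
        "conditions": conditions,
        "truth": truth_df,
    }


# ---------------------------------------------------------------------------
# free-text smoking records


def _dialect(vendor: str, status: str, rng) -> tuple[str, str, str]:
    """(name, value, status) texts for a truth-consistent record.

    Each vendor favours different fields and phrasings; every template
    classifies to its truth status under the default lexicon."""
    year = int(rng.integers(1990, 2018))
    k = int(rng.integers(1, 4))
    pick = lambda opts: opts[int(rng.integers(0, len(opts)))]
    if status == "current":
        by_vendor = {
            "Wolf": [("Smoking", "", "current"), ("Smoking", f"{k} packs/day", "current"),
                     ("Smoking", "cigarettes/day: 10", "smoker")],
            "MedAccess": [("Smoking", "smoker", ""), ("Smoking", f"up to {k}ppd", ""),
                          ("Smoking", "smokes socially", "")],
            "PracticeSolutions": [("Smoking", "", "Current"), ("Smoking", "1 ppd", "Current")],
            "Telin": [("Smoking", "yes", ""), ("Smoking", "", "smoker")],
            "Healthquest": [("Smoking", f"{k} pack/day", ""), ("Smoking", "", "yes")],
        }
    elif status == "past":
        by_vendor = {
            "Wolf": [("Smoking", "", "past"), ("Smoking", f"quit {year}", "past"),
                     ("Smoking", "", "ex-smoker")],
            "MedAccess": [("Smoking", "smoker: quit", ""), ("Smoking", f"quit smoking {year}", ""),
                          ("Smoking", "ex smoker", "")],
            "PracticeSolutions": [("Smoking", "", "Past"), ("Smoking", "former smoker", "Past")],
            "Telin": [("Smoking", "quit", ""), ("Smoking", "", "former")],
            "Healthquest": [("Smoking", f"ex-smoker since {year}", ""), ("Smoking", "", "quit")],
        }
    elif status == "never":
        by_vendor = {
            "Wolf": [("Smoking", "", "never"), ("Smoking", "never smoked", "never")],
            "MedAccess": [("Smoking", "never a smoker", ""), ("Smoking", "never", "")],
            "PracticeSolutions": [("Smoking", "", "Never")],
            "Telin": [("Smoking", "never", "")],
            "Healthquest": [("Smoking", "", "never")],
        }
    else:  # not_current
        by_vendor = {
            "Wolf": [("Smoking", "", "non-smoker")],
            "MedAccess": [("Smoking", "non smoker", "")],
            "PracticeSolutions": [("Smoking", "", "Non-smoker")],
            "Telin": [("Smoking", "no", "")],
            "Healthquest": [("Smoking", "", "no")],
        }
    return pick(by_vendor.get(vendor, by_vendor["Wolf"]))


_RELATION_TEXTS = [
    ("Smoking", "father smokes", ""),
    ("Smoking", "mother quit smoking", ""),
    ("Smoking", "husband smokes 2ppd", ""),
    ("Smoking", "", "aunt is a smoker"),
    ("Smoking", "family history: brother smoker", ""),
]
_MULTI_RISK_TEXTS = [
    ("Unknown", "etoh socially, poor diet, sedentary", ""),
    ("Unknown", "risk factors reviewed: alcohol, exercise, diet", ""),
    ("Smoking", "tobacco use assessment", ""),
    ("Unknown", "lifestyle counselling provided", ""),
]
_NON_SMOKING_TEXTS = [
    ("Smoking", "blister pack medications", ""),
    ("Smoking", "flu shot given", ""),
    ("Smoking", "medication review completed", ""),
]
_CONFLICTING_TEXTS = [
    ("Smoking", "non smoker", "Current"),
    ("Smoking", "1 ppd", "never"),
    ("Smoking", "never smoked", "smoker"),
]


def generate_smoking_text(
    true_status: str,
    vendor: str,
    distractor: str | None,
    rng: np.random.Generator,
) -> tuple[str, str, str, str]:
    """One record's (name_text, value_text, status_text, truth_label).

    ``distractor`` is one of None, 'relationship', 'conflicting',
    'multi_risk', 'non_smoking', 'not_current'."""
    pick = lambda opts: opts[int(rng.integers(0, len(opts)))]
    if distractor == "relationship":
        name, value, status = pick(_RELATION_TEXTS)
        return name, value, status, "unknown"
    if distractor == "multi_risk":
        name, value, status = pick(_MULTI_RISK_TEXTS)
        return name, value, status, "unknown"
    if distractor == "non_smoking":
        name, value, status = pick(_NON_SMOKING_TEXTS)
        return name, value, status, "not_smoking_related"
    if distractor == "conflicting":
        name, value, status = pick(_CONFLICTING_TEXTS)
        return name, value, status, "conflicting"
    if distractor == "not_current":
        name, value, status = _dialect(vendor, "not_current", rng)
        return name, value, status, "not_current"
    name, value, status = _dialect(vendor, true_status, rng)
    return name, value, status, true_status


def _draw_distractor(rates: dict, rng) -> str | None:
    u = rng.random()
    acc = 0.0
    for kind in ("relationship", "conflicting", "multi_risk",
                 "non_smoking", "not_current"):
        acc += rates.get(kind, 0.0)
        if u < acc:
            return kind
    return None


def generate_smoking_records(
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    recording: str = "vendor",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Risk-factor records plus their 7-level truth labels.

    ``recording="vendor"`` gives each patient a record set with the
    vendor-specific probability (the empirically observed completeness
    pattern); ``recording="all"`` records everyone, so missingness can
    then be injected by an explicit mechanism."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    truth_map = truth.set_index("patient_id")["smoking"]
    rows, label_rows = [], []
    for row in patients.itertuples(index=False):
        pid, vendor = row.patient_id, row.emr_system
        if recording == "vendor":
            p_rec = scenario.vendor_record_prob.get(vendor, 0.5)
            if rng.random() >= p_rec:
                continue
        status = truth_map[pid]
        n_rec = 1 + (int(rng.integers(1, 3)) if rng.random() < scenario.multi_record_frac else 0)
        # distinct, ordered record dates; latest usually in-window
        latest_in_window = rng.random() < 0.8
        latest = (
            _random_dates(1, _WINDOW_START, _WINDOW_END, rng)[0]
            if latest_in_window
            else _random_dates(1, dt.date(2012, 1, 1), _WINDOW_START, rng)[0]
        )
        dates = sorted(
            {latest - dt.timedelta(days=int(d)) for d in rng.integers(200, 2000, n_rec - 1)}
        ) + [latest]
        for j, d in enumerate(dates):
            is_latest = j == len(dates) - 1
            distractor = _draw_distractor(scenario.distractor_rates, rng)
            rec_status = status
            if not is_latest and status == "past" and rng.random() < 0.5:
                rec_status = "current"  # plausible smoking history
            name, value, st, label = generate_smoking_text(
                rec_status, vendor, distractor, rng
            )
            rows.append(
                {"patient_id": pid, "entry_date": d, "name_text": name,
                 "value_text": value, "status_text": st}
            )
            label_rows.append(
                {"patient_id": pid, "entry_date": d, "truth_label": label,
                 "is_latest": is_latest}
            )
    risk_factors = pd.DataFrame(
        rows, columns=["patient_id", "entry_date", "name_text",
                       "value_text", "status_text"]
    )
    record_truth = pd.DataFrame(
        label_rows, columns=["patient_id", "entry_date", "truth_label", "is_latest"]
    )
    return risk_factors, record_truth


# ---------------------------------------------------------------------------
# missingness injection


def inject_missingness(
    statuses: pd.Series,
    mechanism: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Remove statuses under a stated mechanism; returns (masked, mask).

    mcar: uniform rate ``p``.  mar_covariate: per-vendor base missingness
    probabilities tilted on the logit scale by age (depends only on
    observed covariates).  mnar_status: per-status rates (e.g. current
    smokers always retained), so missingness depends on the value itself.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    params = params or {}
    n = len(statuses)
    if mechanism == "mcar":
        p = params.get("p", 0.408)
        mask = rng.random(n) < p
    elif mechanism == "mar_covariate":
        if covariates is None:
            raise ValueError("mar_covariate requires covariates")
        vendor_miss = params.get(
            "vendor_miss",
            {v: 1 - p for v, p in _default_record_prob().items()},
        )
        age_coef = params.get("age_coef", 0.01)
        base = covariates["emr_system"].map(vendor_miss).fillna(0.4).to_numpy(float)
        base = np.clip(base, 1e-4, 1 - 1e-4)
        logit = np.log(base / (1 - base))
        if "age" in covariates:
            logit = logit + age_coef * (covariates["age"].to_numpy(float) - 65.0)
        p = 1 / (1 + np.exp(-logit))
        mask = rng.random(n) < p
    elif mechanism == "mnar_status":
        rates = params.get(
            "rates", {"current": 0.0, "past": 0.55, "never": 0.55}
        )
        p = statuses.map(rates).fillna(0.0).to_numpy(float)
        mask = rng.random(n) < p
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    masked = statuses.where(~mask)
    return masked, mask


# ---------------------------------------------------------------------------
# convenience: directly build an analysis-ready cohort frame


def make_cohort_frame(
    scenario: SimulationScenario,
    seed: int | None = None,
    mask_smoking: bool = False,
) -> pd.DataFrame:
    """Analysis-ready cohort table with truth smoking, bypassing record
    text and cohort filtering (covariates drawn as in
    :func:`generate_population`).  With ``mask_smoking`` the scenario's
    missingness mechanism is applied to the smoking column."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_patients
    sex = np.where(rng.random(n) < scenario.female_frac, "F", "M")
    age = np.clip(rng.normal(scenario.age_mean, scenario.age_sd, n), 18, 100)
    copd = rng.random(n) < scenario.copd_rate
    diabetes = rng.random(n) < scenario.diabetes_rate
    vendors = rng.choice(
        list(scenario.vendor_mix), p=list(scenario.vendor_mix.values()), size=n
    )
    rural = rng.random(n) < scenario.rural_frac
    rurality = np.where(rural, "rural", "urban").astype(object)
    rurality[rng.random(n) < scenario.postal_missing_rate] = "missing"
    bmi = np.clip(rng.normal(scenario.bmi_mean, scenario.bmi_sd, n), 14, 65).round(1)
    bmi[rng.random(n) < scenario.bmi_missing_rate] = np.nan
    sbp = rng.normal(scenario.sbp_mean, scenario.sbp_sd, n).round(0)
    dbp = rng.normal(scenario.dbp_mean, scenario.dbp_sd, n).round(0)
    bp_missing = rng.random(n) < scenario.bp_missing_rate
    sbp[bp_missing] = np.nan
    dbp[bp_missing] = np.nan
    n_encounters = 1 + rng.negative_binomial(2, 2 / (2 + 30), n)
    smoking = _truth_smoking(scenario, (sex == "M").astype(float), age,
                             copd.astype(float), rng)

    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age.round(0),
            "rurality": rurality,
            "bmi": bmi,
            "sbp": sbp,
            "dbp": dbp,
            "diabetes": diabetes,
            "copd": copd,
            "emr_system": vendors,
            "n_encounters": n_encounters,
            "smoking": smoking,
        }
    )
    if mask_smoking:
        masked, _ = inject_missingness(
            frame["smoking"], scenario.missing_mechanism,
            {"p": scenario.missing_rate}, rng,
            covariates=frame,
        )
        frame["smoking"] = masked
    return frame


def population_tables(pop: dict[str, pd.DataFrame],
                      risk_factors: pd.DataFrame) -> Tables:
    """Bundle generated frames into the IO Tables container."""
    return Tables(
        patients=pop["patients"],
        encounters=pop["encounters"],
        measurements=pop["measurements"],
        conditions=pop["conditions"],
        risk_factors=risk_factors,
        rejects=pd.DataFrame(columns=["table", "row", "reason", "raw"]),
    )
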