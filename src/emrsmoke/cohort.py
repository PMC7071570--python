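"""Cohort derivation and descriptive comparisons.

Builds the analysis table (one row per hypertensive, active patient with
at least ``min_encounters`` visits in the two-year window) with the
descriptive variables: sex, age at window end, rural/urban residence
from the second postal-code character, cleaned most-recent BMI,
most-recent blood pressures, condition flags, EMR vendor, total distinct
encounter dates, and the resolved smoking status with ``unknown`` and
``not_current`` recoded to missing ahead of imputation.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import RunConfig

log = logging.getLogger(__name__)

#: patient-level smoking levels kept for imputation
RECODE_TO_MISSING = ("unknown", "not_current")

COHORT_COLUMNS = [
    "patient_id", "sex", "age", "rurality", "bmi", "sbp", "dbp",
    "diabetes", "copd", "emr_system", "n_encounters", "smoking",
]


def derive_rurality(postal_code: object) -> str:
    """rural iff the second postal-code character is '0'; urban iff it is
    any other digit; missing when absent or malformed."""
    if postal_code is None or (isinstance(postal_code, float) and np.isnan(postal_code)):
        return "missing"
    s = str(postal_code).strip().upper()
    if len(s) < 2 or not s[0].isalpha() or not s[1].isdigit():
        return "missing"
    return "rural" if s[1] == "0" else "urban"


def clean_bmi(
    values: Sequence[float],
    bmi_min: float = 12.0,
    bmi_max: float = 70.0,
    max_jump: float = 10.0,
) -> list[float]:
    """Plausibility-filter a chronologically ordered BMI series.

    Values outside [bmi_min, bmi_max] are dropped; then, scanning
    forward, a value differing by more than ``max_jump`` from the last
    *retained* value is dropped (the earlier retained value is kept, so
    a single outlier cannot cascade-drop valid data).  The output is a
    subsequence of the input."""
    retained: list[float] = []
    for v in values:
        if not bmi_min <= v <= bmi_max:
            continue
        if retained and abs(v - retained[-1]) > max_jump:
            continue
        retained.append(v)
    return retained


def count_encounters(dates: Iterable, window: tuple | None = None) -> int:
    """Count distinct encounter dates (same-day visits count once),
    optionally restricted to a [start, end] window."""
    ds = {d for d in dates if d is not None and not pd.isna(d)}
    if window is not None:
        start, end = window
        ds = {d for d in ds if start <= d <= end}
    return len(ds)


def recode_unknown(smoking: pd.Series) -> pd.Series:
    """Recode unknown / not_current patient statuses to missing (NaN).
    Idempotent."""
    return smoking.where(~smoking.isin(RECODE_TO_MISSING))


def _latest(measure: pd.DataFrame) -> pd.Series:
    """Most recent value per patient for a single-kind measurement frame."""
    if measure.empty:
        return pd.Series(dtype=float)
    m = measure.sort_values("measure_date", kind="stable")
    return m.groupby("patient_id")["value"].last()


def build_cohort(
    tables,
    statuses: pd.DataFrame | pd.Series,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict]:
    """Derive the analysis cohort and report flow counts.

    Filters, in order: hypertension flag; not deceased/inactive; at
    least ``config.min_encounters`` distinct encounter dates within the
    study window.  ``statuses`` maps patient_id to a five-level resolved
    status (DataFrame with columns patient_id/smoking, or a Series
    indexed by patient_id); unknown and not_current are recoded to
    missing, as is any patient with no status at all.
    """
    config.validate()
    patients = tables.patients if hasattr(tables, "patients") else tables["patients"]
    encounters = tables.encounters if hasattr(tables, "encounters") else tables["encounters"]
    measurements = tables.measurements if hasattr(tables, "measurements") else tables["measurements"]
    conditions = tables.conditions if hasattr(tables, "conditions") else tables["conditions"]

    flow = {"input": int(len(patients))}

    htn_ids = set(conditions.loc[conditions["hypertension"].astype(bool), "patient_id"])
    step1 = patients[patients["patient_id"].isin(htn_ids)]
    flow["excluded_no_hypertension"] = flow["input"] - len(step1)

    alive = step1[~step1["deceased"].astype(bool) & ~step1["inactive"].astype(bool)]
    flow["excluded_deceased_or_inactive"] = len(step1) - len(alive)

    window = (config.window_start, config.window_end)
    enc_dates = encounters.groupby("patient_id")["encounter_date"].agg(list)
    window_counts = alive["patient_id"].map(
        lambda pid: count_encounters(enc_dates.get(pid, []), window)
    )
    active = alive[window_counts >= config.min_encounters]
    flow["excluded_too_few_encounters"] = len(alive) - len(active)
    flow["cohort"] = int(len(active))
    if flow["cohort"] == 0:
        log.warning("cohort is empty after filtering")

    # descriptive variables
    total_counts = active["patient_id"].map(
        lambda pid: count_encounters(enc_dates.get(pid, []))
    )
    bmi_frame = measurements[measurements["kind"] == "bmi"].sort_values(
        "measure_date", kind="stable"
    )
    bmi_series = bmi_frame.groupby("patient_id")["value"].agg(list)

    def _clean_latest(pid):
        vals = clean_bmi(
            bmi_series.get(pid, []), config.bmi_min, config.bmi_max,
            config.bmi_max_jump,
        )
        return vals[-1] if vals else np.nan

    sbp = _latest(measurements[measurements["kind"] == "sbp"])
    dbp = _latest(measurements[measurements["kind"] == "dbp"])
    cond = conditions.set_index("patient_id")

    if isinstance(statuses, pd.DataFrame):
        status_map = statuses.set_index("patient_id")["smoking"]
    else:
        status_map = statuses

    pid = active["patient_id"]
    cohort = pd.DataFrame(
        {
            "patient_id": pid.to_numpy(),
            "sex": active["sex"].replace("", np.nan).to_numpy(),
            "age": (config.window_end.year - active["birth_year"]).to_numpy(),
            "rurality": active["postal_code"].map(derive_rurality).to_numpy(),
            "bmi": pid.map(_clean_latest).to_numpy(),
            "sbp": pid.map(sbp).to_numpy(),
            "dbp": pid.map(dbp).to_numpy(),
            "diabetes": pid.map(cond["diabetes"]).astype(bool).to_numpy(),
            "copd": pid.map(cond["copd"]).astype(bool).to_numpy(),
            "emr_system": active["emr_system"].to_numpy(),
            "n_encounters": total_counts.to_numpy(),
            "smoking": pid.map(status_map).to_numpy(),
        }
    )
    cohort["smoking"] = recode_unknown(cohort["smoking"])
    if (cohort["age"] < 0).any():
        raise ValueError("negative age: birth_year after the index date")
    flow["smoking_missing"] = int(cohort["smoking"].isna().sum())
    return cohort.reset_index(drop=True), flow


# ---------------------------------------------------------------------------
# Table-1-style group comparisons


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ({x.std():.1f})"


def _fmt_median_iqr(x: pd.Series) -> str:
    return f"{x.median():.1f} ({x.quantile(0.25):.0f}, {x.quantile(0.75):.0f})"


def summarize_characteristics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Compare patients with and without a recorded smoking status.

    Categorical variables use a chi-squared test, continuous variables a
    Welch two-sample test, and the skewed encounter counts a Wilcoxon
    rank-sum (Mann-Whitney) test.  Degenerate groups (n < 2, zero
    variance, or an empty contingency level) report an NA p-value with a
    reason.  Per-variable missingness is reported alongside.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    recorded = cohort[cohort["smoking"].notna()]
    missing = cohort[cohort["smoking"].isna()]

    spec = [
        ("sex", "categorical"),
        ("age", "continuous"),
        ("bmi", "continuous"),
        ("sbp", "continuous"),
        ("dbp", "continuous"),
        ("diabetes", "categorical"),
        ("copd", "categorical"),
        ("emr_system", "categorical"),
        ("rurality", "categorical"),
        ("n_encounters", "nonparametric"),
    ]
    rows = []
    for var, kind in spec:
        if var not in cohort.columns:
            continue
        a, b = recorded[var], missing[var]
        row = {
            "variable": var,
            "kind": kind,
            "n_recorded": int(a.notna().sum()),
            "n_missing_group": int(b.notna().sum()),
            "missing_in_recorded": int(a.isna().sum()),
            "missing_in_missing": int(b.isna().sum()),
            "p_value": np.nan,
            "test": "",
            "note": "",
        }
        a_v, b_v = a.dropna(), b.dropna()
        if len(a_v) < 2 or len(b_v) < 2:
            row["note"] = "degenerate group (n < 2)"
            rows.append(row)
            continue
        try:
            if kind == "categorical":
                ct = pd.crosstab(
                    cohort["smoking"].notna(), cohort[var].astype(str)
                )
                ct = ct.loc[:, ct.sum(axis=0) > 0]
                if ct.shape[1] < 2 or ct.shape[0] < 2:
                    row["note"] = "single category"
                else:
                    chi2, p, _, _ = stats.chi2_contingency(ct)
                    row["p_value"], row["test"] = p, "chi-squared"
                top = a_v.astype(str).value_counts(normalize=True)
                row["summary_recorded"] = "; ".join(
                    f"{k}: {v:.1%}" for k, v in top.items()
                )
                topb = b_v.astype(str).value_counts(normalize=True)
                row["summary_missing"] = "; ".join(
                    f"{k}: {v:.1%}" for k, v in topb.items()
                )
            elif kind == "continuous":
                if a_v.std() == 0 and b_v.std() == 0:
                    row["note"] = "zero variance"
                else:
                    _, p = stats.ttest_ind(a_v, b_v, equal_var=False)
                    row["p_value"], row["test"] = p, "welch"
                row["summary_recorded"] = _fmt_mean_sd(a_v)
                row["summary_missing"] = _fmt_mean_sd(b_v)
            else:
                _, p = stats.mannwhitneyu(a_v, b_v, alternative="two-sided")
                row["p_value"], row["test"] = p, "wilcoxon-rank-sum"
                row["summary_recorded"] = _fmt_median_iqr(a_v)
                row["summary_missing"] = _fmt_median_iqr(b_v)
        except ValueError as exc:
            row["note"] = f"test failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def smoking_breakdown(smoking: pd.Series) -> dict:
    """Counts and proportions of a patient-level smoking column.

    Proportions over non-missing patients (the convention of the method
    comparison); missing fraction over all patients."""
    n = int(len(smoking))
    n_missing = int(smoking.isna().sum())
    observed = smoking.dropna()
    counts = observed.value_counts().to_dict()
    denom = max(len(observed), 1)
    return {
        "n": n,
        "n_missing": n_missing,
        "missing_fraction": n_missing / n if n else np.nan,
        "counts": {str(k): int(v) for k, v in counts.items()},
        "proportions": {str(k): v / denom for k, v in counts.items()},
    }
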