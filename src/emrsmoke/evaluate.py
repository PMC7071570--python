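"""Validation harness: confusion matrix against a reference standard,
method-comparison table against a population survey benchmark, and the
end-to-end synthetic pipeline run.

The confusion matrix has five predicted rows (the classifier's output
domain) and seven reference columns: the five statuses plus two
review-only categories, ``conflicting`` (contradictory Status/Value
pairs) and ``not_smoking_related`` (records miscategorized as smoking).
The review-only columns have no diagonal partner and count only against
accuracy denominators.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classifier as clf
from . import cohort as coh
from . import imputation as imp
from . import synthesize as syn
from .types import IMPUTABLE_CATEGORIES, RunConfig

PRED_LEVELS = ("current", "never", "not_current", "past", "unknown")
REF_LEVELS = PRED_LEVELS + ("conflicting", "not_smoking_related")


@dataclass
class ConfusionMatrix:
    table: pd.DataFrame  # predicted rows x reference columns
    per_row_accuracy: pd.Series
    overall_accuracy: float  # matched / total
    n: int


def confusion(pred, ref) -> ConfusionMatrix:
    """Cross-tabulate predicted vs reference labels.

    Raises on length mismatch or out-of-domain labels.  Per-row accuracy
    is the diagonal cell over the row total; overall accuracy is the sum
    of diagonal cells over all evaluated records."""
    pred = pd.Series(list(pred), dtype=object)
    ref = pd.Series(list(ref), dtype=object)
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predicted vs {len(ref)} reference")
    bad_p = set(pred.unique()) - set(PRED_LEVELS)
    if bad_p:
        raise ValueError(f"out-of-domain predicted label(s): {sorted(bad_p)}")
    bad_r = set(ref.unique()) - set(REF_LEVELS)
    if bad_r:
        raise ValueError(f"out-of-domain reference label(s): {sorted(bad_r)}")

    table = pd.crosstab(
        pd.Categorical(pred, categories=PRED_LEVELS),
        pd.Categorical(ref, categories=REF_LEVELS),
        dropna=False,
    ).reindex(index=PRED_LEVELS, columns=REF_LEVELS, fill_value=0)
    table.index.name = "predicted"
    table.columns.name = "reference"

    diag = pd.Series(
        {c: int(table.loc[c, c]) for c in PRED_LEVELS}, dtype=float
    )
    row_totals = table.sum(axis=1).astype(float)
    per_row = (diag / row_totals.replace(0, np.nan)).rename("accuracy")
    n = int(table.to_numpy().sum())
    overall = float(diag.sum() / n) if n else np.nan
    return ConfusionMatrix(table, per_row, overall, n)


@dataclass
class SurveyBenchmark:
    """Population-survey smoking prevalence with 95% CIs (percent)."""

    estimates: dict = field(
        default_factory=lambda: {
            "current": (18.9, 14.8, 22.9),
            "past": (21.1, 17.0, 25.1),
            "never": (60.1, 55.2, 65.0),
        }
    )

    def __post_init__(self) -> None:
        for cat, (point, lo, hi) in self.estimates.items():
            if not lo <= point <= hi:
                raise ValueError(f"survey CI for {cat} must satisfy lo <= point <= hi")

    def contains(self, category: str, proportion_pct: float) -> bool:
        _, lo, hi = self.estimates[category]
        return lo <= proportion_pct <= hi


def method_comparison(
    methods: dict[str, dict],
    survey: SurveyBenchmark,
    total_n: int,
) -> pd.DataFrame:
    """Method-comparison table: per-method category counts/proportions
    plus a residual-missing row, with a flag whether each proportion
    falls inside the survey 95% CI.

    ``methods`` maps a method name to ``{"counts": {category: n},
    "missing": n_missing}``; proportions are computed over non-missing
    patients, the residual-missing proportion over ``total_n``."""
    rows = []
    for name, spec in methods.items():
        counts = spec.get("counts", {})
        n_missing = int(spec.get("missing", 0))
        denom = sum(counts.values())
        for cat in ("current", "past", "never", "not_current"):
            if cat not in counts and cat == "not_current":
                continue
            cnt = int(counts.get(cat, 0))
            pct = 100.0 * cnt / denom if denom else np.nan
            rows.append(
                {
                    "method": name,
                    "category": cat,
                    "count": cnt,
                    "proportion_pct": pct,
                    "in_survey_ci": (
                        survey.contains(cat, pct)
                        if cat in survey.estimates and denom
                        else np.nan
                    ),
                }
            )
        rows.append(
            {
                "method": name,
                "category": "missing",
                "count": n_missing,
                "proportion_pct": 100.0 * n_missing / total_n if total_n else np.nan,
                "in_survey_ci": np.nan,
            }
        )
    return pd.DataFrame(rows)


def _pooled_to_counts(pooled: imp.PooledProportions, total_n: int) -> dict:
    counts = {
        c: int(round(pooled.proportions[c] * total_n))
        for c in IMPUTABLE_CATEGORIES
    }
    return {"counts": counts, "missing": 0}


def end_to_end_run(
    scenario: syn.SimulationScenario,
    config: RunConfig,
    survey: SurveyBenchmark | None = None,
) -> dict:
    """The full synthetic pipeline: simulate -> classify -> cohort ->
    impute (both strategies) -> evaluate.  Reproducible from
    (scenario, config) seeds; stage failures propagate with stage names.
    """
    survey = survey or SurveyBenchmark()
    report: dict = {"scenario_seed": scenario.seed, "config_seed": config.seed}

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    pop = _stage("simulate", syn.generate_population, scenario)
    rng = np.random.default_rng(scenario.seed + 1)
    risk_factors, record_truth = _stage(
        "simulate", syn.generate_smoking_records, pop["patients"],
        pop["truth"], scenario, rng
    )

    lexicon = clf.PatternLexicon.default()
    status_table, audit = _stage("classify", clf.classify_corpus,
                                 risk_factors, lexicon)

    # record-level confusion against the generator's reference labels
    merged = audit.merge(record_truth, on=["patient_id", "entry_date"])
    cm = _stage("evaluate", confusion,
                merged["calculated_status"], merged["truth_label"])
    report["confusion"] = cm

    # structured-status route for the imputation arms: each recorded
    # patient's latest record label, interpretable labels only
    latest = record_truth.sort_values("entry_date", kind="stable").groupby(
        "patient_id"
    ).last()
    structured = latest["truth_label"].where(
        latest["truth_label"].isin(IMPUTABLE_CATEGORIES)
    ).rename("smoking")

    tables = syn.population_tables(pop, risk_factors)
    cohort_df, flow = _stage("cohort", coh.build_cohort, tables, structured, config)
    report["flow"] = flow
    report["table1"] = _stage("cohort", coh.summarize_characteristics, cohort_df)

    total_n = len(cohort_df)
    cc = coh.smoking_breakdown(cohort_df["smoking"])
    stack_mar = _stage(
        "impute", imp.run_fcs, cohort_df,
        replace(config, mi_strategy="mar_all").validate(),
    )
    pooled_mar = imp.pool_proportions(stack_mar)
    stack_mnar = _stage(
        "impute", imp.run_fcs, cohort_df,
        replace(config, mi_strategy="mnar_no_current", seed=config.seed + 1).validate(),
    )
    pooled_mnar = imp.pool_proportions(stack_mnar)
    report["pooled"] = {"mar_all": pooled_mar, "mnar_no_current": pooled_mnar}
    for df in stack_mnar.copies:  # MNAR hard constraint, assertable on every run
        imputed_current = (df.loc[stack_mnar.mask["smoking"], "smoking"] == "current")
        assert not imputed_current.any()

    # classifier route restricted to cohort patients
    clf_status = cohort_df[["patient_id"]].merge(
        status_table, on="patient_id", how="left"
    )["smoking"]
    clf_counts = clf_status[clf_status.isin(
        ("current", "past", "never", "not_current")
    )].value_counts().to_dict()
    clf_missing = int(len(clf_status) - sum(clf_counts.values()))

    methods = {
        "complete_cases": {"counts": cc["counts"], "missing": cc["n_missing"]},
        "mar_all": _pooled_to_counts(pooled_mar, total_n),
        "mnar_no_current": _pooled_to_counts(pooled_mnar, total_n),
        "classifier": {"counts": {str(k): int(v) for k, v in clf_counts.items()},
                       "missing": clf_missing},
    }
    report["comparison"] = _stage("evaluate", method_comparison,
                                  methods, survey, total_n)

    complete = cohort_df[cohort_df["smoking"].notna()].reset_index(drop=True)
    report["injection"] = _stage(
        "impute", imp.simulate_missingness_error, complete,
        replace(config, mi_strategy="mar_all", seed=config.seed + 2).validate(),
    )
    report["cohort"] = cohort_df
    report["classifier_accuracy_overall"] = cm.overall_accuracy
    return report
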