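# emrsmoke

Post-extraction data-quality toolkit for **smoking status in primary-care
EMR extracts**. Risk-factor entries in clinic EMRs are free text ("smoker:
quit", "up to 2ppd", "father smokes"), recorded inconsistently across
vendor systems, and missing for a large share of patients — which biases
any downstream surveillance or epidemiology that conditions on smoking.
`emrsmoke` implements three complementary remedies and the synthetic
machinery to validate them against known truth:

1. **Rule-based classification** of free-text records. Each record has
   three fields — Status, Value, Name — evaluated in that precedence
   order against an editable pattern lexicon. The first field resolving
   to exactly one category fixes the calculated status; a field matching
   two or more categories yields `unknown`; kinship terms ("aunt",
   "father") make a field non-informative. Output categories are
   `current`, `past`, `never`, `not_current` (e.g. "non-smoker":
   currently not smoking, history unclear) and `unknown`. The
   per-patient status is the most recently dated record's category.

2. **Multiple imputation under MAR.** Missing statuses are imputed by
   chained equations (fully conditional specification): each missing
   smoking cell is drawn from a multinomial (polytomous) logistic model
   over {current, past, never} given sex, age, rurality, BMI, systolic
   BP, diabetes, encounter count and EMR vendor; incomplete continuous
   auxiliaries use predictive mean matching. With `m` completed copies,
   estimates pool by Rubin's rules: `T = W + (1 + 1/m) B`.

3. **Multiple imputation under an MNAR restriction.** If clinicians
   reliably record the patients who *do* smoke (smoking being a flagged
   cardiovascular risk factor in a hypertensive population), missingness
   depends on the value itself. The restricted strategy fits the model
   on observed non-current patients only and imputes missing cells from
   {past, never}; the post-imputation current-smoker count equals the
   observed count exactly.

A synthetic cohort generator produces EMR extracts with known truth:
study-shaped demographic and clinical marginals, five EMR-vendor labels
with very different recording completeness, per-vendor free-text
dialects, distractor records (kinship text, conflicting Status/Value
pairs, multi-risk-factor strings, non-smoking strings), and configurable
MCAR / covariate-MAR / status-MNAR missingness mechanisms. The
evaluation harness builds reference-standard confusion matrices,
method-comparison tables against a population-survey benchmark, and the
missingness-injection error simulation.

## Worked example

Run the whole pipeline on a 5,000-patient synthetic world:

```python
from emrsmoke import SimulationScenario, RunConfig, end_to_end_run

scenario = SimulationScenario(n_patients=5000, seed=2024)
config = RunConfig(mi_m=10, mi_iterations=3, seed=2024)
report = end_to_end_run(scenario, config)

print(report["flow"])
print(report["comparison"].round(1).to_string(index=False))
```

prints (abridged):

```
{'input': 5000, 'excluded_no_hypertension': 0,
 'excluded_deceased_or_inactive': 243, 'excluded_too_few_encounters': 191,
 'cohort': 4566, 'smoking_missing': 2030}

         method    category  count  proportion_pct in_survey_ci
 complete_cases     current    481            19.0         True
        mar_all     current    880            19.3         True
mnar_no_current     current    481            10.5        False
     classifier     current    491            19.1         True
     classifier     missing   1996            43.7          NaN
```

Reading this: 44.5% of the cohort had no interpretable smoking record.
Both imputation arms return complete data; the MNAR restriction, by
construction, freezes the current-smoker count at the 481 observed
(10.5% of the cohort) and is flagged outside the survey's 95% CI for
current smokers, while the classifier recovers most missing patients
directly from text (record-level accuracy 98.2% on this distractor
rate). The injection simulation (40.8% of complete cases re-masked,
re-imputed, compared) reports per-category errors below one percentage
point at study scale.

The same stages are scriptable from a shell:

```bash
emrsmoke simulate --n 5000 --seed 1 --out extract/
emrsmoke classify --risk-factors extract/risk_factors.csv --out statuses.csv --audit audit.csv
emrsmoke cohort --in extract/ --statuses statuses.csv --out cohort.csv --flow flow.json
emrsmoke impute --cohort cohort.csv --strategy mnar_no_current --m 40 --seed 1 \
                --out stack/ --pooled pooled.json
emrsmoke run-all --n 5000 --seed 1 --out report/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates, from scratch, a 48,377-patient synthetic cohort with
6,061/6,494/16,079 observed current/past/never smokers and 19,743
missing statuses, runs the MNAR-restricted chained-equations imputation,
pools across copies, and writes the resulting current-smoker percentage
(with the problem size) as JSON.

## Layout

- `src/emrsmoke/classifier.py` — lexicon, precedence, guard, conflicts
- `src/emrsmoke/imputation.py` — FCS engine, MAR/MNAR draws, Rubin pooling,
  injection simulation
- `src/emrsmoke/cohort.py` — filters, BMI cleaning, rurality, comparisons
- `src/emrsmoke/synthesize.py` — synthetic worlds with known truth
- `src/emrsmoke/evaluate.py` — confusion matrices, survey comparison,
  end-to-end orchestration
- `src/emrsmoke/data/default_lexicon.yaml` — the editable English lexicon
- `docs/methods.md` — modelling assumptions, defaults and limitations
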