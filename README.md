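# vtecost

Cost-minimization analysis of D-dimer rule-out cut-off strategies for cancer
patients with suspected venous thromboembolism (VTE).

## The problem

Suspected VTE — deep vein thrombosis (DVT) or pulmonary embolism (PE) — is
common in oncology, but only a minority of suspicions are confirmed.
Guideline pathways gate confirmatory imaging (CT pulmonary angiography for
PE, compression ultrasound for DVT) on a D-dimer test: imaging is performed
only when the concentration reaches the rule-out cut-off. Cancer itself
elevates D-dimer, so the conventional 0.5 mg/L cut-off rules almost nobody
out in this population and the choice of cut-off becomes an economic
question as much as a diagnostic one.

`vtecost` implements, as a tested and reusable pipeline, the comparison of
six cut-off strategies on a 526-patient oncology cohort (152 VTE: 83 PE /
69 DVT; 374 without VTE):

| id | strategy | threshold (mg/L FEU) |
|----|----------|----------------------|
| m1 | conventional fixed | 0.5 |
| m2 | age-adjusted | age × 0.01 over age 50, else 0.5 |
| m3 | inverse age-adjusted | max(0.5, 0.5 + (66 − age) × 0.01) |
| m4 | increased fixed | 1.0 |
| m5 | 95%-specificity | data-derived |
| m6 | ROC-optimal (Youden) | data-derived |

A result strictly below the threshold is *negative* (VTE excluded, imaging
skipped); ties are positive. For each strategy the package computes
sensitivity, specificity, predictive values, likelihood ratios
(PLR = sens/(1−spec), NLR = (1−sens)/spec), the nonparametric AUC with
DeLong variance/CI, and — relative to the 0.5 mg/L reference — the number of
imaging examinations avoided, priced under a German medical-fee-schedule EUR
tariff (CUS €18.89, D-dimer €24.13, CTPA €209.83) and a US price set
(CUS $184, D-dimer $14, CTPA $648), extrapolated linearly to an annual
caseload of 5475 suspected-VTE patients.

The patient-level data behind the published analysis are access-controlled,
so the package ships a constraint-calibrated synthetic cohort generator:
age-stratified log-normal D-dimer distributions fitted to the published
medians/IQRs, with the published hard counts (219/374 controls below
0.5 mg/L; 6/152 VTE patients below 1.0 mg/L and none below 0.5) imposed
exactly for every seed. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from vtecost import (
    default_cohort_spec, generate_cohort, standard_rules, resolve_all,
    confusion, metrics_from_confusion, display_metrics,
    count_saved_exams, savings_from_counts, with_annualization,
    default_price_schedules,
)

cohort = generate_cohort(default_cohort_spec(seed=42))
rules = resolve_all(standard_rules(), cohort)

m = metrics_from_confusion(confusion(cohort, rules["m2"], "overall"))
print(display_metrics(m))

saved = count_saved_exams(cohort, rules["m2"], rules["m1"])
report = with_annualization(
    savings_from_counts(saved, default_price_schedules()["EUR"]),
    cohort_n=len(cohort),
)
print(saved.n_ctpa_saved, saved.n_cus_saved,
      report.savings_total_display, report.annualized)
```

prints

```
{'sensitivity_pct': 100, 'specificity_pct': 69, 'ppv_pct': 57, 'npv_pct': 100, 'plr': 3.2, 'nlr': 0.0, 'false_negatives': 0}
23 15 5109.0 53183.0
```

The age-adjusted strategy keeps sensitivity at 100% (zero false negatives,
enforced by the generator's calibration constraints, matching the published
finding) while trading specificity for avoided imaging: on this seed it
skips 23 CTPA and 15 CUS examinations relative to the 0.5 mg/L reference,
worth €5109 in the cohort and €53,183 per year at the assumed caseload.
Feeding the *published* saved-examination counts (43 CTPA / 18 CUS) through
the same pricing functions reproduces the published €9023 + €340 = €9363
and €97,454 per year exactly; the synthetic cohort's counts differ from the
published ones because the control pathway split is not published (see
`docs/methods.md`).

The same pipeline is available from the shell:

```
vtecost simulate --seed 42 --out cohort.csv
vtecost evaluate --cohort cohort.csv --rules m1,m2,m3,m4,m5,m6 --reference m1 --out metrics.csv
vtecost cost --cohort cohort.csv --prices src/vtecost/data/prices_eur.yaml --out savings.csv
vtecost run --config run.yaml
```

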