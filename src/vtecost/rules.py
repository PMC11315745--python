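"""D-dimer rule-out strategies as threshold functions of age.

Six strategies are supported, addressed by id ``m1`` .. ``m6``:

m1  conventional fixed rule-out cut-off, 0.5 mg/L
m2  age-adjusted cut-off: age x 0.01 mg/L for patients over 50, else 0.5
m3  inverse age-adjusted cut-off: 0.5 + (66 - age) x 0.01 mg/L below age 66,
    clamped at the 0.5 mg/L assay convention from age 66 upward
m4  increased fixed cut-off, 1.0 mg/L
m5  data-derived cut-off at 95% specificity
m6  data-derived ROC-optimal (Youden) cut-off

A patient is called *negative* (VTE excluded, imaging skipped) when the
D-dimer concentration is strictly below the threshold; a value exactly equal
to the threshold is *positive* (imaging required).  Data-derived rules (m5,
m6) must be resolved against a cohort before use.

All thresholds are in mg/L fibrinogen-equivalent units; the common
"age x 10 ug/L" phrasing of the age-adjusted rule is the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateDataError, UnresolvedRuleError

RULE_IDS = ("m1", "m2", "m3", "m4", "m5", "m6")

FIXED = "fixed"
AGE_ADJUSTED = "age_adjusted"
INVERSE_AGE_ADJUSTED = "inverse_age_adjusted"
DATA_DERIVED = "data_derived"


@dataclass(frozen=True)
class CutoffRule:
    """A named rule-out threshold strategy.

    ``fixed_value`` holds the threshold for fixed rules and for data-derived
    rules once resolved; it is ``None`` for an unresolved data-derived rule.
    """

    rule_id: str
    name: str
    kind: str
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (FIXED, AGE_ADJUSTED, INVERSE_AGE_ADJUSTED, DATA_DERIVED):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.fixed_value is not None and self.fixed_value <= 0:
            raise ValueError("fixed_value must be positive")

    @property
    def resolved(self) -> bool:
        return self.kind != DATA_DERIVED or self.fixed_value is not None


@dataclass(frozen=True)
class Classification:
    patient_id: str
    rule_id: str
    threshold: float
    call: str  # "negative" (VTE excluded) or "positive" (imaging required)


def standard_rules() -> dict[str, CutoffRule]:
    """The six strategies keyed by rule id; m5/m6 unresolved."""
    return {
        "m1": CutoffRule("m1", "Rule-out cut-off [0.5 mg/L]", FIXED, 0.5),
        "m2": CutoffRule("m2", "Age-adjusted cut-off [age x 0.01 mg/L]", AGE_ADJUSTED),
        "m3": CutoffRule(
            "m3", "Inverse age-adjusted cut-off [0.5 + (66-age) x 0.01 mg/L]",
            INVERSE_AGE_ADJUSTED,
        ),
        "m4": CutoffRule("m4", "Increased fixed cut-off [1 mg/L]", FIXED, 1.0),
        "m5": CutoffRule("m5", "95%-specificity cut-off", DATA_DERIVED),
        "m6": CutoffRule("m6", "ROC-optimal cut-off", DATA_DERIVED),
    }


def threshold(rule: CutoffRule, age: int | float) -> float:
    """Rule-out threshold (mg/L) for a patient of the given age.

    Age-dependent rules never drop below the 0.5 mg/L assay convention:
    the age-adjusted rule applies only over age 50, and the inverse
    age-adjusted formula is clamped at 0.5 from age 66 upward.
    """
    if age < 18:
        raise ValueError(f"age {age} below adult range")
    if rule.kind == FIXED:
        assert rule.fixed_value is not None
        return rule.fixed_value
    if rule.kind == AGE_ADJUSTED:
        return age * 0.01 if age > 50 else 0.5
    if rule.kind == INVERSE_AGE_ADJUSTED:
        return max(0.5, 0.5 + (66 - age) * 0.01)
    # data-derived
    if rule.fixed_value is None:
        raise UnresolvedRuleError(
            f"rule {rule.rule_id} is data-derived and has not been resolved"
        )
    return rule.fixed_value


def classify(patient, rule: CutoffRule) -> Classification:
    """Negative iff d_dimer is strictly below the patient's threshold.

    Ties go positive: a result exactly at the cut-off does not exclude VTE.
    """
    t = threshold(rule, patient.age)
    call = "negative" if patient.d_dimer < t else "positive"
    return Classification(patient.patient_id, rule.rule_id, t, call)


def _split_scores(cohort) -> tuple[np.ndarray, np.ndarray]:
    cases = np.asarray([p.d_dimer for p in cohort if p.status != "none"], dtype=float)
    controls = np.asarray([p.d_dimer for p in cohort if p.status == "none"], dtype=float)
    return cases, controls


def resolve_specificity_cutoff(cohort, target_specificity: float = 0.95) -> float:
    """Smallest observed value whose specificity reaches the target.

    Candidate thresholds are the observed D-dimer values in the cohort
    (empirical-ROC convention).  Returns the smallest candidate ``t`` such
    that the fraction of controls strictly below ``t`` is at least the
    target; under :func:`classify` this threshold then has specificity
    >= target.
    """
    if not 0 < target_specificity <= 1:
        raise ValueError("target_specificity must be in (0, 1]")
    cases, controls = _split_scores(cohort)
    if controls.size == 0:
        raise DegenerateDataError("cohort has no controls")
    controls_sorted = np.sort(controls)
    candidates = np.unique(np.concatenate([cases, controls]))
    n = controls_sorted.size
    for t in candidates:
        frac_below = np.searchsorted(controls_sorted, t, side="left") / n
        if frac_below >= target_specificity:
            return float(t)
    raise DegenerateDataError(
        f"no observed value attains specificity {target_specificity:g}"
    )


def resolve_roc_optimal_cutoff(cohort) -> float:
    """Observed value maximizing Youden's J = sens + spec - 1.

    Ties are broken toward the lower threshold.
    """
    cases, controls = _split_scores(cohort)
    if cases.size == 0 or controls.size == 0:
        raise DegenerateDataError("need at least one case and one control")
    cases_sorted = np.sort(cases)
    controls_sorted = np.sort(controls)
    candidates = np.unique(np.concatenate([cases, controls]))
    best_t, best_j = None, -np.inf
    for t in candidates:
        sens = 1.0 - np.searchsorted(cases_sorted, t, side="left") / cases_sorted.size
        spec = np.searchsorted(controls_sorted, t, side="left") / controls_sorted.size
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    assert best_t is not None
    return best_t


def resolve(rule: CutoffRule, cohort, target_specificity: float = 0.95) -> CutoffRule:
    """Return a copy of a data-derived rule with its threshold fixed on a cohort."""
    if rule.kind != DATA_DERIVED:
        return rule
    if rule.rule_id == "m5":
        value = resolve_specificity_cutoff(cohort, target_specificity)
    else:
        value = resolve_roc_optimal_cutoff(cohort)
    return replace(rule, fixed_value=value)


def resolve_all(
    rules: dict[str, CutoffRule] | Iterable[CutoffRule], cohort
) -> dict[str, CutoffRule]:
    """Resolve every data-derived rule in a rule set against a cohort."""
    items: Sequence[CutoffRule]
    if isinstance(rules, dict):
        items = list(rules.values())
    else:
        items = list(rules)
    return {r.rule_id: resolve(r, cohort) for r in items}
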