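"""Diagnostic performance of rule-out strategies.

Confusion tables and the usual accuracy statistics (sensitivity, specificity,
predictive values, likelihood ratios), the empirical ROC curve, the
nonparametric AUC with DeLong variance and confidence interval, and Spearman
rank correlation.

Conventions
-----------
* positive call = D-dimer >= threshold (ties positive), so as the threshold
  rises sensitivity is non-increasing and specificity non-decreasing;
* AUC is the Mann-Whitney U statistic scaled to [0, 1], with half credit for
  tied case/control pairs — the same statistic whose variance DeLong's
  placement components estimate;
* ratios whose denominator is zero (e.g. PLR of a test with specificity 1)
  are reported as ``None`` rather than infinity;
* all internal arithmetic is unrounded; half-up display rounding to integer
  percent / one-decimal ratios lives in :func:`display_metrics` only.

Subgroup scoping: the published analyses split results by manifestation but
do not say which controls belong to each split, so scoped analyses here pair
PE cases with CTPA-pathway controls and DVT cases with CUS-pathway controls
(the imaging test those controls would have received).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .exceptions import DegenerateDataError
from .rules import CutoffRule, classify

SCOPES = ("overall", "PE", "DVT")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    scope: str = "overall"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    plr: float | None
    nlr: float | None
    n_false_neg: int
    auc: float | None = None
    auc_ci_lo: float | None = None
    auc_ci_hi: float | None = None


def scope_cohort(cohort, scope: str):
    """Cases and controls belonging to an analysis scope.

    ``overall`` keeps everyone; ``PE`` pairs PE cases with CTPA-pathway
    controls; ``DVT`` pairs DVT cases with CUS-pathway controls.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope {scope!r} not in {SCOPES}")
    if scope == "overall":
        cases = [p for p in cohort if p.status != "none"]
        controls = [p for p in cohort if p.status == "none"]
    else:
        pathway = "CTPA" if scope == "PE" else "CUS"
        cases = [p for p in cohort if p.status == scope]
        controls = [p for p in cohort if p.status == "none" and p.pathway == pathway]
    return cases, controls


def confusion(cohort, rule: CutoffRule, scope: str = "overall") -> ConfusionTable:
    """2x2 counts of a rule on a (possibly scoped) cohort."""
    cases, controls = scope_cohort(cohort, scope)
    if not cases or not controls:
        raise DegenerateDataError(
            f"scope {scope!r}: {len(cases)} cases / {len(controls)} controls"
        )
    tp = sum(classify(p, rule).call == "positive" for p in cases)
    fp = sum(classify(p, rule).call == "positive" for p in controls)
    return ConfusionTable(
        tp=tp, fp=fp, tn=len(controls) - fp, fn=len(cases) - tp, scope=scope
    )


def metrics_from_confusion(ct: ConfusionTable) -> DiagnosticMetrics:
    if ct.n_cases == 0 or ct.n_controls == 0:
        raise DegenerateDataError("confusion table lacks cases or controls")
    sens = ct.tp / ct.n_cases
    spec = ct.tn / ct.n_controls
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ct.tp / (ct.tp + ct.fp) if ct.tp + ct.fp else None,
        npv=ct.tn / (ct.tn + ct.fn) if ct.tn + ct.fn else None,
        plr=sens / (1 - spec) if spec < 1 else None,
        nlr=(1 - sens) / spec if spec > 0 else None,
        n_false_neg=ct.fn,
    )


def metrics_from_summary(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> DiagnosticMetrics:
    """Reconstruct full metrics from a printed (sens, spec, group sizes) row.

    Integer counts are rebuilt by half-up rounding (tp = round(sens * n_pos)
    etc.) and drive the predictive values; the likelihood ratios are taken
    from the given proportions directly, matching how such summary rows are
    conventionally tabulated from rounded percentages.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity/specificity must be proportions")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    tp = int(math.floor(sensitivity * n_pos + 0.5))
    tn = int(math.floor(specificity * n_neg + 0.5))
    ct = ConfusionTable(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    counts = metrics_from_confusion(ct)
    return DiagnosticMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=counts.ppv,
        npv=counts.npv,
        plr=sensitivity / (1 - specificity) if specificity < 1 else None,
        nlr=(1 - sensitivity) / specificity if specificity > 0 else None,
        n_false_neg=ct.fn,
    )


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def display_metrics(m: DiagnosticMetrics) -> dict[str, object]:
    """Half-up display rounding: integer percents, one-decimal ratios."""
    pct = lambda v: None if v is None else int(_round_half_up(100 * v))
    r1 = lambda v: None if v is None else _round_half_up(v, 1)
    out: dict[str, object] = {
        "sensitivity_pct": pct(m.sensitivity),
        "specificity_pct": pct(m.specificity),
        "ppv_pct": pct(m.ppv),
        "npv_pct": pct(m.npv),
        "plr": r1(m.plr),
        "nlr": r1(m.nlr),
        "false_negatives": m.n_false_neg,
    }
    if m.auc is not None:
        out["auc"] = _round_half_up(m.auc, 3)
        out["auc_ci"] = (_round_half_up(m.auc_ci_lo, 3), _round_half_up(m.auc_ci_hi, 3))
    return out


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)
# ---------------------------------------------------------------------------

def _case_control_arrays(
    scores: Sequence[float], labels: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray([bool(l) for l in labels])
    if s.shape != lab.shape:
        raise ValueError("scores and labels must have equal length")
    x, y = s[lab], s[~lab]
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("need at least one case and one control")
    return x, y


def empirical_roc(
    scores: Sequence[float], labels: Sequence
) -> list[tuple[float, float, float]]:
    """(threshold, sensitivity, specificity) triples of the empirical ROC.

    One point per distinct observed score (positive = score >= threshold)
    plus the two trivial endpoints at -inf and +inf.
    """
    x, y = _case_control_arrays(scores, labels)
    xs, ys = np.sort(x), np.sort(y)
    points = [(-math.inf, 1.0, 0.0)]
    for t in np.unique(np.concatenate([x, y])):
        sens = 1.0 - np.searchsorted(xs, t, side="left") / xs.size
        spec = np.searchsorted(ys, t, side="left") / ys.size
        points.append((float(t), float(sens), float(spec)))
    points.append((math.inf, 0.0, 1.0))
    return points


def _placements(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # pairwise case-beats-control matrix with half credit for ties
    m = (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
    return m.mean(axis=1), m.mean(axis=0)  # V10 (per case), V01 (per control)


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Nonparametric AUC: P(case score > control score) + 0.5 P(tie)."""
    x, y = _case_control_arrays(scores, labels)
    v10, _ = _placements(x, y)
    return float(v10.mean())


def delong_ci(
    scores: Sequence[float], labels: Sequence, level: float = 0.95
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1].

    Variance is built from the placement (structural) components: the
    per-case and per-control mean pairwise wins, whose sample variances
    scaled by the group sizes estimate var(AUC).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x, y = _case_control_arrays(scores, labels)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("need >= 2 cases and >= 2 controls for a CI")
    v10, v01 = _placements(x, y)
    a = float(v10.mean())
    var = v10.var(ddof=1) / x.size + v01.var(ddof=1) / y.size
    z = float(ndtri(0.5 + level / 2))
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, a - half), min(1.0, a + half))


def delong_se(scores: Sequence[float], labels: Sequence) -> float:
    """DeLong standard error of the AUC."""
    x, y = _case_control_arrays(scores, labels)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("need >= 2 cases and >= 2 controls")
    v10, v01 = _placements(x, y)
    return float(math.sqrt(v10.var(ddof=1) / x.size + v01.var(ddof=1) / y.size))


def auc_with_ci(cohort, scope: str = "overall", level: float = 0.95):
    """AUC of D-dimer for case/control discrimination in a scope, with CI."""
    cases, controls = scope_cohort(cohort, scope)
    scores = [p.d_dimer for p in cases] + [p.d_dimer for p in controls]
    labels = [True] * len(cases) + [False] * len(controls)
    a = auc(scores, labels)
    lo, hi = delong_ci(scores, labels, level)
    return a, lo, hi


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with two-sided t-approximation p."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    res = stats.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)
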