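"""Constraint-calibrated synthetic cohorts of cancer patients with suspected VTE.

The generator emulates a published 526-patient oncology cohort (152 VTE:
83 PE / 69 DVT; 374 without VTE) for which only age-stratified D-dimer
summaries are available: per age group the median with interquartile range,
the number of controls below 0.5 mg/L (219 overall), and the number of VTE
patients below 1.0 mg/L (6 overall; none below 0.5).  Within each age group
D-dimer is modelled as log-normal, with sigma fitted to the IQR and mu
calibrated so that — after the hard sub-threshold quotas are imposed as
exact sampling strata — the group's population median still equals the
published median.

Hard constraints reproduced exactly for every seed:

* group sizes, the 83/69 PE/DVT split, and the 219 / 6 sub-threshold counts;
* every VTE patient's value exceeds 0.5 mg/L and their personal threshold
  under each rule listed in ``enforce_zero_fn_rules`` (default m1/m2/m3),
  so those strategies show zero false negatives by construction;
* the designated sub-1.0 VTE patients fall in (personal threshold, 1.0),
  so the fixed 1.0 mg/L strategy misses exactly those patients.

Values are quantized to 3 decimals (half-up) at generation time so cohorts
round-trip bytewise through CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from . import rules as _rules
from .exceptions import (
    CohortParseError,
    ConfigError,
    ConstraintInfeasibleError,
    InfeasibleTruncationError,
    InvalidSummaryError,
)

Z75 = 0.6744897501960817  # 0.75 quantile of the standard normal

STATUSES = ("PE", "DVT", "none")
PATHWAYS = ("CTPA", "CUS")
PRETESTS = ("low", "moderate", "high")

COHORT_HEADER = ["patient_id", "age", "d_dimer_mg_l", "status", "pathway", "pretest"]

# sampling margin below a quota boundary so that 3-decimal half-up
# quantization can never push a value across it
_EDGE = 6e-4


def _round3(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class PatientRecord:
    """One subject: age, D-dimer (mg/L FEU), adjudicated status, workup pathway."""

    patient_id: str
    age: int
    d_dimer: float
    status: str  # PE | DVT | none
    pathway: str  # CTPA | CUS
    pretest: str  # low | moderate | high (carried, not computed)

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside [18, 100]")
        if self.d_dimer <= 0:
            raise ValueError(f"d_dimer must be positive, got {self.d_dimer}")
        if self.status not in STATUSES:
            raise ValueError(f"status {self.status!r} not in {STATUSES}")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway {self.pathway!r} not in {PATHWAYS}")
        if self.pretest not in PRETESTS:
            raise ValueError(f"pretest {self.pretest!r} not in {PRETESTS}")
        if self.status == "PE" and self.pathway != "CTPA":
            raise ValueError("PE patients are worked up by CTPA")
        if self.status == "DVT" and self.pathway != "CUS":
            raise ValueError("DVT patients are worked up by CUS")


@dataclass(frozen=True)
class AgeGroupSummary:
    """One age stratum: bounds, size, median/IQR and sub-threshold quotas."""

    age_lo: int
    age_hi: int
    n: int
    median: float
    q25: float | None = None
    q75: float | None = None
    n_below_05: int = 0
    n_below_10: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidSummaryError(f"group {self.label}: negative n")
        if self.age_lo > self.age_hi:
            raise InvalidSummaryError(f"group {self.label}: age bounds disordered")
        if self.median <= 0:
            raise InvalidSummaryError(f"group {self.label}: non-positive median")
        if (self.q25 is None) != (self.q75 is None):
            raise InvalidSummaryError(f"group {self.label}: lone quartile")
        if self.q25 is not None and self.q75 is not None:
            if not (0 < self.q25 <= self.median <= self.q75):
                raise InvalidSummaryError(f"group {self.label}: quartiles disordered")
        if not 0 <= self.n_below_05 <= self.n:
            raise InvalidSummaryError(f"group {self.label}: n_below_05 out of range")
        if self.n_below_10 is not None and not (
            self.n_below_05 <= self.n_below_10 <= self.n
        ):
            raise InvalidSummaryError(f"group {self.label}: n_below_10 out of range")

    @property
    def label(self) -> str:
        return f"{self.age_lo}-{self.age_hi}"


@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale location/spread; exp(mu) is the distribution median."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidSummaryError("sigma must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    vte_groups: tuple[AgeGroupSummary, ...]
    control_groups: tuple[AgeGroupSummary, ...]
    n_pe: int = 83
    n_dvt: int = 69
    control_ctpa_fraction: float = 0.5
    seed: int = 0
    enforce_zero_fn_rules: tuple[str, ...] = ("m1", "m2", "m3")

    def __post_init__(self) -> None:
        object.__setattr__(self, "vte_groups", tuple(self.vte_groups))
        object.__setattr__(self, "control_groups", tuple(self.control_groups))
        object.__setattr__(
            self, "enforce_zero_fn_rules", tuple(self.enforce_zero_fn_rules)
        )
        if not 0 <= self.control_ctpa_fraction <= 1:
            raise ConfigError("control_ctpa_fraction must be in [0, 1]")
        n_vte = sum(g.n for g in self.vte_groups)
        if self.n_pe + self.n_dvt != n_vte:
            raise ConfigError(
                f"n_pe + n_dvt = {self.n_pe + self.n_dvt} but VTE groups sum to {n_vte}"
            )
        known = set(_rules.RULE_IDS)
        for rid in self.enforce_zero_fn_rules:
            if rid not in known:
                raise ConfigError(f"unknown rule id {rid!r} in enforce_zero_fn_rules")

    @property
    def n_vte(self) -> int:
        return sum(g.n for g in self.vte_groups)

    @property
    def n_controls(self) -> int:
        return sum(g.n for g in self.control_groups)


def fit_lognormal_from_median_iqr(
    median: float, q25: float, q75: float
) -> LogNormalParams:
    """Log-normal matching a median and (symmetric-quartile) IQR.

    mu = ln(median); sigma = ln(q75/q25) / (2 * z_0.75).  The implied
    quartiles reproduce (q25, q75) exactly when the printed quartiles are
    log-symmetric about the median, and to the symmetric-quartile
    approximation otherwise.
    """
    if q25 <= 0 or not (q25 <= median <= q75) or not q25 < q75:
        raise InvalidSummaryError(
            f"invalid summary median={median}, q25={q25}, q75={q75}"
        )
    return LogNormalParams(math.log(median), math.log(q75 / q25) / (2 * Z75))


def sample_truncated(
    n: int,
    params: LogNormalParams,
    lower: float = 0.0,
    upper: float = math.inf,
    rng: np.random.Generator | None = None,
    mass_floor: float = 1e-6,
) -> np.ndarray:
    """n iid draws from the log-normal restricted to (lower, upper).

    Inverse-CDF sampling on the truncated law; raises
    :class:`InfeasibleTruncationError` if the interval carries less
    probability mass than ``mass_floor``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if lower >= upper:
        raise ValueError("lower must be below upper")
    if rng is None:
        rng = np.random.default_rng()
    a = ndtr((math.log(lower) - params.mu) / params.sigma) if lower > 0 else 0.0
    b = (
        ndtr((math.log(upper) - params.mu) / params.sigma)
        if math.isfinite(upper)
        else 1.0
    )
    if b - a < mass_floor:
        raise InfeasibleTruncationError(
            f"interval ({lower:g}, {upper:g}) has mass {b - a:.2e} "
            f"under lognormal(mu={params.mu:.3f}, sigma={params.sigma:.3f})"
        )
    if n == 0:
        return np.empty(0)
    u = rng.uniform(a, b, size=n)
    return np.exp(params.mu + params.sigma * ndtri(u))


# ---------------------------------------------------------------------------
# mu calibration under quota strata
# ---------------------------------------------------------------------------

def _mixture_cdf(
    x: float, mu: float, sigma: float, w_low: float, boundary: float
) -> float:
    """CDF of the quota-stratified mixture at x.

    Weight ``w_low`` on the parent law truncated to (0, boundary), the rest
    truncated to (boundary, inf).  The VTE low stratum's true lower edge is
    each patient's personal threshold, but since all its mass lies below the
    boundary (and every calibration target is on the other side or at the
    boundary) the stratum shape never enters the equations used here.
    """
    F = lambda v: float(ndtr((math.log(v) - mu) / sigma))
    fb = F(boundary)
    if x < boundary:
        if w_low == 0.0:
            return 0.0
        return w_low * (F(x) / fb if fb > 0 else 1.0)
    if w_low == 1.0:
        return 1.0
    return w_low + (1.0 - w_low) * (F(x) - fb) / (1.0 - fb)


def _calibrate_mu(
    target_median: float, sigma: float, w_low: float, boundary: float
) -> float:
    """Solve for mu so the stratified mixture's median equals the target.

    The mixture CDF at the target is monotone decreasing in mu, so a Brent
    root-find on a bracket around ln(target) suffices.  A target can be
    unattainable when it sits exactly on the quota boundary (e.g. a printed
    median of 0.5 with more than half the group quota'd below 0.5 — the
    rounding of a true median necessarily below 0.5); chasing it would push
    the off-quota stratum to implausible values, so those groups keep the
    plain mu = ln(median) fit.
    """
    mu0 = math.log(target_median)
    lo, hi = mu0 - 4.0, mu0 + 4.0

    def h(mu: float) -> float:
        return _mixture_cdf(target_median, mu, sigma, w_low, boundary) - 0.5

    h0 = h(mu0)
    if abs(h0) < 1e-12:
        return mu0
    h_lo, h_hi = h(lo), h(hi)
    if h_lo >= 0 >= h_hi:
        return float(brentq(h, lo, hi, xtol=1e-10))
    return mu0


def _fallback_sigma(groups: Sequence[AgeGroupSummary]) -> float:
    """Median sigma over the arm's groups with a usable IQR (for n=1 rows)."""
    sigmas = [
        fit_lognormal_from_median_iqr(g.median, g.q25, g.q75).sigma
        for g in groups
        if g.q25 is not None and g.q75 is not None and g.q25 < g.q75
    ]
    if not sigmas:
        raise ConfigError("no group carries a usable IQR to fit sigma")
    return float(np.median(sigmas))


def _group_sigma(g: AgeGroupSummary, fallback: float) -> float:
    if g.q25 is not None and g.q75 is not None and g.q25 < g.q75:
        return fit_lognormal_from_median_iqr(g.median, g.q25, g.q75).sigma
    return fallback


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` across groups proportionally to ``counts``."""
    quotas = counts * total / counts.sum()
    base = np.floor(quotas).astype(int)
    deficit = total - int(base.sum())
    # stable tie-break: larger remainder first, then lower group index
    order = np.lexsort((np.arange(len(counts)), -(quotas - base)))
    base[order[:deficit]] += 1
    return base


_PRETEST_P = {
    "none": (0.50, 0.45, 0.05),
    "PE": (0.05, 0.45, 0.50),
    "DVT": (0.15, 0.50, 0.35),
}


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a cohort satisfying every constraint in the spec, reproducibly.

    Raises :class:`ConstraintInfeasibleError` (naming the group) when a quota
    cannot be met.
    """
    rng = np.random.default_rng(spec.seed)
    rule_set = _rules.standard_rules()
    enforce = [rule_set[rid] for rid in spec.enforce_zero_fn_rules]
    for r in enforce:
        if not r.resolved:
            raise ConfigError(
                f"rule {r.rule_id} is data-derived and cannot back a "
                "zero-false-negative sampling constraint"
            )

    records: list[tuple[int, float, str, str, str]] = []

    # --- VTE arm ---------------------------------------------------------
    vte_sigma_fb = _fallback_sigma(spec.vte_groups)
    group_ns = np.asarray([g.n for g in spec.vte_groups], dtype=float)
    pe_per_group = _largest_remainder(group_ns, spec.n_pe)

    for g, n_pe_g in zip(spec.vte_groups, pe_per_group):
        k = g.n_below_10 or 0
        if k > g.n:
            raise ConstraintInfeasibleError(
                f"VTE group {g.label}: n_below_10={k} exceeds n={g.n}"
            )
        ages = rng.integers(g.age_lo, g.age_hi + 1, size=g.n)
        floors = np.array(
            [
                max(0.5, *(_rules.threshold(r, int(a)) for r in enforce))
                if enforce
                else 0.5
                for a in ages
            ]
        )
        eligible = np.flatnonzero(floors < 1.0 - _EDGE - 0.01)
        if eligible.size < k:
            raise ConstraintInfeasibleError(
                f"VTE group {g.label}: only {eligible.size} patients can sit in "
                f"the sub-1.0 band but {k} are required"
            )
        sub_idx = (
            rng.choice(eligible, size=k, replace=False) if k else np.empty(0, int)
        )
        sub_mask = np.zeros(g.n, dtype=bool)
        sub_mask[sub_idx] = True

        sigma = _group_sigma(g, vte_sigma_fb)
        mu = _calibrate_mu(g.median, sigma, w_low=k / g.n, boundary=1.0)
        params = LogNormalParams(mu, sigma)

        values = np.empty(g.n)
        try:
            for i in sub_idx:
                values[i] = sample_truncated(
                    1, params, lower=floors[i], upper=1.0 - _EDGE, rng=rng
                )[0]
            values[~sub_mask] = sample_truncated(
                int(g.n - k), params, lower=1.0, upper=math.inf, rng=rng
            )
        except InfeasibleTruncationError as exc:
            raise ConstraintInfeasibleError(
                f"VTE group {g.label}: {exc}"
            ) from exc

        pe_idx = rng.choice(g.n, size=int(n_pe_g), replace=False)
        is_pe = np.zeros(g.n, dtype=bool)
        is_pe[pe_idx] = True
        for i in range(g.n):
            status = "PE" if is_pe[i] else "DVT"
            pretest = rng.choice(PRETESTS, p=_PRETEST_P[status])
            records.append(
                (
                    int(ages[i]),
                    _round3(values[i]),
                    status,
                    "CTPA" if status == "PE" else "CUS",
                    str(pretest),
                )
            )

    # --- control arm -----------------------------------------------------
    ctl_sigma_fb = _fallback_sigma(spec.control_groups)
    for g in spec.control_groups:
        k = g.n_below_05
        if k > g.n:
            raise ConstraintInfeasibleError(
                f"control group {g.label}: n_below_05={k} exceeds n={g.n}"
            )
        ages = rng.integers(g.age_lo, g.age_hi + 1, size=g.n)
        sub_idx = rng.choice(g.n, size=k, replace=False) if k else np.empty(0, int)
        sub_mask = np.zeros(g.n, dtype=bool)
        sub_mask[sub_idx] = True

        sigma = _group_sigma(g, ctl_sigma_fb)
        mu = _calibrate_mu(g.median, sigma, w_low=k / g.n if g.n else 0.0, boundary=0.5)
        params = LogNormalParams(mu, sigma)

        values = np.empty(g.n)
        try:
            if k:
                values[sub_mask] = sample_truncated(
                    int(k), params, lower=1e-3, upper=0.5 - _EDGE, rng=rng
                )
            if g.n - k:
                values[~sub_mask] = sample_truncated(
                    int(g.n - k), params, lower=0.5, upper=math.inf, rng=rng
                )
        except InfeasibleTruncationError as exc:
            raise ConstraintInfeasibleError(
                f"control group {g.label}: {exc}"
            ) from exc

        on_ctpa = rng.random(g.n) < spec.control_ctpa_fraction
        for i in range(g.n):
            pretest = rng.choice(PRETESTS, p=_PRETEST_P["none"])
            records.append(
                (
                    int(ages[i]),
                    _round3(values[i]),
                    "none",
                    "CTPA" if on_ctpa[i] else "CUS",
                    str(pretest),
                )
            )

    return [
        PatientRecord(f"P{i:04d}", age, d, status, pathway, pretest)
        for i, (age, d, status, pathway, pretest) in enumerate(records, start=1)
    ]


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """UTF-8 CSV with the fixed header; D-dimer printed at 3 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for p in cohort:
            writer.writerow(
                [p.patient_id, p.age, f"{p.d_dimer:.3f}", p.status, p.pathway, p.pretest]
            )


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Parse a cohort CSV; malformed rows raise with their line number."""
    cohort: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file (missing header)") from None
        if header != COHORT_HEADER:
            raise CohortParseError(
                f"{path}: line 1: expected header {COHORT_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_HEADER):
                raise CohortParseError(
                    f"{path}: line {lineno}: expected {len(COHORT_HEADER)} fields, "
                    f"got {len(row)}"
                )
            try:
                cohort.append(
                    PatientRecord(
                        patient_id=row[0],
                        age=int(row[1]),
                        d_dimer=float(row[2]),
                        status=row[3],
                        pathway=row[4],
                        pretest=row[5],
                    )
                )
            except (ValueError, TypeError) as exc:
                raise CohortParseError(f"{path}: line {lineno}: {exc}") from exc
    return cohort


# ---------------------------------------------------------------------------
# spec files
# ---------------------------------------------------------------------------

def _group_from_mapping(d: dict, *, label: str) -> AgeGroupSummary:
    try:
        return AgeGroupSummary(
            age_lo=int(d["age_lo"]),
            age_hi=int(d["age_hi"]),
            n=int(d["n"]),
            median=float(d["median"]),
            q25=None if d.get("q25") is None else float(d["q25"]),
            q75=None if d.get("q75") is None else float(d["q75"]),
            n_below_05=int(d.get("n_below_05", 0)),
            n_below_10=None if d.get("n_below_10") is None else int(d["n_below_10"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{label}: missing key {exc}") from exc


def load_cohort_spec(path: str | Path, seed: int | None = None) -> CohortSpec:
    """Load a cohort spec from YAML; ``seed`` overrides the file's seed."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        vte = tuple(
            _group_from_mapping(g, label=f"{path}: vte_groups[{i}]")
            for i, g in enumerate(raw["vte_groups"])
        )
        ctl = tuple(
            _group_from_mapping(g, label=f"{path}: control_groups[{i}]")
            for i, g in enumerate(raw["control_groups"])
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing key {exc}") from exc
    return CohortSpec(
        vte_groups=vte,
        control_groups=ctl,
        n_pe=int(raw.get("n_pe", 83)),
        n_dvt=int(raw.get("n_dvt", 69)),
        control_ctpa_fraction=float(raw.get("control_ctpa_fraction", 0.5)),
        seed=int(raw["seed"] if seed is None else seed) if (
            seed is not None or "seed" in raw
        ) else 0,
        enforce_zero_fn_rules=tuple(
            raw.get("enforce_zero_fn_rules", ("m1", "m2", "m3"))
        ),
    )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The shipped spec encoding the published age-stratified summaries."""
    from importlib.resources import files

    path = files("vtecost.data").joinpath("reference_cohort.yaml")
    return load_cohort_spec(str(path), seed=seed)
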