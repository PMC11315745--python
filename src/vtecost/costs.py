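"""Cost-minimization model for D-dimer-gated imaging.

The model assumes every suspected-VTE patient receives a D-dimer test and
that confirmatory imaging (CTPA for the PE pathway, CUS for the DVT pathway)
is performed only when the result exceeds the strategy's cut-off.  Relative
to a reference strategy, a patient's imaging examination is *saved* when the
reference would have imaged them (positive call) but the evaluated strategy
would not (negative call).  Saved examinations are priced per schedule and
extrapolated linearly to an annual caseload.

Because every strategy tests everyone, D-dimer assay costs cancel between
strategies and never enter savings; they enter only the optional baseline
used for percent-reduction figures.

Monetary components and totals are kept unrounded internally; half-up
rounding to whole currency units is applied at display time only, and
annualization always scales the unrounded total (rounding first would change
the annual figure by whole currency units).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .rules import CutoffRule, classify


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (banker's rounding is never used for money)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PriceSchedule:
    """Tariffs per examination in one currency."""

    currency: str
    price_cus: float
    price_ddimer: float
    price_ctpa: float

    def __post_init__(self) -> None:
        if min(self.price_cus, self.price_ddimer, self.price_ctpa) <= 0:
            raise ConfigError("all prices must be positive")


@dataclass(frozen=True)
class AnnualVolume:
    """Assumed annual caseload of suspected VTE (PE + DVT pathways)."""

    total: int = 5475
    pe: int = 1825
    dvt: int = 3650

    def __post_init__(self) -> None:
        if self.pe + self.dvt != self.total:
            raise ConfigError("pe + dvt must equal total annual volume")
        if self.total <= 0:
            raise ConfigError("annual volume must be positive")


@dataclass(frozen=True)
class SavedExams:
    rule_id: str
    n_ctpa_saved: int
    n_cus_saved: int

    def __post_init__(self) -> None:
        if self.n_ctpa_saved < 0 or self.n_cus_saved < 0:
            raise ValueError("saved-exam counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_ctpa_saved + self.n_cus_saved


@dataclass(frozen=True)
class SavingsReport:
    """Priced savings of one strategy vs the reference, one currency."""

    rule_id: str
    currency: str
    n_ctpa_saved: int
    n_cus_saved: int
    savings_ctpa: float  # unrounded
    savings_cus: float  # unrounded
    savings_total: float  # unrounded; == ctpa + cus
    annualized: float | None = None  # display-rounded, whole currency units
    cohort_n: int | None = None
    annual_n: int | None = None

    @property
    def savings_ctpa_display(self) -> float:
        return round_half_up(self.savings_ctpa)

    @property
    def savings_cus_display(self) -> float:
        return round_half_up(self.savings_cus)

    @property
    def savings_total_display(self) -> float:
        return round_half_up(self.savings_total)


def count_saved_exams(
    cohort, rule: CutoffRule, reference_rule: CutoffRule
) -> SavedExams:
    """Imaging examinations the rule avoids relative to the reference.

    A patient contributes iff the reference calls them positive and the
    evaluated rule calls them negative; the tally is split by workup pathway.
    """
    n_ctpa = n_cus = 0
    for p in cohort:
        if (
            classify(p, reference_rule).call == "positive"
            and classify(p, rule).call == "negative"
        ):
            if p.pathway == "CTPA":
                n_ctpa += 1
            else:
                n_cus += 1
    return SavedExams(rule.rule_id, n_ctpa, n_cus)


def savings_from_counts(saved: SavedExams, prices: PriceSchedule) -> SavingsReport:
    """Price the saved examinations; totals kept unrounded."""
    s_ctpa = saved.n_ctpa_saved * prices.price_ctpa
    s_cus = saved.n_cus_saved * prices.price_cus
    return SavingsReport(
        rule_id=saved.rule_id,
        currency=prices.currency,
        n_ctpa_saved=saved.n_ctpa_saved,
        n_cus_saved=saved.n_cus_saved,
        savings_ctpa=s_ctpa,
        savings_cus=s_cus,
        savings_total=s_ctpa + s_cus,
    )


def annualize(
    report: SavingsReport,
    cohort_n: int = 526,
    annual: AnnualVolume = AnnualVolume(),
) -> float:
    """Annual savings: unrounded cohort total scaled by annual_n / cohort_n.

    Returns the display-rounded whole-currency figure; the exact value is
    ``report.savings_total * annual.total / cohort_n``.
    """
    if cohort_n <= 0:
        raise ConfigError("cohort_n must be positive")
    return round_half_up(report.savings_total * annual.total / cohort_n)


def with_annualization(
    report: SavingsReport,
    cohort_n: int = 526,
    annual: AnnualVolume = AnnualVolume(),
) -> SavingsReport:
    """Copy of a savings report with the annualized figure filled in."""
    from dataclasses import replace

    return replace(
        report,
        annualized=annualize(report, cohort_n, annual),
        cohort_n=cohort_n,
        annual_n=annual.total,
    )


def percent_reduction(savings: float, baseline: float) -> float:
    """Savings as a percentage of a baseline expenditure."""
    if baseline <= 0:
        raise ConfigError("baseline must be positive")
    return 100.0 * savings / baseline


def reference_baseline_cost(
    cohort,
    reference_rule: CutoffRule,
    prices: PriceSchedule,
    pathway: str | None = None,
) -> float:
    """Total diagnostic spend under the reference strategy.

    One D-dimer test per patient plus one imaging examination for every
    reference-positive patient, optionally restricted to one workup pathway.
    This is the default denominator for :func:`percent_reduction`; it is a
    modelling choice (echoed in reports), not a published definition.
    """
    patients = [p for p in cohort if pathway is None or p.pathway == pathway]
    if not patients:
        raise ConfigError(f"no patients on pathway {pathway!r}")
    total = len(patients) * prices.price_ddimer
    for p in patients:
        if classify(p, reference_rule).call == "positive":
            total += prices.price_ctpa if p.pathway == "CTPA" else prices.price_cus
    return total


def load_price_schedule(path: str | Path) -> PriceSchedule:
    """Read a {currency, price_cus, price_ddimer, price_ctpa} YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    try:
        return PriceSchedule(
            currency=str(raw["currency"]),
            price_cus=float(raw["price_cus"]),
            price_ddimer=float(raw["price_ddimer"]),
            price_ctpa=float(raw["price_ctpa"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing key {exc}") from exc


def default_price_schedules() -> dict[str, PriceSchedule]:
    """The shipped EUR (German medical fee schedule) and USD schedules."""
    from importlib.resources import files

    data = files("vtecost.data")
    return {
        sched.currency: sched
        for sched in (
            load_price_schedule(str(data.joinpath("prices_eur.yaml"))),
            load_price_schedule(str(data.joinpath("prices_usd.yaml"))),
        )
    }
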