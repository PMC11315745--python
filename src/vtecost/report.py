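"""End-to-end pipeline: simulate -> classify -> evaluate -> cost -> report.

:func:`run` executes all stages from a :class:`RunConfig` and writes a
reproducible set of outputs (cohort CSV when synthetic, tidy metrics CSV +
JSON, savings CSV + JSON, a human-readable summary).  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    load_cohort_spec,
    read_cohort_csv,
    write_cohort_csv,
)
from .costs import (
    AnnualVolume,
    count_saved_exams,
    default_price_schedules,
    load_price_schedule,
    round_half_up,
    savings_from_counts,
    with_annualization,
)
from .diagnostics import (
    SCOPES,
    auc_with_ci,
    confusion,
    display_metrics,
    metrics_from_confusion,
    scope_cohort,
)
from .exceptions import ConfigError
from .rules import RULE_IDS, resolve_all, standard_rules, threshold

log = logging.getLogger("vtecost")

DEFAULT_RULES = ("m1", "m2", "m3", "m4", "m5", "m6")
DEFAULT_COST_RULES = ("m2", "m3", "m4", "m5")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_spec_path`` / ``cohort_csv_path`` selects the
    cohort source; with neither set the shipped reference spec is used.
    ``include_m6_in_costs`` defaults to False: the ROC-optimal cut-off is
    excluded from cost runs because its false-negative load makes it unsafe
    as a rule-out strategy.
    """

    cohort_spec_path: str | None = None
    cohort_csv_path: str | None = None
    rules: tuple[str, ...] = DEFAULT_RULES
    reference: str = "m1"
    price_schedule_paths: tuple[str, ...] = ()
    annual_total: int = 5475
    annual_pe: int = 1825
    annual_dvt: int = 3650
    cohort_n: int | None = None  # None -> size of the evaluated cohort
    out_dir: str = "vtecost_out"
    seed: int = 0
    include_m6_in_costs: bool = False
    target_specificity: float = 0.95

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(
            self, "price_schedule_paths", tuple(self.price_schedule_paths)
        )
        if self.cohort_spec_path and self.cohort_csv_path:
            raise ConfigError("give a cohort spec or a cohort CSV, not both")
        for rid in self.rules:
            if rid not in RULE_IDS:
                raise ConfigError(f"unknown rule id {rid!r}")
        if self.reference not in self.rules:
            raise ConfigError(f"reference rule {self.reference!r} not in rule set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        for key in ("rules", "price_schedule_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            default=str,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All computed outputs of one run plus provenance."""

    thresholds: dict[str, object]
    metrics: pd.DataFrame  # long: rule_id, scope, metric, value
    savings: pd.DataFrame  # one row per (rule, currency)
    provenance: dict[str, object]
    cohort_size: int = 0


def _metric_rows(rule_id: str, scope: str, metrics, shown: dict) -> list[dict]:
    rows = []
    raw = {
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "ppv": metrics.ppv,
        "npv": metrics.npv,
        "plr": metrics.plr,
        "nlr": metrics.nlr,
        "false_negatives": metrics.n_false_neg,
    }
    raw.update({k: shown[k] for k in ("auc", "auc_ci_lo", "auc_ci_hi") if k in shown})
    for metric, value in raw.items():
        rows.append(
            {"rule_id": rule_id, "scope": scope, "metric": metric, "value": value}
        )
    return rows


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write its outputs to config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort ----------------------------------------------------------
    if config.cohort_csv_path:
        cohort = read_cohort_csv(config.cohort_csv_path)
        cohort_source = f"csv:{config.cohort_csv_path}"
        log.info("stage=cohort source=csv n=%d", len(cohort))
    else:
        spec = (
            load_cohort_spec(config.cohort_spec_path, seed=config.seed)
            if config.cohort_spec_path
            else default_cohort_spec(seed=config.seed)
        )
        cohort = generate_cohort(spec)
        write_cohort_csv(cohort, out / "cohort.csv")
        cohort_source = f"synthetic:seed={config.seed}"
        log.info("stage=cohort source=synthetic seed=%d n=%d", config.seed, len(cohort))

    # --- rules -----------------------------------------------------------
    rule_set = {rid: standard_rules()[rid] for rid in config.rules}
    rule_set = resolve_all(rule_set, cohort)
    thresholds: dict[str, object] = {}
    for rid, rule in rule_set.items():
        if rule.fixed_value is not None:
            thresholds[rid] = rule.fixed_value
        else:
            thresholds[rid] = rule.kind  # age-dependent formula
    log.info("stage=rules resolved=%s", thresholds)

    # --- diagnostics -----------------------------------------------------
    rows: list[dict] = []
    for scope in SCOPES:
        cases, controls = scope_cohort(cohort, scope)
        if not cases or not controls:
            log.warning("stage=metrics scope=%s empty, skipped", scope)
            continue
        a, lo, hi = auc_with_ci(cohort, scope)
        for rid, rule in rule_set.items():
            m = metrics_from_confusion(confusion(cohort, rule, scope))
            rows.extend(
                _metric_rows(rid, scope, m, {"auc": a, "auc_ci_lo": lo, "auc_ci_hi": hi})
            )
    metrics_df = pd.DataFrame(rows, columns=["rule_id", "scope", "metric", "value"])
    log.info("stage=metrics rows=%d", len(metrics_df))

    # --- costs -----------------------------------------------------------
    if config.price_schedule_paths:
        schedules = [load_price_schedule(p) for p in config.price_schedule_paths]
    else:
        schedules = list(default_price_schedules().values())
    annual = AnnualVolume(config.annual_total, config.annual_pe, config.annual_dvt)
    cohort_n = config.cohort_n or len(cohort)
    reference = rule_set[config.reference]
    cost_rules = [
        rid
        for rid in config.rules
        if rid != config.reference and (rid != "m6" or config.include_m6_in_costs)
    ]
    s_rows = []
    for rid in cost_rules:
        saved = count_saved_exams(cohort, rule_set[rid], reference)
        for sched in schedules:
            rep = with_annualization(
                savings_from_counts(saved, sched), cohort_n=cohort_n, annual=annual
            )
            s_rows.append(
                {
                    "rule_id": rid,
                    "currency": rep.currency,
                    "n_ctpa_saved": rep.n_ctpa_saved,
                    "n_cus_saved": rep.n_cus_saved,
                    "savings_ctpa": rep.savings_ctpa_display,
                    "savings_cus": rep.savings_cus_display,
                    "savings_total": rep.savings_total_display,
                    "savings_total_unrounded": rep.savings_total,
                    "annualized": rep.annualized,
                }
            )
            if rep.savings_ctpa_display + rep.savings_cus_display != round_half_up(
                rep.savings_total
            ):
                log.warning(
                    "stage=costs rule=%s %s: rounded components (%d + %d) differ "
                    "from rounded total %d; totals are rounded once, not summed "
                    "from rounded parts",
                    rid,
                    rep.currency,
                    rep.savings_ctpa_display,
                    rep.savings_cus_display,
                    rep.savings_total_display,
                )
    savings_df = pd.DataFrame(
        s_rows,
        columns=[
            "rule_id",
            "currency",
            "n_ctpa_saved",
            "n_cus_saved",
            "savings_ctpa",
            "savings_cus",
            "savings_total",
            "savings_total_unrounded",
            "annualized",
        ],
    )
    log.info("stage=costs rules=%s currencies=%d", cost_rules, len(schedules))

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort_source": cohort_source,
        "cohort_n": len(cohort),
        "reference": config.reference,
        "resolved_thresholds": thresholds,
    }

    # --- outputs ---------------------------------------------------------
    metrics_df.to_csv(out / "metrics.csv", index=False)
    savings_df.to_csv(out / "savings.csv", index=False)
    (out / "metrics.json").write_text(
        json.dumps(
            {
                "provenance": provenance,
                "metrics": metrics_df.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )
    )
    (out / "savings.json").write_text(
        json.dumps(
            {
                "provenance": provenance,
                "savings": savings_df.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )
    )
    (out / "summary.txt").write_text(_summary_text(thresholds, metrics_df, savings_df))

    return RunReport(
        thresholds=thresholds,
        metrics=metrics_df,
        savings=savings_df,
        provenance=provenance,
        cohort_size=len(cohort),
    )


def _summary_text(
    thresholds: dict, metrics_df: pd.DataFrame, savings_df: pd.DataFrame
) -> str:
    lines = ["Resolved thresholds (mg/L or age formula):"]
    for rid, t in thresholds.items():
        lines.append(f"  {rid}: {t}")
    lines.append("")
    lines.append("Overall diagnostic performance:")
    overall = metrics_df[metrics_df.scope == "overall"]
    for rid in overall.rule_id.unique():
        sub = overall[overall.rule_id == rid].set_index("metric")["value"]
        sens = sub.get("sensitivity")
        spec = sub.get("specificity")
        fn = sub.get("false_negatives")
        lines.append(
            f"  {rid}: sens={100 * sens:.0f}% spec={100 * spec:.0f}% "
            f"false_negatives={fn:.0f}"
        )
    if len(savings_df):
        lines.append("")
        lines.append("Savings vs reference (display-rounded):")
        for _, r in savings_df.iterrows():
            lines.append(
                f"  {r.rule_id} [{r.currency}]: total {r.savings_total:.0f} "
                f"(CTPA {r.savings_ctpa:.0f} / CUS {r.savings_cus:.0f}), "
                f"annualized {r.annualized:.0f}"
            )
    return "\n".join(lines) + "\n"


def compare_table(reports: list[RunReport]) -> pd.DataFrame:
    """Long-format (run, rule, scope, metric, value) table across runs."""
    if not reports:
        raise ConfigError("need at least one report")
    frames = []
    for i, rep in enumerate(reports):
        df = rep.metrics.copy()
        df.insert(0, "run", i)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"rule_id": "rule"})[
        ["run", "rule", "scope", "metric", "value"]
    ]
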