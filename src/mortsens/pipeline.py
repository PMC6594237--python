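"""Analytic use cases: descriptive mOS, comparative effectiveness, external control.

Each analysis chooses, per arm, which mortality source supplies the death
dates:

* ``gold`` source: events are the patients with a gold-standard death
  (cells A and C), at their gold dates;
* ``ehr`` source: events are the patients with an EHR death (cells A and B),
  at their EHR dates;

everyone else is censored at their last structured-activity date.  The three
use cases differ only in the source map:

* *descriptive* -- one source for all arms; per-arm Kaplan-Meier median OS;
* *comparative effectiveness (CER)* -- both arms share a source; Cox hazard
  ratio under the EHR source compared with the gold benchmark;
* *external control* -- the experimental arm keeps gold dates (emulating a
  single-arm trial with near-perfect mortality data) while the control arm
  uses EHR dates (an external control from routine data); the benchmark is
  the gold/gold hazard ratio.

Bias is reported as estimate minus benchmark and as percent of benchmark.
``run_full_study`` repeats every use case on sensitivity-degraded data,
summarising each statistic over the degradation iterations by its median and
2.5/97.5 percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import PatientRecord, arms as cohort_arms, tabulate_cells
from .degrade import DegradationConfig, SimulationSummary, run_degradation_study
from .survival import EstimateWithCI, EstimationError, SurvivalRecord, cox_hr, km_median

logger = logging.getLogger(__name__)

USE_CASES = ("descriptive", "cer", "external_control")
MIN_TIME_DAYS = 0.5  # deaths on the index day keep a half-day on study


class PipelineError(ValueError):
    """Invalid analysis specification."""


@dataclass(frozen=True)
class AnalysisSpec:
    """Which mortality source feeds each arm for one analysis."""

    use_case: str
    death_source_by_arm: dict

    def __post_init__(self) -> None:
        if self.use_case not in USE_CASES:
            raise PipelineError(f"unknown use case {self.use_case!r}")
        bad = {s for s in self.death_source_by_arm.values() if s not in ("gold", "ehr")}
        if bad:
            raise PipelineError(f"unknown death source(s) {sorted(bad)}")
        if self.use_case in ("descriptive", "cer"):
            if len(set(self.death_source_by_arm.values())) > 1:
                raise PipelineError(
                    f"{self.use_case} analyses use one source for all arms"
                )


@dataclass(frozen=True)
class BiasReport:
    """Estimate vs benchmark with absolute and percent bias."""

    estimate: EstimateWithCI
    benchmark: EstimateWithCI
    absolute_bias: float
    percent_bias: float

    @classmethod
    def compare(cls, estimate: EstimateWithCI, benchmark: EstimateWithCI) -> "BiasReport":
        return cls(
            estimate=estimate,
            benchmark=benchmark,
            absolute_bias=estimate.value - benchmark.value,
            percent_bias=percent_bias(estimate.value, benchmark.value),
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate.to_dict(),
            "benchmark": self.benchmark.to_dict(),
            "absolute_bias": self.absolute_bias,
            "percent_bias": self.percent_bias,
        }


def percent_bias(estimate: float, benchmark: float) -> float:
    """100 * (estimate - benchmark) / benchmark, rounded to one decimal."""
    if benchmark <= 0:
        raise PipelineError("percent bias needs a positive benchmark")
    return round(100.0 * (estimate - benchmark) / benchmark, 1)


def build_survival_dataset(
    cohort: Sequence[PatientRecord], spec: AnalysisSpec
) -> list[SurvivalRecord]:
    """One survival row per patient under the spec's death-source map.

    A patient whose assigned source holds a death date contributes
    ``(death - index, event=True)``; everyone else contributes
    ``(last_activity - index, event=False)``.  Zero-length times are shifted
    to half a day so no event is dropped.
    """
    rows: list[SurvivalRecord] = []
    for p in cohort:
        try:
            source = spec.death_source_by_arm[p.arm]
        except KeyError:
            raise PipelineError(
                f"arm {p.arm!r} missing from death_source_by_arm"
            ) from None
        death = p.gold_death_date if source == "gold" else p.ehr_death_date
        if death is not None:
            time, event = death - p.index_date, True
        else:
            time, event = p.last_activity_date - p.index_date, False
        rows.append(SurvivalRecord(time=max(time, MIN_TIME_DAYS), event=event, arm=p.arm))
    return rows


def _uniform_spec(cohort: Sequence[PatientRecord], use_case: str, source: str) -> AnalysisSpec:
    return AnalysisSpec(use_case, {arm: source for arm in cohort_arms(cohort)})


def _two_arms(
    cohort: Sequence[PatientRecord], experimental_arm: str, control_arm: str
) -> None:
    present = set(cohort_arms(cohort))
    if {experimental_arm, control_arm} - present:
        raise PipelineError(
            f"cohort arms {sorted(present)} do not include "
            f"{experimental_arm!r} and {control_arm!r}"
        )


def run_descriptive(
    cohort: Sequence[PatientRecord], source: str
) -> dict[str, EstimateWithCI]:
    """Per-arm Kaplan-Meier median OS (months) under one death source."""
    spec = _uniform_spec(cohort, "descriptive", source)
    rows = build_survival_dataset(cohort, spec)
    out: dict[str, EstimateWithCI] = {}
    for arm in cohort_arms(cohort):
        out[arm] = km_median([r for r in rows if r.arm == arm])
    return out


def run_cer(
    cohort: Sequence[PatientRecord],
    experimental_arm: str = "experimental",
    control_arm: str = "control",
) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Hazard ratios (experimental vs control) under gold and EHR sources.

    Returns ``(hr_gold, hr_ehr)`` computed on the same cohort differing only
    in death source.
    """
    _two_arms(cohort, experimental_arm, control_arm)
    hr_gold = cox_hr(
        build_survival_dataset(cohort, _uniform_spec(cohort, "cer", "gold")),
        reference_arm=control_arm,
    )
    hr_ehr = cox_hr(
        build_survival_dataset(cohort, _uniform_spec(cohort, "cer", "ehr")),
        reference_arm=control_arm,
    )
    return hr_gold, hr_ehr


def run_external_control(
    cohort: Sequence[PatientRecord],
    experimental_arm: str = "experimental",
    control_arm: str = "control",
) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Benchmark (gold/gold) HR and external-control (gold/EHR) HR.

    The external-control analysis keeps gold dates for the experimental arm
    and EHR dates for the control arm.
    """
    _two_arms(cohort, experimental_arm, control_arm)
    benchmark = cox_hr(
        build_survival_dataset(
            cohort, _uniform_spec(cohort, "external_control", "gold")
        ),
        reference_arm=control_arm,
    )
    ec_spec = AnalysisSpec(
        "external_control", {experimental_arm: "gold", control_arm: "ehr"}
    )
    external = cox_hr(build_survival_dataset(cohort, ec_spec), reference_arm=control_arm)
    return benchmark, external


# ---------------------------------------------------------------------------
# Full study


def run_full_study(
    cohort: Sequence[PatientRecord],
    degradation_fractions: Sequence[float] = (0.2, 0.3),
    n_iterations: int = 1000,
    seed: int = 0,
    experimental_arm: str = "experimental",
    control_arm: str = "control",
) -> dict:
    """Classification, observed-EHR analyses and degraded re-analyses.

    For each use case the report holds the gold-standard benchmark, the
    observed-EHR estimate with its bias, and -- for each degradation
    fraction -- the median/percentile summary over ``n_iterations``
    independent reclassification draws with its bias.  External-control
    degradations reclassify control-arm patients only.  Partial results are
    preserved under an ``"errors"`` key if a stage fails.
    """
    _two_arms(cohort, experimental_arm, control_arm)
    counts = tabulate_cells(cohort)
    logger.info(
        "full study: n=%d cells=(%d,%d,%d,%d) fractions=%s iterations=%d seed=%d",
        counts.total, counts.a, counts.b, counts.c, counts.d,
        list(degradation_fractions), n_iterations, seed,
    )
    report: dict = {
        "cell_counts": counts.to_dict(),
        "seed": seed,
        "n_iterations": n_iterations,
        "use_cases": {},
        "errors": {},
    }

    stages: list[tuple[str, Callable[[], dict]]] = [
        (
            "descriptive",
            lambda: _descriptive_block(
                cohort, degradation_fractions, n_iterations, seed
            ),
        ),
        (
            "cer",
            lambda: _hr_block(
                cohort, degradation_fractions, n_iterations, seed,
                experimental_arm, control_arm, external_control=False,
            ),
        ),
        (
            "external_control",
            lambda: _hr_block(
                cohort, degradation_fractions, n_iterations, seed,
                experimental_arm, control_arm, external_control=True,
            ),
        ),
    ]
    for name, stage in stages:
        try:
            report["use_cases"][name] = stage()
        except (PipelineError, EstimationError) as exc:
            logger.warning("stage %s failed: %s", name, exc)
            report["errors"][name] = str(exc)
    if not report["errors"]:
        del report["errors"]
    return report


def _stage_seed(seed: int, *streams: int) -> int:
    """Independent, replayable sub-seed for one (stage, arm, fraction) cell."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(streams))
    return int(ss.generate_state(1)[0] % (2**31))


def _summary_dict(summary: SimulationSummary, benchmark: EstimateWithCI) -> dict:
    d = summary.to_dict()
    d.pop("per_iteration_values")
    d["absolute_bias"] = summary.point_estimate - benchmark.value
    d["percent_bias"] = percent_bias(summary.point_estimate, benchmark.value)
    return d


def _descriptive_block(
    cohort: Sequence[PatientRecord],
    fractions: Sequence[float],
    n_iterations: int,
    seed: int,
) -> dict:
    benchmark = run_descriptive(cohort, "gold")
    observed = run_descriptive(cohort, "ehr")
    block: dict = {
        "benchmark": {arm: est.to_dict() for arm, est in benchmark.items()},
        "ehr": {
            arm: BiasReport.compare(observed[arm], benchmark[arm]).to_dict()
            for arm in benchmark
        },
        "simulations": {},
    }
    arm_list = list(benchmark)
    for fi, p in enumerate(fractions):
        per_arm: dict = {}
        for ai, arm in enumerate(arm_list):
            def stat(degraded: list[PatientRecord], arm=arm) -> float:
                return run_descriptive(degraded, "ehr")[arm].value

            cfg = DegradationConfig(
                fraction_p=p, n_iterations=n_iterations,
                seed=_stage_seed(seed, 0, fi, ai),
            )
            summary = run_degradation_study(cohort, cfg, stat)
            per_arm[arm] = _summary_dict(summary, benchmark[arm])
        block["simulations"][_fraction_key(p)] = per_arm
    return block


def _hr_block(
    cohort: Sequence[PatientRecord],
    fractions: Sequence[float],
    n_iterations: int,
    seed: int,
    experimental_arm: str,
    control_arm: str,
    external_control: bool,
) -> dict:
    if external_control:
        benchmark, observed = run_external_control(cohort, experimental_arm, control_arm)
        degrade_arms: Optional[set[str]] = {control_arm}
        stream = 2
    else:
        benchmark, observed = run_cer(cohort, experimental_arm, control_arm)
        degrade_arms = None
        stream = 1

    def stat(degraded: list[PatientRecord]) -> float:
        if external_control:
            return run_external_control(degraded, experimental_arm, control_arm)[1].value
        return run_cer(degraded, experimental_arm, control_arm)[1].value

    block: dict = {
        "benchmark": benchmark.to_dict(),
        "ehr": BiasReport.compare(observed, benchmark).to_dict(),
        "simulations": {},
    }
    for fi, p in enumerate(fractions):
        cfg = DegradationConfig(
            fraction_p=p, n_iterations=n_iterations, seed=_stage_seed(seed, stream, fi)
        )
        summary = run_degradation_study(cohort, cfg, stat, arms=degrade_arms)
        block["simulations"][_fraction_key(p)] = _summary_dict(summary, benchmark)
    return block


def _fraction_key(p: float) -> str:
    return f"p={p:g}"


# ---------------------------------------------------------------------------
# Human-readable report


def _fmt(value, digits: int) -> str:
    if value is None:
        return "NA"
    return f"{value:.{digits}f}"


def _est_cell(d: dict, digits: int) -> str:
    return f"{_fmt(d['value'], digits)} ({_fmt(d['ci_lower'], digits)}-{_fmt(d['ci_upper'], digits)})"


def _sim_cell(d: dict, digits: int) -> str:
    return (
        f"{_fmt(d['point_estimate'], digits)} "
        f"({_fmt(d['ci_lower'], digits)}-{_fmt(d['ci_upper'], digits)})"
    )


def format_report_table(report: dict) -> str:
    """Render a full-study report as aligned text tables.

    Median OS rows are per arm in months (one decimal); hazard-ratio rows
    carry two decimals; every non-benchmark column is followed by its
    percent bias against the gold-standard benchmark.
    """
    lines: list[str] = []
    cells = report["cell_counts"]
    lines.append(
        "Cells A/B/C/D: {a}/{b}/{c}/{d}  sensitivity {s}  specificity {sp}".format(
            a=cells["a"], b=cells["b"], c=cells["c"], d=cells["d"],
            s=_fmt(100 * cells["sensitivity"], 1) + "%" if cells["sensitivity"] is not None else "NA",
            sp=_fmt(100 * cells["specificity"], 1) + "%" if cells["specificity"] is not None else "NA",
        )
    )
    use_cases = report.get("use_cases", {})
    if "descriptive" in use_cases:
        blk = use_cases["descriptive"]
        lines.append("")
        lines.append("Median overall survival (months)")
        header = ["Arm"]
        sims = sorted(blk["simulations"])
        for key in sims:
            header += [f"Simulated {key}", "Bias, %"]
        header += ["EHR-derived", "Bias, %", "Gold standard"]
        rows = [header]
        for arm in blk["benchmark"]:
            row = [arm]
            for key in sims:
                sim = blk["simulations"][key][arm]
                row += [_sim_cell(sim, 1), _fmt(sim["percent_bias"], 1)]
            ehr = blk["ehr"][arm]
            row += [
                _est_cell(ehr["estimate"], 1),
                _fmt(ehr["percent_bias"], 1),
                _est_cell(blk["benchmark"][arm], 1),
            ]
            rows.append(row)
        lines += _align(rows)
    for name, title in (("cer", "Comparative effectiveness (HR)"),
                        ("external_control", "External control arm (HR)")):
        if name not in use_cases:
            continue
        blk = use_cases[name]
        lines.append("")
        lines.append(title)
        header = ["Analysis", "HR (95% CI)", "Bias, %"]
        rows = [header, ["benchmark (gold)", _est_cell(blk["benchmark"], 2), "-"]]
        ehr = blk["ehr"]
        rows.append(["ehr", _est_cell(ehr["estimate"], 2), _fmt(ehr["percent_bias"], 1)])
        for key in sorted(blk["simulations"]):
            sim = blk["simulations"][key]
            rows.append([f"simulated {key}", _sim_cell(sim, 2), _fmt(sim["percent_bias"], 1)])
        lines += _align(rows)
    return "\n".join(lines) + "\n"


def _align(rows: list[list[str]]) -> list[str]:
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
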