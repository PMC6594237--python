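"""Sensitivity degradation: bootstrap reclassification of captured deaths.

To emulate a mortality source with lower capture sensitivity, a fraction
``p`` of the true positives (cell A) is reclassified as false negatives
(cell C): their EHR death date is removed and, because their last-activity
date no longer reflects an unrecorded death, they are re-censored at a date
drawn uniformly between the index date and the gold-standard death date.

Starting sensitivity ``a/(a+c)`` becomes ``(1-p) a / (a+c)`` in expectation;
e.g. 90.6% drops to 63.4% at p = 0.30 and to 72.5% at p = 0.20.

Across iterations the reclassified subset (and every censor date) is redrawn
independently from a master seed; the distribution of a statistic over the
iterations yields a median point estimate with a 2.5/97.5-percentile
interval.  Within one iteration the subset is a simple random sample without
replacement -- a patient cannot be reclassified twice.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import ConfusionCounts, CohortError, MortalityCell, PatientRecord, classify_patient


logger = logging.getLogger(__name__)


class DegradationError(ValueError):
    """Invalid degradation parameters or a statistic failure mid-study."""


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of one degradation study.

    fraction_p : share of cell A reclassified to cell C per iteration.
    n_iterations : number of independent reclassification draws.
    seed : master seed; each iteration runs on its own spawned substream.
    censor_rule : only ``"uniform"`` (uniform between index and gold death)
        is defined.
    """

    fraction_p: float
    n_iterations: int = 1000
    seed: int = 0
    censor_rule: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_p <= 1.0):
            raise DegradationError("fraction_p must be in [0, 1]")
        if self.n_iterations < 1:
            raise DegradationError("n_iterations must be >= 1")
        if self.censor_rule != "uniform":
            raise DegradationError(f"unknown censor_rule {self.censor_rule!r}")


@dataclass(frozen=True)
class SimulationSummary:
    """Per-iteration statistic values with percentile summary."""

    per_iteration_values: tuple[float, ...]
    point_estimate: float
    ci_lower: float
    ci_upper: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SimulationSummary":
        arr = np.asarray(values, dtype=float)
        return cls(
            per_iteration_values=tuple(arr.tolist()),
            point_estimate=float(np.median(arr)),
            ci_lower=float(np.percentile(arr, 2.5)),
            ci_upper=float(np.percentile(arr, 97.5)),
        )

    def to_dict(self) -> dict:
        return {
            "point_estimate": self.point_estimate,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_iterations": len(self.per_iteration_values),
            "per_iteration_values": list(self.per_iteration_values),
        }


def expected_degraded_sensitivity(counts: ConfusionCounts, fraction_p: float) -> float:
    """Closed-form expected sensitivity after reclassifying fraction ``p`` of A.

    ``(1 - p) * a / (a + c)`` -- the analytic twin of :func:`degrade_once`.
    """
    if not (0.0 <= fraction_p <= 1.0):
        raise DegradationError("fraction_p must be in [0, 1]")
    if counts.a + counts.c == 0:
        raise CohortError("sensitivity undefined: no gold-standard deaths (a+c=0)")
    return (1.0 - fraction_p) * counts.a / (counts.a + counts.c)


def degrade_once(
    cohort: Sequence[PatientRecord],
    fraction_p: float,
    rng: np.random.Generator,
    arms: Optional[set[str]] = None,
) -> list[PatientRecord]:
    """Reclassify ``round(p * |A|)`` cell-A patients to cell C.

    Each reclassified patient loses their EHR death date and is re-censored
    uniformly on ``[index_date, gold_death_date)``.  All other patients are
    returned unchanged; the input cohort is never mutated.

    Parameters
    ----------
    arms : set of str, optional
        If given, only cell-A patients in these arms are eligible (used for
        external-control analyses where a single arm's death source is
        degraded).
    """
    if not (0.0 <= fraction_p <= 1.0):
        raise DegradationError("fraction_p must be in [0, 1]")
    eligible = [
        i
        for i, p in enumerate(cohort)
        if classify_patient(p) is MortalityCell.A and (arms is None or p.arm in arms)
    ]
    # round-half-to-even, matching the analytic expectation on average
    n_reclass = round(fraction_p * len(eligible))
    if n_reclass == 0:
        logger.debug(
            "degrade_once: round(p*|A|) = 0 (p=%s, |A|=%d); no-op", fraction_p, len(eligible)
        )
        return list(cohort)
    chosen = rng.choice(len(eligible), size=n_reclass, replace=False)
    selected = {eligible[int(j)] for j in chosen}
    out: list[PatientRecord] = []
    for i, p in enumerate(cohort):
        if i in selected:
            censor = rng.uniform(p.index_date, p.gold_death_date)
            out.append(
                dataclasses.replace(
                    p, ehr_death_date=None, last_activity_date=censor
                )
            )
        else:
            out.append(p)
    return out


def run_degradation_study(
    cohort: Sequence[PatientRecord],
    config: DegradationConfig,
    statistic_fn: Callable[[list[PatientRecord]], float],
    arms: Optional[set[str]] = None,
) -> SimulationSummary:
    """Run ``n_iterations`` independent degradations and summarise a statistic.

    Each iteration draws a fresh reclassified subset and fresh censor dates
    from its own substream of the master seed, applies ``statistic_fn`` to
    the degraded cohort, and collects the value.  The summary is the median
    (point estimate) with the 2.5th/97.5th percentiles as interval bounds.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_iterations)
    values: list[float] = []
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        degraded = degrade_once(cohort, config.fraction_p, rng, arms=arms)
        try:
            values.append(float(statistic_fn(degraded)))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise DegradationError(
                f"statistic failed at iteration {it}: {exc}"
            ) from exc
    return SimulationSummary.from_values(values)
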