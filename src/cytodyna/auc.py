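"""Trajectory AUC summaries (mean-curve trapezoids) and strain ratios.

With terminal sampling no animal has a trajectory, so the AUC of a
mediator is the trapezoidal integral of its per-time-point group mean
against time. Compartment summaries sum the per-mediator AUCs (never
across compartments — plasma and tissue units differ) and report the
wild-type : null ratio with the same degenerate-value convention as the
connection ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UsageError
from .panel import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_SPAN = (0.0, 48.0)


def mediator_auc(
    cohort: CohortTable,
    strain: str,
    compartment: str,
    mediator: str,
    t_start: float = DEFAULT_SPAN[0],
    t_end: float = DEFAULT_SPAN[1],
) -> float:
    """Trapezoidal AUC of the mean concentration trajectory over [t_start, t_end].

    Time points with no data inside the span are linearly bridged by the
    trapezoid rule itself (and logged); fewer than two populated time
    points is an error. Units: concentration-unit x hours.
    """
    df = cohort.subset(strain, compartment)
    df = df[(df["mediator"] == mediator)
            & (df["time_h"] >= t_start) & (df["time_h"] <= t_end)]
    means = df.groupby("time_h")["concentration"].mean().sort_index()
    if len(means) < 2:
        raise InsufficientDataError(
            f"AUC undefined: {len(means)} populated time point(s) for "
            f"{strain}/{compartment}/{mediator} in [{t_start}, {t_end}] h"
        )
    grid = set(means.index)
    expected = {
        t for t in cohort.subset(strain, compartment)["time_h"].unique()
        if t_start <= t <= t_end
    }
    gaps = sorted(expected - grid)
    if gaps:
        logger.info(
            "mediator_auc %s/%s/%s: interpolating across missing time "
            "point(s) %s", strain, compartment, mediator, gaps,
        )
    return float(np.trapezoid(means.to_numpy(), means.index.to_numpy()))


@dataclass
class AUCSummary:
    """Per-mediator AUCs for two strains in one compartment, their sums,
    and the strain_a : strain_b ratio."""

    compartment: str
    strain_a: str
    strain_b: str
    per_mediator: dict[str, dict[str, float]]  # strain -> mediator -> AUC
    compartment_sum: dict[str, float]  # strain -> sum of mediator AUCs
    strain_ratio: float


def compartment_auc_summary(
    cohort: CohortTable,
    compartment: str,
    strain_a: str,
    strain_b: str,
    t_start: float = DEFAULT_SPAN[0],
    t_end: float = DEFAULT_SPAN[1],
) -> AUCSummary:
    """Sum mediator AUCs per strain and form the a : b ratio.

    Degenerate ratios follow the connection-ratio convention: ``inf`` when
    only the denominator sum is zero, ``nan`` when both are.
    """
    present = set(cohort.strains())
    for s in (strain_a, strain_b):
        if s not in present:
            raise UsageError(f"strain {s!r} absent from cohort")
    per: dict[str, dict[str, float]] = {}
    sums: dict[str, float] = {}
    for s in (strain_a, strain_b):
        per[s] = {}
        for med in cohort.panel.names:
            try:
                per[s][med] = mediator_auc(
                    cohort, s, compartment, med, t_start, t_end
                )
            except InsufficientDataError:
                logger.info("AUC skipped for %s/%s/%s", s, compartment, med)
        sums[s] = float(sum(per[s].values()))
    a, b = sums[strain_a], sums[strain_b]
    if b == 0.0:
        ratio = math.nan if a == 0.0 else math.inf
    else:
        ratio = a / b
    return AUCSummary(
        compartment=compartment,
        strain_a=strain_a,
        strain_b=strain_b,
        per_mediator=per,
        compartment_sum=sums,
        strain_ratio=ratio,
    )
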