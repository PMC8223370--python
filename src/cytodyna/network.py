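"""Interval correlation networks and their summary statistics.

A dynamic network analysis builds one undirected, signed graph per
consecutive time interval. For an interval (s, e) all animals sacrificed
at either endpoint are pooled into one cross-section (terminal sampling
precludes within-animal trajectories). A mediator becomes a node eligible
for edges only if its pooled interval values differ significantly from the
0 h control group (Mann–Whitney U, two-sided). An edge joins two eligible
mediators when the Pearson correlation of their pooled values reaches an
absolute threshold (default 0.7, inclusive); the edge sign is the sign of r.

Network complexity for an interval is the degree sum divided by
(n_mediators − 1), i.e. 2·|edges|/(n−1) with n the number of mediators
analyzed, and the total number of connections is the edge count summed
over all intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedCorrelationError,
    UsageError,
)
from .panel import CohortTable

logger = logging.getLogger(__name__)

#: The five consecutive analysis intervals, hours.
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (1.0, 4.0), (4.0, 6.0), (6.0, 12.0), (12.0, 24.0), (24.0, 48.0),
)

DEFAULT_THRESHOLD = 0.7
DEFAULT_ALPHA = 0.05

UNCHANGED = "unchanged"
CHANGED_ISOLATED = "changed_isolated"
CHANGED_CONNECTED = "changed_connected"


@dataclass(frozen=True)
class NodeState:
    """Baseline-change status of one mediator within one interval network."""

    change_status: str
    p_baseline: float

    @property
    def changed(self) -> bool:
        return self.change_status != UNCHANGED


@dataclass(frozen=True)
class Edge:
    """Undirected signed edge; source precedes target in panel order."""

    source: str
    target: str
    r: float
    sign: str


@dataclass
class IntervalNetwork:
    """Signed correlation network for one (strain, compartment, interval)."""

    strain: str
    compartment: str
    interval: tuple[float, float]
    nodes: dict[str, NodeState]
    edges: tuple[Edge, ...]
    skips: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {name: 0 for name in self.nodes}
        for e in self.edges:
            deg[e.source] += 1
            deg[e.target] += 1
        return deg

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalNetwork):
            return NotImplemented
        if (
            self.strain != other.strain
            or self.compartment != other.compartment
            or tuple(self.interval) != tuple(other.interval)
            or self.edges != other.edges
            or set(self.nodes) != set(other.nodes)
        ):
            return False
        for name, st in self.nodes.items():
            ot = other.nodes[name]
            if st.change_status != ot.change_status:
                return False
            if not (
                st.p_baseline == ot.p_baseline
                or (math.isnan(st.p_baseline) and math.isnan(ot.p_baseline))
            ):
                return False
        return True


def interval_samples(
    cohort: CohortTable,
    strain: str,
    compartment: str,
    interval: tuple[float, float],
) -> pd.DataFrame:
    """Pool the animals sacrificed at the interval's two endpoint times.

    Returns an animals x mediators matrix (panel column order). Animals
    missing a mediator carry NaN there and are excluded pairwise downstream.

    Raises
    ------
    ConfigurationError
        If either endpoint time point is absent for this strain/compartment.
    """
    start, end = float(interval[0]), float(interval[1])
    present = set(
        cohort.subset(strain, compartment)["time_h"].unique().tolist()
    )
    for t in (start, end):
        if t not in present:
            raise ConfigurationError(
                f"no records at time {t} h for {strain}/{compartment}; "
                f"interval ({start}, {end}) needs both endpoints"
            )
    return cohort.pivot(strain, compartment, (start, end))


def _mw_changed(
    pooled: np.ndarray, baseline: np.ndarray, alpha: float
) -> tuple[bool, float]:
    """Shared Mann–Whitney change test on raw value arrays."""
    if pooled.size == 0:
        return False, float("nan")
    if np.ptp(pooled) == 0 and np.ptp(baseline) == 0 and pooled[0] == baseline[0]:
        return False, 1.0  # identical constants: U test degenerate, no change
    res = stats.mannwhitneyu(pooled, baseline, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return bool(p < alpha), p


def baseline_change_filter(
    cohort: CohortTable,
    strain: str,
    compartment: str,
    interval: tuple[float, float],
    mediator: str,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[bool, float]:
    """Test whether a mediator's pooled interval values differ from 0 h.

    Two-sided Mann–Whitney U of the pooled endpoint samples against the
    baseline (0 h) control group; exact null distribution when a group has
    at most 8 untied observations, normal approximation otherwise.

    Returns ``(changed, p)`` with ``changed = p < alpha``.
    """
    baseline = cohort.group_values(strain, compartment, mediator, (0.0,))
    if baseline.size < 3:
        raise ConfigurationError(
            f"baseline (0 h) group absent or <3 animals for "
            f"{strain}/{compartment}/{mediator}"
        )
    pooled = cohort.group_values(
        strain, compartment, mediator, (float(interval[0]), float(interval[1]))
    )
    return _mw_changed(pooled, baseline, alpha)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 paired observations.
    UndefinedCorrelationError
        Either vector is constant.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise UsageError("x and y must have equal length")
    if xv.size < 3:
        raise InsufficientDataError(f"need n >= 3 pairs, got {xv.size}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def _edge_sign(r: float) -> str:
    return "+" if r > 0 else "-"


def build_interval_network(
    cohort: CohortTable,
    strain: str,
    compartment: str,
    interval: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> IntervalNetwork:
    """Construct the signed correlation network of one time interval.

    Every panel mediator becomes a node, with its change status from the
    baseline filter. For each unordered pair of changed mediators the
    Pearson r of pairwise-complete pooled samples is computed and an edge
    is added iff ``|r| >= threshold`` (inclusive). Pairs with fewer than 3
    complete cases or a constant vector are skipped and recorded in
    ``skips``. A network with zero changed nodes is valid.
    """
    samples = interval_samples(cohort, strain, compartment, interval)
    panel_names = list(cohort.panel.names)
    skips: list[str] = []

    baseline = cohort.pivot(strain, compartment, (0.0,))
    if len(baseline) < 3:
        raise ConfigurationError(
            f"baseline (0 h) group absent or <3 animals for "
            f"{strain}/{compartment}"
        )
    status: dict[str, tuple[bool, float]] = {}
    for name in panel_names:
        pooled = samples[name].dropna().to_numpy(float)
        base = baseline[name].dropna().to_numpy(float)
        if base.size < 3:
            if pooled.size == 0:
                # mediator simply not measured in this compartment
                status[name] = (False, float("nan"))
                continue
            raise ConfigurationError(
                f"baseline (0 h) group <3 animals for {strain}/{compartment}/{name}"
            )
        status[name] = _mw_changed(pooled, base, alpha)
    changed_names = [n for n in panel_names if status[n][0]]

    edges: list[Edge] = []
    if len(changed_names) >= 2:
        sub = samples[changed_names].to_numpy(dtype=float)
        complete = not np.isnan(sub).any()
        if complete:
            # fast path: one correlation pass over the full matrix
            col_ok = np.ptp(sub, axis=0) > 0
            for j, name in enumerate(changed_names):
                if not col_ok[j]:
                    skips.append(f"{name}: constant across pooled samples")
            if sub.shape[0] >= 3:
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = np.corrcoef(sub, rowvar=False)
                for i in range(len(changed_names)):
                    for j in range(i + 1, len(changed_names)):
                        if not (col_ok[i] and col_ok[j]):
                            continue
                        r = float(np.clip(corr[i, j], -1.0, 1.0))
                        if abs(r) >= threshold:
                            edges.append(
                                Edge(changed_names[i], changed_names[j], r, _edge_sign(r))
                            )
            else:
                skips.append(f"pooled n={sub.shape[0]} < 3: all pairs skipped")
        else:
            for i in range(len(changed_names)):
                for j in range(i + 1, len(changed_names)):
                    a, b = changed_names[i], changed_names[j]
                    xy = samples[[a, b]].dropna().to_numpy(dtype=float)
                    try:
                        r = pearson_r(xy[:, 0], xy[:, 1])
                    except InsufficientDataError:
                        skips.append(f"{a}~{b}: n={xy.shape[0]} < 3")
                        continue
                    except UndefinedCorrelationError:
                        skips.append(f"{a}~{b}: constant vector")
                        continue
                    if abs(r) >= threshold:
                        edges.append(Edge(a, b, r, _edge_sign(r)))

    connected = {e.source for e in edges} | {e.target for e in edges}
    nodes: dict[str, NodeState] = {}
    for name in panel_names:
        changed, p = status[name]
        if not changed:
            st = UNCHANGED
        elif name in connected:
            st = CHANGED_CONNECTED
        else:
            st = CHANGED_ISOLATED
        nodes[name] = NodeState(st, p)

    for msg in skips:
        logger.info(
            "skip [%s/%s %s-%s h]: %s",
            strain, compartment, interval[0], interval[1], msg,
        )
    return IntervalNetwork(
        strain=strain,
        compartment=compartment,
        interval=(float(interval[0]), float(interval[1])),
        nodes=nodes,
        edges=tuple(edges),
        skips=tuple(skips),
    )


def network_complexity(network: IntervalNetwork, n_mediators: int | None = None) -> float:
    """Degree-sum complexity: (Σ_i N_i) / (n − 1) = 2·|edges| / (n − 1).

    ``n`` is the total number of mediators analyzed (the panel size), not
    the number of changed nodes.
    """
    n = len(network.nodes) if n_mediators is None else int(n_mediators)
    if n < 2:
        raise UsageError(f"complexity needs >= 2 mediators, got {n}")
    return 2.0 * network.n_edges / (n - 1)


def total_connections(networks: Iterable[IntervalNetwork]) -> int:
    """Sum of edge counts over a strain/compartment's interval networks."""
    nets = list(networks)
    if not nets:
        return 0
    keys = {(n.strain, n.compartment) for n in nets}
    if len(keys) > 1:
        raise UsageError(f"networks mix strain/compartment: {sorted(keys)}")
    return sum(n.n_edges for n in nets)


def connection_ratio(total_a: int, total_b: int) -> float:
    """Ratio of total connections between two groups (a : b).

    Degenerate cases are in-band IEEE markers: ``inf`` when the denominator
    is zero but the numerator is not, ``nan`` when both are zero.
    """
    if total_a < 0 or total_b < 0:
        raise UsageError("connection totals must be non-negative")
    if total_b == 0:
        return math.nan if total_a == 0 else math.inf
    return total_a / total_b


@dataclass
class ComplexityProfile:
    """Per-interval complexity and the total-connection count for one group."""

    strain: str
    compartment: str
    per_interval: dict[tuple[float, float], float]
    total_connections: int

    @classmethod
    def from_networks(
        cls, networks: Sequence[IntervalNetwork], n_mediators: int | None = None
    ) -> "ComplexityProfile":
        nets = list(networks)
        if not nets:
            raise UsageError("need at least one network")
        total = total_connections(nets)
        per = {
            tuple(n.interval): network_complexity(n, n_mediators) for n in nets
        }
        return cls(nets[0].strain, nets[0].compartment, per, total)
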