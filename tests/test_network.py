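"""Interval network construction, the baseline filter, and graph statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodyna import (
    ConfigurationError,
    Edge,
    InsufficientDataError,
    IntervalNetwork,
    NodeState,
    UndefinedCorrelationError,
    UsageError,
    baseline_change_filter,
    build_interval_network,
    connection_ratio,
    interval_samples,
    network_complexity,
    pearson_r,
    total_connections,
)
from cytodyna.network import CHANGED_CONNECTED, CHANGED_ISOLATED, UNCHANGED

from conftest import cohort_from_blocks


# --- pearson_r --------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # hand-computed: cov 4, sd^2 5 each
    ],
)
def test_pearson_known_values(x, y, expected):
    assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_degenerate_inputs():
    with pytest.raises(InsufficientDataError):
        pearson_r([1, 2], [3, 4])
    with pytest.raises(UndefinedCorrelationError):
        pearson_r([1, 1, 1], [1, 2, 3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
        ),
        min_size=3,
        max_size=30,
    ),
    a=st.floats(0.1, 10),
    b=st.floats(-5, 5),
)
def test_pearson_affine_invariance(data, a, b):
    """r is unchanged by positive-slope affine rescaling and lies in [-1, 1]."""
    x = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    try:
        r = pearson_r(x, y)
    except UndefinedCorrelationError:
        return  # centering underflowed (subnormal spread); out of scope
    assert -1.0 <= r <= 1.0
    assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)


# --- interval assembly ------------------------------------------------------

def _two_time_cohort(small_panel, rng, n=8, with_baseline=True):
    blocks = []
    if with_baseline:
        blocks.append(("WT", "heart", 0.0, np.exp(rng.normal(0, 0.3, (n, 6)))))
    blocks.append(("WT", "heart", 4.0, np.exp(rng.normal(0, 0.3, (n, 6)))))
    blocks.append(("WT", "heart", 6.0, np.exp(rng.normal(0, 0.3, (n, 6)))))
    return cohort_from_blocks(blocks, small_panel)


def test_interval_samples_pools_both_endpoints(small_panel):
    rng = np.random.default_rng(0)
    cohort = _two_time_cohort(small_panel, rng)
    mat = interval_samples(cohort, "WT", "heart", (4, 6))
    assert mat.shape == (16, 6)
    assert list(mat.columns) == list(small_panel.names)


def test_interval_samples_missing_endpoint(small_panel):
    rng = np.random.default_rng(0)
    cohort = _two_time_cohort(small_panel, rng)
    with pytest.raises(ConfigurationError, match="1"):
        interval_samples(cohort, "WT", "heart", (1, 4))


def test_missing_mediator_value_leaves_nan(small_panel):
    rng = np.random.default_rng(1)
    vals = np.exp(rng.normal(0, 0.3, (4, 6)))
    vals[0, 4] = np.nan  # animal 1 missing IL-5
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, np.exp(rng.normal(0, 0.3, (4, 6)))),
         ("WT", "heart", 4.0, vals),
         ("WT", "heart", 6.0, np.exp(rng.normal(0, 0.3, (4, 6))))],
        small_panel,
    )
    mat = interval_samples(cohort, "WT", "heart", (4, 6))
    assert mat["IL-5"].isna().sum() == 1
    assert mat.drop(columns="IL-5").notna().all().all()


# --- baseline change filter -------------------------------------------------

def test_baseline_filter_identical_multiset(small_panel):
    base = np.tile(np.arange(1.0, 9.0)[:, None], (1, 6))
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, base[:4]),
         ("WT", "heart", 6.0, base[4:])],
        small_panel,
    )
    changed, p = baseline_change_filter(cohort, "WT", "heart", (4, 6), "TNF")
    assert not changed
    assert p > 0.9


def test_baseline_filter_full_separation(small_panel):
    rng = np.random.default_rng(2)
    base = np.exp(rng.normal(0, 0.3, (8, 6)))
    up = np.exp(rng.normal(5, 0.3, (4, 6)))
    up2 = np.exp(rng.normal(5, 0.3, (4, 6)))
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, up),
         ("WT", "heart", 6.0, up2)],
        small_panel,
    )
    changed, p = baseline_change_filter(cohort, "WT", "heart", (4, 6), "TNF")
    assert changed
    assert p == pytest.approx(2 / 12870, rel=1e-12)


def test_baseline_filter_alpha_zero(small_panel):
    rng = np.random.default_rng(3)
    cohort = _two_time_cohort(small_panel, rng)
    changed, _ = baseline_change_filter(
        cohort, "WT", "heart", (4, 6), "TNF", alpha=0.0
    )
    assert not changed


def test_baseline_filter_requires_baseline(small_panel):
    rng = np.random.default_rng(4)
    cohort = _two_time_cohort(small_panel, rng, with_baseline=False)
    with pytest.raises(ConfigurationError, match="baseline"):
        baseline_change_filter(cohort, "WT", "heart", (4, 6), "TNF")


# --- network construction ---------------------------------------------------

def test_no_changed_nodes_gives_empty_network(small_panel):
    rng = np.random.default_rng(0)  # a draw with no chance filter passes
    cohort = _two_time_cohort(small_panel, rng)
    net = build_interval_network(cohort, "WT", "heart", (4, 6))
    assert net.n_edges == 0
    assert all(s.change_status == UNCHANGED for s in net.nodes.values())
    assert len(net.nodes) == 6


def test_edge_threshold_boundary_is_inclusive(small_panel):
    """|r| equal to the threshold keeps the edge: check at the exactly
    representable boundary r = 1 with threshold 1.0."""
    rng = np.random.default_rng(6)
    base = np.exp(rng.normal(0, 0.3, (8, 6)))
    x = np.linspace(1.0, 2.0, 16)
    vals = np.exp(rng.normal(3, 0.3, (16, 6)))
    vals[:, 0] = x        # TNF
    vals[:, 1] = 2 * x    # IL-6 exactly collinear -> r == 1.0
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, vals[:8]),
         ("WT", "heart", 6.0, vals[8:])],
        small_panel,
    )
    net = build_interval_network(cohort, "WT", "heart", (4, 6), threshold=1.0)
    assert Edge("TNF", "IL-6", 1.0, "+") in net.edges
    assert net.nodes["TNF"].change_status == CHANGED_CONNECTED


def test_negative_edge_sign(small_panel):
    rng = np.random.default_rng(7)
    base = np.exp(rng.normal(0, 0.3, (8, 6)))
    x = np.linspace(1.0, 2.0, 16)
    vals = np.exp(rng.normal(3, 0.3, (16, 6)))
    vals[:, 0] = x
    vals[:, 1] = 10.0 - 2 * x  # perfectly anti-correlated
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, vals[:8]),
         ("WT", "heart", 6.0, vals[8:])],
        small_panel,
    )
    net = build_interval_network(cohort, "WT", "heart", (4, 6))
    edge = next(e for e in net.edges if {e.source, e.target} == {"TNF", "IL-6"})
    assert edge.sign == "-"
    assert edge.r == pytest.approx(-1.0)


def test_threshold_monotonicity(small_panel):
    """Raising the threshold never adds edges."""
    rng = np.random.default_rng(8)
    base = np.exp(rng.normal(0, 0.3, (8, 6)))
    vals = np.exp(rng.normal(3, 0.3, (16, 6)))
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, vals[:8]),
         ("WT", "heart", 6.0, vals[8:])],
        small_panel,
    )
    prev = None
    for thr in (0.0, 0.3, 0.5, 0.7, 0.9, 1.0 + 1e-9):
        edges = {
            (e.source, e.target)
            for e in build_interval_network(
                cohort, "WT", "heart", (4, 6), threshold=thr
            ).edges
        }
        if prev is not None:
            assert edges <= prev
        prev = edges
    assert prev == set()  # threshold > 1 empties continuous data


def test_constant_mediator_yields_no_edge_not_nan(small_panel):
    rng = np.random.default_rng(9)
    base = np.full((8, 6), 5.0)
    base += rng.normal(0, 0.05, base.shape)
    vals = np.exp(rng.normal(3, 0.3, (16, 6)))
    vals[:, 2] = 7.0  # IL-10 constant in the interval
    cohort = cohort_from_blocks(
        [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, vals[:8]),
         ("WT", "heart", 6.0, vals[8:])],
        small_panel,
    )
    net = build_interval_network(cohort, "WT", "heart", (4, 6), threshold=0.0)
    assert all("IL-10" not in (e.source, e.target) for e in net.edges)
    assert any("IL-10" in s for s in net.skips)


def test_shuffling_destroys_planted_edges(small_panel):
    """Permutation null: independently shuffling each mediator's animal
    labels removes a perfect planted correlation."""
    rng = np.random.default_rng(10)
    base = np.exp(rng.normal(0, 0.3, (8, 6)))
    x = rng.lognormal(3, 0.3, 16)
    vals = np.exp(rng.normal(3, 0.3, (16, 6)))
    vals[:, 0] = np.sort(x)
    vals[:, 1] = np.sort(x) * 2.0
    shuffled = vals.copy()
    for j in range(6):
        shuffled[:, j] = rng.permutation(shuffled[:, j])
    before = build_interval_network(
        cohort_from_blocks(
            [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, vals[:8]),
             ("WT", "heart", 6.0, vals[8:])], small_panel),
        "WT", "heart", (4, 6))
    after = build_interval_network(
        cohort_from_blocks(
            [("WT", "heart", 0.0, base), ("WT", "heart", 4.0, shuffled[:8]),
             ("WT", "heart", 6.0, shuffled[8:])], small_panel),
        "WT", "heart", (4, 6))
    assert any({e.source, e.target} == {"TNF", "IL-6"} for e in before.edges)
    assert not any({e.source, e.target} == {"TNF", "IL-6"} for e in after.edges)


# --- statistics -------------------------------------------------------------

def _toy_network(n_edges: int, strain="WT", comp="heart") -> IntervalNetwork:
    names = [f"M{i}" for i in range(20)]
    edges = []
    k = 0
    for i in range(20):
        for j in range(i + 1, 20):
            if k >= n_edges:
                break
            edges.append(Edge(names[i], names[j], 0.9, "+"))
            k += 1
    nodes = {
        n: NodeState(CHANGED_CONNECTED if any(n in (e.source, e.target)
                                              for e in edges) else UNCHANGED, 0.01)
        for n in names
    }
    return IntervalNetwork(strain, comp, (4.0, 6.0), nodes, tuple(edges))


def test_complexity_examples():
    assert network_complexity(_toy_network(0)) == 0.0
    assert network_complexity(_toy_network(5)) == pytest.approx(10 / 19)


def test_complexity_degree_sum_identity():
    rng = np.random.default_rng(11)
    for _ in range(50):
        net = _toy_network(int(rng.integers(0, 40)))
        degs = net.degrees()
        assert sum(degs.values()) == 2 * net.n_edges
        assert network_complexity(net) == pytest.approx(
            sum(degs.values()) / 19
        )


def test_complexity_rejects_tiny_panel():
    net = IntervalNetwork("WT", "heart", (4.0, 6.0),
                          {"TNF": NodeState(UNCHANGED, 1.0)}, ())
    with pytest.raises(UsageError):
        network_complexity(net)


def test_total_connections():
    assert total_connections([_toy_network(0)] * 5) == 0
    nets = [_toy_network(k) for k in (3, 1, 0, 2, 4)]
    assert total_connections(nets) == 10
    with pytest.raises(UsageError, match="mix"):
        total_connections([_toy_network(1), _toy_network(1, strain="KO")])


def test_connection_ratio_contract():
    assert connection_ratio(40, 10) == 4.0
    assert connection_ratio(7, 0) == math.inf
    assert math.isnan(connection_ratio(0, 0))
    with pytest.raises(UsageError):
        connection_ratio(-1, 2)
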