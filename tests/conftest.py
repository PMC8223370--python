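"""Shared fixtures: programmatic cohort builders and random networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytodyna import CohortTable, Edge, IntervalNetwork, MediatorPanel, NodeState
from cytodyna.network import CHANGED_CONNECTED, CHANGED_ISOLATED, UNCHANGED

SMALL_MEDIATORS = ("TNF", "IL-6", "IL-10", "KC", "IL-5", "MCP-1")


@pytest.fixture
def small_panel() -> MediatorPanel:
    return MediatorPanel(names=SMALL_MEDIATORS, units_by_compartment={"heart": "pg/mg"})


def cohort_from_blocks(blocks, panel: MediatorPanel) -> CohortTable:
    """Build a CohortTable from (strain, compartment, time, values) blocks.

    ``values`` is an (animals x mediators) array aligned to panel order; NaN
    entries become absent rows (missing measurements).
    """
    rows = []
    for strain, comp, time_h, values in blocks:
        arr = np.asarray(values, dtype=float)
        for i in range(arr.shape[0]):
            for j, med in enumerate(panel.names[: arr.shape[1]]):
                if np.isnan(arr[i, j]):
                    continue
                rows.append(
                    {
                        "strain": strain,
                        "compartment": comp,
                        "time_h": float(time_h),
                        "animal_id": f"{strain}-t{time_h:g}-{i + 1}",
                        "mediator": med,
                        "concentration": float(arr[i, j]),
                    }
                )
    return CohortTable(pd.DataFrame(rows), panel)


def random_network(rng: np.random.Generator, panel: MediatorPanel) -> IntervalNetwork:
    """A structurally valid network with random edges among changed nodes.

    Edges are stored once, source before target in panel order, consistent
    with how the builder emits them.
    """
    names = list(panel.names)
    changed = [n for n in names if rng.random() < 0.6]
    edges = []
    for i in range(len(changed)):
        for j in range(i + 1, len(changed)):
            if rng.random() < 0.25:
                mag = rng.uniform(0.7, 1.0)
                r = float(mag if rng.random() < 0.5 else -mag)
                a, b = changed[i], changed[j]
                if names.index(a) > names.index(b):
                    a, b = b, a
                edges.append(Edge(a, b, r, "+" if r > 0 else "-"))
    edges.sort(key=lambda e: (names.index(e.source), names.index(e.target)))
    connected = {e.source for e in edges} | {e.target for e in edges}
    nodes = {}
    for n in names:
        if n not in changed:
            nodes[n] = NodeState(UNCHANGED, float(rng.uniform(0.05, 1.0)))
        elif n in connected:
            nodes[n] = NodeState(CHANGED_CONNECTED, float(rng.uniform(0.0, 0.05)))
        else:
            nodes[n] = NodeState(CHANGED_ISOLATED, float(rng.uniform(0.0, 0.05)))
    return IntervalNetwork(
        strain="C57BL/6",
        compartment="heart",
        interval=(4.0, 6.0),
        nodes=nodes,
        edges=tuple(edges),
    )
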