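"""Reading and writing cohorts and interval networks.

Cohorts travel as tidy CSV (one row per strain/compartment/time/animal/
mediator). Networks are written either as tab-separated edge lists — with
'#'-prefixed metadata lines carrying the strain, compartment, interval and
per-node change status so a read reproduces the network exactly — or as
GraphML via networkx. Edge signs are stored as explicit "+"/"-" characters
next to the raw r so the sign survives any rounding of r in text output.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import SchemaError, UsageError
from .network import Edge, IntervalNetwork, NodeState
from .panel import CohortTable, MediatorPanel, REQUIRED_COLUMNS

EDGELIST = "edgelist"
GRAPHML = "graphml"
FORMATS = (EDGELIST, GRAPHML)

_ID_COLUMNS = ("strain", "compartment", "time_h", "animal_id")


def read_cohort(
    path: str | Path,
    panel: MediatorPanel | None = None,
    wide: bool = False,
) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV with header columns strain, compartment, time_h, animal_id,
        mediator, concentration (long form), or — with ``wide=True`` — the
        four id columns followed by one column per mediator.
    panel
        Panel to validate against; the default 20-mediator panel if None.
    wide
        Convenience flag: melt a wide per-mediator layout into long form
        before validation.
    """
    panel = panel if panel is not None else MediatorPanel.default()
    df = pd.read_csv(path)
    if wide:
        missing = [c for c in _ID_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.melt(
            id_vars=list(_ID_COLUMNS),
            var_name="mediator",
            value_name="concentration",
        ).dropna(subset=["concentration"])
    return CohortTable(df, panel)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def write_network(
    network: IntervalNetwork, path: str | Path, format: str = EDGELIST
) -> None:
    """Serialize a network; ``format`` is "edgelist" or "graphml"."""
    if format == EDGELIST:
        _write_edgelist(network, Path(path))
    elif format == GRAPHML:
        nx.write_graphml(to_networkx(network), str(path))
    else:
        raise UsageError(f"unknown network format {format!r}; use one of {FORMATS}")


def read_network(path: str | Path, format: str = EDGELIST) -> IntervalNetwork:
    if format == EDGELIST:
        return _read_edgelist(Path(path))
    if format == GRAPHML:
        return from_networkx(nx.read_graphml(str(path)))
    raise UsageError(f"unknown network format {format!r}; use one of {FORMATS}")


# -- edge-list dialect -------------------------------------------------------

def _write_edgelist(network: IntervalNetwork, path: Path) -> None:
    lines = [
        "# cytodyna interval network",
        f"# strain\t{network.strain}",
        f"# compartment\t{network.compartment}",
        f"# interval\t{network.interval[0]!r}\t{network.interval[1]!r}",
    ]
    for name, st in network.nodes.items():
        lines.append(f"# node\t{name}\t{st.change_status}\t{st.p_baseline!r}")
    lines.append("source\ttarget\tsign\tr")
    for e in network.edges:
        lines.append(f"{e.source}\t{e.target}\t{e.sign}\t{e.r!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_edgelist(path: Path) -> IntervalNetwork:
    strain = compartment = ""
    interval: tuple[float, float] = (math.nan, math.nan)
    nodes: dict[str, NodeState] = {}
    edges: list[Edge] = []
    header_seen = False
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            tag = parts[0]
            if tag == "strain":
                strain = parts[1]
            elif tag == "compartment":
                compartment = parts[1]
            elif tag == "interval":
                interval = (float(parts[1]), float(parts[2]))
            elif tag == "node":
                nodes[parts[1]] = NodeState(parts[2], float(parts[3]))
            continue
        if not header_seen:
            if line.split("\t") != ["source", "target", "sign", "r"]:
                raise SchemaError(f"unexpected edge-list header: {line!r}")
            header_seen = True
            continue
        src, tgt, sign, r = line.split("\t")
        edges.append(Edge(src, tgt, float(r), sign))
    if not header_seen:
        raise SchemaError(f"{path} has no edge-list header line")
    return IntervalNetwork(strain, compartment, interval, nodes, tuple(edges))


# -- GraphML bridge ----------------------------------------------------------

def to_networkx(network: IntervalNetwork) -> nx.Graph:
    """Undirected graph with node attr change_status/p_baseline and edge
    attrs sign/r; graph attrs identify strain, compartment and interval."""
    g = nx.Graph(
        strain=network.strain,
        compartment=network.compartment,
        interval_start=float(network.interval[0]),
        interval_end=float(network.interval[1]),
        node_order=",".join(network.nodes.keys()),
    )
    for name, st in network.nodes.items():
        g.add_node(name, change_status=st.change_status, p_baseline=st.p_baseline)
    for e in network.edges:
        g.add_edge(e.source, e.target, sign=e.sign, r=e.r)
    return g


def from_networkx(g: nx.Graph) -> IntervalNetwork:
    order = [n for n in str(g.graph.get("node_order", "")).split(",") if n]
    names = order if order else list(g.nodes)
    nodes = {
        name: NodeState(
            g.nodes[name]["change_status"], float(g.nodes[name]["p_baseline"])
        )
        for name in names
    }
    pos = {name: i for i, name in enumerate(names)}
    edges = []
    for u, v, data in g.edges(data=True):
        a, b = (u, v) if pos.get(u, 0) <= pos.get(v, 0) else (v, u)
        edges.append(Edge(a, b, float(data["r"]), str(data["sign"])))
    edges.sort(key=lambda e: (pos.get(e.source, 0), pos.get(e.target, 0)))
    return IntervalNetwork(
        strain=str(g.graph.get("strain", "")),
        compartment=str(g.graph.get("compartment", "")),
        interval=(
            float(g.graph.get("interval_start", math.nan)),
            float(g.graph.get("interval_end", math.nan)),
        ),
        nodes=nodes,
        edges=tuple(edges),
    )
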