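"""End-to-end orchestration: simulate/load -> networks -> AUC -> Spearman.

A run is described by a :class:`RunConfig` (loadable from YAML), executed
by :func:`run_pipeline`, and materialized as a directory of edge lists,
GraphML files and JSON summaries plus a consolidated JSON + Markdown
report ranking compartments by connection ratio and AUC ratio. All results
are computed in memory before anything is written, so a failing stage
leaves no partial outputs; every artifact is stamped with the seed and a
hash of the configuration. Randomness is split into named substreams per
stage, so adding or reordering stages cannot silently change results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as cio
from .auc import compartment_auc_summary
from .correlate import DEFAULT_B, DEFAULT_WINDOWS, window_correlation
from .errors import ConfigurationError, SchemaError, UsageError
from .network import (
    ComplexityProfile,
    DEFAULT_ALPHA,
    DEFAULT_INTERVALS,
    DEFAULT_THRESHOLD,
    build_interval_network,
    connection_ratio,
)
from .panel import CohortTable, MediatorPanel
from .simulate import scenario_paperlike, simulate_cohort

#: fixed substream indices; stage order can never reshuffle draws
_STAGE_KEYS = {"simulate": 0, "correlate": 1}

DEFAULT_PAIRS = (("IL-17A", "GM-CSF"), ("IL-17A", "TNF"))


@dataclass
class RunConfig:
    """Declarative description of one reproducible pipeline run."""

    cohort_csv: str | None = None  # load this cohort...
    scenario: bool = True  # ...or simulate the canned study-like design
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    intervals: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    correlation_compartments: tuple[str, ...] = ("plasma", "spleen")
    B: int = DEFAULT_B
    seed: int = 0
    out_dir: str = "cytodyna-out"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["intervals"] = [list(i) for i in self.intervals]
        d["windows"] = [list(w) for w in self.windows]
        d["pairs"] = [list(p) for p in self.pairs]
        d["correlation_compartments"] = list(self.correlation_compartments)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kw = dict(d)
        for key, caster in (
            ("intervals", lambda v: tuple((float(a), float(b)) for a, b in v)),
            ("windows", lambda v: tuple((float(a), float(b)) for a, b in v)),
            ("pairs", lambda v: tuple((str(a), str(b)) for a, b in v)),
            ("correlation_compartments", lambda v: tuple(str(c) for c in v)),
        ):
            if key in kw and kw[key] is not None:
                kw[key] = caster(kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    )


def _jsonable(x: Any) -> Any:
    """Recursively convert to strict JSON; non-finite floats become strings."""
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if math.isfinite(v) else ("inf" if v > 0 else "nan" if math.isnan(v) else "-inf")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def _ratio_sort_key(item: tuple[str, float]) -> tuple[int, float]:
    v = item[1]
    if isinstance(v, float) and math.isnan(v):
        return (2, 0.0)
    if v == math.inf:
        return (0, 0.0)
    return (1, -float(v))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns the consolidated report dict (the content of report.json).
    """
    # ---- stage: cohort ---------------------------------------------------
    if config.cohort_csv is not None:
        cohort = cio.read_cohort(config.cohort_csv, MediatorPanel.default())
        truth = None
    elif config.scenario:
        design = scenario_paperlike()
        cohort, truth = simulate_cohort(design, _stage_rng(config.seed, "simulate"))
    else:
        raise UsageError("config needs either cohort_csv or scenario=true")
    if len(cohort) == 0:
        raise SchemaError("cohort is empty: nothing to analyze")

    strains = cohort.strains()
    if len(strains) != 2:
        raise UsageError(
            f"pipeline compares exactly two strains, found {strains}"
        )
    strain_a, strain_b = strains  # lexicographic; wild-type first by default
    compartments = cohort.compartments()

    # ---- stage: dynamic networks ----------------------------------------
    networks = {}  # (strain, comp) -> list[IntervalNetwork]
    complexity: dict[str, Any] = {}
    skipped_groups: list[str] = []
    for strain in strains:
        for comp in compartments:
            nets = []
            for interval in config.intervals:
                try:
                    nets.append(
                        build_interval_network(
                            cohort, strain, comp, interval,
                            threshold=config.threshold, alpha=config.alpha,
                        )
                    )
                except ConfigurationError as exc:
                    raise ConfigurationError(f"dyna stage: {exc}") from exc
            networks[(strain, comp)] = nets
            prof = ComplexityProfile.from_networks(nets, len(cohort.panel))
            complexity.setdefault(strain, {})[comp] = {
                "per_interval": {
                    f"{int(a)}-{int(b)}h": v for (a, b), v in prof.per_interval.items()
                },
                "total_connections": prof.total_connections,
                "skips": [s for n in nets for s in n.skips],
            }

    conn_ratios = {
        comp: connection_ratio(
            complexity[strain_a][comp]["total_connections"],
            complexity[strain_b][comp]["total_connections"],
        )
        for comp in compartments
    }

    # ---- stage: AUC summaries -------------------------------------------
    auc_report: dict[str, Any] = {}
    auc_ratios: dict[str, float] = {}
    for comp in compartments:
        summ = compartment_auc_summary(cohort, comp, strain_a, strain_b)
        auc_report[comp] = {
            "unit": f"{cohort.panel.unit(comp)}*h",
            "per_mediator": summ.per_mediator,
            "compartment_sum": summ.compartment_sum,
            "strain_ratio": summ.strain_ratio,
        }
        auc_ratios[comp] = summ.strain_ratio

    # ---- stage: windowed Spearman ---------------------------------------
    corr_rng = _stage_rng(config.seed, "correlate")
    spearman_report: dict[str, Any] = {}
    for strain in strains:
        for comp in config.correlation_compartments:
            if comp not in compartments:
                continue
            for pair in config.pairs:
                for window in config.windows:
                    ci = window_correlation(
                        cohort, strain, comp, pair, window,
                        B=config.B, seed=corr_rng,
                    )
                    key = f"{strain}|{comp}|{pair[0]}~{pair[1]}|{int(window[0])}-{int(window[1])}h"
                    spearman_report[key] = {
                        "rho": ci.rho, "ci_low": ci.ci_low, "ci_high": ci.ci_high,
                        "n": ci.n, "B": ci.B, "significant": ci.significant,
                    }

    # ---- consolidated report --------------------------------------------
    conn_ranking = [c for c, _ in sorted(conn_ratios.items(), key=_ratio_sort_key)]
    auc_ranking = [c for c, _ in sorted(auc_ratios.items(), key=_ratio_sort_key)]
    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "strain_numerator": strain_a,
        "strain_denominator": strain_b,
        "connection_ratio_by_compartment": conn_ratios,
        "connection_ratio_ranking": conn_ranking,
        "auc_ratio_by_compartment": auc_ratios,
        "auc_ratio_ranking": auc_ranking,
        "complexity": complexity,
        "spearman": spearman_report,
        "skipped": skipped_groups,
    }

    # ---- write bundle (only after every stage succeeded) -----------------
    out = Path(config.out_dir)
    net_dir = out / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)
    if config.cohort_csv is None:
        cio.write_cohort(cohort, out / "cohort.csv")
        if truth is not None:
            (out / "ground_truth.json").write_text(
                json.dumps(
                    _jsonable(
                        {
                            "planted_edges": {
                                f"{s}|{c}|{int(i[0])}-{int(i[1])}h": v
                                for (s, c, i), v in truth.planted_edges.items()
                            },
                        }
                    ),
                    sort_keys=True, indent=1,
                )
            )
    for (strain, comp), nets in networks.items():
        for net in nets:
            stem = f"{strain}_{comp}_{int(net.interval[0])}-{int(net.interval[1])}h"
            stem = stem.replace("/", "-").replace(" ", "_")
            cio.write_network(net, net_dir / f"{stem}.tsv", cio.EDGELIST)
            cio.write_network(net, net_dir / f"{stem}.graphml", cio.GRAPHML)
    stamp = {"seed": config.seed, "config_digest": config.digest()}
    for name, payload in (
        ("complexity.json", {**stamp, "complexity": complexity}),
        ("auc.json", {**stamp, "auc": auc_report}),
        ("spearman.json", {**stamp, "spearman": spearman_report}),
        ("report.json", report),
    ):
        (out / name).write_text(
            json.dumps(_jsonable(payload), sort_keys=True, indent=1) + "\n"
        )
    (out / "report.md").write_text(_markdown_report(report))
    config.to_yaml(out / "config.yaml")
    return report


def _fmt_ratio(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return "undefined (0:0)"
    if v == math.inf:
        return "infinite (n:0)"
    return f"{v:.2f}"


def _markdown_report(report: dict[str, Any]) -> str:
    lines = [
        "# Dynamic network analysis report",
        "",
        f"- seed: {report['seed']}",
        f"- config digest: {report['config_digest']}",
        f"- ratio direction: {report['strain_numerator']} : {report['strain_denominator']}",
        "",
        "## Compartments ranked by connection ratio",
        "",
        "| rank | compartment | connection ratio | AUC ratio |",
        "|-----:|-------------|-----------------:|----------:|",
    ]
    for i, comp in enumerate(report["connection_ratio_ranking"], 1):
        lines.append(
            f"| {i} | {comp} | "
            f"{_fmt_ratio(report['connection_ratio_by_compartment'][comp])} | "
            f"{_fmt_ratio(report['auc_ratio_by_compartment'][comp])} |"
        )
    lines += ["", "## Windowed Spearman correlations", ""]
    lines.append("| group | rho | 95% CI | n | significant |")
    lines.append("|-------|----:|--------|--:|:-----------:|")
    for key in sorted(report["spearman"]):
        s = report["spearman"][key]
        lines.append(
            f"| {key} | {s['rho']:.3f} | [{s['ci_low']:.3f}, {s['ci_high']:.3f}] "
            f"| {s['n']} | {'yes' if s['significant'] else 'no'} |"
        )
    lines.append("")
    return "\n".join(lines)
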