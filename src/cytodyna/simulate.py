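"""Synthetic cohorts with planted correlation structure and responders.

The generator emulates the study design end to end: two strains, seven
compartments, terminal sampling at 0/1/4/6/12/24/48 h, group sizes of 8
(wild-type) or 4 (receptor-null) animals per time point, and the default
20-mediator panel. Concentrations are log-normal — the exponential of a
multivariate normal — because multiplex immunoassay readouts are positive
and right-skewed; both planted correlations and responder effect sizes are
therefore defined on the log scale, with effects expressed in units of the
baseline log-SD.

Correlation is planted per interval: every pair listed in an edge block is
given the target correlation at both endpoint time points of its interval,
so the pooled two-endpoint cross-section — exactly the sample the dynamic
network analysis consumes — carries the planted association. Because
consecutive intervals share an endpoint, the union of all blocks touching
a time point must itself be a valid (PSD) correlation matrix; the design
validator enforces this and rejects conflicting targets for the same pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .panel import (
    CohortTable,
    DEFAULT_COMPARTMENTS,
    DEFAULT_TIME_POINTS,
    MediatorPanel,
)

Interval = tuple[float, float]
EdgeBlockKey = tuple[str, str, Interval]  # (strain, compartment, interval)
PlantedPair = tuple[str, str, float]  # (mediator_a, mediator_b, rho)

WT = "C57BL/6"
KO = "TLR4-null"


@dataclass
class PlantedDesign:
    """Declarative description of a synthetic cohort.

    Attributes
    ----------
    strains
        Strain label -> global response scaling multiplied into every
        responder effect for that strain.
    n_per_timepoint
        Strain label -> animals sacrificed per time point.
    responders
        (strain, compartment) -> mediator -> {time_h: effect size}, effects
        in units of the baseline log-SD (scale-free).
    edge_blocks
        (strain, compartment, interval) -> list of (mediator_a, mediator_b,
        target correlation); planted at both endpoint times of the interval.
    noise_cv
        Coefficient of variation of the log-normal measurement noise.
    baseline_mean
        Median baseline concentration (pg/ml or pg/mg), shared by all
        mediators; only ratios matter downstream.
    """

    strains: dict[str, float] = field(default_factory=lambda: {WT: 1.0, KO: 1.0})
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_per_timepoint: dict[str, int] = field(default_factory=lambda: {WT: 8, KO: 4})
    responders: dict[tuple[str, str], dict[str, dict[float, float]]] = field(
        default_factory=dict
    )
    edge_blocks: dict[EdgeBlockKey, list[PlantedPair]] = field(default_factory=dict)
    noise_cv: float = 0.3
    baseline_mean: float = 100.0
    panel: MediatorPanel = field(default_factory=MediatorPanel.default)
    seed: int | None = None

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        tp = tuple(float(t) for t in self.time_points_h)
        if not tp or tp[0] != 0.0:
            raise DesignError("time_points_h must start at 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise DesignError("time_points_h must be strictly increasing")
        if self.noise_cv <= 0:
            raise DesignError("noise_cv must be positive")
        for strain in self.strains:
            if self.n_per_timepoint.get(strain, 0) < 1:
                raise DesignError(f"n_per_timepoint missing/invalid for {strain}")
        for (strain, comp, interval), pairs in self.edge_blocks.items():
            if strain not in self.strains or comp not in self.compartments:
                raise DesignError(f"edge block references unknown {strain}/{comp}")
            lo, hi = float(interval[0]), float(interval[1])
            if lo not in tp or hi not in tp or hi <= lo:
                raise DesignError(
                    f"edge-block interval {interval} not on the time grid"
                )
            for a, b, rho in pairs:
                if a == b:
                    raise DesignError(f"self-pair {a} in block {interval}")
                for m in (a, b):
                    if m not in self.panel:
                        raise DesignError(f"planted mediator {m} not in panel")
                if not -1.0 <= rho <= 1.0:
                    raise DesignError(f"|rho| > 1 for pair ({a}, {b})")
            cmat = self._block_matrix(pairs, f"interval {interval}")
            self._check_psd(cmat, f"{strain}/{comp} interval {interval}")
        # union matrices at shared endpoints must also be valid
        for strain in self.strains:
            for comp in self.compartments:
                for t in tp:
                    pairs = self._pairs_at(strain, comp, t)
                    if pairs:
                        cmat = self._block_matrix(
                            pairs, f"time {t} ({strain}/{comp})"
                        )
                        self._check_psd(cmat, f"{strain}/{comp} at {t} h")
        for (strain, comp), meds in self.responders.items():
            for m in meds:
                if m not in self.panel:
                    raise DesignError(f"responder {m} not in panel")

    def _pairs_at(self, strain: str, comp: str, t: float) -> list[PlantedPair]:
        """All planted pairs whose interval has t as an endpoint; conflicting
        targets for the same pair raise."""
        seen: dict[tuple[str, str], float] = {}
        out: list[PlantedPair] = []
        for (s, c, interval), pairs in self.edge_blocks.items():
            if s != strain or c != comp:
                continue
            if float(interval[0]) != t and float(interval[1]) != t:
                continue
            for a, b, rho in pairs:
                key = (a, b) if self.panel.index(a) < self.panel.index(b) else (b, a)
                if key in seen:
                    if seen[key] != rho:
                        raise DesignError(
                            f"conflicting planted rho for {key} at shared "
                            f"endpoint {t} h ({strain}/{comp})"
                        )
                    continue
                seen[key] = rho
                out.append((key[0], key[1], rho))
        return out

    def _block_matrix(self, pairs: Sequence[PlantedPair], where: str) -> np.ndarray:
        k = len(self.panel)
        cmat = np.eye(k)
        for a, b, rho in pairs:
            i, j = self.panel.index(a), self.panel.index(b)
            if cmat[i, j] not in (0.0, rho):
                raise DesignError(f"conflicting rho for ({a}, {b}) in {where}")
            cmat[i, j] = cmat[j, i] = rho
        return cmat

    @staticmethod
    def _check_psd(cmat: np.ndarray, where: str) -> None:
        lam = np.linalg.eigvalsh(cmat)
        if lam.min() < -1e-9:
            raise DesignError(
                f"planted correlation matrix not positive semi-definite "
                f"({where}); min eigenvalue {lam.min():.4g}"
            )

    def restrict(self, compartments: Sequence[str]) -> "PlantedDesign":
        """Same design limited to a subset of compartments."""
        comps = tuple(compartments)
        return replace(
            self,
            compartments=comps,
            responders={
                k: v for k, v in self.responders.items() if k[1] in comps
            },
            edge_blocks={
                k: v for k, v in self.edge_blocks.items() if k[1] in comps
            },
        )


@dataclass
class GroundTruth:
    """What was planted: edges per (strain, compartment, interval) and
    responder effect schedules."""

    planted_edges: dict[EdgeBlockKey, list[PlantedPair]]
    responders: dict[tuple[str, str], dict[str, dict[float, float]]]

    def planted_pairs(
        self, strain: str, compartment: str, interval: Interval
    ) -> list[tuple[str, str]]:
        key = (strain, compartment, (float(interval[0]), float(interval[1])))
        return [(a, b) for a, b, _ in self.planted_edges.get(key, [])]


def simulate_cohort(
    design: PlantedDesign, seed: int | np.random.Generator | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort from a planted design; reproducible given a seed.

    For each (strain, compartment, time point) the log-concentrations of the
    n animals are a multivariate normal with the planted correlation matrix
    of that time point (identity off the planted blocks) and mean
    ``log(baseline) + sigma * scaling * effect``; concentrations are the
    exponential, hence strictly positive.
    """
    design.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    sigma = float(np.sqrt(np.log(1.0 + design.noise_cv ** 2)))
    mu0 = float(np.log(design.baseline_mean))
    names = list(design.panel.names)
    k = len(names)

    frames: list[pd.DataFrame] = []
    for strain, scale in design.strains.items():
        n = design.n_per_timepoint[strain]
        # terminal sampling: one animal-id roster per (strain, time), shared
        # across compartments as in the real necropsy design
        rosters = {
            t: [f"{strain}-t{t:g}-{i + 1}" for i in range(n)]
            for t in design.time_points_h
        }
        for comp in design.compartments:
            effects = design.responders.get((strain, comp), {})
            for t in design.time_points_h:
                t = float(t)
                pairs = design._pairs_at(strain, comp, t)
                cmat = design._block_matrix(pairs, f"time {t}")
                root = np.linalg.cholesky(cmat + 1e-12 * np.eye(k))
                z = rng.standard_normal((n, k)) @ root.T
                mean = np.full(k, mu0)
                for m, schedule in effects.items():
                    eff = schedule.get(t, schedule.get(int(t), 0.0))
                    mean[design.panel.index(m)] += sigma * scale * eff
                conc = np.exp(mean[None, :] + sigma * z)
                frames.append(
                    pd.DataFrame(
                        {
                            "strain": strain,
                            "compartment": comp,
                            "time_h": t,
                            "animal_id": np.repeat(rosters[t], k),
                            "mediator": np.tile(names, n),
                            "concentration": conc.ravel(),
                        }
                    )
                )
    table = CohortTable(pd.concat(frames, ignore_index=True), design.panel)
    truth = GroundTruth(
        planted_edges={
            (s, c, (float(i[0]), float(i[1]))): list(v)
            for (s, c, i), v in design.edge_blocks.items()
        },
        responders={k2: {m: dict(sched) for m, sched in v.items()}
                    for k2, v in design.responders.items()},
    )
    return table, truth


# -- canned study-like scenario ---------------------------------------------

def _profile(times: Sequence[float], effect: float) -> dict[float, float]:
    return {float(t): float(effect) for t in times}


def scenario_paperlike(seed: int | None = None) -> PlantedDesign:
    """A canned design reproducing the study's headline qualitative findings.

    Wild-type networks are denser than null in heart, liver, kidney and
    plasma — most extreme in heart — while the null strain carries extra
    edge blocks in gut, lung and spleen at 4–6/12–24 h (negative planted
    correlations in lung, positive in spleen). Responder amplitudes are
    larger and broader in wild-type, so compartment AUC sums are higher in
    wild-type with the largest strain ratio in heart. Rank association
    between IL-17A and GM-CSF and between IL-17A and TNF is planted in
    wild-type plasma and spleen only at 24 and 48 h, confining the
    detectable window signal to 12–48 h.
    """
    responders: dict[tuple[str, str], dict[str, dict[float, float]]] = {}
    blocks: dict[EdgeBlockKey, list[PlantedPair]] = {}

    def respond(strain: str, comp: str, med: str, schedule: Mapping[float, float]):
        sched = responders.setdefault((strain, comp), {}).setdefault(med, {})
        for t, e in schedule.items():
            sched[float(t)] = max(sched.get(float(t), 0.0), float(e))

    def plant(strain: str, comp: str, interval: Interval,
              pairs: Sequence[PlantedPair], effect: float = 3.5):
        key = (strain, comp, (float(interval[0]), float(interval[1])))
        blocks.setdefault(key, []).extend(pairs)
        for a, b, _ in pairs:
            for m in (a, b):
                respond(strain, comp, m, _profile(interval, effect))

    # --- heart: strongly wild-type-dependent, TNF-centred 4-12 h ----------
    plant(WT, "heart", (1, 4), [("IL-1β", "KC", 0.9)])
    plant(WT, "heart", (4, 6), [("TNF", "MIP-1α", 0.9), ("IL-6", "IL-12p40", 0.9)])
    plant(WT, "heart", (6, 12), [("TNF", "MIP-1α", 0.9), ("IL-6", "IL-12p40", 0.9)])
    plant(WT, "heart", (12, 24), [("MCP-1", "IL-10", 0.9)])
    plant(WT, "heart", (24, 48), [("IL-5", "IFN-γ", 0.9)])
    plant(KO, "heart", (6, 12), [("TNF", "MIP-1α", 0.95)], effect=4.0)
    # broad wild-type heart inflammation drives the AUC ratio
    for med in ("IL-1β", "KC", "TNF", "MIP-1α", "IL-6", "IL-12p40",
                "MCP-1", "IL-10", "IL-5", "IFN-γ"):
        respond(WT, "heart", med,
                {1: 2.0, 4: 4.0, 6: 4.0, 12: 4.0, 24: 3.0, 48: 1.5})

    # --- liver / kidney / plasma: wild-type denser, null sparse -----------
    plant(WT, "liver", (1, 4), [("IL-6", "KC", 0.9)])
    plant(WT, "liver", (12, 24), [("IL-1β", "MCP-1", 0.9), ("IL-6", "KC", 0.9)])
    plant(WT, "liver", (24, 48), [("IL-6", "KC", 0.9)])
    plant(KO, "liver", (1, 4), [("IL-6", "KC", 0.95), ("IL-1β", "MCP-1", 0.95)],
          effect=4.0)

    plant(WT, "kidney", (6, 12), [("IP-10", "MIG", 0.9)])
    plant(WT, "kidney", (12, 24), [("IP-10", "MIG", 0.9), ("KC", "MCP-1", 0.9)])
    plant(KO, "kidney", (12, 24), [("IP-10", "MIG", 0.95)], effect=4.0)

    plant(WT, "plasma", (6, 12), [("IL-6", "KC", 0.9)])
    plant(WT, "plasma", (12, 24), [("IL-6", "KC", 0.9)])
    plant(KO, "plasma", (6, 12), [("IL-6", "KC", 0.95)], effect=4.0)
    plant(KO, "plasma", (12, 24), [("IL-6", "KC", 0.95)], effect=4.0)

    # --- gut / lung / spleen: null connectivity matches or exceeds WT -----
    plant(WT, "gut", (4, 6), [("IL-6", "KC", 0.9)])
    plant(KO, "gut", (4, 6), [("IL-6", "KC", 0.95), ("IL-1β", "MCP-1", 0.95)],
          effect=4.0)

    plant(WT, "lung", (6, 12), [("KC", "MCP-1", 0.9)])
    plant(KO, "lung", (12, 24),
          [("IL-10", "TNF", -0.95), ("IL-4", "IFN-γ", -0.95), ("IL-13", "MIG", 0.95)],
          effect=4.0)

    plant(KO, "spleen", (12, 24),
          [("IL-6", "KC", 0.95), ("IL-1β", "MCP-1", 0.95),
           ("IL-10", "MIG", 0.95), ("IL-2", "IL-12p70", 0.95)],
          effect=4.0)

    # --- late pathogenic-Th17-like signature: WT plasma & spleen ----------
    th17 = [("IL-17A", "GM-CSF", 0.85), ("IL-17A", "TNF", 0.85),
            ("GM-CSF", "TNF", 0.85)]
    plant(WT, "plasma", (24, 48), th17)
    plant(WT, "spleen", (24, 48), th17)

    # light wild-type background responses for AUC direction elsewhere
    for comp in ("liver", "kidney", "plasma", "gut", "lung", "spleen"):
        for med in ("IL-1α", "VEGF"):
            respond(WT, comp, med, {4: 2.0, 6: 2.0, 12: 2.0})

    design = PlantedDesign(
        responders=responders,
        edge_blocks=blocks,
        seed=seed,
    )
    design.validate()
    return design
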