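"""Mediator panels and the long-format cohort table.

The study design this package targets is a multiplex immunoassay time
course: two mouse strains, seven sampled compartments (plasma plus six
organs), seven sacrifice time points, and a 20-mediator cytokine/chemokine
panel. Sampling is terminal — each animal contributes exactly one time
point — so every record is keyed by (strain, compartment, time, animal,
mediator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, PanelMembershipError, SchemaError

#: Canonical 20-plex mouse panel (Luminex-style bead kit naming).
DEFAULT_MEDIATORS: tuple[str, ...] = (
    "GM-CSF", "IFN-γ", "IL-1α", "IL-1β", "IL-2", "IL-4", "IL-5", "IL-6",
    "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-17A", "IP-10", "KC",
    "MCP-1", "MIG", "MIP-1α", "TNF", "VEGF",
)

#: Compartments sampled in the study design: plasma plus six organs.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "plasma", "heart", "liver", "kidney", "gut", "lung", "spleen",
)

#: Sacrifice time points, hours post-challenge.
DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 1.0, 4.0, 6.0, 12.0, 24.0, 48.0)

REQUIRED_COLUMNS = (
    "strain", "compartment", "time_h", "animal_id", "mediator", "concentration",
)


def _default_units() -> dict[str, str]:
    units = {c: "pg/mg" for c in DEFAULT_COMPARTMENTS}
    units["plasma"] = "pg/ml"
    return units


@dataclass(frozen=True)
class MediatorPanel:
    """An ordered mediator panel with per-compartment concentration units.

    Parameters
    ----------
    names
        Unique, non-empty mediator identifiers; the order defines the
        canonical node order of every network built from the panel.
    units_by_compartment
        Maps compartment label to its unit string ("pg/ml" for plasma,
        "pg/mg" total protein for tissue compartments).
    """

    names: tuple[str, ...] = DEFAULT_MEDIATORS
    units_by_compartment: Mapping[str, str] = field(default_factory=_default_units)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise PanelMembershipError("panel must contain at least one mediator")
        if any(not n or not str(n).strip() for n in self.names):
            raise PanelMembershipError("panel names must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise PanelMembershipError("panel names must be unique")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def unit(self, compartment: str) -> str:
        return self.units_by_compartment.get(compartment, "pg/ml")

    @classmethod
    def default(cls) -> "MediatorPanel":
        return cls()


class CohortTable:
    """Validated long-format table of mediator concentrations.

    One row per (strain, compartment, time_h, animal_id, mediator); the
    constructor enforces the three structural invariants of the design:

    * at most one concentration per (block, mediator),
    * terminal sampling — each animal appears at exactly one time point
      within its strain,
    * every mediator belongs to the declared panel.

    Missing measurements are absent rows, never sentinel values.
    """

    def __init__(self, frame: pd.DataFrame, panel: MediatorPanel | None = None):
        self.panel = panel if panel is not None else MediatorPanel.default()
        self.frame = self._validate(frame, self.panel)

    @staticmethod
    def _validate(frame: pd.DataFrame, panel: MediatorPanel) -> pd.DataFrame:
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("strain", "compartment", "animal_id", "mediator"):
            df[col] = df[col].astype(str).str.strip()
        df["time_h"] = pd.to_numeric(df["time_h"])
        df["concentration"] = pd.to_numeric(df["concentration"])
        if (df["time_h"] < 0).any():
            bad = sorted(df.loc[df["time_h"] < 0, "time_h"].unique())
            raise ValueError(f"negative time points: {bad}")
        if (df["concentration"] < 0).any():
            n_bad = int((df["concentration"] < 0).sum())
            raise ValueError(f"{n_bad} negative concentration value(s)")
        unknown = sorted(set(df["mediator"]) - set(panel.names))
        if unknown:
            raise PanelMembershipError(
                f"mediator(s) not in panel: {', '.join(unknown)}"
            )
        key = ["strain", "compartment", "time_h", "animal_id", "mediator"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            offenders = df.loc[dup, key].drop_duplicates().head(10)
            raise IntegrityError(
                "duplicate (block, mediator) rows:\n"
                + offenders.to_string(index=False)
            )
        times_per_animal = df.groupby(["strain", "animal_id"])["time_h"].nunique()
        multi = times_per_animal[times_per_animal > 1]
        if not multi.empty:
            raise IntegrityError(
                "terminal sampling violated; animals at multiple time points: "
                + ", ".join(f"{s}/{a}" for s, a in multi.index[:10])
            )
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
        return df

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            self.panel.names == other.panel.names
            and self.frame.equals(other.frame)
        )

    def __repr__(self) -> str:
        return (
            f"CohortTable({len(self.frame)} records, "
            f"{len(self.strains())} strain(s), "
            f"{len(self.compartments())} compartment(s))"
        )

    # -- accessors -----------------------------------------------------------
    def strains(self) -> list[str]:
        return sorted(self.frame["strain"].unique())

    def compartments(self) -> list[str]:
        return sorted(self.frame["compartment"].unique())

    def time_points(self) -> list[float]:
        return sorted(self.frame["time_h"].unique())

    def subset(
        self,
        strain: str | None = None,
        compartment: str | None = None,
        times: Iterable[float] | None = None,
    ) -> pd.DataFrame:
        """Filtered view of the underlying frame (no re-validation)."""
        df = self.frame
        if strain is not None:
            df = df[df["strain"] == strain]
        if compartment is not None:
            df = df[df["compartment"] == compartment]
        if times is not None:
            df = df[df["time_h"].isin(list(times))]
        return df

    def pivot(
        self, strain: str, compartment: str, times: Iterable[float]
    ) -> pd.DataFrame:
        """Animals x mediators matrix for the given times, panel column order.

        Animals missing a mediator get NaN in that column; downstream
        consumers apply their own pairwise-complete-case rules.
        """
        df = self.subset(strain, compartment, times)
        if df.empty:
            return pd.DataFrame(columns=list(self.panel.names))
        wide = df.pivot_table(
            index="animal_id", columns="mediator", values="concentration",
            aggfunc="first",
        )
        wide = wide.reindex(columns=list(self.panel.names))
        return wide.sort_index()

    def group_values(
        self, strain: str, compartment: str, mediator: str, times: Iterable[float]
    ) -> np.ndarray:
        """All concentrations of one mediator pooled over the given times."""
        df = self.subset(strain, compartment, times)
        return df.loc[df["mediator"] == mediator, "concentration"].to_numpy(float)
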