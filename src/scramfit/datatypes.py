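"""Shared data containers: vesicle populations, assay traces, titration points.

Traces are exchanged as plain CSV (columns ``time_s``, ``fluorescence_au``)
with event markers (dithionite addition, light on/off) in a JSON sidecar
named ``<stem>.events.json`` next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

EVENT_DITHIONITE = "dithionite_addition"
EVENT_LIGHT_ON = "light_on"
EVENT_LIGHT_OFF = "light_off"


@dataclass
class VesiclePopulation:
    """A simulated reconstitution: one entry per vesicle.

    radii : vesicle radii (nm)
    scramblase_counts : functional scramblase units per vesicle
    refractory_flags : True for vesicles that cannot accept protein
    lipid_counts : phospholipids per vesicle (sets its fluorescence weight)
    """

    radii: np.ndarray
    scramblase_counts: np.ndarray
    refractory_flags: np.ndarray
    lipid_counts: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.scramblase_counts = np.asarray(self.scramblase_counts, dtype=int)
        self.refractory_flags = np.asarray(self.refractory_flags, dtype=bool)
        self.lipid_counts = np.asarray(self.lipid_counts, dtype=int)
        n = len(self.radii)
        if not (
            len(self.scramblase_counts) == len(self.refractory_flags)
            == len(self.lipid_counts) == n
        ):
            raise InvalidParameterError("population arrays must have equal length")
        if n == 0:
            raise InvalidParameterError("population must be non-empty")
        if np.any(self.radii <= 0):
            raise InvalidParameterError("radii must be positive")
        if np.any(self.scramblase_counts < 0):
            raise InvalidParameterError("scramblase counts must be >= 0")
        if np.any(self.lipid_counts <= 0):
            raise InvalidParameterError("lipid counts must be positive")
        if np.any(self.scramblase_counts[self.refractory_flags] != 0):
            raise InvalidParameterError("refractory vesicles cannot carry scramblases")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def occupied_fraction(self) -> float:
        """Fraction of vesicles carrying at least one functional scramblase."""
        return float(np.mean(self.scramblase_counts >= 1))


@dataclass
class AssayTrace:
    """A time-stamped fluorescence trace with labelled event markers.

    time : strictly increasing sample times (s)
    fluorescence : fluorescence (arbitrary units; finite, >= 0)
    events : label -> event time (s), e.g. ``{"dithionite_addition": 50.0}``
    flags : free-form quality flags raised by simulation or analysis
    """

    time: np.ndarray
    fluorescence: np.ndarray
    events: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.fluorescence):
            raise InvalidParameterError("time and fluorescence must be equal-length 1-D")
        if len(self.time) < 2:
            raise InvalidParameterError("trace needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise InvalidParameterError("fluorescence must be finite")
        for label, t in self.events.items():
            if not (self.time[0] <= t <= self.time[-1]):
                raise InvalidParameterError(
                    f"event {label!r} at t={t} lies outside the trace"
                )

    def to_csv(self, path: str | Path) -> None:
        """Write the trace CSV and its ``.events.json`` sidecar."""
        path = Path(path)
        pd.DataFrame(
            {"time_s": self.time, "fluorescence_au": self.fluorescence}
        ).to_csv(path, index=False)
        sidecar = {"events": self.events, "flags": self.flags}
        path.with_suffix(".events.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssayTrace":
        path = Path(path)
        df = pd.read_csv(path)
        for col in ("time_s", "fluorescence_au"):
            if col not in df.columns:
                raise InvalidParameterError(f"trace CSV is missing column {col!r}")
        events: dict[str, float] = {}
        flags: list[str] = []
        sidecar = path.with_suffix(".events.json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            events = {k: float(v) for k, v in payload.get("events", {}).items()}
            flags = list(payload.get("flags", []))
        return cls(
            time=df["time_s"].to_numpy(),
            fluorescence=df["fluorescence_au"].to_numpy(),
            events=events,
            flags=flags,
        )


@dataclass
class ReconstitutionPoint:
    """One point of a scramblase titration.

    ppr : protein-to-phospholipid ratio (g protein / mol phospholipid)
    ppr_star : PPR corrected for the refractory vesicle pool
    F : percent fluorescence reduction at this PPR
    P : probability of >= 1 scramblase per vesicle, in [0, 1]
    clipped : True if P was clipped into [0, 1] during the transform
    """

    ppr: float
    ppr_star: float
    F: float
    P: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.ppr < 0:
            raise InvalidParameterError("ppr must be >= 0")
        if not 0 <= self.P <= 1:
            raise InvalidParameterError("P must lie in [0, 1] (clip before storing)")


def points_to_frame(points: list[ReconstitutionPoint]) -> pd.DataFrame:
    """Tabulate titration points (columns ppr_g_per_mol, ppr_star_g_per_mol,
    reduction_pct, p_occupied, clipped)."""
    return pd.DataFrame(
        {
            "ppr_g_per_mol": [p.ppr for p in points],
            "ppr_star_g_per_mol": [p.ppr_star for p in points],
            "reduction_pct": [p.F for p in points],
            "p_occupied": [p.P for p in points],
            "clipped": [p.clipped for p in points],
        }
    )
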