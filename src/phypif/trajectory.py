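"""Time-course container shared by every simulation stage.

All species are dimensionless, expressed relative to their dark stationary
level, on a common time grid in days starting at the light switch (t = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

# solver round-off below this magnitude is clipped to zero rather than rejected
_NEG_TOL = 1e-9


@dataclass
class Trajectory:
    """A time grid (days) with one value sequence per species.

    Species names are free-form: ``"phyb"``, ``"pfr"``, ``"pif"`` and one
    entry per gene id for expression trajectories.
    """

    times: np.ndarray
    species: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D grid")
        if self.times[0] != 0.0:
            raise ValueError("time grid must start at 0 (the light switch)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        clean = {}
        for name, values in self.species.items():
            v = np.asarray(values, dtype=float)
            if v.shape != self.times.shape:
                raise ValueError(
                    f"species {name!r} has length {v.size}, grid has {self.times.size}"
                )
            if np.any(v < -_NEG_TOL):
                raise ValueError(f"species {name!r} contains negative values")
            clean[name] = np.clip(v, 0.0, None)
        self.species = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.species[name]

    def __contains__(self, name: str) -> bool:
        return name in self.species

    @property
    def names(self) -> list[str]:
        return list(self.species)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns time_days, species, value."""
        frames = [
            pd.DataFrame(
                {"time_days": self.times, "species": name, "value": values}
            )
            for name, values in self.species.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path, params: dict | None = None) -> None:
        """JSON export with an optional parameter block echoed for provenance."""
        payload = {
            "params": params or {},
            "time_days": self.times.tolist(),
            "species": {k: v.tolist() for k, v in self.species.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
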