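"""Raw landmark observations and their factor annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Factor columns recognised on a :class:`ShapeDataset`.  Each is optional;
#: individual analyses validate the subset they need.
FACTOR_COLUMNS = (
    "individual", "side", "measurement", "line", "population", "sex",
    "temperature_C", "latitude_deg", "species",
)

SIDES = ("left", "right", "none")


@dataclass
class LandmarkConfiguration:
    """A single digitized wing: ``n_landmarks`` two-dimensional landmarks.

    Coordinates are in arbitrary digitizing units; ``side`` records which
    wing of the individual was measured and ``replicate`` the repeated
    measurement number (1-based).
    """

    specimen_id: str
    side: str = "none"
    replicate: int = 1
    coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be (n_landmarks, 2); got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}; got {self.side!r}")
        if self.replicate < 1:
            raise ValueError("replicate numbers are 1-based")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class ShapeDataset:
    """A collection of landmark configurations plus a factor table.

    ``factors`` has one row per observation (same order as ``observations``)
    and any subset of :data:`FACTOR_COLUMNS`.  The landmark count must be
    homogeneous across observations.
    """

    observations: list[LandmarkConfiguration]
    factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("empty dataset")
        counts = {obs.n_landmarks for obs in self.observations}
        if len(counts) != 1:
            raise ValueError(f"heterogeneous landmark counts: {sorted(counts)}")
        if self.factors is None:
            self.factors = pd.DataFrame(
                {
                    "individual": [o.specimen_id for o in self.observations],
                    "side": [o.side for o in self.observations],
                    "measurement": [o.replicate for o in self.observations],
                }
            )
        else:
            self.factors = self.factors.reset_index(drop=True)
            if len(self.factors) != len(self.observations):
                raise ValueError(
                    "factor table must have one row per observation "
                    f"({len(self.factors)} rows vs {len(self.observations)} observations)"
                )
            unknown = set(self.factors.columns) - set(FACTOR_COLUMNS)
            if unknown:
                raise ValueError(f"unknown factor columns: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_landmarks(self) -> int:
        return self.observations[0].n_landmarks

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n_obs, n_landmarks, 2) array."""
        return np.stack([obs.coords for obs in self.observations])

    def check_balanced_replicates(self) -> int:
        """For FA designs: verify each (individual, side) cell has the same
        number of measurement replicates; return that count."""
        for col in ("individual", "side"):
            if col not in self.factors.columns:
                raise ValueError(f"factor column {col!r} required")
        sizes = self.factors.groupby(["individual", "side"], sort=False).size()
        if sizes.nunique() != 1:
            raise ValueError(
                "unbalanced replicate counts per (individual, side) cell: "
                f"{sorted(sizes.unique())}"
            )
        return int(sizes.iloc[0])
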