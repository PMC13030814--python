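"""1-D retinal profiles and their delimited-text I/O.

The analysis substrate is an A-scan-like profile: retinal thickness (or
ellipsoid-zone height) sampled on a uniform lateral grid across the fovea,
as exported from a segmented horizontal B-scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: minimum number of samples for a profile to be measurable
MIN_POINTS = 51

#: tolerance on grid uniformity (µm)
GRID_TOL = 1e-6


class ProfileError(ValueError):
    """Raised for profiles violating the container invariants."""


@dataclass(frozen=True)
class AScanProfile:
    """A 1-D profile: lateral position ``x`` (µm) vs value ``t`` (µm).

    ``x`` must be strictly increasing on a uniform grid with at least
    :data:`MIN_POINTS` samples.  Thickness profiles must be strictly
    positive; ellipsoid-zone *height* profiles may touch zero, so
    positivity is only enforced when ``require_positive`` is set at
    construction time (the default).
    """

    x: np.ndarray
    t: np.ndarray
    require_positive: bool = True

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        if x.ndim != 1 or t.ndim != 1 or x.size != t.size:
            raise ProfileError("x and t must be 1-D arrays of equal length")
        if x.size < MIN_POINTS:
            raise ProfileError(f"profile needs >= {MIN_POINTS} points, got {x.size}")
        dx = np.diff(x)
        if np.any(dx <= 0):
            raise ProfileError("x must be strictly increasing")
        if np.ptp(dx) > GRID_TOL:
            raise ProfileError("x must be uniformly spaced")
        if not np.all(np.isfinite(t)):
            raise ProfileError("t contains non-finite values")
        if self.require_positive and np.any(t <= 0):
            raise ProfileError("thickness must be strictly positive")

    @property
    def step(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def n(self) -> int:
        return int(self.x.size)

    def with_values(self, t: np.ndarray) -> "AScanProfile":
        """Same grid, new values (keeps the positivity policy)."""
        return AScanProfile(self.x, np.asarray(t, float), self.require_positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_um": self.x, "thickness_um": self.t})


def read_profile_csv(path: str | Path, require_positive: bool = True) -> AScanProfile:
    """Read a two-column per-eye profile CSV (``x_um, thickness_um``)."""
    df = pd.read_csv(path)
    missing = {"x_um", "thickness_um"} - set(df.columns)
    if missing:
        raise ProfileError(f"{path}: missing columns {sorted(missing)}")
    return AScanProfile(df["x_um"].to_numpy(), df["thickness_um"].to_numpy(),
                        require_positive)


def write_profile_csv(profile: AScanProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_long_profiles(path: str | Path) -> dict[tuple[str, str, str], AScanProfile]:
    """Read a long-format profile table keyed by participant/laterality/layer.

    Expected columns: ``participant_id, laterality, layer, x_um, value_um``
    with ``layer`` in ``{ILM_thickness, EZ_height}``.
    """
    df = pd.read_csv(path)
    out: dict[tuple[str, str, str], AScanProfile] = {}
    for (pid, lat, layer), g in df.groupby(
            ["participant_id", "laterality", "layer"], sort=False):
        g = g.sort_values("x_um")
        out[(str(pid), str(lat), str(layer))] = AScanProfile(
            g["x_um"].to_numpy(), g["value_um"].to_numpy(),
            require_positive=(layer == "ILM_thickness"))
    return out


def write_long_profiles(profiles: dict[tuple[str, str, str], AScanProfile],
                        path: str | Path) -> None:
    rows = []
    for (pid, lat, layer), prof in profiles.items():
        rows.append(pd.DataFrame({
            "participant_id": pid, "laterality": lat, "layer": layer,
            "x_um": prof.x, "value_um": prof.t}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
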