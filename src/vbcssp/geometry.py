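"""Sensor-array geometry for OPM-MEG helmets.

A :class:`SensorArray` holds one entry per *channel*: a position in metres,
a unit orientation vector (the sensitive axis of that channel), a label, and
the origin of the harmonic expansion.  Multi-axis OPM sensors contribute one
channel per measured axis at the same position.

Synthetic helmets are produced by :func:`build_sensor_array`, which places
sensor sites quasi-uniformly on the upper hemisphere of a sphere (a Fibonacci
lattice) and emits a radial channel plus up to two tangential channels per
site.  Real layouts can be loaded from a CSV via :func:`load_geometry_csv`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SensorArray",
    "InvalidGeometryError",
    "build_sensor_array",
    "load_geometry_csv",
    "save_geometry_csv",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class InvalidGeometryError(ValueError):
    """Raised when sensor geometry violates its invariants."""


@dataclass(frozen=True)
class SensorArray:
    """Channel positions and orientations of an OPM array.

    Parameters
    ----------
    positions : (M, 3) array
        Channel positions in metres.
    orientations : (M, 3) array
        Unit vectors along each channel's sensitive axis.
    channel_ids : sequence of str
        Unique channel labels.
    origin : (3,) array, optional
        Centre of the harmonic expansion, metres.  Defaults to the centroid
        of the sensor positions.
    """

    positions: np.ndarray
    orientations: np.ndarray
    channel_ids: tuple[str, ...]
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        ids = tuple(str(c) for c in self.channel_ids)
        if pos.shape != ori.shape or pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidGeometryError(
                f"positions {pos.shape} and orientations {ori.shape} must both be (M, 3)"
            )
        if pos.shape[0] < 1:
            raise InvalidGeometryError("need at least one channel")
        if len(ids) != pos.shape[0]:
            raise InvalidGeometryError("channel_ids length does not match positions")
        if len(set(ids)) != len(ids):
            raise InvalidGeometryError("channel_ids must be unique")
        if not (np.isfinite(pos).all() and np.isfinite(ori).all()):
            raise InvalidGeometryError("non-finite geometry")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidGeometryError("orientation vectors must have unit norm (1e-9)")
        origin = self.origin
        if origin is None:
            origin = pos.mean(axis=0)
        origin = np.asarray(origin, dtype=float).reshape(3)
        radii = np.linalg.norm(pos - origin, axis=1)
        if np.any(radii <= 0):
            raise InvalidGeometryError("a channel position coincides with the origin")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "channel_ids", ids)
        object.__setattr__(self, "origin", origin)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def centered_positions(self) -> np.ndarray:
        """Positions relative to the expansion origin."""
        return self.positions - self.origin

    def subset(self, mask: np.ndarray) -> "SensorArray":
        """Return the sub-array of channels where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(c for c, keep in zip(self.channel_ids, mask) if keep)
        return SensorArray(self.positions[mask], self.orientations[mask], ids, self.origin)


def _fibonacci_hemisphere(n: int, phase: float) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper (z > 0) hemisphere."""
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n  # in (0, 1): strictly above the equator
    rho = np.sqrt(1.0 - z**2)
    phi = i * _GOLDEN_ANGLE + phase
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _tangent_frame(n_hat: np.ndarray, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangent vectors at radial direction ``n_hat``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n_hat @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(n_hat, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n_hat, t1)
    ca, sa = np.cos(angle), np.sin(angle)
    return ca * t1 + sa * t2, -sa * t1 + ca * t2


def build_sensor_array(
    n_sensors: int,
    axes_per_sensor: int = 3,
    helmet_radius: float = 0.1,
    seed: int = 0,
) -> SensorArray:
    """Build a synthetic helmet of multi-axis OPM sensors.

    Sensor sites are placed quasi-uniformly on the upper hemisphere of a
    sphere of ``helmet_radius`` metres; each site contributes a radial
    channel and, for multi-axis sensors, one or two tangential channels with
    a seeded random roll about the radial axis.  The expansion origin is the
    sphere centre.

    Parameters
    ----------
    n_sensors : int
        Number of sensor sites (>= 4 recommended for stable order-1 bases).
    axes_per_sensor : {1, 2, 3}
        Channels per site: radial, +1 tangential, +2 tangentials.
    helmet_radius : float
        Sphere radius in metres; must be positive.
    seed : int
        Seed for the azimuthal phase and tangential rolls.
    """
    if helmet_radius <= 0:
        raise InvalidGeometryError(f"helmet_radius must be positive, got {helmet_radius}")
    if axes_per_sensor not in (1, 2, 3):
        raise InvalidGeometryError("axes_per_sensor must be 1, 2 or 3")
    if n_sensors < 1:
        raise InvalidGeometryError("n_sensors must be >= 1")
    rng = np.random.default_rng(seed)
    sites = helmet_radius * _fibonacci_hemisphere(n_sensors, phase=rng.uniform(0, 2 * np.pi))
    rolls = rng.uniform(0, 2 * np.pi, size=n_sensors)

    positions, orientations, ids = [], [], []
    axis_names = ("rad", "tan1", "tan2")
    for k in range(n_sensors):
        n_hat = sites[k] / np.linalg.norm(sites[k])
        t1, t2 = _tangent_frame(n_hat, rolls[k])
        for a, ori in zip(axis_names[:axes_per_sensor], (n_hat, t1, t2)):
            positions.append(sites[k])
            orientations.append(ori)
            ids.append(f"S{k:03d}_{a}")
    return SensorArray(
        np.asarray(positions),
        np.asarray(orientations),
        tuple(ids),
        origin=np.zeros(3),
    )


def save_geometry_csv(array: SensorArray, path: str | Path) -> None:
    """Write geometry as CSV (channel_id, x, y, z, ox, oy, oz) + JSON origin sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel_id,x,y,z,ox,oy,oz\n")
        for cid, p, o in zip(array.channel_ids, array.positions, array.orientations):
            fh.write(f"{cid},{p[0]:.12g},{p[1]:.12g},{p[2]:.12g},"
                     f"{o[0]:.17g},{o[1]:.17g},{o[2]:.17g}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"origin": list(map(float, array.origin))}))


def load_geometry_csv(path: str | Path) -> SensorArray:
    """Load geometry written by :func:`save_geometry_csv`; validates invariants."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    required = ["channel_id", "x", "y", "z", "ox", "oy", "oz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidGeometryError(f"geometry CSV missing columns: {missing}")
    origin = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        origin = np.asarray(json.loads(sidecar.read_text())["origin"], dtype=float)
    return SensorArray(
        df[["x", "y", "z"]].to_numpy(float),
        df[["ox", "oy", "oz"]].to_numpy(float),
        tuple(df["channel_id"].astype(str)),
        origin=origin,
    )
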