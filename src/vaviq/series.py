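"""Time-resolved fields on mesh nodes and their HDF5 container.

A :class:`FieldSeries` holds one vector field (displacement in mm,
velocity in mm/s or wall traction in Pa) sampled at a uniform timestep
on every mesh node.  The on-disk container is a single HDF5 file with a
``values`` dataset of shape (n_timesteps, n_nodes, 3) and the timestep /
cardiac period stored as attributes, which is what fluid-structure
solvers can export without an intermediate conversion step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "FieldSeries",
    "VelocityGradientSeries",
    "read_field_series",
    "write_field_series",
    "FIELD_NAMES",
]

FIELD_NAMES = ("displacement", "velocity", "wall_traction")


class SeriesValidationError(ValueError):
    """Raised when a field series violates its invariants."""


@dataclass
class FieldSeries:
    """Per-timestep, per-node 3-vector field with uniform timestep.

    Attributes
    ----------
    field_name : one of 'displacement' (mm), 'velocity' (mm/s),
        'wall_traction' (Pa)
    values : (n_timesteps, n_nodes, 3) float array
    dt : timestep in s
    cycle_length : cardiac period T in s
    """

    field_name: str
    values: np.ndarray
    dt: float
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if self.field_name not in FIELD_NAMES:
            raise SeriesValidationError(
                f"field_name must be one of {FIELD_NAMES}, got {self.field_name!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise SeriesValidationError("values must be (n_timesteps, n_nodes, 3)")
        if not self.dt > 0:
            raise SeriesValidationError("dt must be > 0")
        if self.n_timesteps * self.dt < self.cycle_length - 1e-12:
            raise SeriesValidationError(
                "series shorter than one cardiac cycle: "
                f"{self.n_timesteps} x {self.dt} s < {self.cycle_length} s"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            t_bad = int(np.flatnonzero(bad.any(axis=(1, 2)))[0])
            raise SeriesValidationError(
                f"non-finite values, first offending timestep {t_bad}"
            )

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timesteps) * self.dt

    def steps_per_cycle(self) -> int:
        return int(round(self.cycle_length / self.dt))

    def integer_cycle_window(self) -> int:
        """Number of leading timesteps covering the longest whole number
        of cardiac cycles (used so time averages are cycle averages)."""
        spc = self.steps_per_cycle()
        n_cyc = self.n_timesteps // spc
        if n_cyc < 1:
            raise SeriesValidationError("series shorter than one cycle")
        return n_cyc * spc

    def magnitude(self) -> np.ndarray:
        """(n_timesteps, n_nodes) Euclidean magnitude."""
        return np.linalg.norm(self.values, axis=2)

    def with_values(self, values: np.ndarray) -> "FieldSeries":
        return FieldSeries(self.field_name, values, self.dt, self.cycle_length)


@dataclass
class VelocityGradientSeries:
    """Per-timestep velocity-gradient tensors at sample points.

    values : (n_timesteps, n_points, 3, 3) array, 1/s; entry [i, j] is
        d u_i / d x_j.
    sample_coords : (n_points, 3) in mm.
    """

    values: np.ndarray
    sample_coords: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_coords = np.asarray(self.sample_coords, dtype=float)
        if self.values.ndim != 4 or self.values.shape[2:] != (3, 3):
            raise SeriesValidationError("values must be (n_t, n_points, 3, 3)")
        if not np.isfinite(self.values).all():
            raise SeriesValidationError("velocity gradients contain non-finite entries")


def write_field_series(series: FieldSeries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=series.values)
        ds.attrs["field_name"] = series.field_name
        fh.attrs["dt"] = series.dt
        fh.attrs["cycle_length"] = series.cycle_length
        fh.attrs["units"] = {
            "displacement": "mm",
            "velocity": "mm/s",
            "wall_traction": "Pa",
        }[series.field_name]
    return path


def read_field_series(
    path: str | Path,
    field_name: str | None = None,
    n_nodes: int | None = None,
) -> FieldSeries:
    """Read a field series from the native HDF5 container.

    Parameters
    ----------
    field_name
        Expected field; mismatch with the stored name is an error.
    n_nodes
        When given (typically the mesh node count), enforce agreement.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        if "values" not in fh:
            raise SeriesValidationError(f"{path}: missing 'values' dataset")
        if "dt" not in fh.attrs:
            raise SeriesValidationError(f"{path}: missing 'dt' attribute")
        values = fh["values"][...]
        stored_name = fh["values"].attrs.get("field_name", field_name)
        if isinstance(stored_name, bytes):
            stored_name = stored_name.decode()
        dt = float(fh.attrs["dt"])
        cycle_length = float(fh.attrs.get("cycle_length", 1.0))
    if field_name is not None and stored_name != field_name:
        raise SeriesValidationError(
            f"{path}: stored field {stored_name!r} != requested {field_name!r}"
        )
    series = FieldSeries(stored_name, values, dt, cycle_length)
    if n_nodes is not None and series.n_nodes != n_nodes:
        raise SeriesValidationError(
            f"{path}: series has {series.n_nodes} nodes, mesh has {n_nodes}"
        )
    return series
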