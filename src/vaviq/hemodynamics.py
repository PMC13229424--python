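"""Wall-shear-stress indices and the Q-criterion.

The pipeline consumes wall traction vectors (Pa) exported by the flow
solver rather than recomputing them from volumetric velocity; the
Q-criterion likewise consumes supplied velocity-gradient tensors.

Indices
-------
TAWSS   time-averaged magnitude of the traction vector, Pa
OSI     0.5 * (1 - |mean vector| / mean magnitude), in [0, 0.5];
        0 for unidirectional shear, 0.5 for a fully reversing one
SPI     spectral power index of the traction-magnitude signal (fraction
        of mean-removed power above the vibration cutoff)
Q       0.5 * (||Omega||^2 - ||S||^2) from the velocity-gradient
        decomposition; positive where rotation dominates strain
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import FieldSeries, VelocityGradientSeries
from .spectral import spi as _spi_scalar

__all__ = [
    "WallShearSummary",
    "tawss",
    "osi",
    "wss_spi",
    "q_criterion",
    "summarize_wall_shear",
]


@dataclass
class WallShearSummary:
    tawss: np.ndarray
    osi: np.ndarray
    spi: np.ndarray
    jav_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if (self.tawss < 0).any():
            raise ValueError("TAWSS must be non-negative")
        if (self.osi < -1e-12).any() or (self.osi > 0.5 + 1e-12).any():
            raise ValueError("OSI must lie in [0, 0.5]")
        if (self.spi < -1e-12).any() or (self.spi > 1 + 1e-12).any():
            raise ValueError("SPI must lie in [0, 1]")


def _cycle_values(traction: FieldSeries) -> np.ndarray:
    return traction.values[: traction.integer_cycle_window()]


def tawss(traction: FieldSeries) -> np.ndarray:
    """Per-node time-averaged traction magnitude over whole cycles, Pa."""
    v = _cycle_values(traction)
    return np.linalg.norm(v, axis=2).mean(axis=0)


def osi(traction: FieldSeries) -> np.ndarray:
    """Per-node oscillatory shear index in [0, 0.5].

    OSI = 0.5 * (1 - ||int tau dt|| / int ||tau|| dt); defined as 0
    where the magnitude integral vanishes.
    """
    v = _cycle_values(traction)
    mean_vec = np.linalg.norm(v.mean(axis=0), axis=1)
    mean_mag = np.linalg.norm(v, axis=2).mean(axis=0)
    out = np.zeros(v.shape[1])
    nz = mean_mag > 0
    out[nz] = 0.5 * (1.0 - mean_vec[nz] / mean_mag[nz])
    return np.clip(out, 0.0, 0.5)


def wss_spi(traction: FieldSeries, cutoff_hz: float = 25.0) -> np.ndarray:
    """Per-node SPI of the traction-magnitude signal (mean removed)."""
    mags = np.linalg.norm(_cycle_values(traction), axis=2)
    return np.array(
        [_spi_scalar(mags[:, i], traction.dt, cutoff_hz) for i in range(mags.shape[1])]
    )


def q_criterion(gradients: VelocityGradientSeries) -> np.ndarray:
    """Q = 0.5 * (||Omega||_F^2 - ||S||_F^2) per point per timestep, 1/s^2.

    S and Omega are the symmetric and antisymmetric parts of the
    velocity gradient.  Invariant to uniform translation (gradient
    unchanged) and to orthogonal frame changes.
    """
    g = gradients.values
    s = 0.5 * (g + np.swapaxes(g, -1, -2))
    w = 0.5 * (g - np.swapaxes(g, -1, -2))
    return 0.5 * (
        np.einsum("...ij,...ij->...", w, w) - np.einsum("...ij,...ij->...", s, s)
    )


def summarize_wall_shear(
    traction: FieldSeries,
    cutoff_hz: float = 25.0,
    jav_nodes: np.ndarray | None = None,
) -> WallShearSummary:
    """TAWSS / OSI / SPI maps plus their means over the analysis region."""
    t = tawss(traction)
    o = osi(traction)
    s = wss_spi(traction, cutoff_hz)
    jav = slice(None) if jav_nodes is None else jav_nodes
    means = {
        "tawss": float(t[jav].mean()),
        "osi": float(o[jav].mean()),
        "spi": float(s[jav].mean()),
    }
    return WallShearSummary(tawss=t, osi=o, spi=s, jav_means=means)
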