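"""Synthetic vessel-wall motion with controlled spectral and statistical structure.

Real inputs to the pipeline are fluid-structure-interaction exports for
patient fistulas; this module builds substitutes whose *analysis-level*
behaviour is prescribed, so every downstream stage can be verified
without patient data:

* tube meshes with centerlines standing in for patient geometry,
* displacement series = quasi-static cardiac pulsation + narrowband
  vibration modes localized in the juxta-anastomotic segment + a white
  noise floor,
* group presets emulating the three observed regimes — patency
  (broadband, low-level), stenosis (two narrow bands between 45 and
  100 Hz), dilatation (a single band near 50 Hz),
* traction series and velocity-gradient tensors with closed-form
  shear-index / Q-criterion values.

The vibration component is a sum of two band-limited Gaussian fields:
a near-rigid lateral *sway* of the vessel (carries displacement
amplitude but almost no membrane strain) and a radial *breathing* mode
(whose hoop strain is amplitude/radius).  The two scales are
self-calibrated per vessel, through the actual measurement pipeline,
so the slice-mean time-averaged amplitude and high-pass strain land on
the preset targets within 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .mesh import Centerline, SurfaceMesh
from .series import FieldSeries, VelocityGradientSeries
from .slicing import _project_arclength, assign_nodes_to_slices
from .vibration import MM_TO_UM, highpass_filter, highpass_strain

__all__ = [
    "SyntheticPreset",
    "PatientRecord",
    "GROUP_PRESETS",
    "make_tube",
    "generate_wall_motion",
    "generate_traction_series",
    "generate_velocity_gradients",
    "make_cohort",
    "simulate_slice_table",
]

# Fraction of a group's pooled slice SD attributed to between-patient
# variability (the rest is across-slice, within patient); equal split.
BETWEEN_PATIENT_VAR_FRAC = 0.5


class CalibrationError(RuntimeError):
    """Raised when the generator cannot reach its amplitude/strain targets."""


@dataclass(frozen=True)
class SyntheticPreset:
    """Target spectral and statistical structure for one regime.

    vib_bands entries are (center_hz, full_bandwidth_hz, power_weight);
    the band-limited component is synthesised in the frequency domain
    with raised-cosine edges, so its power is confined to
    [center - bw/2, center + bw/2] up to the 20% edge roll-off.
    Targets are the slice-mean time-averaged high-pass amplitude (um)
    and principal strain (x1e-3) over the juxta-anastomotic extent;
    the *_sd fields are the pooled across-slice SDs of the group.
    """

    group_label: str
    vib_bands: tuple[tuple[float, float, float], ...]
    target_timeavg_amp_um: float
    target_strain_e3: float
    amp_sd_um: float = 0.0
    strain_sd_e3: float = 0.0
    base_pulsation_amp_mm: float = 0.05
    noise_floor_um: float = 0.02
    narrowband: bool = True
    sway_coherence_mm: float = 15.0
    breath_coherence_mm: float = 5.0
    envelope_curvature: float = 0.45
    axial_modulation_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.target_timeavg_amp_um < 0 or self.target_strain_e3 < 0:
            raise ValueError("targets must be >= 0")
        for c, bw, w in self.vib_bands:
            if bw <= 0 or w < 0:
                raise ValueError("bands need positive bandwidth, weight >= 0")


GROUP_PRESETS: dict[str, SyntheticPreset] = {
    # patent fistula: low-level broadband content, no narrow band
    "patency": SyntheticPreset(
        group_label="patency",
        vib_bands=((90.0, 130.0, 1.0),),
        target_timeavg_amp_um=6.6,
        target_strain_e3=0.30,
        amp_sd_um=2.0,
        strain_sd_e3=0.10,
        narrowband=False,
    ),
    # stenosing fistula: two narrow bands inside 45-100 Hz, the lower
    # one carrying most of the power
    "stenosis": SyntheticPreset(
        group_label="stenosis",
        vib_bands=((55.0, 12.0, 0.65), (85.0, 12.0, 0.35)),
        target_timeavg_amp_um=31.7,
        target_strain_e3=1.68,
        amp_sd_um=9.7,
        strain_sd_e3=0.58,
    ),
    # excessively dilating fistula: a single band near 50 Hz
    "dilatation": SyntheticPreset(
        group_label="dilatation",
        vib_bands=((50.0, 10.0, 1.0),),
        target_timeavg_amp_um=15.9,
        target_strain_e3=1.00,
        amp_sd_um=4.8,
        strain_sd_e3=0.35,
    ),
}


@dataclass
class PatientRecord:
    patient_id: str
    group_label: str
    mesh: SurfaceMesh
    centerline: Centerline
    displacement: FieldSeries
    preset: SyntheticPreset | None = None
    diagnostics: dict = field(default_factory=dict)


# ----------------------------------------------------------------- geometry


def make_tube(
    radius_mm: float = 3.5,
    length_mm: float = 30.0,
    n_axial: int = 50,
    n_circ: int = 32,
) -> tuple[SurfaceMesh, Centerline]:
    """Open cylinder along z with outward normals and an axial centerline.

    n_axial rings of n_circ nodes each; 2*(n_axial-1)*n_circ triangles.
    Arclength 0 is the z=0 end (the anastomosis, by convention).
    """
    if radius_mm <= 0 or length_mm <= 0:
        raise ValueError("radius and length must be positive")
    if n_axial < 2 or n_circ < 3:
        raise ValueError("need n_axial >= 2 and n_circ >= 3")
    z = np.linspace(0.0, length_mm, n_axial)
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    coords = np.column_stack(
        [radius_mm * np.cos(tt).ravel(), radius_mm * np.sin(tt).ravel(), zz.ravel()]
    )
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(n_axial * n_circ)]
    )
    tris = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            tris.append([a, b, c])
            tris.append([b, d, c])
    mesh = SurfaceMesh(coords, np.asarray(tris), normals)
    cl_pts = np.column_stack([np.zeros(n_axial), np.zeros(n_axial), z])
    return mesh, Centerline(cl_pts)


# ----------------------------------------------- band-limited field synthesis


def _bandlimited_noise(
    rng: np.random.Generator,
    n_t: int,
    n_cols: int,
    dt: float,
    bands: tuple[tuple[float, float, float], ...],
    coherence_cols: float,
) -> np.ndarray:
    """(n_t, n_cols) zero-mean unit-variance field, band-limited in time,
    Gaussian-correlated across columns with the given coherence length
    (in column units)."""
    white = rng.standard_normal((n_t, n_cols))
    if coherence_cols > 0:
        half = int(np.ceil(3 * coherence_cols))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / coherence_cols) ** 2)
        kern /= np.sqrt(np.sum(kern**2))  # preserve variance
        pad = np.pad(white, ((0, 0), (half, half)), mode="reflect")
        white = _conv_cols(pad, kern)
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_t, dt)
    gain = np.zeros_like(freqs)
    for c, bw, w in bands:
        lo, hi = c - bw / 2.0, c + bw / 2.0
        roll = 0.2 * bw
        g = np.zeros_like(freqs)
        core = (freqs >= lo + roll) & (freqs <= hi - roll)
        g[core] = 1.0
        lo_edge = (freqs >= lo - roll) & (freqs < lo + roll)
        g[lo_edge] = 0.5 * (1 + np.sin(np.pi * (freqs[lo_edge] - lo) / (2 * roll)))
        hi_edge = (freqs > hi - roll) & (freqs <= hi + roll)
        g[hi_edge] = 0.5 * (1 - np.sin(np.pi * (freqs[hi_edge] - hi) / (2 * roll)))
        gain = np.sqrt(gain**2 + w * g**2)
    out = np.fft.irfft(spec * gain[:, None], n=n_t, axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _conv_cols(padded: np.ndarray, kern: np.ndarray) -> np.ndarray:
    from scipy.signal import fftconvolve

    return fftconvolve(padded, kern[None, :], mode="valid", axes=1)


def _envelope(arc: np.ndarray, length: float, curvature: float) -> np.ndarray:
    x = (arc - length / 2.0) / (length / 2.0)
    return np.maximum(1.0 - curvature * x**2, 0.0)


# ------------------------------------------------------------- wall motion


def generate_wall_motion(
    mesh: SurfaceMesh,
    centerline: Centerline,
    preset: SyntheticPreset,
    dt: float = 5e-4,
    n_cycles: int = 3,
    seed: int = 0,
    cycle_length: float = 1.0,
    highpass_cutoff_hz: float = 25.0,
    slice_extent_mm: float = 25.0,
    slice_spacing_mm: float = 1.0,
    calibration_rtol: float = 0.05,
    return_diagnostics: bool = False,
) -> FieldSeries | tuple[FieldSeries, dict]:
    """Synthesize a displacement series matching the preset's targets.

    displacement = cardiac pulsation (radial, harmonics of 1/T, well
    below the cutoff) + lateral sway + radial breathing (both
    band-limited to the preset bands, axially coherent, scaled by a
    smooth axial envelope and a frozen axial modulation) + white noise.
    The sway and breathing scales are calibrated so the slice-mean
    time-averaged high-pass amplitude and strain over the analysis
    extent hit the preset targets; a residual above ``calibration_rtol``
    raises :class:`CalibrationError`.
    """
    max_c = max((c for c, bw, w in preset.vib_bands if w > 0), default=0.0)
    if max_c and dt > 1.0 / (10.0 * max_c):
        raise ValueError(
            f"dt={dt} too coarse for bands up to {max_c} Hz (need dt <= {1/(10*max_c):.2e})"
        )
    for c, bw, w in preset.vib_bands:
        if w > 0 and c <= highpass_cutoff_hz:
            raise CalibrationError(
                f"band center {c} Hz not above the high-pass cutoff "
                f"{highpass_cutoff_hz} Hz"
            )
    rng = np.random.default_rng(seed)
    n_t = int(round(n_cycles * cycle_length / dt))
    n_nodes = mesh.n_nodes

    arc = _project_arclength(mesh.node_coords, centerline)
    env = _envelope(arc, centerline.length, preset.envelope_curvature)
    # frozen multiplicative axial modulation (coherence ~ breathing)
    m_grid = np.arange(0.0, centerline.length + 1.0, 1.0)
    g = rng.standard_normal(m_grid.size)
    half = 15
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / preset.breath_coherence_mm) ** 2)
    kern /= np.sqrt((kern**2).sum())
    g = np.convolve(np.pad(g, half, mode="reflect"), kern, mode="valid")
    modulation = 1.0 + preset.axial_modulation_sd * np.interp(arc, m_grid, g)
    modulation = np.maximum(modulation, 0.3)
    shape = env * modulation

    # axial sample grid for the coherent processes, 1 mm pitch
    grid = np.arange(0.0, centerline.length + 1.0, 1.0)
    col = np.clip(np.searchsorted(grid, arc) - 1, 0, grid.size - 2)
    frac = (arc - grid[col]) / np.diff(grid)[col]

    def field_on_nodes(grid_field: np.ndarray) -> np.ndarray:
        return grid_field[:, col] * (1 - frac) + grid_field[:, col + 1] * frac

    bands = preset.vib_bands
    sway_g = _bandlimited_noise(rng, n_t, grid.size, dt, bands, preset.sway_coherence_mm)
    breath_g = _bandlimited_noise(rng, n_t, grid.size, dt, bands, preset.breath_coherence_mm)

    normals = mesh.node_normals
    if normals is None:
        raise ValueError("mesh must carry outward normals")
    # lateral direction: any unit vector orthogonal to the mean tangent
    tbar = centerline.tangents.mean(axis=0)
    tbar /= np.linalg.norm(tbar)
    lat = np.cross(tbar, [1.0, 0.0, 0.0])
    if np.linalg.norm(lat) < 1e-6:
        lat = np.cross(tbar, [0.0, 1.0, 0.0])
    lat /= np.linalg.norm(lat)

    sway_nodes = field_on_nodes(sway_g) * shape[None, :]       # (n_t, n_nodes)
    breath_nodes = field_on_nodes(breath_g) * shape[None, :]
    noise = rng.standard_normal((n_t, n_nodes, 3)) * (preset.noise_floor_um / MM_TO_UM)

    slice_map = assign_nodes_to_slices(mesh, centerline, slice_extent_mm, slice_spacing_mm)

    def vec(sc_lat: np.ndarray | None, sc_rad: np.ndarray | None, with_noise: bool):
        out = np.zeros((n_t, n_nodes, 3))
        if sc_lat is not None:
            out += sc_lat[:, :, None] * lat[None, None, :]
        if sc_rad is not None:
            out += sc_rad[:, :, None] * normals[None, :, :]
        if with_noise:
            out += noise
        return out

    spc = int(round(cycle_length / dt))
    n_used = (n_t // spc) * spc

    def measure(values: np.ndarray) -> tuple[float, float]:
        """Slice-mean time-averaged amplitude (um) and strain (x1e-3)."""
        mags = np.linalg.norm(values[:n_used], axis=2)
        amp = mags.mean(axis=0) * MM_TO_UM
        series = FieldSeries("displacement", values[:n_used], dt, cycle_length)
        strain = highpass_strain(mesh, series) * 1e3
        sel = slice_map >= 0
        amp_slices = _per_slice_mean(amp, slice_map)
        strain_slices = _per_slice_mean(strain, slice_map)
        return float(np.mean(amp_slices)), float(np.mean(strain_slices))

    amp_t = preset.target_timeavg_amp_um
    strain_t = preset.target_strain_e3
    radius_est = float(np.median(_node_radius(mesh, centerline)))
    if radius_est * strain_t * 1e-3 * MM_TO_UM > 0.9 * amp_t:
        raise CalibrationError(
            "strain target needs a breathing amplitude "
            f"(~{radius_est * strain_t:.2f} um) incompatible with the "
            f"amplitude target ({amp_t} um)"
        )

    # unit-scale component measurements (um-scale working amplitude)
    unit = 10.0 / MM_TO_UM  # 10 um in mm
    amp_s1, strain_s1 = measure(vec(unit * sway_nodes, None, False))
    amp_b1, strain_b1 = measure(vec(None, unit * breath_nodes, False))
    amp_n, strain_n = measure(vec(None, None, True)) if preset.noise_floor_um > 0 else (0.0, 0.0)

    if amp_t == 0:
        a_s = a_b = 0.0
    else:
        # quadrature model: |sum| of independent Gaussians adds in rms
        a_b = math.sqrt(
            max(strain_t**2 - strain_n**2, 0.0)
        ) / strain_b1 if strain_b1 > 0 else 0.0
        a_s = math.sqrt(
            max(amp_t**2 - (a_b * amp_b1) ** 2 - amp_n**2, (0.05 * amp_t) ** 2)
        ) / amp_s1

    diag = {"iterations": []}
    pulsation = _pulsation(mesh, n_t, dt, cycle_length, preset.base_pulsation_amp_mm)

    for it in range(6):
        total = vec(unit * a_s * sway_nodes, unit * a_b * breath_nodes, True)
        total += pulsation
        series = FieldSeries("displacement", total, dt, cycle_length)
        hp = highpass_filter(series, highpass_cutoff_hz)
        amp_m, strain_m = measure(hp.values)
        diag["iterations"].append({"amp_um": amp_m, "strain_e3": strain_m})
        amp_err = abs(amp_m - amp_t) / amp_t if amp_t else 0.0
        strain_err = abs(strain_m - strain_t) / strain_t if strain_t else 0.0
        if amp_err <= 0.02 and strain_err <= 0.02:
            break
        if strain_t and strain_m > 0:
            a_b *= strain_t / strain_m
        if amp_t and amp_m > 0:
            contrib_b = a_b * amp_b1
            target_sq = amp_t**2 - contrib_b**2 - amp_n**2
            meas_s_sq = max(amp_m**2 - contrib_b**2 - amp_n**2, 1e-12)
            a_s *= math.sqrt(max(target_sq, (0.02 * amp_t) ** 2) / meas_s_sq)
    else:
        if amp_err > calibration_rtol or strain_err > calibration_rtol:
            raise CalibrationError(
                f"calibration did not converge: amp {amp_m:.2f}/{amp_t} um, "
                f"strain {strain_m:.3f}/{strain_t} x1e-3"
            )

    diag.update(
        amp_um=amp_m, strain_e3=strain_m,
        amp_target_um=amp_t, strain_target_e3=strain_t,
        sway_scale_um=unit * a_s * MM_TO_UM, breath_scale_um=unit * a_b * MM_TO_UM,
    )
    out = FieldSeries("displacement", total, dt, cycle_length)
    return (out, diag) if return_diagnostics else out


def _per_slice_mean(values: np.ndarray, slice_map: np.ndarray) -> np.ndarray:
    n_sl = slice_map.max() + 1
    num = np.bincount(slice_map[slice_map >= 0], weights=values[slice_map >= 0], minlength=n_sl)
    den = np.bincount(slice_map[slice_map >= 0], minlength=n_sl)
    return num[den > 0] / den[den > 0]


def _node_radius(mesh: SurfaceMesh, centerline: Centerline) -> np.ndarray:
    arc = _project_arclength(mesh.node_coords, centerline)
    pts = np.empty_like(mesh.node_coords)
    for k in range(3):
        pts[:, k] = np.interp(arc, centerline.arclength, centerline.points[:, k])
    return np.linalg.norm(mesh.node_coords - pts, axis=1)


def _pulsation(
    mesh: SurfaceMesh, n_t: int, dt: float, cycle_length: float, amp_mm: float
) -> np.ndarray:
    """Quasi-static radial cardiac pulsation: harmonics of 1/T up to 3/T."""
    t = np.arange(n_t) * dt
    f1 = 1.0 / cycle_length
    wave = (
        0.6 * np.sin(2 * np.pi * f1 * t)
        + 0.3 * np.sin(4 * np.pi * f1 * t + 0.7)
        + 0.1 * np.sin(6 * np.pi * f1 * t + 1.3)
    )
    return amp_mm * wave[:, None, None] * mesh.node_normals[None, :, :]


# ------------------------------------------------------------ traction & Q


def generate_traction_series(
    mesh: SurfaceMesh,
    regime: str,
    dt: float = 5e-4,
    n_cycles: int = 3,
    seed: int = 0,
    cycle_length: float = 1.0,
    magnitude_pa: float = 1.5,
    pulsatile_frac: float = 0.5,
    hf_power_frac: float = 0.3,
    cutoff_hz: float = 25.0,
) -> FieldSeries:
    """Wall-traction stand-ins with closed-form index values.

    steady           constant axial traction (TAWSS = magnitude, OSI = 0)
    oscillatory      zero-mean sinusoid at the cardiac frequency (OSI = 0.5)
    turbulent_like   pulsatile mean plus supra-cutoff broadband noise whose
                     share of the mean-removed power is ``hf_power_frac``
                     (SPI of the magnitude signal ~ hf_power_frac)
    """
    n_t = int(round(n_cycles * cycle_length / dt))
    t = np.arange(n_t) * dt
    axis = np.array([0.0, 0.0, 1.0])
    if regime == "steady":
        sig = np.full(n_t, magnitude_pa)
    elif regime == "oscillatory":
        sig = magnitude_pa * np.sin(2 * np.pi * t / cycle_length)
    elif regime == "turbulent_like":
        if not (0 <= hf_power_frac < 1):
            raise ValueError("hf_power_frac must lie in [0, 1)")
        rng = np.random.default_rng(seed)
        puls = pulsatile_frac * magnitude_pa * np.sin(2 * np.pi * t / cycle_length)
        lf_power = np.mean(puls**2)
        white = rng.standard_normal(n_t)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_t, dt)
        spec[freqs <= cutoff_hz] = 0.0
        spec[freqs > 8 * cutoff_hz] = 0.0
        hf = np.fft.irfft(spec, n=n_t)
        hf *= math.sqrt(lf_power * hf_power_frac / (1 - hf_power_frac)) / hf.std()
        sig = magnitude_pa + puls + hf
    else:
        raise ValueError(f"unknown regime {regime!r}")
    values = sig[:, None, None] * axis[None, None, :] * np.ones((1, mesh.n_nodes, 1))
    return FieldSeries("wall_traction", values, dt, cycle_length)


def generate_velocity_gradients(
    regime: str, omega_or_gamma: float = 1.0, n_points: int = 4
) -> VelocityGradientSeries:
    """Analytic constant velocity-gradient tensors for Q-criterion checks."""
    a = omega_or_gamma
    if regime == "solid_rotation":
        g = np.array([[0.0, -a, 0.0], [a, 0.0, 0.0], [0.0, 0.0, 0.0]])
    elif regime == "simple_shear":
        g = np.array([[0.0, a, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    elif regime == "pure_extension":
        g = np.diag([a, -a, 0.0])
    else:
        raise ValueError(f"unknown regime {regime!r}")
    values = np.broadcast_to(g, (1, n_points, 3, 3)).copy()
    coords = np.zeros((n_points, 3))
    return VelocityGradientSeries(values=values, sample_coords=coords, dt=1.0)


# ------------------------------------------------------------------ cohorts


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd
    return float(sp_stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def make_cohort(
    n_per_group: int | dict[str, int] = 2,
    presets: dict[str, SyntheticPreset] | None = None,
    seed: int = 0,
    dt: float = 5e-4,
    n_cycles: int = 3,
    radius_mm: float = 3.5,
    length_mm: float = 30.0,
    n_axial: int = 50,
    n_circ: int = 32,
    cycle_length: float = 1.0,
) -> list[PatientRecord]:
    """Six-patient style cohort: per-patient amplitude/strain targets are
    drawn from the group mean +/- between-patient SD (normal truncated at
    zero) and the wall-motion generator is calibrated to each draw, so
    slice-level statistics reproduce the group numbers in expectation."""
    presets = dict(presets or GROUP_PRESETS)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in presets}
    rng = np.random.default_rng(seed)
    records = []
    prefix = {"patency": "P", "stenosis": "S", "dilatation": "D"}
    for group, n in n_per_group.items():
        if n < 1:
            raise ValueError("n_per_group must be >= 1 for every requested group")
        preset = presets[group]
        b_frac = math.sqrt(BETWEEN_PATIENT_VAR_FRAC)
        for i in range(n):
            amp_i = _truncated_normal(rng, preset.target_timeavg_amp_um, b_frac * preset.amp_sd_um)
            strain_i = _truncated_normal(rng, preset.target_strain_e3, b_frac * preset.strain_sd_e3)
            p_i = replace(
                preset, target_timeavg_amp_um=amp_i, target_strain_e3=strain_i
            )
            mesh, cl = make_tube(radius_mm, length_mm, n_axial, n_circ)
            series, diag = generate_wall_motion(
                mesh,
                cl,
                p_i,
                dt=dt,
                n_cycles=n_cycles,
                seed=int(rng.integers(2**31 - 1)),
                cycle_length=cycle_length,
                return_diagnostics=True,
            )
            pid = f"{prefix.get(group, group[:1].upper())}{i + 1}"
            records.append(
                PatientRecord(pid, group, mesh, cl, series, preset=p_i, diagnostics=diag)
            )
    return records


def simulate_slice_table(
    n_per_group: int | dict[str, int] = 2,
    presets: dict[str, SyntheticPreset] | None = None,
    seed: int = 0,
    n_slices: int = 25,
    spacing_mm: float = 1.0,
) -> pd.DataFrame:
    """Slice-table-level simulation of the cohort's statistical model.

    Draws the same patient-level targets as :func:`make_cohort` and
    adds across-slice variation directly, without field synthesis — the
    patient/slice variance structure the field generator is calibrated
    to.  Used for simulation studies (type-I error, power) where
    hundreds of cohorts are needed.
    """
    presets = dict(presets or GROUP_PRESETS)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in presets}
    rng = np.random.default_rng(seed)
    b_frac = math.sqrt(BETWEEN_PATIENT_VAR_FRAC)
    w_frac = math.sqrt(1.0 - BETWEEN_PATIENT_VAR_FRAC)
    prefix = {"patency": "P", "stenosis": "S", "dilatation": "D"}
    rows = []
    for group, n in n_per_group.items():
        preset = presets[group]
        for i in range(n):
            pid = f"{prefix.get(group, group[:1].upper())}{i + 1}"
            amp_i = _truncated_normal(rng, preset.target_timeavg_amp_um, b_frac * preset.amp_sd_um)
            strain_i = _truncated_normal(rng, preset.target_strain_e3, b_frac * preset.strain_sd_e3)
            for metric, mean_i, sd_w in (
                ("amp_um", amp_i, w_frac * preset.amp_sd_um),
                ("strain_e3", strain_i, w_frac * preset.strain_sd_e3),
            ):
                vals = mean_i + sd_w * rng.standard_normal(n_slices)
                vals = np.maximum(vals, 0.05 * max(mean_i, 1e-9))
                for k in range(n_slices):
                    rows.append(
                        {
                            "patient_id": pid,
                            "group_label": group,
                            "slice_index": k,
                            "arclength_mm": (k + 0.5) * spacing_mm,
                            "metric_name": metric,
                            "mean_value": vals[k],
                        }
                    )
    return pd.DataFrame(rows)
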