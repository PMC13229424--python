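"""Pipeline-wide configuration.

Units are fixed repo-wide: lengths in mm, time in s, traction in Pa,
frequency in Hz.  Displacement *amplitudes* are reported in micrometres
(x1000 from mm) because wall vibrations are three orders of magnitude
smaller than the vessel geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Knobs shared by every stage of the vibration-quantification pipeline.

    Parameters
    ----------
    highpass_cutoff_hz
        Cutoff separating quasi-static cardiac motion from vibration.
        Everything below is "wall motion", everything above is "vibration".
    percentile_q
        Spatial percentile used for the per-timestep vibration trace
        (robust maximum over the wall).
    slice_extent_mm
        Length of the juxta-anastomotic vein segment that is sliced,
        measured as arclength from the anastomosis.
    slice_spacing_mm
        Slice thickness; ``extent/spacing`` slices per vessel.
    spectrogram_window_s, spectrogram_overlap_frac
        Short-time-Fourier window length and fractional overlap.  The
        0.1 s default gives 10 Hz resolution, enough to separate the
        45-65 Hz and 70-100 Hz stenotic bands.
    band_threshold_db
        Detection threshold for narrowband vibration modes, in dB of
        per-bin power re 1 mm^2 of the analysis trace.
    band_detection_window_s
        Window for the time-averaged detection spectrum.  Longer than
        the display window: at 10 Hz resolution the Hann main lobe
        bridges the gap between the two stenotic bands, so detection
        runs at 2.5 Hz resolution by default.
    dynamic_viscosity_pa_s
        Blood dynamic viscosity; carried for traction-from-gradient
        conversions by callers, unused by the shear indices themselves.
    rng_seed
        Seed for every stochastic stage (synthesis, permutation tests).
    """

    highpass_cutoff_hz: float = 25.0
    percentile_q: float = 99.0
    slice_extent_mm: float = 25.0
    slice_spacing_mm: float = 1.0
    spectrogram_window_s: float = 0.1
    spectrogram_overlap_frac: float = 0.9
    band_threshold_db: float = -48.0
    band_min_width_hz: float = 5.0
    band_min_gap_hz: float = 12.0
    band_detection_window_s: float = 0.4
    dynamic_viscosity_pa_s: float = 3.5e-3
    cycle_length_s: float = 1.0
    area_weighted_slices: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.highpass_cutoff_hz <= 0:
            raise ValueError("highpass_cutoff_hz must be > 0")
        if not (0 < self.percentile_q <= 100):
            raise ValueError("percentile_q must lie in (0, 100]")
        if self.slice_spacing_mm <= 0 or self.slice_spacing_mm > self.slice_extent_mm:
            raise ValueError("slice_spacing_mm must be > 0 and <= slice_extent_mm")
        if not (0 <= self.spectrogram_overlap_frac < 1):
            raise ValueError("spectrogram_overlap_frac must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
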