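"""End-to-end orchestration: synthesize or ingest, quantify, aggregate,
compare, report.

A run is fully described by its manifest: the configuration snapshot,
the seed, hashes of any ingested inputs and the paths of every output.
Rerunning with the same manifest reproduces the numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .mesh import read_surface_mesh
from .series import read_field_series
from .slicing import assign_nodes_to_slices, slice_means
from .spectral import detect_bands, detection_spectrum, spectrogram
from .stats import GroupComparisonModel, summarize_groups
from .synthetic import GROUP_PRESETS, PatientRecord, make_cohort
from .vibration import highpass_filter, summarize_vibration

log = logging.getLogger("vaviq")

SLICE_COLUMNS = [
    "patient_id",
    "group_label",
    "slice_index",
    "arclength_mm",
    "metric_name",
    "mean_value",
]


@dataclass
class RunManifest:
    config: dict
    seed: int
    tool_version: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_patient(
    record: PatientRecord, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Vibration metrics, slice means and band detection for one vessel."""
    vib = summarize_vibration(
        record.mesh,
        record.displacement,
        cutoff_hz=config.highpass_cutoff_hz,
        percentile_q=config.percentile_q,
    )
    slice_map = assign_nodes_to_slices(
        record.mesh, record.centerline, config.slice_extent_mm, config.slice_spacing_mm
    )
    weights = record.mesh.node_areas() if config.area_weighted_slices else None
    table = slice_means(
        {"amp_um": vib.amp_map, "strain_e3": vib.strain_map * 1e3},
        slice_map,
        spacing_mm=config.slice_spacing_mm,
        patient_id=record.patient_id,
        group_label=record.group_label,
        node_weights=weights,
    )
    # analysis-region spatial-mean displacement vector for the spectrogram
    hp = highpass_filter(record.displacement, config.highpass_cutoff_hz)
    jav = slice_map >= 0
    trace = hp.values[:, jav, :].mean(axis=1)
    det = detection_spectrum(trace, hp.dt, window_s=config.band_detection_window_s)
    bands = detect_bands(
        det,
        threshold_db=config.band_threshold_db,
        min_width_hz=config.band_min_width_hz,
        min_gap_hz=config.band_min_gap_hz,
        f_min_hz=config.highpass_cutoff_hz,
    )
    summary = {
        "patient_id": record.patient_id,
        "group_label": record.group_label,
        "peak_amp_um": vib.peak_amp_um,
        "cycleavg_amp_um": vib.cycleavg_amp_um,
        "bands": bands.to_dict(),
    }
    return table, summary


def run_pipeline(
    config: PipelineConfig,
    input_spec: dict,
    out_dir: str | Path,
) -> RunManifest:
    """Execute the post-solver pipeline and write the report.

    ``input_spec`` is either ``{"synthetic": {...make_cohort kwargs...}}``
    or ``{"patients": [{"patient_id", "group_label", "mesh", "displacement"},
    ...]}`` with file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed,
                           tool_version=__version__)

    stage = "ingest"
    try:
        if "synthetic" in input_spec:
            kwargs = dict(input_spec["synthetic"])
            kwargs.setdefault("seed", config.rng_seed)
            kwargs.setdefault("cycle_length", config.cycle_length_s)
            log.info("stage %s: synthesizing cohort %s", stage, kwargs)
            records = make_cohort(**kwargs)
        else:
            records = []
            for spec in input_spec["patients"]:
                mesh = read_surface_mesh(spec["mesh"])
                series = read_field_series(
                    spec["displacement"], "displacement", n_nodes=mesh.n_nodes
                )
                from .mesh import Centerline

                cl_pts = np.loadtxt(spec["centerline"], ndmin=2)
                records.append(
                    PatientRecord(
                        spec["patient_id"],
                        spec.get("group_label", "unknown"),
                        mesh,
                        Centerline(cl_pts),
                        series,
                    )
                )
                for key in ("mesh", "displacement", "centerline"):
                    manifest.input_hashes[f"{spec['patient_id']}:{key}"] = _sha256(
                        Path(spec[key])
                    )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "vibration"
    tables, summaries = [], []
    try:
        for rec in records:
            log.info("stage %s: patient %s", stage, rec.patient_id)
            table, summary = analyze_patient(rec, config)
            tables.append(table)
            summaries.append(summary)
        slice_table = pd.concat(tables, ignore_index=True)[SLICE_COLUMNS]
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "stats"
    try:
        group_summary = summarize_groups(slice_table)
        stats_out = {}
        n_groups = slice_table["group_label"].nunique()
        for response in ("amp_um", "strain_e3"):
            stats_out[response] = {}
            designs = ["two_group"] + (["three_group"] if n_groups >= 3 else [])
            for design in designs:
                res = GroupComparisonModel(slice_table, response, design).fit()
                stats_out[response][design] = res.to_dict()
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "report"
    try:
        paths = write_report_tables(
            out_dir,
            slice_table=slice_table,
            group_summary=group_summary,
            stats=stats_out,
            band_summaries=summaries,
        )
        manifest.outputs = {k: str(v) for k, v in paths.items()}
        manifest.write(out_dir / "manifest.json")
        manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    return manifest


def write_report_tables(
    out_dir: str | Path,
    slice_table: pd.DataFrame,
    group_summary: pd.DataFrame | None = None,
    stats: dict | None = None,
    band_summaries: list | None = None,
    correlations: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """CSV tables plus one JSON summary, deterministic column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    slice_path = out_dir / "slices.csv"
    if slice_table.empty:
        slice_table = pd.DataFrame(columns=SLICE_COLUMNS)
    cols = [c for c in SLICE_COLUMNS if c in slice_table.columns]
    slice_table.to_csv(slice_path, index=False, columns=cols or None)
    paths["slices"] = slice_path
    if group_summary is not None:
        p = out_dir / "group_summary.csv"
        group_summary.to_csv(p, index=False)
        paths["group_summary"] = p
    if correlations is not None:
        p = out_dir / "correlations.csv"
        correlations.to_csv(p, index=False)
        paths["correlations"] = p
    summary = {
        "n_patients": int(slice_table["patient_id"].nunique()) if not slice_table.empty else 0,
        "groups": sorted(slice_table["group_label"].unique().tolist())
        if not slice_table.empty
        else [],
        "stats": stats or {},
        "patients": band_summaries or [],
    }
    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    paths["summary"] = p
    return paths
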