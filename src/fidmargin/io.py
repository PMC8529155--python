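"""File formats: NIfTI phase volumes, trace/trajectory CSV, config YAML.

World axes are (x = R-L, y = A-P, z = I-S) in mm; volumes are written as
NIfTI with a diagonal affine carrying spacing and origin.  Traces and
trajectories travel as plain CSV:

* trace CSV:       object_id, phase, dx_mm, dy_mm, dz_mm
* trajectory CSV:  marker_id, phase, dx_mm, dy_mm, dz_mm, mi
* detections JSON: list of {id, label, centroid_mm, voxel_count, peak_hu}
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .detection import MarkerDetection
from .phantom import (GtvSpec, MarkerSpec, MotionModel, MotionTrace,
                      PhantomSpec, PhaseVolume, Volume4D, analytic_trace)
from .tracking import TemplateConfig, Trajectory

__all__ = [
    "write_volume", "read_volume", "write_volume4d", "read_volume4d",
    "write_traces_csv", "read_traces_csv",
    "write_trajectories_csv", "read_trajectories_csv",
    "write_detections_json", "read_detections_json",
    "phantom_spec_from_dict", "load_run_config", "RunConfig",
]


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def write_volume(volume: PhaseVolume, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data, np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> PhaseVolume:
    img = nib.load(str(path))
    affine = img.affine
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    return PhaseVolume(data=data, spacing=spacing, origin=origin)


def phase_filenames(n_phases: int) -> list[str]:
    return [f"phase_{k * 100 // n_phases:02d}.nii.gz" for k in range(n_phases)]


def write_volume4d(volumes: Volume4D, out_dir,
                   spec: Optional[PhantomSpec] = None) -> list[Path]:
    """Write one NIfTI per phase plus a JSON sidecar with the generating
    spec and its analytic ground-truth traces (when a spec is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, vol in zip(phase_filenames(volumes.n_phases), volumes):
        p = out / name
        write_volume(vol, p)
        paths.append(p)
    if spec is not None:
        sidecar = {
            "phantom_spec": _spec_to_jsonable(spec),
            "ground_truth_traces": {
                f"marker_{i + 1}": analytic_trace(
                    mk.motion, spec.n_phases).displacement_mm.tolist()
                for i, mk in enumerate(spec.marker_specs)
            },
        }
        if spec.gtv_spec is not None:
            sidecar["ground_truth_traces"]["gtv"] = analytic_trace(
                spec.gtv_spec.motion, spec.n_phases).displacement_mm.tolist()
        (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def read_volume4d(in_dir) -> Volume4D:
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob("phase_*.nii.gz")) or sorted(
        in_dir.glob("phase_*.nii"))
    if len(files) < 2:
        raise FileNotFoundError(
            f"no phase_*.nii[.gz] volumes found in {in_dir}")
    return Volume4D(phases=[read_volume(f) for f in files])


def _spec_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _spec_to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _spec_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_spec_to_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
# traces / trajectories / detections
# --------------------------------------------------------------------------

def write_traces_csv(traces: Sequence[MotionTrace], path) -> None:
    rows = []
    for tr in traces:
        for k, d in enumerate(tr.displacement_mm):
            rows.append({"object_id": tr.object_id, "phase": k,
                         "dx_mm": d[0], "dy_mm": d[1], "dz_mm": d[2]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_traces_csv(path) -> list[MotionTrace]:
    df = pd.read_csv(path)
    traces = []
    for oid, grp in df.groupby("object_id", sort=False):
        grp = grp.sort_values("phase")
        traces.append(MotionTrace(
            object_id=str(oid),
            displacement_mm=grp[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(),
        ))
    return traces


def write_trajectories_csv(trajectories: Sequence[Trajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for k in range(tr.n_phases):
            d = tr.displacement_mm[k]
            rows.append({"marker_id": tr.marker_id, "phase": k,
                         "dx_mm": d[0], "dy_mm": d[1], "dz_mm": d[2],
                         "mi": tr.mi_score[k]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_trajectories_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for mid, grp in df.groupby("marker_id", sort=False):
        grp = grp.sort_values("phase")
        disp = grp[["dx_mm", "dy_mm", "dz_mm"]].to_numpy()
        out.append(Trajectory(
            marker_id=int(mid),
            displacement_mm=disp,
            mi_score=grp["mi"].to_numpy(),
            failed_phases=[int(k) for k in
                           np.nonzero(np.isnan(disp).any(axis=1))[0]],
        ))
    return out


def trajectories_to_traces(trajectories: Sequence[Trajectory]) -> list[MotionTrace]:
    """View trajectories as motion traces keyed "marker_<id>"."""
    return [MotionTrace(object_id=f"marker_{tr.marker_id}",
                        displacement_mm=tr.displacement_mm)
            for tr in trajectories]


def write_detections_json(detections: Sequence[MarkerDetection], path) -> None:
    payload = [
        {"id": d.id, "label": d.label,
         "centroid_mm": np.asarray(d.centroid_mm).tolist(),
         "voxel_count": d.voxel_count, "peak_hu": d.peak_hu}
        for d in detections
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_detections_json(path) -> list[MarkerDetection]:
    payload = json.loads(Path(path).read_text())
    return [
        MarkerDetection(id=d["id"], centroid_mm=np.asarray(d["centroid_mm"]),
                        voxel_count=d["voxel_count"], peak_hu=d["peak_hu"],
                        label=d.get("label"))
        for d in payload
    ]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _motion_from_dict(d: Optional[dict]) -> MotionModel:
    if not d:
        return MotionModel()
    kind = d.get("kind", "cos4")
    if kind == "custom_per_phase":
        return MotionModel(kind=kind, table=np.asarray(d["table"], float))
    return MotionModel(
        kind="cos4",
        b=d.get("b", (0.0, 0.0, 0.0)),
        tau=d.get("tau", 4.0),
        z0=d.get("z0", (0.0, 0.0, 0.0)),
        phase_lag=d.get("phase_lag", (0.0, 0.0, 0.0)),
    )


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    markers = [
        MarkerSpec(
            rest_center_mm=m["rest_center_mm"],
            diameter_mm=m.get("diameter_mm", 1.0),
            length_mm=m.get("length_mm", 3.0),
            hu_value=m.get("hu_value", 3000.0),
            motion=_motion_from_dict(m.get("motion")),
        )
        for m in d.get("marker_specs", [])
    ]
    gtv = None
    if d.get("gtv_spec"):
        g = d["gtv_spec"]
        gtv = GtvSpec(
            center_mm=g["center_mm"],
            radius_mm=g.get("radius_mm", 8.0),
            hu_value=g.get("hu_value", 0.0),
            motion=_motion_from_dict(g.get("motion")),
        )
    kwargs = {k: d[k] for k in
              ("grid_shape", "spacing_mm", "background_hu", "n_phases",
               "noise_sigma_hu", "seed", "origin_mm", "psf_sigma_mm")
              if k in d}
    return PhantomSpec(marker_specs=markers, gtv_spec=gtv, **kwargs)


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (see the YAML schema in README)."""

    phantom: Optional[PhantomSpec] = None
    phases_dir: Optional[str] = None
    gtv_trace_csv: Optional[str] = None
    template: TemplateConfig = dataclasses.field(default_factory=TemplateConfig)
    threshold_hu: float = 1500.0
    min_voxels: int = 2
    amplitude_method: str = "cycle_mean"
    seed: int = 0
    verbosity: int = 0


def load_run_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "phantom" in d:
        cfg.phantom = phantom_spec_from_dict(d["phantom"])
    if "template" in d:
        cfg.template = TemplateConfig(**d["template"])
    for k in ("phases_dir", "gtv_trace_csv", "threshold_hu", "min_voxels",
              "amplitude_method", "seed", "verbosity"):
        if k in d:
            setattr(cfg, k, d[k])
    if cfg.phases_dir and not Path(cfg.phases_dir).exists():
        raise FileNotFoundError(f"phases_dir does not exist: {cfg.phases_dir}")
    if cfg.gtv_trace_csv and not Path(cfg.gtv_trace_csv).exists():
        raise FileNotFoundError(
            f"gtv_trace_csv does not exist: {cfg.gtv_trace_csv}")
    return cfg
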