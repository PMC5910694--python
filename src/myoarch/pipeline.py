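"""End-to-end orchestration: tensors -> geometry -> tracking -> fascicles -> records.

``analyze_scan`` is the in-memory core used by the CLI, the tests and the
acceptance runs; ``run_pipeline`` wraps it with file I/O, configuration and a
run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dti import TensorVolume, eigen_maps, fit_tensor, smooth_tensor_components
from .fascicle import analyze_streamlines, pcsa
from .geometry import (LabelVolume, LongAxis, SurfaceMesh, auto_long_axis, build_surface,
                       make_seed_and_boundary_masks, mesh_volume, muscle_length)
from .tract import TrackingParams, track_compartment
from . import io as mio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ScanResult", "PipelineError", "analyze_scan", "run_pipeline"]

# how the ambiguous extension filter is interpreted; recorded in every manifest
FILTER_SEMANTICS = ("extension = sum of both end extensions; total length = fitted arc "
                    "length + extensions; accept iff extension < 20 mm and "
                    "extension/total < 0.5")


class PipelineError(RuntimeError):
    """Stage-qualified pipeline failure."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


@dataclass
class PipelineConfig:
    labels: str
    output_dir: str
    tensors: str | None = None
    dwi: str | None = None
    bvals: str | None = None
    bvecs: str | None = None
    meshes: dict[int, str] = field(default_factory=dict)
    label_names: dict[int, str] = field(default_factory=dict)
    long_axis: str | dict = "auto"  # or {"proximal": [...], "distal": [...]}
    tracking: dict = field(default_factory=dict)
    smoothing_sigma_mm: float = 0.0
    subject_id: str = "subject"
    condition: str = "short"
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["meshes"] = {int(k): v for k, v in (raw.get("meshes") or {}).items()}
        raw["label_names"] = {int(k): v for k, v in (raw.get("label_names") or {}).items()}
        return cls(**raw)

    def tracking_params(self) -> TrackingParams:
        kwargs = dict(self.tracking)
        kwargs.setdefault("rng_seed", self.rng_seed)
        return TrackingParams(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class ScanResult:
    records: pd.DataFrame  # one row per compartment (subject/condition constant)
    fascicles: pd.DataFrame  # one row per streamline across compartments
    muscle_length_mm: float
    axis: LongAxis
    tracking_stats: dict
    volumes_cm3: dict[int, float]


def analyze_scan(tensors: TensorVolume, labels: LabelVolume,
                 meshes: dict[int, SurfaceMesh], params: TrackingParams,
                 axis: LongAxis | None = None, label_names: dict[int, str] | None = None,
                 subject_id: str = "subject", condition: str = "short") -> ScanResult:
    """Run eigen-decomposition, masking, tracking and fascicle analysis for one
    scan, returning per-compartment architecture records."""
    label_names = label_names or {}
    maps = eigen_maps(tensors)
    present = labels.labels()
    missing = [lab for lab in present if lab not in meshes]
    if missing:
        raise ValueError(f"no surface mesh for labels {missing}")
    masks = make_seed_and_boundary_masks(labels, tensors.affine, tensors.shape)
    if axis is None:
        axis = auto_long_axis(meshes[lab] for lab in present)
    length_mm = muscle_length((meshes[lab] for lab in present), axis)

    records = []
    fascicle_frames = []
    stats = {}
    volumes = {}
    for lab in present:
        seed, boundary = masks[lab]
        streamlines, st = track_compartment(maps, seed, boundary, params, label=lab)
        name = label_names.get(lab, str(lab))
        df = analyze_streamlines(streamlines, meshes[lab], axis, compartment=name)
        fascicle_frames.append(df)
        stats[lab] = st
        vol = mesh_volume(meshes[lab])
        volumes[lab] = vol
        acc = df[df["accepted"]]
        mean_len = float(acc["length_mm"].mean()) if len(acc) else float("nan")
        records.append({
            "subject_id": subject_id,
            "compartment": name,
            "condition": condition,
            "volume_cm3": vol,
            "pcsa_cm2": pcsa(vol, mean_len) if np.isfinite(mean_len) else float("nan"),
            "fascicle_length_mm": mean_len,
            "normalized_fascicle_length": mean_len / length_mm if np.isfinite(mean_len) else float("nan"),
            "pennation_deg": float(acc["pennation_deg"].mean()) if len(acc) else float("nan"),
            "curvature_per_m": float(acc["curvature_per_m"].mean()) if len(acc) else float("nan"),
            "n_fascicles": int(len(acc)),
            "n_tracked": int(len(df)),
        })
        logger.info("compartment %s: %d tracked, %d accepted fascicles", name, len(df), len(acc))
    fascicles = (pd.concat(fascicle_frames, ignore_index=True)
                 if fascicle_frames else pd.DataFrame())
    return ScanResult(records=pd.DataFrame(records), fascicles=fascicles,
                      muscle_length_mm=length_mm, axis=axis, tracking_stats=stats,
                      volumes_cm3=volumes)


def _load_tensors(config: PipelineConfig) -> TensorVolume:
    if config.tensors:
        tensors = mio.load_tensor_volume(config.tensors)
    else:
        if not (config.dwi and config.bvals and config.bvecs):
            raise ValueError("config needs either 'tensors' or 'dwi' + 'bvals' + 'bvecs'")
        data, affine = mio.load_nifti(config.dwi)
        bvals, bvecs = mio.load_bvals_bvecs(config.bvals, config.bvecs)
        b0_sel = bvals <= 0
        if not b0_sel.any():
            raise ValueError("no b0 volume in the DWI series")
        b0 = data[..., b0_sel].mean(axis=-1)
        dwi = data[..., ~b0_sel]
        tensors = fit_tensor(dwi, float(bvals[~b0_sel].mean()), bvecs[~b0_sel], b0, affine)
    if config.smoothing_sigma_mm > 0:
        tensors = smooth_tensor_components(tensors, config.smoothing_sigma_mm)
    return tensors


def run_pipeline(config: PipelineConfig) -> ScanResult:
    """Execute the staged pipeline with file inputs/outputs and a run manifest.

    On a stage failure, whatever was produced is kept and the manifest is
    written with a ``.partial`` suffix naming the failed stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.digest(),
        "rng_seed": config.rng_seed,
        "versions": {"myoarch": __version__, "numpy": np.__version__},
        "filter_semantics": FILTER_SEMANTICS,
        "stages": {},
    }
    stage = "dti"
    try:
        tensors = _load_tensors(config)
        maps = eigen_maps(tensors)
        mio.save_nifti(out / "fa.nii", maps.fa, tensors.affine)
        mio.save_nifti(out / "md.nii", maps.md, tensors.affine)
        from .dti import primary_eigenvector_rgb
        mio.save_nifti(out / "e1_rgb.nii", primary_eigenvector_rgb(maps), tensors.affine)
        manifest["stages"]["dti"] = {"n_mask_voxels": int(tensors.mask.sum())}

        stage = "geometry"
        labels = mio.load_label_volume(config.labels)
        meshes = {}
        for lab in labels.labels():
            if lab in config.meshes:
                meshes[lab] = mio.load_mesh(config.meshes[lab])
                meshes[lab].label = lab
            else:
                meshes[lab] = build_surface(labels, lab)
            mio.save_ply(out / f"surface_{lab}.ply", meshes[lab])
        if config.long_axis == "auto":
            axis = None
        else:
            axis = LongAxis(np.asarray(config.long_axis["proximal"], dtype=float),
                            np.asarray(config.long_axis["distal"], dtype=float))
        manifest["stages"]["geometry"] = {"labels": labels.labels()}

        stage = "tract+fascicle"
        params = config.tracking_params()
        result = analyze_scan(tensors, labels, meshes, params, axis=axis,
                              label_names=config.label_names,
                              subject_id=config.subject_id, condition=config.condition)
        for lab, st in result.tracking_stats.items():
            manifest["stages"].setdefault("tract", {})[str(lab)] = {
                "n_accepted": st.n_accepted, "n_attempts": st.n_attempts,
                "rejections": dict(st.rejections),
            }

        stage = "outputs"
        result.fascicles.to_csv(out / "fascicles.csv", index=False)
        result.records.to_csv(out / "records.csv", index=False)
        term = pd.DataFrame([
            {"compartment": str(lab), **{f"n_{k}": v for k, v in st.rejections.items()}}
            for lab, st in result.tracking_stats.items()
        ])
        term.to_csv(out / "termination.csv", index=False)
        manifest["muscle_length_mm"] = result.muscle_length_mm
        manifest["stages"]["fascicle"] = {
            str(r["compartment"]): int(r["n_fascicles"]) for _, r in result.records.iterrows()
        }
    except Exception as exc:  # noqa: BLE001 - re-raised stage-qualified
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(stage, exc) from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result
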