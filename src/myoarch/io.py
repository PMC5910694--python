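"""File format round-tripping: NIfTI volumes, FSL-style bval/bvec text,
ASCII STL/PLY meshes, TCK/VTK streamlines and CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dti import TensorVolume
from .geometry import LabelVolume, SurfaceMesh

__all__ = [
    "save_nifti", "load_nifti", "save_tensor_volume", "load_tensor_volume",
    "save_label_volume", "load_label_volume", "save_bvals_bvecs", "load_bvals_bvecs",
    "save_stl", "load_stl", "save_ply", "load_ply", "save_mesh", "load_mesh",
    "save_tck", "load_tck", "save_vtk_polylines", "save_truth",
]


# -- NIfTI ------------------------------------------------------------------

def save_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_tensor_volume(path, tensors: TensorVolume) -> None:
    """6-component lower-triangular tensor NIfTI (float64 to keep precision)
    plus a sibling ``<stem>_mask.nii`` mask volume."""
    path = Path(path)
    save_nifti(path, tensors.lower, tensors.affine, dtype=np.float64)
    save_nifti(path.with_name(path.stem.split(".")[0] + "_mask.nii"),
               tensors.mask.astype(np.uint8), tensors.affine, dtype=np.uint8)


def load_tensor_volume(path) -> TensorVolume:
    path = Path(path)
    lower, affine = load_nifti(path)
    mask_path = path.with_name(path.stem.split(".")[0] + "_mask.nii")
    if mask_path.exists():
        mask = load_nifti(mask_path)[0] > 0
    else:
        mask = np.any(lower != 0, axis=-1)
    return TensorVolume(lower, affine, mask)


def save_label_volume(path, labels: LabelVolume) -> None:
    save_nifti(path, labels.data, labels.affine, dtype=np.int16)


def load_label_volume(path) -> LabelVolume:
    data, affine = load_nifti(path)
    return LabelVolume(np.rint(data).astype(np.int16), affine)


# -- FSL-dialect gradient tables -------------------------------------------

def save_bvals_bvecs(bval_path, bvec_path, b_value: float, directions: np.ndarray) -> None:
    """One b0 column followed by the diffusion-weighted columns."""
    g = np.asarray(directions, dtype=float)
    bvals = np.concatenate([[0.0], np.full(len(g), float(b_value))])
    bvecs = np.column_stack([np.zeros(3), g.T])  # (3, N+1)
    np.savetxt(str(bval_path), bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), bvecs, fmt="%.8f")


def load_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(str(bval_path)).reshape(-1)
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    return bvals, bvecs.T  # (N+1,), (N+1, 3)


# -- meshes -----------------------------------------------------------------

def save_stl(path, mesh: SurfaceMesh) -> None:
    v, f = mesh.vertices, mesh.faces
    tris = v[f]  # (F, 3, 3)
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norms, out=np.zeros_like(n), where=norms > 0)
    with open(path, "w") as fh:
        fh.write(f"solid label{mesh.label}\n")
        for tri, nn in zip(tris, n):
            fh.write(f"  facet normal {nn[0]:.9e} {nn[1]:.9e} {nn[2]:.9e}\n    outer loop\n")
            for p in tri:
                fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid label{mesh.label}\n")


def load_stl(path) -> SurfaceMesh:
    verts = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(x) for x in parts[1:4]])
    tri = np.asarray(verts, dtype=float).reshape(-1, 3)
    # merge duplicated vertices so the mesh is closed again
    uniq, inverse = np.unique(tri.round(decimals=6), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(uniq, faces)


def save_ply(path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment label {mesh.label}\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_ply(path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline()
        if line.strip() != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        label = 0
        while True:
            line = fh.readline().split()
            if not line:
                continue
            if line[0] == "element":
                if line[1] == "vertex":
                    n_vert = int(line[2])
                elif line[1] == "face":
                    n_face = int(line[2])
            elif line[0] == "comment" and len(line) >= 3 and line[1] == "label":
                label = int(line[2])
            elif line[0] == "end_header":
                break
        verts = np.array([[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)])
        faces = np.array([[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)])
    return SurfaceMesh(verts, faces, label=label)


def save_mesh(path, mesh: SurfaceMesh) -> None:
    path = Path(path)
    if path.suffix.lower() == ".stl":
        save_stl(path, mesh)
    elif path.suffix.lower() == ".ply":
        save_ply(path, mesh)
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def load_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".stl":
        return load_stl(path)
    if path.suffix.lower() == ".ply":
        return load_ply(path)
    raise ValueError(f"unsupported mesh format: {path.suffix}")


# -- streamlines ------------------------------------------------------------

def save_tck(path, streamlines) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s.points if hasattr(s, "points") else s, dtype=float) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


def load_tck(path) -> list[np.ndarray]:
    tck = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in tck.streamlines]


def save_vtk_polylines(path, streamlines) -> None:
    """Legacy ASCII VTK polydata with one polyline per streamline."""
    pts = [np.asarray(s.points if hasattr(s, "points") else s, dtype=float) for s in streamlines]
    n_total = sum(len(p) for p in pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstreamlines\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n_total} double\n")
        for p in pts:
            for row in p:
                fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")
        fh.write(f"LINES {len(pts)} {len(pts) + n_total}\n")
        offset = 0
        for p in pts:
            idx = " ".join(str(offset + i) for i in range(len(p)))
            fh.write(f"{len(p)} {idx}\n")
            offset += len(p)


def load_digitised_polylines(path) -> dict:
    """Digitised fascicle polylines from CSV with columns
    fascicle_id, point_index, x, y, z -> {fascicle_id: (N, 3) array}."""
    df = pd.read_csv(path)
    required = {"fascicle_id", "point_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"polyline CSV missing columns: {sorted(missing)}")
    out = {}
    for fid, grp in df.groupby("fascicle_id"):
        grp = grp.sort_values("point_index")
        out[fid] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return out


def save_points_ply(path, points: np.ndarray) -> None:
    """PLY point cloud (e.g. fascicle attachment points)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\nend_header\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")


# -- misc -------------------------------------------------------------------

def save_truth(csv_path, json_path, truth) -> None:
    rows = [vars(t) for t in truth.compartments.values()]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump({str(t.label): vars(t) for t in truth.compartments.values()}, fh, indent=2)
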