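"""Fascicle reconstruction: cubic fits to streamlines, linear extrapolation to
the compartment surface, plausibility filtering, and architecture metrics.

A fascicle is a third-order polynomial curve fitted per coordinate to a raw
streamline (parameterised by normalised cumulative chord length, t in [0, 1]),
plus straight extensions from both end points along the end-point tangents to
the muscle surface. Fascicle length is the fitted arc length plus both
extension lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LongAxis, SurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "Extension", "FascicleCurve", "fit_polynomial", "extrapolate_to_surface",
    "accept_fascicle", "pennation_angle", "mean_curvature", "fascicle_length",
    "pcsa", "normalized_fascicle_length", "digitised_polyline_metrics",
    "ray_mesh_intersections", "point_in_mesh", "analyze_streamlines",
    "MAX_EXTENSION_MM", "MAX_EXTENSION_FRACTION",
]

MAX_EXTENSION_MM = 20.0
MAX_EXTENSION_FRACTION = 0.5

_DENSE_SEGMENTS = 2048  # arc-length quadrature resolution (spec floor: 1000)


@dataclass
class Extension:
    direction: np.ndarray  # outward unit tangent at the curve end point
    length_mm: float = 0.0
    hit_point: np.ndarray | None = None

    @property
    def hit(self) -> bool:
        return self.hit_point is not None


@dataclass
class FascicleCurve:
    """Cubic polynomial r(t) = c0 + c1 t + c2 t^2 + c3 t^3 per coordinate."""

    coeffs: np.ndarray  # (4, 3), ascending powers
    arc_length_mm: float  # fitted-curve length (dense sampling, no extensions)
    ext_start: Extension | None = None  # at t = 0
    ext_end: Extension | None = None  # at t = 1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        c = self.coeffs
        return c[0] + t * (c[1] + t * (c[2] + t * c[3]))

    def derivative(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        c = self.coeffs
        return c[1] + t * (2 * c[2] + t * 3 * c[3])

    def second_derivative(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        return 2 * self.coeffs[2] + 6 * t * self.coeffs[3]

    @property
    def extension_total_mm(self) -> float:
        total = 0.0
        for ext in (self.ext_start, self.ext_end):
            if ext is not None:
                total += ext.length_mm
        return total

    @property
    def both_ends_hit(self) -> bool:
        return (self.ext_start is not None and self.ext_start.hit
                and self.ext_end is not None and self.ext_end.hit)

    @property
    def origin(self) -> np.ndarray | None:
        return None if self.ext_start is None else self.ext_start.hit_point

    @property
    def insertion(self) -> np.ndarray | None:
        return None if self.ext_end is None else self.ext_end.hit_point


def fit_polynomial(points: np.ndarray) -> FascicleCurve:
    """Independent least-squares cubic per coordinate against normalised
    cumulative chord length."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError(f"need at least 4 points to fit a cubic, got {len(pts)}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise ValueError("degenerate streamline (zero chord length)")
    t = cum / cum[-1]
    design = np.vander(t, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, pts, rcond=None)
    curve = FascicleCurve(coeffs=coeffs, arc_length_mm=0.0)
    curve.arc_length_mm = _dense_arc_length(curve)
    return curve


def _dense_arc_length(curve: FascicleCurve, n_segments: int = _DENSE_SEGMENTS) -> float:
    t = np.linspace(0.0, 1.0, n_segments + 1)
    p = curve.evaluate(t)
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def ray_mesh_intersections(origin: np.ndarray, direction: np.ndarray,
                           mesh: SurfaceMesh, eps: float = 1e-12) -> np.ndarray:
    """Sorted positive ray parameters of all ray/triangle hits (Moller-Trumbore)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(ok, 1.0 / det, 0.0)
        tvec = origin - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = (qvec @ direction) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    return np.sort(t[hit])


def point_in_mesh(point: np.ndarray, mesh: SurfaceMesh) -> bool:
    """Ray-parity containment test (odd number of crossings = inside)."""
    # deliberately incommensurate components: avoids grazing axis-aligned
    # faces, edges and the main diagonal of box-like meshes
    probe = np.array([0.12787512, 0.35917201, 0.92447623])
    return len(ray_mesh_intersections(point, probe, mesh)) % 2 == 1


def extrapolate_to_surface(curve: FascicleCurve, mesh: SurfaceMesh) -> FascicleCurve:
    """Extend both curve ends linearly along the end-point tangents until they
    intersect the muscle surface; the nearest positive hit is the attachment.

    Ends whose ray misses the mesh get a zero-length no-hit extension flag.
    Raises if a curve end point lies outside the mesh (upstream masking bug).
    """
    exts = []
    for t_end, sign in ((0.0, -1.0), (1.0, 1.0)):
        endpoint = curve.evaluate(t_end)
        tangent = sign * curve.derivative(t_end)
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            raise ValueError("degenerate end-point tangent")
        tangent = tangent / norm
        if not point_in_mesh(endpoint, mesh):
            raise ValueError(f"curve end point {endpoint} lies outside the surface mesh")
        hits = ray_mesh_intersections(endpoint, tangent, mesh)
        if len(hits) == 0:
            exts.append(Extension(direction=tangent))
        else:
            dist = float(hits[0])
            exts.append(Extension(direction=tangent, length_mm=dist,
                                  hit_point=endpoint + dist * tangent))
    return FascicleCurve(coeffs=curve.coeffs.copy(), arc_length_mm=curve.arc_length_mm,
                         ext_start=exts[0], ext_end=exts[1])


def accept_fascicle(curve: FascicleCurve) -> tuple[bool, str]:
    """Plausibility filter: both ends attached, total extension < 20 mm and
    < 50% of the total fascicle length."""
    if not curve.both_ends_hit:
        return False, "no_surface_hit"
    ext = curve.extension_total_mm
    total = fascicle_length(curve)
    if ext >= MAX_EXTENSION_MM:
        return False, "extension_over_20mm"
    if ext / total >= MAX_EXTENSION_FRACTION:
        return False, "extension_over_half_length"
    return True, "accepted"


def fascicle_length(curve: FascicleCurve) -> float:
    """Fitted-polynomial arc length plus both extension lengths (mm)."""
    return curve.arc_length_mm + curve.extension_total_mm


def pennation_angle(curve: FascicleCurve, axis: LongAxis) -> float:
    """Angle (deg, in [0, 90]) between the origin-insertion chord and the long axis."""
    if not curve.both_ends_hit:
        raise ValueError("both attachment points required for pennation")
    chord = curve.insertion - curve.origin
    n = np.linalg.norm(chord)
    if n < 1e-12:
        raise ValueError("zero-length origin-insertion chord")
    cosang = abs(chord @ axis.direction) / n
    return math.degrees(math.acos(min(1.0, cosang)))


def mean_curvature(curve: FascicleCurve, n_points: int = 100) -> float:
    """Frenet-Serret curvature |r' x r''| / |r'|^3 averaged over ``n_points``
    points equidistant in arc length along the fitted polynomial (extensions
    excluded), converted to 1/m."""
    t_dense = np.linspace(0.0, 1.0, _DENSE_SEGMENTS + 1)
    p = curve.evaluate(t_dense)
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))])
    if cum[-1] <= 0:
        return 0.0
    targets = np.linspace(0.0, cum[-1], n_points)
    ts = np.interp(targets, cum, t_dense)
    d1 = curve.derivative(ts)
    d2 = curve.second_derivative(ts)
    speed = np.linalg.norm(d1, axis=1)
    good = speed > 1e-12
    n_skipped = int((~good).sum())
    if n_skipped:
        logger.info("mean_curvature: skipped %d degenerate evaluation points", n_skipped)
    if not good.any():
        return 0.0
    kappa = np.linalg.norm(np.cross(d1[good], d2[good]), axis=1) / speed[good] ** 3
    return float(kappa.mean() * 1000.0)  # 1/mm -> 1/m


def pcsa(volume_cm3: float, mean_fascicle_length_mm: float) -> float:
    """Physiological cross-sectional area: volume / fascicle length (cm^2)."""
    if volume_cm3 <= 0 or mean_fascicle_length_mm <= 0:
        raise ValueError("volume and fascicle length must be positive")
    return volume_cm3 / (mean_fascicle_length_mm / 10.0)


def normalized_fascicle_length(mean_fascicle_length_mm: float, muscle_length_mm: float) -> float:
    if mean_fascicle_length_mm <= 0 or muscle_length_mm <= 0:
        raise ValueError("lengths must be positive")
    return mean_fascicle_length_mm / muscle_length_mm


def digitised_polyline_metrics(points: np.ndarray, reference_line: tuple[np.ndarray, np.ndarray]
                               ) -> tuple[float, float]:
    """(length mm, pennation deg) of a digitised fascicle polyline.

    Length is the sum of segment lengths; pennation is the acute angle between
    the first-to-last chord and the reference line. Duplicate consecutive
    points are collapsed (and logged).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dup = seg < 1e-12
    if dup.any():
        logger.info("digitised polyline: collapsed %d duplicate consecutive points", int(dup.sum()))
        pts = np.vstack([pts[0], pts[1:][~dup]])
        if len(pts) < 2:
            raise ValueError("polyline degenerate after collapsing duplicates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    a, b = (np.asarray(p, dtype=float) for p in reference_line)
    ref = b - a
    if np.linalg.norm(ref) < 1e-12:
        raise ValueError("reference line points must be distinct")
    chord = pts[-1] - pts[0]
    cosang = abs(chord @ ref) / (np.linalg.norm(chord) * np.linalg.norm(ref))
    return length, math.degrees(math.acos(min(1.0, cosang)))


def analyze_streamlines(streamlines, mesh: SurfaceMesh, axis: LongAxis,
                        compartment: int | str = 0) -> pd.DataFrame:
    """Fit, extrapolate, filter and measure a batch of streamlines.

    Returns one row per input streamline with columns id, compartment,
    length_mm, pennation_deg, curvature_per_m, extension_mm,
    extension_fraction, accepted, reason. Metrics needing both attachments are
    NaN for fascicles that never reach the surface.
    """
    rows = []
    for i, sl in enumerate(streamlines):
        pts = sl.points if hasattr(sl, "points") else np.asarray(sl)
        curve = extrapolate_to_surface(fit_polynomial(pts), mesh)
        ok, reason = accept_fascicle(curve)
        length = fascicle_length(curve)
        ext = curve.extension_total_mm
        origin = curve.origin if curve.both_ends_hit else np.full(3, np.nan)
        insertion = curve.insertion if curve.both_ends_hit else np.full(3, np.nan)
        rows.append({
            "id": i,
            "compartment": compartment,
            "length_mm": length if curve.both_ends_hit else np.nan,
            "pennation_deg": pennation_angle(curve, axis) if curve.both_ends_hit else np.nan,
            "curvature_per_m": mean_curvature(curve),
            "extension_mm": ext,
            "extension_fraction": ext / length if length > 0 else np.nan,
            "accepted": ok,
            "reason": reason,
            "origin_x": origin[0], "origin_y": origin[1], "origin_z": origin[2],
            "insertion_x": insertion[0], "insertion_y": insertion[1], "insertion_z": insertion[2],
        })
    return pd.DataFrame(rows)
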