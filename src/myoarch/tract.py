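"""Deterministic streamline tracking through the primary-eigenvector field.

Streamlines grow bi-directionally from random seeds, following the trilinearly
interpolated primary eigenvector (sign-aligned to the previous step), with
acceptance windows on FA and MD, a maximum turning angle per step, and
termination at the compartment boundary layer.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dti import EigenMaps

logger = logging.getLogger(__name__)

__all__ = ["TrackingParams", "Streamline", "TrackStats", "FieldSampler",
           "track_from_seed", "track_compartment"]


@dataclass
class TrackingParams:
    fa_min: float = 0.1
    fa_max: float = 0.5
    md_min: float = 1e-3
    md_max: float = 2e-3
    max_angle_deg: float = 10.0
    step_mm: float = 1.0
    min_length_mm: float = 15.0
    max_length_mm: float = 200.0
    n_target: int = 1000
    max_seed_attempts: int | None = None  # default 100 * n_target
    rng_seed: int = 0
    interpolation: str = "trilinear"  # or "nearest"

    def __post_init__(self):
        if not 0.0 <= self.fa_min < self.fa_max <= 1.0:
            raise ValueError("need 0 <= fa_min < fa_max <= 1")
        if not self.md_min < self.md_max:
            raise ValueError("need md_min < md_max")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not self.min_length_mm < self.max_length_mm:
            raise ValueError("need min_length_mm < max_length_mm")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ValueError("interpolation must be 'trilinear' or 'nearest'")

    @property
    def attempts_budget(self) -> int:
        return self.max_seed_attempts if self.max_seed_attempts is not None else 100 * self.n_target


@dataclass
class Streamline:
    """Ordered world-frame points (mm) with per-end termination reasons."""

    points: np.ndarray  # (N, 3)
    seed_index: int
    reasons: tuple[str, str]  # (backward end, forward end)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TrackStats:
    n_accepted: int
    n_attempts: int
    rejections: Counter = field(default_factory=Counter)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempts if self.n_attempts else 0.0


_CUBE = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])


class FieldSampler:
    """Interpolated access to e1/FA/MD plus nearest-voxel mask membership."""

    def __init__(self, maps: EigenMaps, seed_mask: np.ndarray, boundary_mask: np.ndarray,
                 interpolation: str = "trilinear"):
        self.e1 = np.ascontiguousarray(maps.e1)
        self.fa = np.ascontiguousarray(maps.fa)
        self.md = np.ascontiguousarray(maps.md)
        self.seed_mask = np.asarray(seed_mask, dtype=bool)
        self.boundary_mask = np.asarray(boundary_mask, dtype=bool)
        if self.seed_mask.shape != self.fa.shape or self.boundary_mask.shape != self.fa.shape:
            raise ValueError("mask shapes must match the eigenvector grid")
        inv = np.linalg.inv(maps.affine)
        self.inv_rot = inv[:3, :3]
        self.inv_trans = inv[:3, 3]
        self.shape = np.array(self.fa.shape)
        self.nearest = interpolation == "nearest"

    def to_voxel(self, p: np.ndarray) -> np.ndarray:
        return self.inv_rot @ p + self.inv_trans

    def _corners(self, v: np.ndarray):
        f = np.floor(v)
        t = v - f
        i0 = np.clip(f.astype(np.int64), 0, self.shape - 1)
        i1 = np.clip(i0 + 1, 0, self.shape - 1)
        ii = np.where(_CUBE, i1, i0)  # (8, 3)
        w = np.prod(np.where(_CUBE, t, 1.0 - t), axis=1)  # (8,)
        return ii, w

    def mask_state(self, p: np.ndarray) -> str:
        """'seed' | 'boundary' | 'out_of_mask' | 'out_of_volume' at the nearest voxel."""
        v = np.rint(self.to_voxel(p)).astype(np.int64)
        if np.any(v < 0) or np.any(v >= self.shape):
            return "out_of_volume"
        ijk = tuple(v)
        if self.seed_mask[ijk]:
            return "seed"
        if self.boundary_mask[ijk]:
            return "boundary"
        return "out_of_mask"

    def direction(self, p: np.ndarray, ref: np.ndarray | None) -> np.ndarray | None:
        """Unit e1 at p, per-lobe sign-aligned to ``ref``; None if degenerate."""
        v = self.to_voxel(p)
        if self.nearest:
            idx = tuple(np.clip(np.rint(v).astype(np.int64), 0, self.shape - 1))
            d = self.e1[idx].copy()
            if ref is not None and d @ ref < 0:
                d = -d
        else:
            ii, w = self._corners(v)
            vecs = self.e1[ii[:, 0], ii[:, 1], ii[:, 2]]  # (8, 3)
            if ref is not None:
                flip = np.sign(vecs @ ref)
                flip[flip == 0] = 1.0
                vecs = vecs * flip[:, None]
            d = w @ vecs
        if not np.all(np.isfinite(d)):
            return None
        n = np.linalg.norm(d)
        if n < 1e-12:
            return None
        return d / n

    def scalars(self, p: np.ndarray) -> tuple[float, float]:
        """(FA, MD) at p by the configured interpolation."""
        v = self.to_voxel(p)
        if self.nearest:
            idx = tuple(np.clip(np.rint(v).astype(np.int64), 0, self.shape - 1))
            return float(self.fa[idx]), float(self.md[idx])
        ii, w = self._corners(v)
        fa = w @ self.fa[ii[:, 0], ii[:, 1], ii[:, 2]]
        md = w @ self.md[ii[:, 0], ii[:, 1], ii[:, 2]]
        return float(fa), float(md)


def _half_track(sampler: FieldSampler, p0: np.ndarray, d0: np.ndarray,
                params: TrackingParams, max_steps: int) -> tuple[list[np.ndarray], str]:
    cos_max = math.cos(math.radians(params.max_angle_deg)) - 1e-12  # ties accepted
    pts = [p0]
    d_prev = d0
    for _ in range(max_steps):
        d = sampler.direction(pts[-1], d_prev)
        if d is None:
            return pts, "invalid_field"
        if d @ d_prev < cos_max:
            return pts, "angle"
        cand = pts[-1] + params.step_mm * d
        state = sampler.mask_state(cand)
        if state == "out_of_volume":
            return pts, "out_of_volume"
        if state == "boundary" or state == "out_of_mask":
            return pts, "boundary"
        fa, md = sampler.scalars(cand)
        if not params.fa_min <= fa <= params.fa_max:
            return pts, "fa_window"
        if not params.md_min <= md <= params.md_max:
            return pts, "md_window"
        pts.append(cand)
        d_prev = d
    return pts, "max_length"


def track_from_seed(seed_point: np.ndarray, sampler: FieldSampler, params: TrackingParams,
                    seed_index: int = 0) -> tuple[Streamline | None, str]:
    """Grow one bidirectional streamline; returns (streamline, 'accepted') or
    (None, rejection reason). A seed outside the seed mask or outside the FA/MD
    windows is a rejection, not an error."""
    p0 = np.asarray(seed_point, dtype=float)
    if sampler.mask_state(p0) != "seed":
        return None, "seed_outside_mask"
    fa, md = sampler.scalars(p0)
    if not params.fa_min <= fa <= params.fa_max:
        return None, "seed_fa_window"
    if not params.md_min <= md <= params.md_max:
        return None, "seed_md_window"
    d0 = sampler.direction(p0, None)
    if d0 is None:
        return None, "invalid_field"

    max_steps = int(params.max_length_mm / params.step_mm)
    fwd, fwd_reason = _half_track(sampler, p0, d0, params, max_steps)
    bwd, bwd_reason = _half_track(sampler, p0, -d0, params, max_steps)
    points = np.vstack([np.array(bwd[::-1]), np.array(fwd[1:]).reshape(-1, 3)])
    length = (len(points) - 1) * params.step_mm
    if length < params.min_length_mm:
        return None, "too_short"
    if length > params.max_length_mm:
        return None, "too_long"
    return Streamline(points=points, seed_index=seed_index, reasons=(bwd_reason, fwd_reason)), "accepted"


def track_compartment(maps: EigenMaps, seed_mask: np.ndarray, boundary_mask: np.ndarray,
                      params: TrackingParams, label: int = 0) -> tuple[list[Streamline], TrackStats]:
    """Seed uniformly at random (uniform voxel, uniform jitter inside the voxel)
    until ``n_target`` streamlines are accepted or the attempt budget runs out.

    Deterministic given ``params.rng_seed`` (per-compartment substream derived
    from the seed and the label). Exhausting the budget yields a warning and a
    partial result.
    """
    if not np.any(seed_mask):
        raise ValueError("seed mask is empty")
    rng = np.random.default_rng([params.rng_seed, label])
    seed_voxels = np.argwhere(seed_mask)
    affine = maps.affine
    sampler = FieldSampler(maps, seed_mask, boundary_mask, interpolation=params.interpolation)

    accepted: list[Streamline] = []
    rejections: Counter = Counter()
    attempt = 0
    budget = params.attempts_budget
    while len(accepted) < params.n_target and attempt < budget:
        vox = seed_voxels[rng.integers(len(seed_voxels))]
        jitter = rng.uniform(-0.5, 0.5, 3)
        world = affine[:3, :3] @ (vox + jitter) + affine[:3, 3]
        sl, reason = track_from_seed(world, sampler, params, seed_index=attempt)
        attempt += 1
        if sl is not None:
            accepted.append(sl)
        else:
            rejections[reason] += 1
    stats = TrackStats(n_accepted=len(accepted), n_attempts=attempt, rejections=rejections)
    if len(accepted) < params.n_target:
        warnings.warn(
            f"compartment {label}: only {len(accepted)}/{params.n_target} streamlines "
            f"accepted after {attempt} seed attempts (sparse fibre tracts)",
            stacklevel=2,
        )
    logger.info("compartment %s: %d/%d accepted (rate %.2f)", label, stats.n_accepted,
                stats.n_attempts, stats.acceptance_rate)
    return accepted, stats
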