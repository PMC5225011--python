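"""Synthetic MR-colonography-like tube phantoms with analytic ground truth.

Generates a dark lumen inside a bright, contrast-enhancing wall embedded in
an intermediate background — the appearance assumed by the tracker's
measurement model.  The tube axis may be straight, a torus segment (constant
curvature) or a helix; optional degradations emulate the failure modes seen
in patient data: haustral indentations, local collapse of the lumen, a
smooth multiplicative bias field, and additive Gaussian noise.

Partial-volume behaviour is emulated by analytic linear coverage ramps one
voxel wide at both wall surfaces, which makes sub-voxel thickness recovery
meaningful on 1–2 mm grids.  Ground truth (axis polyline, per-arc-length
inner radius and wall thickness) is analytic — the phantom is built *from*
it, so it is exact by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom"]

Profile = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic bowel segment.

    Intensities loosely follow a post-contrast T1 appearance on an arbitrary
    scanner scale: dark lumen (default 10), enhancing wall (default 100),
    intermediate background (default 40).  ``wall_intensity`` must exceed
    ``lumen_intensity`` — the contrast assumption the tracker relies on.
    """

    shape: str = "straight"  # straight | torus | helix
    length_mm: float = 80.0
    inner_radius_mm: Profile = 8.0
    wall_thickness_mm: Profile = 3.0
    lumen_intensity: float = 10.0
    wall_intensity: float = 100.0
    background_intensity: float = 40.0
    noise_sigma: float = 0.0
    bias: str = "none"  # none | linear | quadratic
    bias_amplitude: float = 0.0
    haustra_count: int = 0
    haustra_depth_mm: float = 0.0
    collapse_mm: Optional[Tuple[float, float]] = None
    collapse_taper_mm: float = 0.5
    spacing_mm: Union[float, Tuple[float, float, float]] = 1.0
    margin_mm: float = 6.0
    torus_radius_mm: float = 60.0
    helix_radius_mm: float = 25.0
    helix_pitch_mm: float = 40.0
    seed: int = 0
    grid_shape: Optional[Tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.shape not in ("straight", "torus", "helix"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.wall_intensity <= self.lumen_intensity:
            raise ValueError("wall intensity must exceed lumen intensity")
        if self.lumen_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Analytic truth sampled densely along arc length ``s``."""

    s: np.ndarray                 # arc length, mm
    axis: np.ndarray              # (n, 3) axis points, world mm
    tangent: np.ndarray           # (n, 3) unit tangents
    inner_radius: np.ndarray      # effective lumen radius (haustra/collapse applied)
    thickness: np.ndarray         # wall thickness, mm (the spec profile)

    def to_json(self, path: str) -> None:
        payload = {
            "s_mm": self.s.tolist(),
            "axis_mm": self.axis.tolist(),
            "tangent": self.tangent.tolist(),
            "inner_radius_mm": self.inner_radius.tolist(),
            "thickness_mm": self.thickness.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            s=np.array(d["s_mm"]),
            axis=np.array(d["axis_mm"]),
            tangent=np.array(d["tangent"]),
            inner_radius=np.array(d["inner_radius_mm"]),
            thickness=np.array(d["thickness_mm"]),
        )


def _as_profile(p: Profile, s: np.ndarray) -> np.ndarray:
    if callable(p):
        return np.asarray(p(s), dtype=np.float64)
    return np.full_like(s, float(p))


def _axis_curve(spec: PhantomSpec, s: np.ndarray):
    if spec.shape == "straight":
        axis = np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=1)
        tang = np.tile([0.0, 0.0, 1.0], (s.size, 1))
    elif spec.shape == "torus":
        R = spec.torus_radius_mm
        ang = s / R
        axis = np.stack([R * np.sin(ang), np.zeros_like(s), R * (1 - np.cos(ang))], axis=1)
        tang = np.stack([np.cos(ang), np.zeros_like(s), np.sin(ang)], axis=1)
    else:  # helix
        rh, pitch = spec.helix_radius_mm, spec.helix_pitch_mm
        c = pitch / (2 * math.pi)
        rate = 1.0 / math.hypot(rh, c)
        ang = s * rate
        axis = np.stack([rh * np.cos(ang), rh * np.sin(ang), c * ang], axis=1)
        d = np.stack([-rh * np.sin(ang), rh * np.cos(ang), np.full_like(ang, c)], axis=1)
        tang = d / np.linalg.norm(d, axis=1, keepdims=True)
        axis = axis - axis[0]
    return axis, tang


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, GroundTruth]:
    """Voxelise the phantom described by ``spec``.

    Construction order: anti-aliased tube (wall between the effective inner
    radius and inner radius + thickness), haustral indentation and collapse
    folded into the effective inner-radius profile, then multiplicative bias,
    then additive Gaussian noise.  Deterministic given ``spec.seed``.
    """
    ds = 0.25
    s = np.arange(0.0, spec.length_mm + ds / 2, ds)
    axis, tang = _axis_curve(spec, s)

    r_in = _as_profile(spec.inner_radius_mm, s).copy()
    thick = _as_profile(spec.wall_thickness_mm, s)
    if np.any(r_in <= 0) or np.any(thick <= 0):
        raise ValueError("inner radius and thickness must be positive")

    if spec.haustra_count > 0 and spec.haustra_depth_mm > 0:
        indent = spec.haustra_depth_mm * np.sin(
            math.pi * spec.haustra_count * s / spec.length_mm
        ) ** 2
        r_in = np.maximum(r_in - indent, 0.25 * r_in)

    if spec.collapse_mm is not None:
        s0, s1 = spec.collapse_mm
        w = max(spec.collapse_taper_mm, 1e-6)
        # distance outside [s0, s1], scaled: 0 inside, 1 beyond the taper
        outside = np.maximum(s0 - s, s - s1) / w
        r_in = r_in * np.clip(outside, 0.0, 1.0)

    r_out = r_in + thick

    spacing = np.asarray(
        spec.spacing_mm if not np.isscalar(spec.spacing_mm) else [spec.spacing_mm] * 3,
        dtype=np.float64,
    )
    pad = float(np.max(r_out)) + spec.margin_mm
    lo = axis.min(axis=0) - pad
    hi = axis.max(axis=0) + pad
    if spec.grid_shape is not None:
        shape = np.asarray(spec.grid_shape, dtype=int)
        needed = np.ceil((hi - lo) / spacing).astype(int) + 1
        if np.any(shape < needed):
            raise ValueError("tube exits the requested volume grid")
    else:
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    vol = Volume(np.zeros(tuple(shape)), spacing, origin, np.eye(3))

    pts = vol.voxel_grid_world().reshape(-1, 3)
    tree = cKDTree(axis)
    rho, idx = tree.query(pts, workers=-1)
    rin_v = r_in[idx]
    rout_v = r_out[idx]

    w_aa = float(spacing.min())  # one-voxel coverage ramp

    def cov(x):
        return np.clip(x / w_aa + 0.5, 0.0, 1.0)

    bg, wall, lum = (
        spec.background_intensity,
        spec.wall_intensity,
        spec.lumen_intensity,
    )
    # voxels past either end see their distance to the end point, closing the
    # tube with hemispherical caps (lumen pocket inside a wall shell);
    # a lumen narrower than a voxel fades out entirely (full collapse)
    lumen_presence = np.clip(rin_v / w_aa, 0.0, 1.0)
    img = bg + (wall - bg) * cov(rout_v - rho) + (lum - wall) * cov(rin_v - rho) * lumen_presence

    if spec.bias != "none" and spec.bias_amplitude != 0.0:
        span = np.maximum(hi - lo, 1e-9)
        u = 2.0 * (pts - lo) / span - 1.0  # each axis in [-1, 1]
        if spec.bias == "linear":
            q = u[:, 0]
        elif spec.bias == "quadratic":
            q = (u**2).sum(axis=1) / 3.0 * 2.0 - 1.0
        else:
            raise ValueError(f"unknown bias kind {spec.bias!r}")
        img = img * (1.0 + spec.bias_amplitude * q)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    vol.data[...] = img.reshape(vol.shape)
    gt = GroundTruth(s=s, axis=axis, tangent=tang, inner_radius=r_in, thickness=thick)
    return vol, gt
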