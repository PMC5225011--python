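"""Frames, rotation-minimising framing, ellipses and angular perturbation.

Shared geometric primitives: orthonormal reference frames ``U = [r s t]``
(``t`` the tangent, ``r``/``s`` spanning the normal plane), the
double-reflection rotation-minimising-frame (RMF) sweep used both to frame
the centreline and to perturb the tracker's orientation, elliptical
cross-section parametrisation, and direct least-squares ellipse fitting.

All vectors are world mm, frames are right-handed (``r x s = t``).
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Sequence, Tuple

import numpy as np
from skimage.measure import EllipseModel

__all__ = [
    "Frame",
    "Ellipse",
    "rmf_double_reflection",
    "double_reflection_step",
    "perturb_normal",
    "ellipse_points",
    "fit_ellipse",
    "EllipseFitError",
]

_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal frame; columns of ``matrix`` are r, s, t."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
            raise ValueError("frame is not orthonormal")
        if not np.allclose(np.cross(m[:, 0], m[:, 1]), m[:, 2], atol=1e-8):
            raise ValueError("frame is not right-handed (r x s != t)")

    @property
    def r(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def s(self) -> np.ndarray:
        return self.matrix[:, 1]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.eye(3))

    @classmethod
    def from_approximate(cls, matrix: np.ndarray) -> "Frame":
        """Nearest rotation (via SVD) to an almost-orthonormal matrix, e.g.
        a frame read back from a rounded text file."""
        m = np.asarray(matrix, dtype=np.float64).reshape(3, 3)
        u, _, vt = np.linalg.svd(m)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        return cls(r)

    @classmethod
    def from_tangent(cls, tangent: np.ndarray) -> "Frame":
        """Any right-handed frame whose t-axis is the given tangent."""
        t = np.asarray(tangent, dtype=np.float64)
        n = np.linalg.norm(t)
        if n < _TOL:
            raise ValueError("zero tangent")
        t = t / n
        helper = np.array([1.0, 0.0, 0.0])
        if abs(t @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        r = np.cross(helper, t)
        r /= np.linalg.norm(r)
        s = np.cross(t, r)
        return cls(np.stack([r, s, t], axis=1))


@dataclasses.dataclass
class Ellipse:
    """In-plane ellipse: semi-major ``a`` >= semi-minor ``b`` > 0 (mm),
    orientation ``phi`` wrapped to [0, pi)."""

    a: float
    b: float
    phi: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.a <= 0:
            raise ValueError("ellipse axes must be positive")
        if self.a < self.b:
            self.a, self.b = self.b, self.a
            self.phi += math.pi / 2.0
        self.phi = self.phi % math.pi

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.phi])


# -- rotation minimising frames -------------------------------------------


def double_reflection_step(
    x0: np.ndarray, frame: Frame, x1: np.ndarray, t1: np.ndarray
) -> Frame:
    """One double-reflection RMF step from ``x0`` (with ``frame``) to ``x1``
    where the new tangent is ``t1`` (unit)."""
    v1 = x1 - x0
    c1 = v1 @ v1
    if c1 < _TOL**2:
        raise ValueError("coincident points in double reflection step")
    r0, t0 = frame.r, frame.t
    rl = r0 - (2.0 / c1) * (v1 @ r0) * v1
    tl = t0 - (2.0 / c1) * (v1 @ t0) * v1
    v2 = t1 - tl
    c2 = v2 @ v2
    if c2 < _TOL**2:
        r1 = rl
    else:
        r1 = rl - (2.0 / c2) * (v2 @ rl) * v2
    t1 = t1 / np.linalg.norm(t1)
    r1 = r1 - (r1 @ t1) * t1
    r1 /= np.linalg.norm(r1)
    s1 = np.cross(t1, r1)
    return Frame(np.stack([r1, s1, t1], axis=1))


def rmf_double_reflection(
    points: np.ndarray, initial_frame: Frame
) -> List[Frame]:
    """Sweep a rotation-minimising frame along an ordered polyline.

    Tangents are taken from chords (forward/central/backward differences);
    the double-reflection method propagates the initial frame with minimal
    twist about the tangent.  Raises on duplicate consecutive points, naming
    the offending index.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need at least 2 points of dimension 3")
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    dup = np.where(seglen < _TOL)[0]
    if dup.size:
        raise ValueError(f"duplicate consecutive points at index {int(dup[0])}")
    n = pts.shape[0]
    tangents = np.empty_like(pts)
    tangents[0] = seg[0] / seglen[0]
    tangents[-1] = seg[-1] / seglen[-1]
    for i in range(1, n - 1):
        t = seg[i - 1] / seglen[i - 1] + seg[i] / seglen[i]
        nrm = np.linalg.norm(t)
        t = t / nrm if nrm > _TOL else seg[i] / seglen[i]
        tangents[i] = t
    if initial_frame.t @ tangents[0] <= 0:
        raise ValueError("initial frame tangent deviates >90 deg from first segment")
    # re-anchor the initial frame's r to the actual first tangent
    t0 = tangents[0]
    r0 = initial_frame.r - (initial_frame.r @ t0) * t0
    nr = np.linalg.norm(r0)
    if nr < 1e-6:
        f0 = Frame.from_tangent(t0)
    else:
        r0 = r0 / nr
        f0 = Frame(np.stack([r0, np.cross(t0, r0), t0], axis=1))
    frames = [f0]
    for i in range(n - 1):
        frames.append(
            double_reflection_step(pts[i], frames[i], pts[i + 1], tangents[i + 1])
        )
    return frames


def frame_angle(f0: Frame, f1: Frame) -> float:
    """Rotation angle between two frames (radians)."""
    rel = f0.matrix.T @ f1.matrix
    c = (np.trace(rel) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def total_twist(frames: Sequence[Frame]) -> float:
    """Sum of inter-frame rotation angles along the sweep."""
    return float(
        sum(frame_angle(frames[i], frames[i + 1]) for i in range(len(frames) - 1))
    )


# -- perturbation sampling -------------------------------------------------


def perturb_normal(sigma_psi: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a unit direction about the pole (0,0,1).

    The azimuthal angle is uniform on (0, 2pi); the off-pole angle is
    N(0, sigma_psi^2), so samples thin out away from the pole.  Returns
    ``(cos e_th sin e_ps, sin e_th sin e_ps, cos e_ps)``.
    """
    if sigma_psi < 0:
        raise ValueError("sigma_psi must be >= 0")
    e_th = rng.uniform(0.0, 2.0 * math.pi)
    e_ps = rng.normal(0.0, sigma_psi) if sigma_psi > 0 else 0.0
    return spherical_direction(e_th, e_ps)


def spherical_direction(e_th: float, e_ps: float) -> np.ndarray:
    """Unit vector at azimuth ``e_th``, polar offset ``e_ps`` from (0,0,1)."""
    return np.array(
        [
            math.cos(e_th) * math.sin(e_ps),
            math.sin(e_th) * math.sin(e_ps),
            math.cos(e_ps),
        ]
    )


# -- ellipse parametrisation and fitting -----------------------------------


def ellipse_points(
    centre: np.ndarray, frame: Frame, e: Ellipse, H: int
) -> np.ndarray:
    """``H`` boundary points of the ellipse in the frame's normal plane.

    Point ``j`` sits at parameter ``h = 2 pi j / H``:
    ``u = R [a cos h cos phi - b sin h sin phi,
             a cos h sin phi + b sin h cos phi, 0]^T + c``.
    """
    if H < 8:
        raise ValueError("H must be >= 8")
    h = 2.0 * math.pi * np.arange(H) / H
    ca, sa = np.cos(h), np.sin(h)
    cp, sp = math.cos(e.phi), math.sin(e.phi)
    local = np.stack(
        [
            e.a * ca * cp - e.b * sa * sp,
            e.a * ca * sp + e.b * sa * cp,
            np.zeros(H),
        ],
        axis=1,
    )
    return local @ frame.matrix.T + np.asarray(centre, dtype=np.float64)


class EllipseFitError(ValueError):
    """Raised when a conic fit does not yield a valid ellipse."""


def fit_ellipse(points2d: np.ndarray) -> Tuple[np.ndarray, Ellipse]:
    """Direct least-squares ellipse fit to >=5 in-plane points.

    Returns the in-plane centre offset and the fitted :class:`Ellipse`.
    Degenerate inputs (collinear points, non-elliptical conics) raise
    :class:`EllipseFitError`.
    """
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 5 or pts.shape[1] != 2:
        raise EllipseFitError("need at least 5 two-dimensional points")
    if hasattr(EllipseModel, "from_estimate"):  # scikit-image >= 0.26
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise EllipseFitError("ellipse fit failed (degenerate points?)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        model = EllipseModel()
        if not model.estimate(pts):
            raise EllipseFitError("ellipse fit failed (degenerate points?)")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("ellipse fit failed (degenerate points?)")
    if a <= 0 or b <= 0:
        raise EllipseFitError("fit produced non-positive axes")
    return np.array([xc, yc]), Ellipse(a=float(a), b=float(b), phi=float(theta))
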