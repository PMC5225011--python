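"""Particle-filter tracking of the colonic lumen.

A cloud of 15-D states — centre, 3x3 reference frame, ellipse (a, b, phi) —
is advanced along the lumen one tangent step at a time.  Each particle is
weighted by how well wall detections on radial rays agree with its predicted
ellipse; a dynamic intensity threshold separating lumen from wall voxels is
re-estimated after every iteration; weight degeneracy (effective sample size
below a fraction of the ensemble) terminates the track, which in practice
fires at local collapse, intraluminal matter or loss of wall contrast.

The weighted particle history over all iterations is the input to the
centreline stage.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    Ellipse,
    Frame,
    double_reflection_step,
    ellipse_points,
    perturb_normal,
)
from .volume import Volume

__all__ = [
    "ParticleState",
    "BoundaryDetection",
    "TrackerConfig",
    "IterationRecord",
    "TrackHistory",
    "TrackerError",
    "predict",
    "detect_boundary",
    "measurement_cost",
    "update_weights",
    "effective_sample_size",
    "resample",
    "update_threshold",
    "initial_threshold",
    "run_tracker",
]


class TrackerError(RuntimeError):
    pass


@dataclasses.dataclass
class ParticleState:
    """Tracker state: centre ``c`` (mm), frame ``R``, ellipse ``e``, weight ``q``."""

    c: np.ndarray
    R: Frame
    e: Ellipse
    q: float = 1.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64).reshape(3)
        if self.q < 0:
            raise ValueError("weight must be >= 0")

    def copy(self) -> "ParticleState":
        return ParticleState(self.c.copy(), self.R, Ellipse(self.e.a, self.e.b, self.e.phi), self.q)


@dataclasses.dataclass
class BoundaryDetection:
    """Per-angle wall detections for one particle.

    ``radii`` holds the detection distance from the particle centre per ray
    (NaN where missing); ``points`` the corresponding world points;
    ``upsilon`` the fraction of detections strictly inside the eta-scaled
    inner ellipse; ``omega`` the fraction of rays with a detection.
    """

    points: np.ndarray   # (H, 3), NaN rows where missing
    radii: np.ndarray    # (H,)
    ellipse_radii: np.ndarray  # (H,) predicted boundary distance per ray
    upsilon: float
    omega: float

    @property
    def detected(self) -> np.ndarray:
        return np.isfinite(self.radii)


@dataclasses.dataclass
class TrackerConfig:
    """Tunables of the tracking stage (all lengths mm, angles radians).

    The wall-sampling depth (3 mm) matches a typical bowel wall; the
    termination fraction (1%) is the effective-sample-size rule.  ``W=None``
    auto-calibrates the weighting sharpness so the median first-iteration
    cost maps to unit exponent; the calibrated value is recorded in the
    history.  ``literal_cost`` switches the measurement penalty to the
    literal printed form ``F (1 - Upsilon) Omega`` for comparison.
    """

    Ns: int = 500
    H: int = 32
    sigma_c: float = 0.5
    sigma_e: Tuple[float, float, float] = (0.25, 0.25, 0.05)
    sigma_psi: float = 0.15
    eta: float = 0.5
    W: Optional[float] = None
    tau: float = 0.5
    wall_depth_mm: float = 3.0
    max_radius_mm: float = 25.0
    ess_frac: float = 0.01
    T_max: int = 500
    step_mm: float = 1.0
    ray_step_factor: float = 0.25
    lambda_upsilon: float = 10.0
    omega_eps: float = 1e-3
    literal_cost: bool = False
    min_axis_mm: float = 0.5
    end_tol_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.Ns < 2:
            raise ValueError("Ns must be >= 2")
        if not (0 < self.eta < 1):
            raise ValueError("eta must be in (0, 1)")
        if not (0 < self.tau < 1):
            raise ValueError("tau must be in (0, 1)")
        if not (0 < self.ess_frac < 1):
            raise ValueError("ess_frac must be in (0, 1)")


@dataclasses.dataclass
class IterationRecord:
    states: List[ParticleState]  # weights as of this iteration (pre-resampling)
    k: float
    ess: float


@dataclasses.dataclass
class TrackHistory:
    iterations: List[IterationRecord]
    termination_reason: str
    W: float
    seed_state: ParticleState

    def particle_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """All particle centres and weights pooled over iterations."""
        cs, qs = [], []
        for it in self.iterations:
            for st in it.states:
                cs.append(st.c)
                qs.append(st.q)
        return np.asarray(cs), np.asarray(qs)

    def mean_centres(self) -> np.ndarray:
        """Weighted ensemble mean centre per iteration."""
        out = []
        for it in self.iterations:
            c = np.array([st.c for st in it.states])
            q = np.array([st.q for st in it.states])
            out.append((c * q[:, None]).sum(axis=0) / max(q.sum(), 1e-300))
        return np.asarray(out)

    def thresholds(self) -> np.ndarray:
        return np.array([it.k for it in self.iterations])


# -- prediction ------------------------------------------------------------


def predict(
    x: ParticleState, cfg: TrackerConfig, rng: np.random.Generator
) -> ParticleState:
    """One prediction step: advance the centre along the frame tangent with
    Gaussian positional noise, perturb the ellipse, and rotate the frame by
    a rotation-minimising step toward a direction drawn about the pole."""
    c_new = x.c + cfg.step_mm * x.R.t + rng.normal(0.0, cfg.sigma_c, size=3)

    ea = x.e.a + rng.normal(0.0, cfg.sigma_e[0])
    eb = x.e.b + rng.normal(0.0, cfg.sigma_e[1])
    ep = x.e.phi + rng.normal(0.0, cfg.sigma_e[2])
    ea = max(ea, cfg.min_axis_mm)
    eb = max(eb, cfg.min_axis_mm)
    e_new = Ellipse(a=max(ea, eb), b=min(ea, eb), phi=ep if ea >= eb else ep + math.pi / 2)

    if cfg.sigma_psi > 0:
        direction = perturb_normal(cfg.sigma_psi, rng)
        # local frame: one RMF step from the pole to the sampled direction
        local = double_reflection_step(
            np.zeros(3), Frame.identity(), direction, direction
        )
        R_new = Frame(x.R.matrix @ local.matrix)
    else:
        R_new = x.R
    return ParticleState(c_new, R_new, e_new, x.q)


# -- measurement -----------------------------------------------------------


def detect_boundary(
    vol: Volume, x: ParticleState, k: float, cfg: TrackerConfig
) -> BoundaryDetection:
    """March radial rays from the particle centre through its ellipse
    boundary points; the first sub-voxel sample exceeding threshold ``k`` is
    the wall detection for that ray.  Rays that leave the volume or reach
    ``max_radius_mm`` first are missing."""
    u = ellipse_points(x.c, x.R, x.e, cfg.H)
    rel = u - x.c
    r_u = np.linalg.norm(rel, axis=1)
    dirs = rel / r_u[:, None]

    step = cfg.ray_step_factor * vol.min_spacing
    radii = np.arange(step, cfg.max_radius_mm + step / 2, step)
    pts = x.c + radii[None, :, None] * dirs[:, None, :]  # (H, n, 3)
    vals = vol.sample(pts.reshape(-1, 3)).reshape(cfg.H, radii.size)

    hit = vals > k
    invalid = ~np.isfinite(vals)
    n = radii.size
    first_hit = np.where(hit.any(axis=1), hit.argmax(axis=1), n)
    first_bad = np.where(invalid.any(axis=1), invalid.argmax(axis=1), n)
    ok = first_hit < first_bad

    det_r = np.full(cfg.H, np.nan)
    det_r[ok] = radii[first_hit[ok]]
    det_p = np.full((cfg.H, 3), np.nan)
    det_p[ok] = x.c + det_r[ok, None] * dirs[ok]

    omega = float(ok.mean())
    if ok.any():
        # proportion of all rays whose detection falls strictly inside the
        # eta-scaled ellipse
        upsilon = float((det_r[ok] < cfg.eta * r_u[ok]).sum() / cfg.H)
    else:
        upsilon = 0.0
    return BoundaryDetection(det_p, det_r, r_u, upsilon, omega)


def measurement_cost(
    det: BoundaryDetection, x: ParticleState, cfg: TrackerConfig
) -> float:
    """Cost of a state given its detections.

    ``F`` is the mean squared distance between detections and the predicted
    ellipse over detected rays.  The composed cost strictly increases with
    missing rays and with detections inside the inner ellipse:
    ``d = F (1 + lambda Upsilon) / max(Omega, eps)`` (the literal printed
    product ``F (1 - Upsilon) Omega`` is available via ``literal_cost``).
    No detections at all yield infinite cost."""
    ok = det.detected
    if not ok.any():
        return math.inf
    F = float(np.mean((det.radii[ok] - det.ellipse_radii[ok]) ** 2))
    if cfg.literal_cost:
        return F * (1.0 - det.upsilon) * det.omega
    return F * (1.0 + cfg.lambda_upsilon * det.upsilon) / max(det.omega, cfg.omega_eps)


def update_weights(
    prev_q: np.ndarray, costs: Sequence[float], W: float
) -> np.ndarray:
    """Multiply prior weights by the softmax likelihood exp(-W d) and
    renormalise; infinite-cost particles receive weight zero."""
    prev_q = np.asarray(prev_q, dtype=np.float64)
    d = np.asarray(costs, dtype=np.float64)
    if prev_q.shape != d.shape:
        raise ValueError("weight/cost length mismatch")
    finite = np.isfinite(d)
    if not finite.any():
        raise TrackerError("all particle costs are infinite")
    logw = np.full(d.shape, -np.inf)
    with np.errstate(invalid="ignore"):
        logw[finite] = np.log(np.maximum(prev_q[finite], 1e-300)) - W * d[finite]
    logw -= logw[finite].max()
    w = np.exp(logw)
    return w / w.sum()


def effective_sample_size(q: np.ndarray) -> float:
    """ESS = 1 / sum(q_i^2) for normalised weights."""
    q = np.asarray(q, dtype=np.float64)
    return float(1.0 / np.sum(q**2))


def resample(
    particles: Sequence[ParticleState], rng: np.random.Generator
) -> List[ParticleState]:
    """Systematic resampling; output weights uniform, expected multiplicity
    of particle i equal to Ns q_i (realised counts within floor/ceil)."""
    q = np.array([p.q for p in particles], dtype=np.float64)
    q = q / q.sum()
    n = len(particles)
    positions = (rng.random() + np.arange(n)) / n
    cum = np.cumsum(q)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions, side="right")
    out = []
    for i in idx:
        p = particles[int(i)].copy()
        p.q = 1.0 / n
        out.append(p)
    return out


# -- dynamic threshold -----------------------------------------------------


def _threshold_objective(
    vw: np.ndarray, vl: np.ndarray, candidates: np.ndarray, tau: float
) -> np.ndarray:
    vw_s = np.sort(vw)
    vl_s = np.sort(vl)
    n_wall_above = vw_s.size - np.searchsorted(vw_s, candidates, side="right")
    n_lumen_below = np.searchsorted(vl_s, candidates, side="left")
    return tau * n_wall_above + (1.0 - tau) * n_lumen_below


def threshold_from_samples(
    vw: np.ndarray,
    vl: np.ndarray,
    tau: float,
    candidates: Optional[np.ndarray] = None,
) -> float:
    """Threshold maximising tau * #{wall > k} + (1-tau) * #{lumen < k} by
    linear search over the candidate set (default: the sorted unique sampled
    intensities); ties resolve to the smallest candidate."""
    vw = np.asarray(vw, dtype=np.float64)
    vl = np.asarray(vl, dtype=np.float64)
    if candidates is None:
        candidates = np.unique(np.concatenate([vw, vl]))
    else:
        candidates = np.sort(np.asarray(candidates, dtype=np.float64))
    if candidates.size == 0:
        raise ValueError("no threshold candidates")
    obj = _threshold_objective(vw, vl, candidates, tau)
    return float(candidates[int(np.argmax(obj))])


def _wall_lumen_samples(
    vol: Volume,
    detections: Sequence[BoundaryDetection],
    centres: Sequence[np.ndarray],
    cfg: TrackerConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    step = cfg.ray_step_factor * vol.min_spacing
    offs = np.arange(0.0, cfg.wall_depth_mm + step / 2, step)
    wall_pts, lumen_pts = [], []
    for det, c in zip(detections, centres):
        ok = det.detected
        if not ok.any():
            continue
        p = det.points[ok]
        dirs = (p - c) / np.linalg.norm(p - c, axis=1)[:, None]
        wall_pts.append((p[:, None, :] + offs[None, :, None] * dirs[:, None, :]).reshape(-1, 3))
        inward = offs[1:]
        lumen_pts.append((p[:, None, :] - inward[None, :, None] * dirs[:, None, :]).reshape(-1, 3))
    if not wall_pts:
        return np.empty(0), np.empty(0)
    vw = vol.sample(np.concatenate(wall_pts))
    vl = vol.sample(np.concatenate(lumen_pts))
    return vw[np.isfinite(vw)], vl[np.isfinite(vl)]


def update_threshold(
    vol: Volume,
    detections: Sequence[BoundaryDetection],
    centres: Sequence[np.ndarray],
    cfg: TrackerConfig,
    prev_k: Optional[float] = None,
) -> Tuple[float, bool]:
    """Re-estimate the wall threshold from all particles' detections.

    Wall voxels are sampled 3 mm outward from every detected wall point
    along its centre-to-detection ray, lumen voxels 3 mm inward; the
    threshold maximises the group separation.  Without any detections the
    previous threshold is retained and flagged."""
    vw, vl = _wall_lumen_samples(vol, detections, centres, cfg)
    if vw.size == 0 or vl.size == 0:
        if prev_k is None:
            raise TrackerError("no detections and no previous threshold")
        return float(prev_k), False
    return threshold_from_samples(vw, vl, cfg.tau), True


def initial_threshold(
    vol: Volume, seed_state: ParticleState, cfg: TrackerConfig
) -> float:
    """Threshold from the seed cross-section, taking the seed ellipse's own
    boundary points as wall positions (the seed ellipse is fitted to the
    inner wall)."""
    u = ellipse_points(seed_state.c, seed_state.R, seed_state.e, cfg.H)
    rel = np.linalg.norm(u - seed_state.c, axis=1)
    det = BoundaryDetection(
        points=u,
        radii=rel,
        ellipse_radii=rel,
        upsilon=0.0,
        omega=1.0,
    )
    vw, vl = _wall_lumen_samples(vol, [det], [seed_state.c], cfg)
    if vw.size == 0 or vl.size == 0:
        raise TrackerError("seed cross-section leaves the volume")
    return threshold_from_samples(vw, vl, cfg.tau)


# -- main loop -------------------------------------------------------------


def run_tracker(
    vol: Volume,
    seed_state: ParticleState,
    cfg: TrackerConfig,
    rng: np.random.Generator,
    end_point: Optional[np.ndarray] = None,
) -> TrackHistory:
    """Run the full prediction/measurement/resampling loop.

    Per iteration: predict every particle, detect wall points, compute
    costs, update weights, record the ensemble, test termination (effective
    sample size below ``ess_frac * Ns``; optionally proximity to
    ``end_point``), then resample and refresh the dynamic threshold.
    Deterministic given ``rng``'s seed."""
    k = initial_threshold(vol, seed_state, cfg)
    particles = [
        ParticleState(seed_state.c.copy(), seed_state.R, Ellipse(seed_state.e.a, seed_state.e.b, seed_state.e.phi), 1.0 / cfg.Ns)
        for _ in range(cfg.Ns)
    ]
    W = cfg.W
    history: List[IterationRecord] = []
    reason = "t_max"
    for t in range(1, cfg.T_max + 1):
        particles = [predict(p, cfg, rng) for p in particles]
        detections = [detect_boundary(vol, p, k, cfg) for p in particles]
        costs = np.array(
            [measurement_cost(d, p, cfg) for d, p in zip(detections, particles)]
        )
        finite = np.isfinite(costs)
        if not finite.any():
            if t == 1:
                raise TrackerError("tracking failed at seed")
            reason = "no_wall"
            break
        if W is None:
            med = float(np.median(costs[finite]))
            W = 1.0 / med if med > 1e-12 else 1.0
        prev_q = np.array([p.q for p in particles])
        prev_q = prev_q / prev_q.sum()
        q = update_weights(prev_q, costs, W)
        for p, qi in zip(particles, q):
            p.q = float(qi)
        ess = effective_sample_size(q)
        history.append(
            IterationRecord(states=[p.copy() for p in particles], k=k, ess=ess)
        )
        if ess < cfg.ess_frac * cfg.Ns:
            if t == 1:
                raise TrackerError("tracking failed at seed")
            reason = "ess_collapse"
            break
        if end_point is not None:
            mean_c = (np.array([p.c for p in particles]) * q[:, None]).sum(axis=0)
            if np.linalg.norm(mean_c - np.asarray(end_point)) < cfg.end_tol_mm:
                reason = "end_reached"
                break
        centres = [p.c for p in particles]
        particles = resample(particles, rng)
        k, _ = update_threshold(vol, detections, centres, cfg, prev_k=k)
    if not history:
        raise TrackerError("tracking failed at seed")
    return TrackHistory(
        iterations=history,
        termination_reason=reason,
        W=float(W if W is not None else 0.0),
        seed_state=seed_state,
    )
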