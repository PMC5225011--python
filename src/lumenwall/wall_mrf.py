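"""Inner/outer bowel-wall localisation by MRF labelling on radial sections.

At regular arc-length intervals along the centreline a reference frame is
taken and the image is resampled on a radial lattice (angle theta around the
tangent, distance f from the centre).  Finding the inner wall becomes a
labelling problem: one site per (frame, angle), labels are radial distances,
node potentials reward a strong image gradient pointing outward with no
supra-threshold (wall-intensity) voxels crossed on the way, and edge
potentials tie neighbouring sites — adjacent angles and the same angle on
adjacent frames — to similar distances and intensities.  Max-product belief
propagation (exact on trees, empirically reliable on these ring-structured
graphs) yields the inner contour; the outer wall is then localised the same
way on rays cast outward along the inner contour's normals, rewarding a
gradient pointing back toward the lumen beyond the first local minimum of
gradient magnitude.  Wall thickness is the inner-to-outer distance per site.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .centreline import Centreline
from .geometry import Frame
from .tracker import TrackHistory
from .volume import Volume

__all__ = [
    "WallConfig",
    "RadialSection",
    "WallGraph",
    "WallMeasurement",
    "BPResult",
    "build_sections",
    "inner_node_potentials",
    "edge_potential",
    "bp_map",
    "outer_node_potentials",
    "measure_walls",
    "match_to_roi",
    "measurements_to_dataframe",
    "write_point_cloud_ply",
]

_FLOOR = 1e-12


@dataclasses.dataclass
class WallConfig:
    """Tunables of the wall-measurement stage.

    Label grids are radial distances in mm (inner: from the frame centre;
    outer: from the inner-wall point along its outward normal).  ``beta``
    controls the per-crossed-voxel attenuation of the inner node potential,
    ``gamma`` (per mm) the distance-continuity rate and ``lam`` the
    intensity-similarity sharpness of the edge potential; ``kappa`` is an
    overall outer-potential scale (argmax-invariant).  ``literal_h2``
    switches the inner attenuation to the literal printed form
    ``beta * count`` for comparison.
    """

    spacing_mm: float = 1.0
    n_angles: int = 64
    inner_f_min: float = 1.0
    inner_f_max: float = 20.0
    outer_f_min: float = 0.5
    outer_f_max: float = 10.0
    f_step: float = 0.25
    beta: float = 0.5
    gamma: float = 1.0
    lam: float = 4.0
    kappa: float = 1.0
    bp_iters: int = 50
    bp_damping: float = 0.5
    bp_tol: float = 1e-8
    smooth_sigma_mm: Optional[float] = None
    literal_h2: bool = False
    floor: float = _FLOOR

    def inner_labels(self) -> np.ndarray:
        return np.arange(self.inner_f_min, self.inner_f_max + self.f_step / 2, self.f_step)

    def outer_labels(self) -> np.ndarray:
        return np.arange(self.outer_f_min, self.outer_f_max + self.f_step / 2, self.f_step)


@dataclasses.dataclass
class RadialSection:
    """Image samples on one frame's radial lattice."""

    frame_index: int
    arc_length: float
    centre: np.ndarray
    frame: Frame
    k: float                      # wall threshold for this frame
    theta: np.ndarray             # (A,)
    labels: np.ndarray            # (L,) strictly increasing, > 0
    ray_f: np.ndarray             # (M,) dense radial samples from ~0 outward
    intensity: np.ndarray         # (A, L)
    gradient: np.ndarray          # (A, L, 3)
    ray_intensity: np.ndarray     # (A, M) along each ray, for obstruction counts
    outside: np.ndarray           # (A, L) True where the lattice left the volume

    def ray_dirs(self) -> np.ndarray:
        """Unit in-plane outward direction per angle, shape (A, 3)."""
        ct, st = np.cos(self.theta), np.sin(self.theta)
        return ct[:, None] * self.frame.r[None, :] + st[:, None] * self.frame.s[None, :]


@dataclasses.dataclass
class WallGraph:
    """Pairwise MRF over sites with a shared label grid.

    ``log_node`` is (S, L); each undirected edge (u, v) carries a (L, L)
    log-potential matrix indexed [f_u, f_v].  ``uniform_ok`` marks sites
    whose node potential is legitimately uninformative (resolved via edges).
    """

    labels: np.ndarray
    log_node: np.ndarray
    edges: List[Tuple[int, int]]
    log_edge: List[np.ndarray]
    uniform_ok: Optional[np.ndarray] = None

    @property
    def n_sites(self) -> int:
        return self.log_node.shape[0]


@dataclasses.dataclass
class BPResult:
    labels_idx: np.ndarray
    labels_f: np.ndarray
    beliefs: np.ndarray
    converged: bool
    iterations: int


@dataclasses.dataclass
class WallMeasurement:
    frame_index: int
    arc_length: float
    angle: float
    inner: np.ndarray
    outer: np.ndarray
    thickness: float
    flags: str = ""

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


# -- sections --------------------------------------------------------------


def _threshold_lookup(history: Optional[TrackHistory]):
    if history is None:
        return None
    centres = history.mean_centres()
    ks = history.thresholds()
    def lookup(c: np.ndarray) -> float:
        i = int(np.argmin(np.linalg.norm(centres - c, axis=1)))
        return float(ks[i])
    return lookup


def build_sections(
    vol: Volume,
    cl: Centreline,
    cfg: WallConfig,
    history: Optional[TrackHistory] = None,
    k: Optional[float] = None,
) -> List[RadialSection]:
    """Sample radial lattices at every ``spacing_mm`` of centreline arc.

    The per-frame wall threshold comes from the tracker's threshold history
    (nearest iteration by ensemble-mean centre) or an explicit ``k``.
    Lattice points outside the volume are flagged and carry zero potential.
    """
    if cl.length < cfg.spacing_mm:
        raise ValueError("centreline shorter than the section spacing")
    if history is None and k is None:
        raise ValueError("need a tracker history or an explicit threshold k")
    lookup = _threshold_lookup(history)
    targets = np.arange(0.0, cl.length + 1e-9, cfg.spacing_mm)
    idxs = np.searchsorted(cl.arc_length, targets)
    idxs = np.unique(np.clip(idxs, 0, len(cl.points) - 1))

    labels = cfg.inner_labels()
    theta = 2.0 * math.pi * np.arange(cfg.n_angles) / cfg.n_angles
    ray_f = np.arange(cfg.f_step, cfg.inner_f_max + cfg.f_step / 2, cfg.f_step)
    sections = []
    for fi in idxs:
        c = cl.points[fi]
        fr = cl.frames[fi]
        dirs = (
            np.cos(theta)[:, None] * fr.r[None, :]
            + np.sin(theta)[:, None] * fr.s[None, :]
        )
        lat = c[None, None, :] + labels[None, :, None] * dirs[:, None, :]
        flat = lat.reshape(-1, 3)
        inten = vol.sample(flat).reshape(cfg.n_angles, labels.size)
        grad = vol.sample_gradient(flat, smooth_sigma_mm=cfg.smooth_sigma_mm).reshape(
            cfg.n_angles, labels.size, 3
        )
        rays = c[None, None, :] + ray_f[None, :, None] * dirs[:, None, :]
        ray_int = vol.sample(rays.reshape(-1, 3)).reshape(cfg.n_angles, ray_f.size)
        outside = ~np.isfinite(inten) | ~np.isfinite(grad).all(axis=-1)
        kf = float(k) if k is not None else lookup(c)
        sections.append(
            RadialSection(
                frame_index=int(fi),
                arc_length=float(cl.arc_length[fi]),
                centre=c,
                frame=fr,
                k=kf,
                theta=theta,
                labels=labels,
                ray_f=ray_f,
                intensity=inten,
                gradient=grad,
                ray_intensity=ray_int,
                outside=outside,
            )
        )
    return sections


# -- potentials ------------------------------------------------------------

_COS_PI4 = math.cos(math.pi / 4.0)


def _gradient_term(grad: np.ndarray, dirs: np.ndarray, sign: float) -> np.ndarray:
    """|grad| weighted by alignment of the gradient with ``sign * dirs``.

    Full weight when the (signed) gradient direction is within pi/4 of the
    ray direction; otherwise attenuated by ((dot + 1)/2)^2 where ``dot`` is
    the signed-direction cosine."""
    mag = np.linalg.norm(grad, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dot = np.einsum("...i,...i->...", grad, sign * dirs) / np.where(
            mag > 0, mag, 1.0
        )
    att = ((dot + 1.0) / 2.0) ** 2
    out = np.where(dot >= _COS_PI4, mag, mag * att)
    return np.where(np.isfinite(out), out, 0.0)


def inner_node_potentials(sec: RadialSection, beta: Optional[float] = None,
                          literal: bool = False) -> np.ndarray:
    """Inner-wall node potential table V(angle, label) >= 0.

    H1 rewards a strong gradient pointing along the outward ray (within
    pi/4; quadratically attenuated otherwise).  H2 attenuates labels that
    lie beyond bright structures: with c the number of supra-threshold ray
    samples strictly closer than the label, not counting the first
    contiguous bright run (the wall itself), H2 = beta^c — 1 for an
    unobstructed ray.  The literal cumulative form beta*c is available for
    comparison."""
    if beta is None:
        beta = 0.5
    dirs = sec.ray_dirs()
    h1 = _gradient_term(sec.gradient, dirs[:, None, :], +1.0)

    supra = np.where(np.isfinite(sec.ray_intensity), sec.ray_intensity, 0.0) > sec.k
    counts = _obstruction_counts(supra)
    # counts at dense ray positions -> at label positions (strictly before label)
    pos = np.searchsorted(sec.ray_f, sec.labels - 1e-9)
    c_at = np.concatenate([np.zeros((supra.shape[0], 1)), counts], axis=1)[:, pos]
    if literal:
        h2 = beta * c_at
        h2 = np.where(c_at > 0, h2, 1.0)
    else:
        h2 = beta**c_at
    v = h1 * h2
    v[sec.outside] = 0.0
    return v


def _obstruction_counts(supra: np.ndarray) -> np.ndarray:
    """Cumulative supra-threshold counts excluding the first contiguous run.

    ``supra`` is (A, M) booleans along each ray; returns (A, M) where entry
    m counts supra samples at positions <= m that do not belong to the first
    bright run of that ray."""
    A, M = supra.shape
    cum = np.cumsum(supra, axis=1)
    first = np.where(supra.any(axis=1), supra.argmax(axis=1), M)
    # length of the first contiguous run per ray
    run_len = np.zeros(A, dtype=int)
    for a in range(A):
        f = first[a]
        if f >= M:
            continue
        r = 0
        while f + r < M and supra[a, f + r]:
            r += 1
        run_len[a] = r
    # samples in the first run contribute nothing
    idx = np.arange(M)[None, :]
    in_run = (idx >= first[:, None]) & (idx < (first + run_len)[:, None])
    cum_run = np.cumsum(in_run, axis=1)
    return cum - cum_run


def edge_potential(
    f_i: np.ndarray,
    f_j: np.ndarray,
    I_i: np.ndarray,
    I_j: np.ndarray,
    gamma: float = 1.0,
    lam: float = 4.0,
) -> np.ndarray:
    """Pairwise agreement potential, maximal (=1) at equal distance and
    equal intensity: exp(-gamma |f_i - f_j|) * exp(-lam (1 - min/max)^2).
    Symmetric; two zero intensities count as perfectly similar."""
    f_i, f_j = np.asarray(f_i, float), np.asarray(f_j, float)
    I_i = np.maximum(np.asarray(I_i, float), 0.0)
    I_j = np.maximum(np.asarray(I_j, float), 0.0)
    hi = np.maximum(I_i, I_j)
    lo = np.minimum(I_i, I_j)
    dis = np.where(hi > 0, 1.0 - lo / np.where(hi > 0, hi, 1.0), 0.0)
    return np.exp(-gamma * np.abs(f_i - f_j)) * np.exp(-lam * dis**2)


def _edge_matrix(
    labels: np.ndarray, I_u: np.ndarray, I_v: np.ndarray, gamma: float, lam: float
) -> np.ndarray:
    return edge_potential(
        labels[:, None], labels[None, :], I_u[:, None], I_v[None, :], gamma, lam
    )


def _ring_graph_edges(n_frames: int, n_angles: int) -> List[Tuple[int, int]]:
    """Angular ring edges (wrapping) plus same-angle inter-frame edges."""
    edges = []
    for t in range(n_frames):
        base = t * n_angles
        for i in range(n_angles):
            edges.append((base + i, base + (i + 1) % n_angles))
        if t + 1 < n_frames:
            nxt = (t + 1) * n_angles
            for i in range(n_angles):
                edges.append((base + i, nxt + i))
    return edges


def build_wall_graph(
    labels: np.ndarray,
    node_pot: np.ndarray,            # (S, L) raw potentials >= 0
    site_intensity: np.ndarray,      # (S, L) intensity at each site's label points
    edges: List[Tuple[int, int]],
    gamma: float,
    lam: float,
    floor: float = _FLOOR,
    uniform_ok: Optional[np.ndarray] = None,
) -> WallGraph:
    """Assemble log-domain node/edge tables; zero node rows either raise
    (naming the site) or, when flagged in ``uniform_ok``, become uniform."""
    node = np.array(node_pot, dtype=np.float64)
    S = node.shape[0]
    if uniform_ok is None:
        uniform_ok = np.zeros(S, dtype=bool)
    dead = ~(node.max(axis=1) > 0)
    bad = np.where(dead & ~uniform_ok)[0]
    if bad.size:
        raise ValueError(f"all-zero node potentials at site {int(bad[0])}")
    node[dead] = 1.0
    log_node = np.log(np.maximum(node, floor))
    log_edge = []
    for (u, v) in edges:
        m = _edge_matrix(labels, site_intensity[u], site_intensity[v], gamma, lam)
        log_edge.append(np.log(np.maximum(m, floor)))
    return WallGraph(
        labels=np.asarray(labels, float),
        log_node=log_node,
        edges=list(edges),
        log_edge=log_edge,
        uniform_ok=uniform_ok,
    )


# -- max-product belief propagation ---------------------------------------


def bp_map(graph: WallGraph, T_iters: int = 50, damping: float = 0.5,
           tol: float = 1e-8) -> BPResult:
    """Parallel max-product BP in the log domain.

    Messages start uniform, are normalised to max zero each sweep and
    damped for stability on loopy graphs; iteration stops at ``T_iters`` or
    when the largest message change falls below ``tol``.  Each site takes
    the label with maximum belief; ties resolve to the smallest distance."""
    S, L = graph.log_node.shape
    E = len(graph.edges)
    src = np.empty(2 * E, dtype=int)
    dst = np.empty(2 * E, dtype=int)
    logM = np.empty((2 * E, L, L), dtype=np.float64)
    for e, (u, v) in enumerate(graph.edges):
        src[e], dst[e] = u, v
        logM[e] = graph.log_edge[e]
        src[E + e], dst[E + e] = v, u
        logM[E + e] = graph.log_edge[e].T
    rev = np.concatenate([np.arange(E, 2 * E), np.arange(0, E)])

    m = np.zeros((2 * E, L))
    converged = False
    it = 0
    for it in range(1, T_iters + 1):
        incoming = np.zeros((S, L))
        np.add.at(incoming, dst, m)
        A = graph.log_node[src] + incoming[src] - m[rev]
        new_m = np.empty_like(m)
        for c0 in range(0, 2 * E, 512):  # chunked to bound temporaries
            c1 = min(c0 + 512, 2 * E)
            new_m[c0:c1] = (A[c0:c1, :, None] + logM[c0:c1]).max(axis=1)
        new_m -= new_m.max(axis=1, keepdims=True)
        delta = float(np.max(np.abs(new_m - m)))
        m = damping * m + (1.0 - damping) * new_m
        if delta < tol:
            converged = True
            break
    incoming = np.zeros((S, L))
    np.add.at(incoming, dst, m)
    beliefs = graph.log_node + incoming
    labels_idx = beliefs.argmax(axis=1)  # first max = smallest distance
    return BPResult(
        labels_idx=labels_idx,
        labels_f=graph.labels[labels_idx],
        beliefs=beliefs,
        converged=converged,
        iterations=it,
    )


def map_assignment_score(graph: WallGraph, labels_idx: np.ndarray) -> float:
    """Log-score of a full assignment (node plus undirected edge terms)."""
    s = float(graph.log_node[np.arange(graph.n_sites), labels_idx].sum())
    for e, (u, v) in enumerate(graph.edges):
        s += float(graph.log_edge[e][labels_idx[u], labels_idx[v]])
    return s


# -- outer wall ------------------------------------------------------------


def _contour_normals(
    contour: np.ndarray, centre: np.ndarray, frame: Frame
) -> np.ndarray:
    """Outward in-plane normals of a closed per-frame contour, smoothed
    over three sites."""
    rel = contour - centre
    q = np.stack([rel @ frame.r, rel @ frame.s], axis=1)  # (A, 2)
    tang = np.roll(q, -1, axis=0) - np.roll(q, 1, axis=0)
    nrm = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    flip = np.einsum("ij,ij->i", nrm, q) < 0
    nrm[flip] *= -1.0
    nrm = (np.roll(nrm, 1, axis=0) + nrm + np.roll(nrm, -1, axis=0)) / 3.0
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-12)
    return nrm[:, 0:1] * frame.r[None, :] + nrm[:, 1:2] * frame.s[None, :]


def _first_local_min_counts(gmag: np.ndarray) -> np.ndarray:
    """Eq-style run counter from the first local minimum of |grad| per ray.

    Returns (A, M) with 0 before the first local minimum, 1 at it and
    incrementing outward; all zeros when the profile has no interior
    minimum."""
    A, M = gmag.shape
    out = np.zeros((A, M))
    tol = 1e-12
    for a in range(A):
        g = gmag[a]
        cand = -1
        descending = False
        for m in range(1, M):
            if g[m] < g[m - 1] - tol:
                descending = True
                cand = m
            elif descending and g[m] > g[m - 1] + tol:
                break
            elif descending and cand == -1:
                cand = m
        if cand >= 0 and descending:
            out[a, cand:] = np.arange(1, M - cand + 1)
    return out


def outer_node_potentials(
    sec: RadialSection,
    inner_points: np.ndarray,
    vol: Volume,
    cfg: WallConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Outer-wall potentials on rays along the inner contour's normals.

    Returns ``(V, ray_points, intensities, flagged)`` where ``V`` is
    (A, L_out) over the outer label grid (distance from the inner point),
    ``flagged`` marks rays with no local gradient-magnitude minimum (their
    potential is identically zero and the site is resolved via edges).

    H1 mirrors the inner gradient term with the sign flipped: full weight
    when the gradient points back toward the lumen (intensity decreasing
    outward).  H2 = kappa * F where F counts positions from the first local
    minimum of gradient magnitude outward."""
    labels = cfg.outer_labels()
    normals = _contour_normals(inner_points, sec.centre, sec.frame)
    ray_f = np.arange(0.0, cfg.outer_f_max + cfg.f_step / 2, cfg.f_step)
    pts = inner_points[:, None, :] + ray_f[None, :, None] * normals[:, None, :]
    flat = pts.reshape(-1, 3)
    grad = vol.sample_gradient(flat, smooth_sigma_mm=cfg.smooth_sigma_mm).reshape(
        len(normals), ray_f.size, 3
    )
    inten = vol.sample(flat).reshape(len(normals), ray_f.size)
    gmag = np.linalg.norm(grad, axis=-1)
    gmag = np.where(np.isfinite(gmag), gmag, 0.0)

    h1_full = _gradient_term(grad, normals[:, None, :], -1.0)
    F = _first_local_min_counts(gmag)
    v_full = h1_full * (cfg.kappa * F)

    pos = np.searchsorted(ray_f, labels - 1e-9)
    V = v_full[:, pos]
    ray_points = pts[:, pos, :]
    intens = np.where(np.isfinite(inten), inten, 0.0)[:, pos]
    outside = ~np.isfinite(inten[:, pos])
    V = np.where(outside, 0.0, V)
    flagged = ~(V.max(axis=1) > 0)
    return V, ray_points, intens, flagged


# -- assembly --------------------------------------------------------------


def measure_walls(
    vol: Volume,
    cl: Centreline,
    cfg: Optional[WallConfig] = None,
    history: Optional[TrackHistory] = None,
    k: Optional[float] = None,
) -> List[WallMeasurement]:
    """Full wall measurement along a centreline.

    Sections are built at regular intervals; inner-wall BP runs over the
    full multi-frame graph; per frame, the inner contour seeds outward rays
    for the outer-wall graph (same edge potentials); thickness is the
    distance from inner to outer point per (frame, angle)."""
    cfg = cfg or WallConfig()
    sections = build_sections(vol, cl, cfg, history=history, k=k)
    if not sections:
        raise ValueError("no sections along centreline")
    A = cfg.n_angles
    nF = len(sections)
    labels_in = cfg.inner_labels()

    node = np.concatenate(
        [inner_node_potentials(s, beta=cfg.beta, literal=cfg.literal_h2) for s in sections],
        axis=0,
    )
    site_int = np.concatenate(
        [np.where(np.isfinite(s.intensity), s.intensity, 0.0) for s in sections], axis=0
    )
    edges = _ring_graph_edges(nF, A)
    try:
        graph = build_wall_graph(
            labels_in, node, site_int, edges, cfg.gamma, cfg.lam, cfg.floor
        )
    except ValueError as exc:
        raise ValueError(f"inner wall graph: {exc}") from exc
    inner_bp = bp_map(graph, cfg.bp_iters, cfg.bp_damping, cfg.bp_tol)
    f_inner = inner_bp.labels_f.reshape(nF, A)

    # inner contours per frame -> outer graph on normal-directed rays
    labels_out = cfg.outer_labels()
    node_out = np.empty((nF * A, labels_out.size))
    int_out = np.empty((nF * A, labels_out.size))
    pts_out = np.empty((nF, A, labels_out.size, 3))
    inner_pts = np.empty((nF, A, 3))
    flagged = np.zeros(nF * A, dtype=bool)
    for t, sec in enumerate(sections):
        dirs = sec.ray_dirs()
        inner_pts[t] = sec.centre[None, :] + f_inner[t][:, None] * dirs
        V, rp, Iv, fl = outer_node_potentials(sec, inner_pts[t], vol, cfg)
        sl = slice(t * A, (t + 1) * A)
        node_out[sl] = V
        int_out[sl] = Iv
        pts_out[t] = rp
        flagged[sl] = fl
    try:
        graph_out = build_wall_graph(
            labels_out, node_out, int_out, edges, cfg.gamma, cfg.lam, cfg.floor,
            uniform_ok=flagged,
        )
    except ValueError as exc:
        raise ValueError(f"outer wall graph: {exc}") from exc
    outer_bp = bp_map(graph_out, cfg.bp_iters, cfg.bp_damping, cfg.bp_tol)
    f_outer = outer_bp.labels_f.reshape(nF, A)
    oidx = outer_bp.labels_idx.reshape(nF, A)

    out: List[WallMeasurement] = []
    for t, sec in enumerate(sections):
        for a in range(A):
            flags = []
            if flagged[t * A + a]:
                flags.append("outer_no_gradient_minimum")
            if not inner_bp.converged or not outer_bp.converged:
                flags.append("bp_not_converged")
            out.append(
                WallMeasurement(
                    frame_index=sec.frame_index,
                    arc_length=sec.arc_length,
                    angle=float(sec.theta[a]),
                    inner=inner_pts[t, a],
                    outer=pts_out[t, a, oidx[t, a]],
                    thickness=float(f_outer[t, a]),
                    flags=";".join(flags),
                )
            )
    return out


def match_to_roi(
    measurements: Sequence[WallMeasurement],
    roi_point: np.ndarray,
    max_dist_mm: float = 5.0,
) -> Optional[WallMeasurement]:
    """Measurement whose inner point is nearest the observer ROI; ``None``
    (failure) when no measurement lies within ``max_dist_mm``."""
    if not measurements:
        return None
    roi = np.asarray(roi_point, dtype=np.float64)
    inner = np.array([m.inner for m in measurements])
    d = np.linalg.norm(inner - roi, axis=1)
    i = int(np.argmin(d))
    if d[i] > max_dist_mm:
        return None
    return measurements[i]


# -- export ----------------------------------------------------------------


def measurements_to_dataframe(measurements: Sequence[WallMeasurement]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                frame_index=m.frame_index,
                arc_length_mm=m.arc_length,
                angle_rad=m.angle,
                inner_x=m.inner[0], inner_y=m.inner[1], inner_z=m.inner[2],
                outer_x=m.outer[0], outer_y=m.outer[1], outer_z=m.outer[2],
                thickness_mm=m.thickness,
                flags=m.flags,
            )
            for m in measurements
        ]
    )


def write_point_cloud_ply(measurements: Sequence[WallMeasurement], path: str) -> None:
    """ASCII PLY point cloud of inner (label 0) and outer (label 1) points."""
    n = len(measurements)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {2 * n}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar surface\nend_header\n"
        )
        for m in measurements:
            fh.write(f"{m.inner[0]:.4f} {m.inner[1]:.4f} {m.inner[2]:.4f} 0\n")
        for m in measurements:
            fh.write(f"{m.outer[0]:.4f} {m.outer[1]:.4f} {m.outer[2]:.4f} 1\n")
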