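import itertools
import math

import numpy as np
import pytest

from lumenwall.centreline import Centreline
from lumenwall.geometry import Frame, rmf_double_reflection
from lumenwall.phantom import PhantomSpec, generate_phantom
from lumenwall.volume import Volume
from lumenwall.wall_mrf import (
    WallConfig,
    WallGraph,
    WallMeasurement,
    bp_map,
    build_sections,
    build_wall_graph,
    edge_potential,
    inner_node_potentials,
    map_assignment_score,
    match_to_roi,
    measure_walls,
    outer_node_potentials,
)

from conftest import make_ring_volume


def straight_centreline(z0=10.0, z1=30.0, step=1.0):
    z = np.arange(z0, z1 + step / 2, step)
    pts = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    frames = rmf_double_reflection(pts, Frame.identity())
    return Centreline(points=pts, frames=frames, arc_length=z - z0)


def annulus_volume(r_in=5.0, thickness=3.0, half=16):
    return make_ring_volume(radius=r_in, thickness=thickness, half=half,
                            wall=100.0, lumen=0.0, background=0.0)


@pytest.fixture(scope="module")
def annulus_sections():
    spec = PhantomSpec(shape="straight", length_mm=30, inner_radius_mm=5,
                       wall_thickness_mm=3, background_intensity=0.0,
                       lumen_intensity=0.0)
    vol, _ = generate_phantom(spec)
    cl = straight_centreline(10.0, 20.0)
    cfg = WallConfig(n_angles=16, inner_f_max=12.0)
    return vol, cl, cfg, build_sections(vol, cl, cfg, k=50.0)


class TestSections:
    def test_section_count_and_centres(self, annulus_sections):
        _, cl, cfg, secs = annulus_sections
        assert len(secs) == 11  # every 1 mm over 10 mm inclusive
        for s in secs:
            assert np.allclose(s.centre[:2], 0.0, atol=1e-9)

    def test_lattice_positions_satisfy_radial_parametrisation(self, annulus_sections):
        vol, _, cfg, secs = annulus_sections
        s = secs[3]
        a, l = 5, 7
        p = s.centre + s.labels[l] * (
            math.cos(s.theta[a]) * s.frame.r + math.sin(s.theta[a]) * s.frame.s
        )
        assert vol.sample(p) == pytest.approx(s.intensity[a, l], abs=1e-12)

    def test_intensity_peaks_near_ring_radius(self, annulus_sections):
        _, _, cfg, secs = annulus_sections
        s = secs[5]
        wall_mid = 5 + 1.5
        for a in range(s.theta.size):
            peak = s.labels[np.argmax(s.intensity[a])]
            assert abs(peak - wall_mid) <= 1.5


class TestInnerPotentials:
    def test_zero_gradient_region_zero_potential(self):
        vol = Volume(np.full((25, 25, 25), 30.0), [1, 1, 1], [-12, -12, -12], np.eye(3))
        cl = straight_centreline(-4.0, 4.0)
        cfg = WallConfig(n_angles=8, inner_f_max=8.0)
        secs = build_sections(vol, cl, cfg, k=1000.0)
        v = inner_node_potentials(secs[0], beta=0.5)
        assert np.allclose(v, 0.0)

    def test_antialigned_gradient_fully_suppressed(self):
        # intensity decreasing outward: gradient points inward (dot = -1)
        n = 33
        ax = np.arange(n) - 16.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        rho = np.sqrt(xx**2 + yy**2)
        data = np.repeat((50.0 - 3 * rho)[:, :, None], n, axis=2)
        vol = Volume(data, [1, 1, 1], [-16, -16, -16], np.eye(3))
        cl = straight_centreline(-4.0, 4.0)
        cfg = WallConfig(n_angles=8, inner_f_max=8.0)
        secs = build_sections(vol, cl, cfg, k=1e9)
        v = inner_node_potentials(secs[2], beta=0.5)
        mag = np.linalg.norm(secs[2].gradient, axis=-1)
        assert np.all(v <= mag * 1e-3 + 1e-9)

    def test_annulus_argmax_at_inner_radius(self, annulus_sections):
        _, _, cfg, secs = annulus_sections
        for s in secs[2:9]:
            v = inner_node_potentials(s, beta=0.5)
            best = s.labels[np.argmax(v, axis=1)]
            assert np.all(np.abs(best - 5.0) <= cfg.f_step + 1e-9)

    def test_argmax_invariant_under_intensity_scaling(self, annulus_sections):
        vol, cl, cfg, secs = annulus_sections
        scaled = Volume(vol.data * 7.5, vol.spacing, vol.origin, vol.direction)
        secs2 = build_sections(scaled, cl, cfg, k=50.0 * 7.5)
        v1 = inner_node_potentials(secs[4], beta=0.5)
        v2 = inner_node_potentials(secs2[4], beta=0.5)
        assert np.array_equal(np.argmax(v1, axis=1), np.argmax(v2, axis=1))

    def test_obstruction_attenuates_labels_beyond_bright_structure(self, annulus_sections):
        _, _, cfg, secs = annulus_sections
        s = secs[5]
        v = inner_node_potentials(s, beta=0.5)
        # labels well beyond the wall run have crossed supra-threshold voxels
        beyond = s.labels > 9.5
        inner_edge = np.argmin(np.abs(s.labels - 5.0))
        for a in range(s.theta.size):
            assert v[a, beyond].max() < v[a, inner_edge] + 1e-9


class TestEdgePotential:
    def test_maximal_at_perfect_agreement(self):
        assert edge_potential(3.0, 3.0, 80.0, 80.0) == pytest.approx(1.0)
        assert edge_potential(3.0, 4.0, 80.0, 80.0) < 1.0
        assert edge_potential(3.0, 3.0, 80.0, 40.0) < 1.0

    def test_symmetry(self, rng):
        for _ in range(20):
            f = rng.uniform(1, 10, size=2)
            i = rng.uniform(0, 100, size=2)
            assert edge_potential(f[0], f[1], i[0], i[1]) == pytest.approx(
                edge_potential(f[1], f[0], i[1], i[0]), rel=1e-12
            )

    def test_exponential_distance_rate(self):
        v1 = edge_potential(2.0, 3.0, 50.0, 50.0, gamma=1.0)
        v2 = edge_potential(2.0, 4.0, 50.0, 50.0, gamma=1.0)
        assert math.log(v1) * 2 == pytest.approx(math.log(v2), rel=1e-9)

    def test_zero_intensities_count_as_similar(self):
        assert edge_potential(2.0, 2.0, 0.0, 0.0) == pytest.approx(1.0)


def random_chain_graph(rng, n_sites, n_labels):
    labels = np.arange(1.0, n_labels + 1)
    node = rng.uniform(0.1, 1.0, size=(n_sites, n_labels))
    edges = [(i, i + 1) for i in range(n_sites - 1)]
    graph = WallGraph(
        labels=labels,
        log_node=np.log(node),
        edges=edges,
        log_edge=[np.log(rng.uniform(0.1, 1.0, size=(n_labels, n_labels)))
                  for _ in edges],
    )
    return graph


def exhaustive_map(graph):
    best, best_s = None, -np.inf
    L = graph.labels.size
    for assign in itertools.product(range(L), repeat=graph.n_sites):
        s = map_assignment_score(graph, np.array(assign))
        if s > best_s + 1e-12:
            best_s, best = s, assign
    return np.array(best), best_s


class TestBeliefPropagation:
    def test_exact_on_random_chains(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = random_chain_graph(rng, int(rng.integers(3, 6)), int(rng.integers(2, 5)))
            res = bp_map(g, T_iters=60, damping=0.0)
            brute, brute_s = exhaustive_map(g)
            assert map_assignment_score(g, res.labels_idx) == pytest.approx(brute_s, abs=1e-9)

    def test_converged_rings_reach_exhaustive_maximum(self):
        n_checked = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            L = 4
            labels = np.arange(1.0, L + 1)
            node = rng.uniform(0.1, 1.0, size=(6, L))
            edges = [(i, (i + 1) % 6) for i in range(6)]
            g = WallGraph(
                labels=labels, log_node=np.log(node), edges=edges,
                log_edge=[np.log(rng.uniform(0.1, 1.0, size=(L, L))) for _ in edges],
            )
            res = bp_map(g, T_iters=200, damping=0.5, tol=1e-10)
            if not res.converged:
                continue
            n_checked += 1
            _, brute_s = exhaustive_map(g)
            assert map_assignment_score(g, res.labels_idx) == pytest.approx(brute_s, abs=1e-8)
        assert n_checked >= 25  # most instances converge

    def test_constant_edges_decouple_to_per_site_argmax(self, rng):
        L, S = 5, 4
        node = rng.uniform(0.1, 1.0, size=(S, L))
        g = WallGraph(
            labels=np.arange(1.0, L + 1), log_node=np.log(node),
            edges=[(i, i + 1) for i in range(S - 1)],
            log_edge=[np.zeros((L, L)) for _ in range(S - 1)],
        )
        res = bp_map(g, T_iters=50, damping=0.0)
        assert np.array_equal(res.labels_idx, node.argmax(axis=1))

    def test_all_zero_node_potentials_error_names_site(self):
        node = np.ones((3, 4))
        node[1] = 0.0
        with pytest.raises(ValueError, match="site 1"):
            build_wall_graph(np.arange(1.0, 5), node, np.ones((3, 4)),
                             [(0, 1), (1, 2)], gamma=1.0, lam=4.0)

    def test_tie_break_selects_smallest_distance(self):
        L = 4
        g = WallGraph(
            labels=np.arange(1.0, L + 1),
            log_node=np.zeros((2, L)),
            edges=[(0, 1)],
            log_edge=[np.zeros((L, L))],
        )
        res = bp_map(g, T_iters=10)
        assert np.all(res.labels_f == 1.0)


class TestOuterPotentials:
    def _section(self, vol, cfg):
        cl = straight_centreline(-4.0, 4.0)
        return build_sections(vol, cl, cfg, k=50.0)[2]

    def test_monotone_increasing_intensity_suppressed(self):
        n = 33
        ax = np.arange(n) - 16.0
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        rho = np.sqrt(xx**2 + yy**2)
        data = np.repeat((3.0 * rho)[:, :, None], n, axis=2)
        vol = Volume(data, [1, 1, 1], [-16, -16, -16], np.eye(3))
        cfg = WallConfig(n_angles=8, inner_f_max=8.0, outer_f_max=6.0)
        sec = self._section(vol, cfg)
        inner = sec.centre + 3.0 * sec.ray_dirs()
        V, _, _, flagged = outer_node_potentials(sec, inner, vol, cfg)
        mag_scale = 3.0
        assert np.all(V <= 1e-3 * mag_scale * V.shape[1] + 1e-9)

    def test_positions_before_first_gradient_minimum_zero(self):
        vol = annulus_volume(r_in=5.0, thickness=3.0)
        cfg = WallConfig(n_angles=8, inner_f_max=10.0, outer_f_max=6.0)
        sec = self._section(vol, cfg)
        inner = sec.centre + 5.0 * sec.ray_dirs()
        V, _, _, flagged = outer_node_potentials(sec, inner, vol, cfg)
        # the first labels (closest to the inner contour, before the
        # gradient-magnitude minimum inside the wall) carry no potential
        assert np.allclose(V[:, 0], 0.0)

    def test_annulus_argmax_at_wall_thickness(self):
        spec = PhantomSpec(shape="straight", length_mm=30, inner_radius_mm=5,
                           wall_thickness_mm=3, background_intensity=0.0,
                           lumen_intensity=0.0)
        vol, _ = generate_phantom(spec)
        cl = straight_centreline(10.0, 20.0)
        cfg = WallConfig(n_angles=16, inner_f_max=10.0, outer_f_max=6.0)
        sec = build_sections(vol, cl, cfg, k=50.0)[5]
        inner = sec.centre + 5.0 * sec.ray_dirs()
        V, _, _, flagged = outer_node_potentials(sec, inner, vol, cfg)
        assert not flagged.any()
        best = cfg.outer_labels()[np.argmax(V, axis=1)]
        assert np.all(np.abs(best - 3.0) <= 2 * cfg.f_step + 1e-9)


class TestMeasureWalls:
    @pytest.mark.parametrize("thickness", [2.0, 4.0])
    def test_annulus_thickness_recovery(self, thickness):
        spec = PhantomSpec(shape="straight", length_mm=30, inner_radius_mm=6,
                           wall_thickness_mm=thickness)
        vol, _ = generate_phantom(spec)
        cl = straight_centreline(10.0, 20.0)
        cfg = WallConfig(n_angles=32)
        ms = measure_walls(vol, cl, cfg, k=50.0)
        th = np.array([m.thickness for m in ms])
        assert np.abs(th - thickness).mean() <= max(0.5, cfg.f_step)
        assert np.all(th > 0)
        inner_r = np.array([np.linalg.norm(m.inner[:2]) for m in ms])
        assert np.abs(inner_r - 6.0).mean() <= 0.5

    def test_inner_contour_continuity_on_smooth_phantom(self):
        spec = PhantomSpec(shape="straight", length_mm=30, inner_radius_mm=6,
                           wall_thickness_mm=3)
        vol, _ = generate_phantom(spec)
        cl = straight_centreline(10.0, 20.0)
        cfg = WallConfig(n_angles=32)
        ms = measure_walls(vol, cl, cfg, k=50.0)
        by_frame = {}
        for m in ms:
            by_frame.setdefault(m.frame_index, []).append(np.linalg.norm(m.inner - [0, 0, m.inner[2]]))
        for fvals in by_frame.values():
            f = np.array(fvals)
            steps = np.abs(np.diff(np.concatenate([f, f[:1]])))
            assert steps.max() <= 3 * cfg.f_step + 1e-9

    def test_outer_point_farther_than_inner(self):
        spec = PhantomSpec(shape="straight", length_mm=30)
        vol, _ = generate_phantom(spec)
        cl = straight_centreline(10.0, 20.0)
        ms = measure_walls(vol, cl, WallConfig(n_angles=16), k=50.0)
        for m in ms:
            c = np.array([0.0, 0.0, m.inner[2]])
            assert np.linalg.norm(m.outer - c) > np.linalg.norm(m.inner - c)


class TestMatchToRoi:
    def _measurements(self):
        return [
            WallMeasurement(frame_index=0, arc_length=0.0, angle=0.0,
                            inner=np.array([x, 0.0, 0.0]),
                            outer=np.array([x + 3.0, 0.0, 0.0]), thickness=3.0)
            for x in (10.0, 14.0)
        ]

    def test_exact_hit_returns_that_measurement(self):
        ms = self._measurements()
        m = match_to_roi(ms, [10.0, 0.0, 0.0])
        assert m is ms[0]

    def test_nearest_candidate_wins(self):
        ms = self._measurements()
        m = match_to_roi(ms, [12.5, 0.0, 0.0])  # 2.5 mm vs 1.5 mm
        assert m is ms[1]

    def test_beyond_five_mm_fails(self):
        ms = self._measurements()
        assert match_to_roi(ms, [20.1, 0.0, 0.0], max_dist_mm=5.0) is None
        assert match_to_roi([], [0.0, 0.0, 0.0]) is None
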