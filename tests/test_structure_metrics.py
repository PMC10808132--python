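"""Base-pair state, denaturation, site distances and pore geometry."""

import numpy as np
import pytest
from scipy.optimize import linprog

from dmckit.oxdna_io import DEFAULT_UNITS, Topology, TrajectoryFrame
from dmckit.structure_metrics import (HBOND_SITE_OFFSET, PoreSeries, PoreSpec,
                                      ValidationError, denatured_fraction,
                                      detect_base_pairs, incircle_radius,
                                      leakage_frames, pore_series,
                                      site_distance_series)

NM = DEFAULT_UNITS.nm_per_length_unit


def _duplex(n_bp=10, separation=0.8):
    """An ideal straight duplex: strand 1 at y=0, strand 2 at y=separation,
    base vectors facing each other.  Pairs are (i, 2n-1-i)."""
    seq1 = ("ACGT" * n_bp)[:n_bp]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seq2 = "".join(comp[b] for b in reversed(seq1))
    n3 = [-1] + list(range(0, n_bp - 1)) + [-1] + list(range(n_bp,
                                                             2 * n_bp - 1))
    n5 = list(range(1, n_bp)) + [-1] + list(range(n_bp + 1, 2 * n_bp)) + [-1]
    topo = Topology([(1, seq1), (2, seq2)], n3, n5)
    pos = np.zeros((2 * n_bp, 3))
    pos[:n_bp, 0] = np.arange(n_bp)
    pos[n_bp:, 0] = np.arange(n_bp)[::-1]
    pos[n_bp:, 1] = separation
    bv = np.zeros((2 * n_bp, 3))
    bv[:n_bp, 1] = 1.0
    bv[n_bp:, 1] = -1.0
    nv = np.tile([0.0, 0.0, 1.0], (2 * n_bp, 1))
    frame = TrajectoryFrame(time=0.0, box=np.full(3, 100.0), positions=pos,
                            base_vectors=bv, normal_vectors=nv)
    pairs = [(i, 2 * n_bp - 1 - i) for i in range(n_bp)]
    return topo, frame, pairs


def _brute_force_mask(frame, pairs, cutoff, antiparallel):
    """Independent per-pair scan written with explicit loops."""
    out = []
    for i, j in pairs:
        si = frame.positions[i] + HBOND_SITE_OFFSET * frame.base_vectors[i]
        sj = frame.positions[j] + HBOND_SITE_OFFSET * frame.base_vectors[j]
        ok = float(np.sqrt(((si - sj) ** 2).sum())) < cutoff
        if antiparallel:
            ok = ok and float(np.dot(frame.base_vectors[i],
                                     frame.base_vectors[j])) < 0
        out.append(ok)
    return np.array(out)


class TestBasePairs:
    def test_ideal_duplex_fully_bound(self):
        topo, frame, pairs = _duplex()
        assert detect_base_pairs(frame, topo, pairs).all()

    def test_separated_strands_fully_unbound(self):
        topo, frame, pairs = _duplex()
        frame.positions[10:, 1] += 10.0
        assert not detect_base_pairs(frame, topo, pairs).any()

    def test_antiparallel_flag_vetoes_coaligned_bases(self):
        topo, frame, pairs = _duplex()
        frame.base_vectors[10:, 1] = 1.0  # now parallel to strand 1
        assert not detect_base_pairs(frame, topo, pairs,
                                     require_antiparallel=True).any()
        # distance criterion alone is indifferent to orientation sign only
        # when the sites still meet; flipping moved the sites apart too
        assert not detect_base_pairs(frame, topo, pairs,
                                     require_antiparallel=False).all()

    def test_random_configurations_match_brute_force(self, rng):
        topo, base, pairs = _duplex()
        for _ in range(200):
            pos = rng.uniform(-1.5, 1.5, (20, 3))
            bv = rng.normal(size=(20, 3))
            bv /= np.linalg.norm(bv, axis=1, keepdims=True)
            frame = TrajectoryFrame(time=0.0, box=base.box, positions=pos,
                                    base_vectors=bv,
                                    normal_vectors=base.normal_vectors)
            for anti in (True, False):
                got = detect_base_pairs(frame, topo, pairs,
                                        require_antiparallel=anti)
                want = _brute_force_mask(frame, pairs, 0.4, anti)
                np.testing.assert_array_equal(got, want)

    def test_non_complementary_pair_rejected(self):
        topo, frame, _ = _duplex()
        with pytest.raises(ValidationError, match="not complementary"):
            detect_base_pairs(frame, topo, [(0, 1)])


class TestDenaturedFraction:
    def test_intact_trajectory_is_zero_everywhere(self):
        topo, frame, pairs = _duplex()
        series, end = denatured_fraction([frame] * 4, topo, pairs)
        np.testing.assert_allclose(series, 0.0)
        assert end == 0.0

    def test_four_of_ten_broken_in_final_frame(self):
        topo, frame, pairs = _duplex()
        broken = TrajectoryFrame(time=1.0, box=frame.box,
                                 positions=frame.positions.copy(),
                                 base_vectors=frame.base_vectors,
                                 normal_vectors=frame.normal_vectors)
        for i, j in pairs[:4]:
            broken.positions[j] = broken.positions[j] + (0, 10.0, 0)
        series, end = denatured_fraction([frame, broken], topo, pairs)
        assert end == pytest.approx(0.4)
        assert series[0] == 0.0

    def test_empty_reference_set_rejected(self):
        topo, frame, _ = _duplex()
        with pytest.raises(ValidationError):
            denatured_fraction([frame], topo, [])


class TestSiteDistances:
    def test_same_index_is_zero(self):
        _, frame, _ = _duplex()
        np.testing.assert_allclose(
            site_distance_series([frame] * 3, 2, 2), 0.0)

    def test_pythagorean_offset_in_nm(self):
        topo, frame, _ = _duplex()
        frame.positions[5] = frame.positions[0] + (3.0, 4.0, 0.0)
        d = site_distance_series([frame], 0, 5)
        assert d[0] == pytest.approx(5.0 * NM)

    def test_index_out_of_range(self):
        _, frame, _ = _duplex()
        with pytest.raises(IndexError):
            site_distance_series([frame], 0, 99)


def _incircle_lp(p1, p2, p3):
    """Independent oracle: largest inscribed circle by linear programming
    in the triangle's own plane."""
    e1 = p2 - p1
    e1 = e1 / np.linalg.norm(e1)
    normal = np.cross(p2 - p1, p3 - p1)
    e2 = np.cross(normal / np.linalg.norm(normal), e1)
    verts = np.array([[0.0, 0.0],
                      [(p2 - p1) @ e1, (p2 - p1) @ e2],
                      [(p3 - p1) @ e1, (p3 - p1) @ e2]])
    centroid = verts.mean(axis=0)
    a_ub, b_ub = [], []
    for k in range(3):
        p, q = verts[k], verts[(k + 1) % 3]
        edge = q - p
        n = np.array([-edge[1], edge[0]])
        n = n / np.linalg.norm(n)
        if (centroid - p) @ n < 0:
            n = -n
        # distance of (x, y) to the edge must be at least r
        a_ub.append([-n[0], -n[1], 1.0])
        b_ub.append(-p @ n)
    res = linprog(c=[0.0, 0.0, -1.0], A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None)] * 3)
    return res.x[2]


class TestIncircle:
    def test_right_triangle_3_4_5(self):
        r = incircle_radius((0, 0, 0), (3, 0, 0), (0, 4, 0))
        assert r == pytest.approx(1.0)

    def test_equilateral_closed_form(self):
        a = 6.8
        p3 = (a / 2, a * np.sqrt(3) / 2, 0)
        r = incircle_radius((0, 0, 0), (a, 0, 0), p3)
        assert r == pytest.approx(a / (2 * np.sqrt(3)))

    def test_degenerate_triangle_is_zero(self):
        assert incircle_radius((0, 0, 0), (1, 0, 0), (2, 0, 0)) == 0.0

    def test_matches_inscribed_circle_search_on_random_triangles(self, rng):
        for _ in range(1000):
            p1, p2, p3 = rng.normal(0, 5, (3, 3))
            r = incircle_radius(p1, p2, p3)
            if r == 0.0:
                continue
            r_lp = _incircle_lp(p1, p2, p3)
            assert r == pytest.approx(r_lp, rel=1e-3)

    def test_rigid_motion_invariance_and_linear_scaling(self, rng):
        p = rng.normal(0, 3, (3, 3))
        r = incircle_radius(*p)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = p @ q.T + np.array([5.0, -2.0, 9.0])
        assert incircle_radius(*moved) == pytest.approx(r, rel=1e-9)
        assert incircle_radius(*(2.5 * p)) == pytest.approx(2.5 * r,
                                                            rel=1e-9)

    def test_never_exceeds_circumradius(self, rng):
        for _ in range(100):
            p1, p2, p3 = rng.normal(0, 2, (3, 3))
            r = incircle_radius(p1, p2, p3)
            a = np.linalg.norm(p2 - p3)
            b = np.linalg.norm(p1 - p3)
            c = np.linalg.norm(p1 - p2)
            area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
            if area <= 1e-9:
                continue
            circum = a * b * c / (4 * area)
            assert r <= circum + 1e-12


def _tetra_frame(edge_nm=6.8):
    """Regular tetrahedron with a bead on each vertex (sim units)."""
    s = edge_nm / (2 * np.sqrt(2)) / NM
    pos = s * np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                       dtype=float)
    bv = np.tile([1.0, 0, 0], (4, 1))
    nv = np.tile([0.0, 1.0, 0], (4, 1))
    return TrajectoryFrame(time=0.0, box=np.full(3, 100.0), positions=pos,
                           base_vectors=bv, normal_vectors=nv)


class TestPores:
    def test_regular_tetrahedron_closed_form(self):
        frame = _tetra_frame(6.8)
        spec = PoreSpec([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        series = pore_series([frame], spec)
        expected = 6.8 / (2 * np.sqrt(3))
        np.testing.assert_allclose(series.radii, expected, rtol=1e-6)
        assert series.max_radius[0] == pytest.approx(series.mean_radius[0])
        assert expected == pytest.approx(1.963, abs=1e-3)

    def test_collapsed_face_contributes_zero_and_max_ignores_it(self):
        frame = _tetra_frame(6.8)
        # collapse face (0,1,2) onto a line
        frame.positions[2] = (frame.positions[0] + frame.positions[1]) / 2
        spec = PoreSpec([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        series = pore_series([frame], spec)
        assert series.radii[0, 0] == 0.0
        assert series.max_radius[0] > 0.0

    def test_max_never_below_mean(self, pull_run):
        build, _, _, result = pull_run
        series = pore_series(result.frames, build.pore_spec)
        assert np.all(series.max_radius >= series.mean_radius - 1e-12)

    def test_matches_direct_per_face_oracle_on_sim_frames(self, pull_run):
        build, _, _, result = pull_run
        series = pore_series(result.frames[::20], build.pore_spec)
        for fi, frame in enumerate(result.frames[::20]):
            pos = frame.positions * NM
            for k, face in enumerate(build.pore_spec.faces):
                want = incircle_radius(pos[face[0]], pos[face[1]],
                                       pos[face[2]])
                assert series.radii[fi, k] == pytest.approx(want, rel=1e-9)

    def test_face_with_repeated_index_rejected(self):
        with pytest.raises(ValidationError):
            PoreSpec([[0, 1, 1], [0, 1, 3], [0, 2, 3], [1, 2, 3]])


class TestLeakage:
    def _series(self, maxima):
        radii = np.zeros((len(maxima), 4))
        radii[:, 0] = maxima
        return PoreSeries(radii=radii, times=np.arange(len(maxima)))

    def test_small_pores_never_leak(self):
        series = self._series([1.8, 2.0, 1.9])
        assert leakage_frames(series, 2.3).size == 0

    def test_large_pores_leak_every_frame(self):
        series = self._series([1.963, 1.963])
        np.testing.assert_array_equal(leakage_frames(series, 1.0), [0, 1])

    def test_boundary_is_strict(self):
        series = self._series([2.3])
        assert leakage_frames(series, 2.3).size == 0

    def test_nonpositive_cargo_rejected(self):
        with pytest.raises(ValueError):
            leakage_frames(self._series([1.0]), 0.0)
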