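"""Boundary extraction chain and the ΔLinearity statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ectimetry as em
from ectimetry.errors import (
    DegenerateImageError,
    ExtractionError,
    GeometryError,
    TracingError,
)
from ectimetry.trace import (
    GAP,
    EdgeMap,
    min_cost_path,
    pixel_costs,
    topmost_candidates,
)
from conftest import semicircle_points


def _line_edge_map(nz=100, nx=60, row=80):
    edges = np.zeros((nz, nx), dtype=bool)
    edges[row, :] = True
    grad = np.zeros((nz, nx))
    grad[row, :] = 10.0
    return EdgeMap(edges=edges, gradient=grad, sigma=2.0, low=0.4, high=0.8)


class TestReslice:
    def _toy_stack(self):
        vol = np.arange(27).reshape(3, 3, 3)
        return em.ImageStack(volume_af=vol, volume_shg=vol * 10,
                             px_lateral=0.5, z_step=2.0)

    def test_xz_plane_is_constructed_correctly(self):
        stack = self._toy_stack()
        sec = em.reslice_stack(stack, "xz", 1)
        assert np.array_equal(sec.channel_af, stack.volume_af[:, 1, :])
        assert sec.px_axial == 2.0 and sec.px_lateral == 0.5

    def test_orthogonal_reslices_share_a_line(self):
        stack = self._toy_stack()
        xz = em.reslice_stack(stack, "xz", 1)
        yz = em.reslice_stack(stack, "yz", 2)
        # column x=2 of the x-z plane equals column y=1 of the y-z plane
        assert np.array_equal(xz.channel_af[:, 2], yz.channel_af[:, 1])

    def test_stack_of_identical_sections_reslices_to_the_section(self, flat_section):
        section, _ = flat_section
        af = np.repeat(section.channel_af[:, None, :], 4, axis=1)
        shg = np.repeat(section.channel_shg[:, None, :], 4, axis=1)
        stack = em.ImageStack(volume_af=af, volume_shg=shg,
                              px_lateral=section.px_lateral, z_step=section.px_axial)
        sec = em.reslice_stack(stack, "xz", 2)
        assert np.array_equal(sec.channel_shg, section.channel_shg)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            em.reslice_stack(self._toy_stack(), "xz", 3)


class TestThreshold:
    def test_two_valued_image(self):
        shg = np.zeros((64, 64))
        shg[32:, :] = 200.0
        sec = em.CrossSection(channel_af=shg, channel_shg=shg,
                              px_lateral=1.0, px_axial=1.0)
        res = em.threshold_shg(sec)
        assert np.array_equal(res.mask, shg == 200.0)

    def test_constant_image_degenerate(self):
        z = np.zeros((64, 64))
        sec = em.CrossSection(channel_af=z, channel_shg=z, px_lateral=1, px_axial=1)
        with pytest.raises(DegenerateImageError):
            em.threshold_shg(sec)

    def test_noiseless_phantom_mask_tracks_boundary(self, flat_model):
        params = em.PhantomParams(noise=em.NoiseModel(0, 0), texture_sd=0.0,
                                  rng_seed=1)
        section, truth = em.render_phantom(params, flat_model)
        res = em.threshold_shg(section)
        top = res.mask.argmax(axis=0)  # topmost True row per column
        true_row = truth.true_thickness_profile / section.px_axial
        assert np.all(np.abs(top - true_row) <= 1)


class TestDetectEdges:
    def test_constant_raster_no_edges(self):
        e = em.detect_edges(np.full((64, 64), 7.0))
        assert not e.edges.any()

    def test_horizontal_step_single_edge_row(self):
        img = np.zeros((64, 64))
        img[30:, :] = 100.0
        e = em.detect_edges(img)
        rows = np.where(e.edges)[0]
        assert rows.size > 0 and np.all(np.abs(rows - 29.5) <= 1)

    def test_phantom_edges_near_true_boundary(self, noisy_sine_section):
        section, truth = noisy_sine_section
        e = em.detect_edges(np.minimum(section.channel_shg.astype(float),
                                       em.threshold_shg(section).level))
        ok = 0
        true_row = truth.true_thickness_profile / section.px_axial
        for col in range(section.shape[1]):
            rows = np.flatnonzero(e.edges[:, col])
            if rows.size and np.min(np.abs(rows - true_row[col])) <= 2:
                ok += 1
        assert ok >= 0.95 * section.shape[1]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            em.detect_edges(np.zeros((8, 8)), sigma=0)
        with pytest.raises(ValueError):
            em.detect_edges(np.zeros((8, 8)), low=0.9, high=0.4)


class TestTopmostCandidates:
    def test_full_width_line(self):
        mask = np.zeros((100, 40), dtype=bool)
        mask[80, :] = True
        assert np.all(topmost_candidates(mask) == 80)

    def test_hole_becomes_gap_markers(self):
        mask = np.zeros((100, 40), dtype=bool)
        mask[80, :] = True
        mask[80, 10:13] = False
        cand = topmost_candidates(mask)
        assert np.all(cand[10:13] == GAP)
        assert np.all(cand[:10] == 80) and np.all(cand[13:] == 80)

    def test_speckle_rejected_by_jump_rule(self):
        mask = np.zeros((100, 40), dtype=bool)
        mask[80, :] = True
        mask[5, 20] = True  # isolated speckle far above the line
        cand = topmost_candidates(mask)
        assert cand[20] == 80

    def test_too_many_gaps_raises(self):
        mask = np.zeros((100, 40), dtype=bool)
        mask[80, :15] = True
        with pytest.raises(ExtractionError):
            topmost_candidates(mask)


class TestMinCostPath:
    def test_uniform_grid_minimal_cost_is_column_count(self):
        # on a uniform grid every monotone path costs one per column; the
        # exact pixel sequence is tie-dependent but the cost is not
        cost = np.ones((5, 9))
        path, total = min_cost_path(cost, (2, 0), (2, 8))
        assert total == pytest.approx(9.0)
        assert path[0] == (2, 0) and path[-1] == (2, 8)
        assert len(path) == 9

    def test_cost_matches_exhaustive_relaxation_on_random_grids(self):
        # independent oracle: relax every edge to a fixed point (exact for
        # positive costs), compared over 100 random 8x8 instances
        moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

        def relax(cost, start, end):
            nz, nx = cost.shape
            dist = np.full((nz, nx), np.inf)
            dist[start] = cost[start]
            changed = True
            while changed:
                changed = False
                for z in range(nz):
                    for x in range(nx):
                        if not np.isfinite(dist[z, x]):
                            continue
                        for dz, dx in moves:
                            z2, x2 = z + dz, x + dx
                            if (0 <= z2 < nz and 0 <= x2 < nx and
                                    dist[z, x] + cost[z2, x2] < dist[z2, x2] - 1e-15):
                                dist[z2, x2] = dist[z, x] + cost[z2, x2]
                                changed = True
            return dist[end]

        rng = np.random.default_rng(0)
        for _ in range(100):
            cost = 0.01 + rng.uniform(0.01, 1.0, (8, 8))
            s = (int(rng.integers(8)), 0)
            e = (int(rng.integers(8)), 7)
            _, got = min_cost_path(cost, s, e)
            assert got == pytest.approx(relax(cost, s, e), abs=1e-9)

    def test_beats_or_matches_monotone_dynamic_program(self):
        # the unrestricted minimal cost can never exceed the best strictly
        # left-to-right path (dz in {-1,0,1} per column step)
        rng = np.random.default_rng(1)
        for _ in range(20):
            cost = pixel_costs(rng.uniform(0, 50, (10, 10)))
            dp = cost[:, 0].copy()
            for c in range(1, 10):
                prev = np.full(12, np.inf)
                prev[1:11] = dp
                dp = cost[:, c] + np.minimum(np.minimum(prev[:10], prev[1:11]), prev[2:12])
            s = (int(np.argmin(cost[:, 0])), 0)
            best = np.inf
            for srow in range(10):
                for erow in range(10):
                    _, g = min_cost_path(cost, (srow, 0), (erow, 9))
                    best = min(best, g)
            assert best <= dp.min() + 1e-9


class TestTraceBoundary:
    def test_horizontal_line_traces_exactly(self):
        e = _line_edge_map()
        tr = em.trace_boundary(e, px_lateral=0.625, px_axial=1.0)
        assert tr.delta_L_norm == pytest.approx(0.0, abs=1e-6)
        assert np.all(tr.points[:, 1] == 80.0)

    def test_sine_phantom_traces_close_to_truth(self, noisy_sine_section, sine_model):
        section, _ = noisy_sine_section
        tr = em.trace_section(section)
        x = tr.points[:, 0]
        true_z = sine_model.depth(x + section.px_lateral / 2) - section.px_axial / 2
        rms = float(np.sqrt(np.mean((tr.points[:, 1] - true_z) ** 2)))
        assert rms <= 2.0

    def test_endpoints_must_be_extreme_columns(self):
        e = _line_edge_map()
        with pytest.raises(TracingError):
            em.trace_boundary(e, 0.625, 1.0, start=(80, 5), end=(80, 59))

    def test_gap_ceiling_enforced(self):
        e = _line_edge_map(nx=60)
        e.edges[:, 20:50] = False
        e.gradient[:, 20:50] = 0.0  # featureless 30-column gap
        with pytest.raises(TracingError):
            em.trace_boundary(e, 0.625, 1.0, max_bridge_px=20)


class TestArcLength:
    def test_3_4_5_triangle(self):
        assert em.arc_length([(0, 0), (3, 4)]) == 5.0

    def test_unit_conversion_done_upstream(self):
        # 8 px at 0.625 um/px lateral
        assert em.arc_length([(0, 0), (8 * 0.625, 0)]) == pytest.approx(5.0)

    def test_semicircle_closed_form(self):
        pts = semicircle_points(radius=50.0, n=10_000)
        assert em.arc_length(pts) == pytest.approx(np.pi * 50.0, rel=5e-3)

    def test_degenerate_raises(self):
        with pytest.raises(GeometryError):
            em.arc_length([(0, 0)])


class TestDeltaLinearity:
    def test_flat_trace_zero(self):
        pts = np.column_stack([np.linspace(0, 320, 100), np.full(100, 150.0)])
        l, L, dl, dln = em.delta_linearity(pts)
        assert dln == pytest.approx(0.0, abs=1e-12)
        assert dl == pytest.approx(0.0, abs=1e-9) and l == pytest.approx(L)

    def test_semicircle_closed_form(self):
        _, _, _, dln = em.delta_linearity(semicircle_points(n=200_000))
        assert dln == pytest.approx(np.pi / 2 - 1, rel=1e-4)

    def test_matches_quadrature_oracle_on_sine(self, sine_model):
        x = np.linspace(0, 320, 100_000)
        pts = np.column_stack([x, sine_model.depth(x)])
        dln = em.delta_linearity(pts)[3]
        assert dln == pytest.approx(em.true_delta_linearity(sine_model, 320.0), rel=1e-2)

    def test_zero_chord_raises(self):
        with pytest.raises(ValueError):
            # strictly-increasing x enforced upstream; closed loop invalid
            em.BoundaryTrace(points=np.array([[0.0, 0.0], [0.0, 0.0]]))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_and_translation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        x = np.cumsum(rng.uniform(0.1, 2.0, n))
        z = rng.normal(100, 10, n)
        pts = np.column_stack([x, z])
        l, L, dl, dln = em.delta_linearity(pts)
        assert dln >= 0 and l >= L > 0
        shifted = pts + np.array([17.3, -42.0])
        l2, L2, _, dln2 = em.delta_linearity(shifted)
        assert dln2 == pytest.approx(dln, abs=1e-12)
        assert l2 == pytest.approx(l) and L2 == pytest.approx(L)

    def test_zero_iff_collinear(self):
        x = np.linspace(0, 100, 50)
        collinear = np.column_stack([x, 5 + 0.3 * x])
        assert em.delta_linearity(collinear)[3] == pytest.approx(0.0, abs=1e-12)
        bent = collinear.copy()
        bent[25, 1] += 1.0
        assert em.delta_linearity(bent)[3] > 0


class TestRecoveryProperties:
    def test_bump_amplitude_monotonicity(self):
        # measured DLn never decreases along a noiseless amplitude ladder
        measured = []
        for amp in (5.0, 15.0, 25.0, 35.0):
            m = em.BoundaryModel(baseline_depth=160,
                                 bumps=((160.0, amp, 20.0),))
            p = em.PhantomParams(noise=em.NoiseModel(0, 0), texture_sd=0.0,
                                 rng_seed=0)
            section, _ = em.render_phantom(p, m)
            measured.append(em.trace_section(section).delta_L_norm)
        assert all(b >= a for a, b in zip(measured, measured[1:]))

    def test_flat_phantom_recovery_within_tolerance(self, noisy_flat_section):
        section, _ = noisy_flat_section
        assert em.trace_section(section).delta_L_norm <= 0.02
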