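import numpy as np
import pytest

from conftest import v1_on_v2_grid
from shapecortex.fields import OrientationField
from shapecortex.stimuli import StimulusSpec, render
from shapecortex.v2v3 import (
    bown_compete_step,
    bown_init,
    subsample,
    v2_curvature,
    v2_longrange,
    v2v3_corner,
)


class TestSubsample:
    def test_constant_preserved(self):
        out = subsample(np.full((10, 11), 0.3), 3)
        assert np.allclose(out, 0.3)

    def test_reference_grid_sizes(self):
        """The 321x481 reference image maps to the documented area grids."""
        img = np.zeros((321, 481))
        assert subsample(img, 3).shape == (107, 161)
        assert subsample(img, 4).shape == (81, 121)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            subsample(np.zeros((6, 6)), 0)


class TestLongRange:
    def test_and_gate_silent_beyond_contour_end(self, config):
        """A cell past the end of a line drives only one subfield and must
        stay (nearly) silent relative to on-contour cells."""
        img = render(
            StimulusSpec(kind="bar", orientation=0, length=40, line_width=2,
                         canvas=(96, 96), center=(28, 48))
        )
        fld = v2_longrange(v1_on_v2_grid(img, config), config.v2_params())
        beyond_end = fld.data[15:18, 21:26, 0].max()
        on_line = fld.data[15:18, 6:14, 0].max()
        assert beyond_end < 0.05 * on_line

    def test_bridges_gap_between_collinear_segments(self, config):
        b1 = render(StimulusSpec(kind="bar", orientation=0, length=30,
                                 line_width=2, canvas=(96, 96), center=(20, 48)))
        b2 = render(StimulusSpec(kind="bar", orientation=0, length=30,
                                 line_width=2, canvas=(96, 96), center=(76, 48)))
        img = np.minimum(b1, b2)
        fld = v2_longrange(v1_on_v2_grid(img, config), config.v2_params())
        assert fld.data[15:18, 14:18, 0].max() > 0.05

    def test_clutter_suppresses_contour_fragment(self, config):
        iso = render(StimulusSpec(kind="bar", orientation=0, length=40,
                                  line_width=2, canvas=(96, 96)))
        rng = np.random.default_rng(7)
        clut = iso.copy()
        placed = 0
        while placed < 60:
            cx, cy = rng.uniform(8, 88, 2)
            th = rng.uniform(0, np.pi)
            if abs(cy - 48) < 5:
                continue
            seg = render(StimulusSpec(kind="bar", orientation=th, length=8,
                                      line_width=2, canvas=(96, 96),
                                      center=(cx, cy)))
            clut = np.minimum(clut, seg)
            placed += 1
        vi = v2_longrange(v1_on_v2_grid(iso, config), config.v2_params())
        vc = v2_longrange(v1_on_v2_grid(clut, config), config.v2_params())
        assert vc.data[15:18, 13:20, 0].max() < vi.data[15:18, 13:20, 0].max()


class TestCurvature:
    def test_matched_radius_dominates_small_sweep(self, config):
        from shapecortex.experiments import probe_curvature_cell

        omega_c = 15.0
        responses = {
            r: probe_curvature_cell(r, omega_c, config) for r in (10, 15, 22)
        }
        assert max(responses, key=responses.get) == 15

    def test_straight_line_weaker_than_matched_arc(self, config):
        from shapecortex.experiments import probe_curvature_cell

        matched = probe_curvature_cell(15.0, 15.0, config)
        img = render(StimulusSpec(kind="bar", orientation=0, length=400,
                                  line_width=2, canvas=(140, 140),
                                  center=(70, 25)))
        fld = v1_on_v2_grid(img, config)
        curv = v2_curvature(fld, 15.0, config.curv_sigma_dist,
                            config.curv_sigma_ring)
        line_resp = curv.data[7:10, :, 0, :].max()
        assert line_resp < matched

    def test_mirror_flip_swaps_curvature_signs(self, config):
        img = render(StimulusSpec(kind="circle", radius=30, line_width=2,
                                  canvas=(99, 120), center=(50, 49.5)))
        a = v2_curvature(v1_on_v2_grid(img, config), 10.0)
        b = v2_curvature(v1_on_v2_grid(img[:, ::-1], config), 10.0)
        n = 8
        scale = a.data.max()
        for i in range(n):
            for s in range(2):
                # the tangent channel whose normal lies on the mirror axis
                # keeps its sign; every other channel swaps left/right
                s2 = s if i == 0 else 1 - s
                mirrored = b.data[3:-3, :, (n - i) % n, s2][:, ::-1][:, 3:-3]
                assert np.abs(a.data[3:-3, 3:-3, i, s] - mirrored).max() < 1e-6 * scale

    def test_bad_radius(self, config):
        with pytest.raises(ValueError):
            v2_curvature(OrientationField(np.zeros((8, 8, 8))), omega_c=0.0)


class TestCorners:
    def test_blank_image_silent(self, blank_image, config):
        fld = v2v3_corner(v1_on_v2_grid(blank_image, config))
        assert fld.data.max() < 1e-9

    def test_square_outline_peaks_at_vertices(self, config):
        img = render(StimulusSpec(kind="square", side=60, line_width=2,
                                  canvas=(128, 128)))
        corn = v2v3_corner(v1_on_v2_grid(img, config)).data.max(-1)
        corner_vals = [corn[a - 3:a + 4, b - 3:b + 4].max()
                       for a in (11, 31) for b in (11, 31)]
        edge_vals = max(corn[8:15, 17:26].max(), corn[17:26, 8:15].max())
        assert min(corner_vals) > edge_vals

    def test_junction_beats_straight_edge(self, config):
        """Corner response on a straight step edge is far below its value at
        an L-junction of the same contrast (filled square corner)."""
        img = render(StimulusSpec(kind="square", side=60, fill=True,
                                  canvas=(128, 128)))
        corn = v2v3_corner(v1_on_v2_grid(img, config)).data.max(-1)
        corner_vals = [corn[a - 3:a + 4, b - 3:b + 4].max()
                       for a in (11, 31) for b in (11, 31)]
        edge_vals = max(corn[8:15, 17:26].max(), corn[17:26, 8:15].max())
        assert edge_vals < min(corner_vals)


class TestBOwn:
    def test_vertical_contour_drives_lateral_directions_only(self):
        data = np.zeros((5, 5, 8))
        data[2, 2, 4] = 1.0  # vertical orientation channel
        fld = bown_init(OrientationField(data))
        pop = fld.data[2, 2]
        assert pop[0] > 0 and pop[2] > 0
        assert pop[0] == pytest.approx(pop[2])
        assert pop[1] == pytest.approx(0.0) and pop[3] == pytest.approx(0.0)

    def test_blank_input_all_zero(self):
        fld = bown_init(OrientationField(np.zeros((4, 4, 8))))
        assert np.all(fld.data == 0)

    def test_isotropic_init_gives_four_equal_hypotheses(self):
        data = np.zeros((3, 3, 8))
        data[1, 1, 4] = 2.0
        fld = bown_init(OrientationField(data), isotropic=True)
        pop = fld.data[1, 1]
        assert np.all(pop > 0)
        assert np.allclose(pop, pop[0])
        oriented = bown_init(OrientationField(data), isotropic=False)
        active = (oriented.data[1, 1] > 0.1 * oriented.data[1, 1].max()).sum()
        assert active == 2


class TestCompetition:
    def test_symmetry_is_preserved(self):
        a = b = np.full(4, 0.4)
        A = np.full(4, 0.6)
        for _ in range(50):
            a, b = bown_compete_step(a, b, A)
        assert np.allclose(a, b)

    def test_initial_advantage_wins(self):
        """Integrating the opposing pair to convergence yields winner-take-
        all: the initially weaker side collapses below 5% of the winner."""
        a, b = np.array([0.5]), np.array([0.4])
        A = np.array([0.6])
        for _ in range(2000):
            a, b = bown_compete_step(a, b, A, dt=0.1)
        assert b[0] < 0.05 * a[0]

    def test_origin_is_fixed_point_without_drive(self):
        a, b = bown_compete_step(np.zeros(3), np.zeros(3), np.zeros(3))
        assert np.all(a == 0) and np.all(b == 0)
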