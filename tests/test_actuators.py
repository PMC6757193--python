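import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmjsim.actuators import (
    HillMuscle,
    LigamentCable,
    build_distributed_attachment,
    hill_force,
    hill_force_and_slope,
    ligament_tension,
    wrap_path,
)


def _muscle(f_max=100.0, l_opt=0.05):
    return HillMuscle("m", "a", np.zeros(3), "b", np.zeros(3), f_max=f_max, l_opt=l_opt)


class TestHill:
    def test_normalization(self):
        m = _muscle()
        assert hill_force(m, m.l_opt, 0.0, 1.0) == pytest.approx(m.f_max)

    def test_passive_zero_below_optimum(self):
        m = _muscle()
        assert hill_force(m, 0.8 * m.l_opt, 0.0, 0.0) == 0.0

    def test_force_velocity_intercept(self):
        m = _muscle()
        v_max = m.curves.v_max_per_lopt * m.l_opt
        # at maximal shortening the active contribution vanishes; only the
        # (negative) damping remains, clamped at zero
        assert hill_force(m, m.l_opt, -v_max, 1.0) == 0.0

    def test_activation_bounds_checked(self):
        m = _muscle()
        with pytest.raises(ValueError):
            hill_force(m, 0.05, 0.0, 1.5)

    def test_slope_nonnegative_and_matches_fd(self):
        m = _muscle()
        # the concentric/eccentric branches meet with a slope kink at v=0,
        # so the finite-difference check stays strictly inside one branch
        for v in (-0.2, -0.01, 0.01, 0.2):
            T, slope = hill_force_and_slope(m, 0.055, v, 0.7)
            assert slope >= 0.0
            h = 1e-7
            fd = (hill_force(m, 0.055, v + h, 0.7) - hill_force(m, 0.055, v - h, 0.7)) / (2 * h)
            if T > 0:
                assert slope == pytest.approx(fd, rel=1e-4)
        _, slope0 = hill_force_and_slope(m, 0.055, 0.0, 0.7)
        assert slope0 >= 0.0

    @settings(deadline=None, max_examples=60)
    @given(
        lhat=st.floats(0.5, 1.8),
        vhat=st.floats(-0.99, 1.0),
        a=st.floats(0.0, 1.0),
    )
    def test_tension_never_negative(self, lhat, vhat, a):
        m = _muscle()
        v = vhat * m.curves.v_max_per_lopt * m.l_opt
        assert hill_force(m, lhat * m.l_opt, v, a) >= 0.0

    def test_continuity_in_length(self):
        m = _muscle()
        ls = np.linspace(0.7, 1.7, 400) * m.l_opt
        T = np.array([hill_force(m, l, 0.0, 0.5) for l in ls])
        assert np.abs(np.diff(T)).max() < 0.05 * m.f_max  # no jumps


class TestWrap:
    def test_clear_segment_straight(self):
        L, via = wrap_path([-2, 1.5, 0], [2, 1.5, 0], [0, 0, 0], [0, 0, 1], 1.0)
        assert L == pytest.approx(4.0)
        assert len(via) == 0

    def test_tangent_arc_geometry(self):
        L, via = wrap_path([-2, 0, 0], [2, 0, 0], [0, 0, 0], [0, 0, 1], 1.0)
        assert L == pytest.approx(2 * np.sqrt(3) + np.pi / 3, rel=1e-9)
        assert len(via) >= 2
        assert np.allclose(np.hypot(via[:, 0], via[:, 1]), 1.0, atol=1e-9)

    def test_axial_component(self):
        L, _ = wrap_path([-2, 0, 0], [2, 0, 3], [0, 0, 0], [0, 0, 1], 1.0)
        assert L == pytest.approx(np.hypot(2 * np.sqrt(3) + np.pi / 3, 3.0), rel=1e-9)

    def test_radius_to_zero_limit(self):
        for r in (0.5, 0.1, 1e-3):
            L, _ = wrap_path([-2, 0, 0], [2, 0, 0], [0, 0, 0], [0, 0, 1], r)
            assert L >= 4.0
        L, _ = wrap_path([-2, 0, 0], [2, 0, 0], [0, 0, 0], [0, 0, 1], 1e-6)
        assert L == pytest.approx(4.0, abs=1e-4)

    def test_endpoint_inside_rejected(self):
        with pytest.raises(ValueError):
            wrap_path([0.5, 0, 0], [2, 0, 0], [0, 0, 0], [0, 0, 1], 1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-3, 3), st.floats(1.2, 4.0), st.floats(-3, 3))
    def test_length_at_least_straight(self, y0, x1, y1):
        p0, p1 = np.array([-3.0, y0, 0.0]), np.array([x1, y1, 0.5])
        L, _ = wrap_path(p0, p1, [0, 0, 0], [0, 0, 1], 1.0)
        assert L >= np.linalg.norm(p1 - p0) - 1e-9


class TestLigament:
    def _cable(self, slack=0.03):
        return LigamentCable("c", ("a", np.zeros(3)), ("b", np.zeros(3)),
                             slack_length=slack)

    def test_slack_region_and_onset(self):
        c = self._cable()
        assert ligament_tension(c, 0.029) == 0.0
        assert ligament_tension(c, 0.030) == 0.0

    def test_modulus_conversion(self):
        c = self._cable(slack=0.03)
        assert c.k_eff == pytest.approx(250e6 * 1e-6 / 0.03)
        assert ligament_tension(c, 0.031) == pytest.approx(8.333, rel=1e-3)

    def test_monotone_and_continuous(self):
        c = self._cable()
        ls = np.linspace(0.025, 0.04, 500)
        T = np.array([ligament_tension(c, l) for l in ls])
        assert np.all(np.diff(T) >= 0)
        assert np.abs(np.diff(T)).max() < 1.0  # no jump at the slack threshold

    def test_work_equals_stored_energy(self):
        """Quasi-static elongation work matches the spring energy."""
        c = self._cable(slack=0.03)
        ls = np.linspace(0.03, 0.035, 2000)
        T = np.array([ligament_tension(c, l) for l in ls])
        work = np.trapezoid(T, ls)
        stored = 0.5 * c.k_eff * (ls[-1] - c.slack_length) ** 2
        assert work == pytest.approx(stored, rel=1e-2)


class TestDistributedAttachment:
    def test_symmetric_point_equal_weights(self, anatomy):
        fb = anatomy.system.fem_bodies["disk_right"]
        att = build_distributed_attachment(fb, fb.positions[fb.surface_nodes[0]],
                                           n_target=20, radius=5e-3)
        assert len(att.node_ids) <= 20
        assert att.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(att.weights >= 0)

    def test_force_redistribution_exact(self, anatomy):
        fb = anatomy.system.fem_bodies["disk_right"]
        point = fb.positions[fb.surface_nodes].mean(axis=0)
        point = fb.positions[fb.surface_nodes[3]]
        att = build_distributed_attachment(fb, point, n_target=20, radius=5e-3)
        force = np.array([1.3, -0.4, 2.2])
        nodal = att.distribute(force)
        assert np.allclose(nodal.sum(axis=0), force, atol=1e-12)

    def test_too_few_candidates_rejected(self, anatomy):
        fb = anatomy.system.fem_bodies["disk_right"]
        with pytest.raises(ValueError):
            build_distributed_attachment(fb, np.array([1.0, 1.0, 1.0]), radius=1e-4)
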