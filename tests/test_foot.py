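"""Foot-model variants: structure, geometry invariants, PF-length formulas."""

import math

import numpy as np
import pytest

from archwalk.foot import (FootJointState, build_foot,
                           ligament_generalized_forces, ligament_path_lengths,
                           residual_joint_torque)
from archwalk.params import (FOOT_KINDS, FootGeometry, default_geometry,
                             has_mobile_arch, has_toe, is_coupled,
                             variant_config, geometry_from_config)

DEG = math.pi / 180.0


class TestKindPredicates:
    def test_toe(self):
        assert {k for k in FOOT_KINDS if has_toe(k)} == {"2s-TJ", "3s-nW", "3s-W"}

    def test_arch(self):
        assert {k for k in FOOT_KINDS if has_mobile_arch(k)} == {
            "2s-MTJ", "3s-nW", "3s-W"}

    def test_coupled(self):
        assert {k for k in FOOT_KINDS if is_coupled(k)} == {"3s-W"}


class TestBuild:
    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown foot model"):
            build_foot("4s-X")

    def test_arch_length_invariant_all_variants(self):
        for kind in FOOT_KINDS:
            g = default_geometry(kind)
            assert abs(g.l_arch_cm - 17.0) < 0.1  # 17 cm to within 1 mm
            build_foot(kind)  # does not raise

    def test_bundled_configs_match_defaults(self):
        for kind in FOOT_KINDS:
            doc = variant_config(kind)
            g = geometry_from_config(doc)
            assert g == default_geometry(kind)

    def test_arch_violation_rejected(self):
        g = FootGeometry(r_A_CB=(14.0, -2.27))  # 18 cm spacing
        with pytest.raises(ValueError, match="17 cm"):
            build_foot("2s-MTJ", geometry=g)

    def test_rigid_single_segment(self):
        m = build_foot("1s-lA")
        assert m.segments == ("A",)
        assert m.joints == ()
        assert m.ligaments == ()
        assert len(m.contacts) == 2

    def test_windlass_full_structure(self):
        m = build_foot("3s-W")
        assert m.segments == ("A", "M", "T")
        assert m.joints == ("MTJ", "TJ")
        assert set(m.ligaments) == {"PF", "PL"}
        assert len(m.contacts) == 3
        assert m.is_coupled

    def test_ball_element_rides_on_toe_when_present(self):
        m = build_foot("2s-TJ")
        cb = {c.name: c for c in m.contacts}["C_B"]
        assert cb.segment == "T"
        assert cb.radius == pytest.approx(0.0573)
        assert {c.name: c for c in m.contacts}["C_H"].radius == pytest.approx(0.05)
        m2 = build_foot("2s-MTJ")
        assert {c.name: c for c in m2.contacts}["C_B"].segment == "M"
        m3 = build_foot("1s-hA")
        assert {c.name: c for c in m3.contacts}["C_B"].segment == "A"

    def test_rigid_variants_differ_only_in_contact_placement(self):
        lo = build_foot("1s-lA")
        hi = build_foot("1s-hA")
        assert lo.ligaments == hi.ligaments == ()
        zl = {c.name: c.center for c in lo.contacts}
        zh = {c.name: c.center for c in hi.contacts}
        # same horizontal layout, vertically offset by the sole height
        for name in ("C_H", "C_B"):
            assert zl[name][0] == pytest.approx(zh[name][0])
            assert zl[name][1] - zh[name][1] == pytest.approx(0.08)


class TestPathLengths:
    def test_neutral_pose_is_chord(self):
        m = build_foot("3s-W")
        out = ligament_path_lengths(m, FootJointState())
        assert out["l_PF"] == pytest.approx(m.chord_neutral)
        assert out["l_PL"] == pytest.approx(m.chord_neutral)

    def test_toe_arc_term(self):
        # 35 deg of toe dorsiflexion adds phi * R_PF = 0.611 cm
        m = build_foot("2s-TJ")
        out = ligament_path_lengths(m, FootJointState(phi_TJ=35.0))
        assert out["l_PF"] == pytest.approx(0.15610865238198016, rel=1e-12)

    def test_decoupled_pair_independence(self):
        m = build_foot("3s-nW")
        base = ligament_path_lengths(m, FootJointState(phi_MTJ=5.0, phi_TJ=20.0))
        only_tj = ligament_path_lengths(m, FootJointState(phi_MTJ=5.0, phi_TJ=25.0))
        only_mtj = ligament_path_lengths(m, FootJointState(phi_MTJ=8.0, phi_TJ=20.0))
        assert only_tj["l_PF_1"] == pytest.approx(base["l_PF_1"])  # TJ-invariant
        assert only_mtj["l_PF_2"] == pytest.approx(base["l_PF_2"])  # MTJ-invariant
        assert only_tj["l_PF_2"] > base["l_PF_2"]
        assert only_mtj["l_PF_1"] != base["l_PF_1"]

    def test_coupled_partial_derivatives_match_finite_differences(self):
        m = build_foot("3s-W")
        h = 1e-4  # degrees
        s0 = FootJointState(phi_MTJ=3.0, phi_TJ=20.0)
        f = lambda s: ligament_path_lengths(m, s)["l_PF"]
        d_tj = (f(FootJointState(3.0, 20.0 + h)) - f(FootJointState(3.0, 20.0 - h))) / (
            2 * h * DEG)
        assert d_tj == pytest.approx(m.R_PF, rel=1e-6)
        d_mtj = (f(FootJointState(3.0 + h, 20.0)) - f(FootJointState(3.0 - h, 20.0))) / (
            2 * h * DEG)
        # equals the chord derivative, independent of the arc term
        g = lambda s: ligament_path_lengths(build_foot("2s-MTJ"), s)["l_PF"]
        d_chord = (g(FootJointState(3.0 + h, 0.0)) - g(FootJointState(3.0 - h, 0.0))) / (
            2 * h * DEG)
        assert d_mtj == pytest.approx(d_chord, rel=1e-6)

    def test_state_consistency_enforced(self):
        with pytest.raises(ValueError, match="no toe"):
            ligament_path_lengths(build_foot("2s-MTJ"), FootJointState(phi_TJ=5.0))
        with pytest.raises(ValueError, match="rigid arch"):
            ligament_path_lengths(build_foot("2s-TJ"), FootJointState(phi_MTJ=5.0))


class TestGeneralizedForces:
    def test_zero_tension_zero_output(self):
        m = build_foot("3s-W")
        out = ligament_generalized_forces(m)
        assert out.M_TJ == 0.0
        assert not out.f_on_A.any() and not out.f_on_M.any()

    def test_toe_moment_is_tension_times_wrap_radius(self):
        m = build_foot("2s-TJ")
        out = ligament_generalized_forces(m, F_PF_toe=100.0)
        assert out.M_TJ == pytest.approx(1.0)  # 100 N * 0.01 m

    def test_chord_pair_equal_and_opposite(self):
        m = build_foot("2s-MTJ")
        out = ligament_generalized_forces(m, F_PL=50.0, F_PF_chord=30.0)
        assert np.allclose(out.f_on_A, -out.f_on_M)
        assert np.linalg.norm(out.f_on_A) == pytest.approx(80.0)

    def test_coupling_in_windlass(self):
        # one PF tension simultaneously makes a chord force and a toe moment
        m = build_foot("3s-W")
        out = ligament_generalized_forces(m, F_PF_chord=120.0, F_PF_toe=120.0,
                                          state=FootJointState(phi_TJ=20.0))
        assert out.M_TJ > 0.0
        assert np.linalg.norm(out.f_on_A) > 0.0

    def test_negative_tension_rejected(self):
        with pytest.raises(ValueError):
            ligament_generalized_forces(build_foot("3s-W"), F_PL=-1.0)


class TestResidualTorque:
    @pytest.mark.parametrize(
        "phi, phid, tau",
        [(0.0, 0.0, 0.0), (10.0, 0.0, -0.1), (69.0, 0.0, -0.69),
         (0.0, 10.0, -0.01), (-10.0, 0.0, 0.1)],
    )
    def test_linear_law(self, phi, phid, tau):
        assert residual_joint_torque(phi, phid) == pytest.approx(tau)
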