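import numpy as np
import pytest

from helixrope import (HelixSpec, RotationProfile, assign_layers,
                       circumcircle_diameter, classify_twist, detect_hbonds,
                       fit_helix, gen_triple_helix, mirror_structure,
                       trace_strands, triple_helix_metrics)


def profile_from_theta(theta):
    theta = np.asarray(theta, float)
    return RotationProfile(np.arange(len(theta)), theta,
                           np.array([0.0, 0.0, 1.0]), np.zeros(len(theta)))


class TestClassifyTwist:
    def test_decreasing_is_clockwise_is_S(self):
        call = classify_twist(profile_from_theta([0, -60, -120, -180]))
        assert call.verdict == "S"
        assert call.slope == pytest.approx(-60.0)

    def test_increasing_is_counterclockwise_is_Z(self):
        call = classify_twist(profile_from_theta([0, 60, 120, 180]))
        assert call.verdict == "Z"
        assert call.slope == pytest.approx(60.0)

    def test_flat_profile_undetermined(self):
        call = classify_twist(profile_from_theta([0, 0.1, -0.1, 0]),
                              threshold=1.0)
        assert call.verdict == "undetermined"

    def test_too_few_layers_errors(self):
        with pytest.raises(ValueError):
            classify_twist(profile_from_theta([0, -60]))


class TestRotationProfile:
    def test_constructed_minus_sixty_per_layer(self, helix_structure):
        """The default synthetic helix rotates its H-bonds by exactly
        Δθ per layer; the unwrapped profile must reproduce it."""
        structure, truth = helix_structure
        layers = assign_layers(structure)
        hbonds = detect_hbonds(structure)
        from helixrope.chirality import rotation_profile
        strands = trace_strands(hbonds, structure, layers)
        prof = rotation_profile(hbonds, structure, layers, strands=strands)
        expected = truth["delta_theta"] * np.arange(len(prof.theta))
        assert np.allclose(prof.theta, expected, atol=1e-8)

    def test_parallel_layers_give_zero(self):
        spec = HelixSpec(delta_theta=-1e-9, n_layers=6)
        # exactly zero twist is a degenerate spec; emulate parallel
        # H-bonds with an explicitly constructed two-layer stack instead
        from helixrope import Atom, CrystalStructure, UnitCell
        atoms = []
        aid = 0
        for n in range(4):
            for name, el, off in (("N", "N", (0.0, 0, 0)), ("H", "H", (1.0, 0, 0)),
                                  ("O", "O", (2.9, 0, -3.0))):
                atoms.append(Atom(aid, el, name, "TRP", n,
                                  np.array(off) + (0, 0, 3.0 * n)))
                aid += 1
        s = CrystalStructure(atoms, UnitCell(50, 50, 50))
        layers = assign_layers(s, gap_tol=1.5)
        hbonds = detect_hbonds(s)
        from helixrope.chirality import rotation_profile
        prof = rotation_profile(hbonds, s, layers)
        assert np.allclose(prof.theta, 0.0, atol=1e-10)

    def test_mirror_negates_profile(self, helix_structure):
        structure, _ = helix_structure
        from helixrope.chirality import rotation_profile
        layers = assign_layers(structure)
        strands = trace_strands(detect_hbonds(structure), structure, layers)
        prof = rotation_profile(detect_hbonds(structure), structure, layers,
                                strands=strands)
        mirrored = mirror_structure(structure)
        layers_m = assign_layers(mirrored)
        strands_m = trace_strands(detect_hbonds(mirrored), mirrored, layers_m)
        prof_m = rotation_profile(detect_hbonds(mirrored), mirrored, layers_m,
                                  strands=strands_m)
        assert np.allclose(prof_m.theta, -prof.theta, atol=1e-9)


class TestTraceStrands:
    def test_three_strands_of_eight(self, helix_structure):
        structure, truth = helix_structure
        layers = assign_layers(structure)
        strands = trace_strands(detect_hbonds(structure), structure, layers)
        assert len(strands) == truth["n_strands"]
        assert all(len(s.molecule_ids) == truth["n_layers"] for s in strands)
        assert len({s.helix_id for s in strands}) == 1

    def test_no_hbonds_no_strands(self, helix_structure):
        structure, _ = helix_structure
        layers = assign_layers(structure)
        assert trace_strands([], structure, layers) == []

    def test_two_separated_bundles_get_two_ids(self):
        spec = HelixSpec(n_bundles=2, bundle_spacing=40.0, n_layers=8)
        structure, truth = gen_triple_helix(spec)
        layers = assign_layers(structure)
        strands = trace_strands(detect_hbonds(structure), structure, layers)
        assert len(strands) == 6
        assert len({s.helix_id for s in strands}) == 2


class TestFitHelix:
    def test_constructed_parameters_recovered(self):
        n = np.arange(10)
        pts = np.column_stack([7.8 * np.cos(np.radians(36.0 * n)),
                               7.8 * np.sin(np.radians(36.0 * n)),
                               3.6 * n])
        fit = fit_helix(pts)
        assert fit.radius == pytest.approx(7.8, rel=1e-6)
        assert fit.pitch == pytest.approx(36.0, rel=1e-6)
        assert fit.handedness == "Z"

    def test_mirrored_points_flip_handedness(self):
        n = np.arange(10)
        pts = np.column_stack([7.8 * np.cos(np.radians(36.0 * n)),
                               -7.8 * np.sin(np.radians(36.0 * n)),
                               3.6 * n])
        fit = fit_helix(pts)
        assert fit.handedness == "S"
        assert fit.radius == pytest.approx(7.8, rel=1e-6)
        assert fit.pitch == pytest.approx(36.0, rel=1e-6)

    def test_jittered_recovery_within_one_percent(self):
        rng = np.random.default_rng(21)
        n = np.arange(24)
        for _ in range(20):
            pts = np.column_stack([7.8 * np.cos(np.radians(25.0 * n)),
                                   7.8 * np.sin(np.radians(25.0 * n)),
                                   3.0 * n]) + rng.normal(0, 0.1, (24, 3))
            fit = fit_helix(pts, axis_hint=(0, 0, 1.0), fix_axis=True)
            assert fit.radius == pytest.approx(7.8, rel=0.01)
            assert fit.pitch == pytest.approx(360 / 25 * 3.0, rel=0.01)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="[cd]ollinear|degenerate"):
            fit_helix(pts)


class TestCircumcircle:
    def test_equilateral_closed_form(self):
        s = 10.0
        p1 = (0.0, 0.0, 0.0)
        p2 = (s, 0.0, 0.0)
        p3 = (s / 2, s * np.sqrt(3) / 2, 0.0)
        assert circumcircle_diameter(p1, p2, p3) == pytest.approx(
            2 * s / np.sqrt(3))

    def test_right_triangle_thales(self):
        assert circumcircle_diameter((0, 0, 0), (3, 0, 0), (0, 4, 0)) == \
            pytest.approx(5.0)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(8)
        pts = rng.uniform(-5, 5, (3, 3))
        d0 = circumcircle_diameter(*pts)
        rot = Rotation.random(rng=rng)
        assert circumcircle_diameter(*rot.apply(pts)) == pytest.approx(d0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            circumcircle_diameter((0, 0, 0), (1, 0, 0), (2, 0, 0))


class TestTripleHelixMetrics:
    def test_synthetic_closed_form(self):
        spec = HelixSpec(n_strands=3, delta_theta=-20.0, delta_z=3.0,
                         radius=7.8, n_layers=8)
        structure, truth = gen_triple_helix(spec)
        m = triple_helix_metrics(structure, fit_atom="N")
        assert m["twist"].verdict == "S"
        assert m["pitch_A"] == pytest.approx(54.0, rel=1e-6)
        assert m["radius_A"] == pytest.approx(7.8, rel=1e-6)
        assert m["n_strands"] == 3
        assert m["n_layers"] == 8
        assert np.allclose(m["inner_diameter_A"], truth["ca_circle_diameter"],
                           rtol=1e-9)

    def test_mirror_antisymmetry_exact(self, helix_structure):
        structure, _ = helix_structure
        m = triple_helix_metrics(structure)
        mm = triple_helix_metrics(mirror_structure(structure))
        assert {m["twist"].verdict, mm["twist"].verdict} == {"S", "Z"}
        assert mm["twist"].slope == pytest.approx(-m["twist"].slope)

    def test_rigid_motion_invariance(self, helix_structure):
        from scipy.spatial.transform import Rotation
        structure, _ = helix_structure
        m = triple_helix_metrics(structure, fit_atom="N")
        rng = np.random.default_rng(9)
        rot = Rotation.random(rng=rng)
        pos = rot.apply(structure.positions) + rng.uniform(-4, 4, 3)
        moved = structure.with_positions(pos)
        axis = rot.apply([0.0, 0.0, 1.0])
        mv = triple_helix_metrics(moved, axis=axis, fit_atom="N")
        assert mv["twist"].verdict == m["twist"].verdict
        assert mv["pitch_A"] == pytest.approx(m["pitch_A"], abs=1e-6)
        assert mv["radius_A"] == pytest.approx(m["radius_A"], abs=1e-6)
        assert np.mean(mv["inner_diameter_A"]) == pytest.approx(
            np.mean(m["inner_diameter_A"]), abs=1e-6)

    def test_strand_fit_sign_agrees_with_profile(self):
        for dth in (-35.0, 15.0, -60.0, 80.0):
            spec = HelixSpec(delta_theta=dth, n_layers=10, jitter=0.05, seed=3)
            structure, _ = gen_triple_helix(spec)
            m = triple_helix_metrics(structure, fit_atom="N")
            for fit in m["helix_fits"]:
                assert (fit.delta_theta < 0) == (m["twist"].slope < 0)
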