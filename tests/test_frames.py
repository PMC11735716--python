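"""Axis fitting and the tilt/twist (beta, gamma) conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fisskit as fk
from fisskit.errors import (
    AtomMissingError,
    InsufficientPointsError,
    NotACoiledCoilError,
)
from fisskit.frames import (
    DomainOrientation,
    domain_orientation,
    frame_from_angles,
    rotation_zyz,
    wrap_angle,
)
from fisskit.structio import Atom, StructureModel


SEL12 = fk.AtomSelection("A", 1, 12)


class TestHelixAxis:
    @pytest.mark.parametrize("beta,gamma", [(0.0, 0.0), (82.0, 10.0), (130.0, -75.0)])
    def test_ideal_helix_axis_recovered(self, beta, gamma):
        h = fk.make_helix(20, orientation=(beta, gamma))
        frame = fk.fit_helix_axis(h, fk.AtomSelection("A", 1, 20))
        expected = rotation_zyz(0.0, beta, gamma)[:, 2]
        assert np.dot(frame.axis, expected) > np.cos(np.radians(0.5))

    def test_rotated_helix_axis_follows_rotation(self):
        h = fk.make_helix(15, orientation=(0.0, 0.0))
        R = rotation_zyz(25.0, 40.0, 60.0)
        pos = np.asarray([a.pos for a in h.atoms if a.name == "CA"])
        frame0 = fk.fit_helix_axis(pos)
        frame1 = fk.fit_helix_axis(pos @ R.T)
        assert np.allclose(frame1.axis, R @ frame0.axis, atol=1e-9)

    def test_noisy_axis_within_three_degrees(self):
        """0.3 A isotropic coordinate noise, 12 residues, 100 seeds."""
        errs = []
        base = fk.make_helix(12, orientation=(0.0, 0.0))
        pos = np.asarray([a.pos for a in base.atoms if a.name == "CA"])
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = pos + rng.normal(scale=0.3, size=pos.shape)
            frame = fk.fit_helix_axis(noisy)
            errs.append(np.degrees(np.arccos(np.clip(frame.axis[2], -1, 1))))
        assert np.mean(errs) < 3.0
        assert np.percentile(errs, 95) < 3.0

    def test_too_few_residues(self):
        h = fk.make_helix(4)
        with pytest.raises(InsufficientPointsError):
            fk.fit_helix_axis(h, fk.AtomSelection("A", 1, 4))

    def test_reversed_chain_gives_antiparallel_axis(self):
        h = fk.make_helix(12)
        pos = np.asarray([a.pos for a in h.atoms if a.name == "CA"])
        f_fwd = fk.fit_helix_axis(pos)
        f_rev = fk.fit_helix_axis(pos[::-1])
        assert np.dot(f_fwd.axis, f_rev.axis) < -0.999


class TestCoiledCoilAxis:
    def _two_helix_model(self, tilt):
        # equal-and-opposite tilts about z: same beta, azimuths 180 apart
        a = fk.make_helix(12, orientation=(tilt, 0.0), chain="A",
                          origin=(5.0, 0.0, 0.0))
        b = fk.make_helix(12, orientation=(tilt, 0.0), alpha=180.0, chain="B",
                          origin=(-5.0, 0.0, 0.0))
        return StructureModel(atoms=a.atoms + b.atoms, source_id="cc")

    def test_parallel_helices_give_z(self):
        model = self._two_helix_model(0.0)
        frame = fk.fit_coiled_coil_axis(
            model, SEL12, fk.AtomSelection("B", 1, 12)
        )
        assert frame.axis[2] > np.cos(np.radians(0.1))

    def test_symmetric_tilt_cancels(self):
        model = self._two_helix_model(10.0)
        frame = fk.fit_coiled_coil_axis(
            model, SEL12, fk.AtomSelection("B", 1, 12)
        )
        assert frame.axis[2] > np.cos(np.radians(0.1))

    def test_divergent_helices_rejected(self):
        a = fk.make_helix(12, orientation=(0.0, 0.0), chain="A")
        b = fk.make_helix(12, orientation=(80.0, 0.0), chain="B",
                          origin=(10.0, 0.0, 0.0))
        model = StructureModel(atoms=a.atoms + b.atoms, source_id="bad")
        with pytest.raises(NotACoiledCoilError):
            fk.fit_coiled_coil_axis(model, SEL12, fk.AtomSelection("B", 1, 12))

    def test_antiparallel_helices_coorient(self):
        a = fk.make_helix(12, orientation=(5.0, 0.0), chain="A")
        b = fk.make_helix(12, orientation=(175.0, 0.0), chain="B",
                          origin=(8.0, 0.0, 0.0))
        model = StructureModel(atoms=a.atoms + b.atoms, source_id="ap")
        frame = fk.fit_coiled_coil_axis(model, SEL12, fk.AtomSelection("B", 1, 12))
        assert abs(frame.axis[2]) > np.cos(np.radians(6.0))


class TestFilamentAxis:
    def test_axis_along_z_with_polarity(self):
        fil = fk.make_filament(14)
        frame = fk.fit_filament_axis(fil, fil.chains())
        # last chain is nearest the pointed end by construction -> +z
        assert frame.axis[2] > 0.999

    def test_rotated_filament(self):
        fil = fk.make_filament(14, orientation=(40.0, 20.0))
        frame = fk.fit_filament_axis(fil, fil.chains())
        expected = rotation_zyz(0.0, 40.0, 20.0)[:, 2]
        assert np.dot(frame.axis, expected) > np.cos(np.radians(0.5))

    def test_reversed_polarity_flips_axis(self):
        fil = fk.make_filament(14)
        chains = fil.chains()
        up = fk.fit_filament_axis(fil, chains, pointed_end_chain=chains[-1])
        down = fk.fit_filament_axis(fil, chains, pointed_end_chain=chains[0])
        assert np.dot(up.axis, down.axis) < -0.999

    def test_too_few_subunits(self):
        with pytest.raises(InsufficientPointsError):
            fk.make_filament(2)
        fil = fk.make_filament(5)
        with pytest.raises(InsufficientPointsError):
            fk.fit_filament_axis(fil, fil.chains()[:2])


class TestDomainOrientation:
    def test_axis_parallel_to_z_is_beta_zero(self, lab_frame):
        frame = frame_from_angles(0.0, 0.0)
        o = domain_orientation(frame, lab_frame)
        assert o.beta == pytest.approx(0.0, abs=1e-9)
        assert o.degenerate

    def test_euler_roundtrip_exact(self, lab_frame):
        rng = np.random.default_rng(7)
        for _ in range(25):
            beta = rng.uniform(1.0, 179.0)
            gamma = rng.uniform(-179.0, 179.0)
            alpha = rng.uniform(-180.0, 180.0)
            frame = frame_from_angles(beta, gamma, alpha_deg=alpha)
            o = domain_orientation(frame, lab_frame)
            assert o.beta == pytest.approx(beta, abs=1e-6)
            assert o.gamma == pytest.approx(gamma, abs=1e-6)

    def test_gamma_sense_counterclockwise_from_c_terminal_end(self, lab_frame):
        """Right-handed rotation of the domain about its own axis adds to gamma."""
        base = frame_from_angles(60.0, 20.0)
        M = base.basis() @ rotation_zyz(10.0, 0.0, 0.0)  # intrinsic about +axis
        rotated = fk.AxisFrame(base.origin, M[:, 2], M[:, 0])
        o = domain_orientation(rotated, lab_frame)
        assert o.gamma == pytest.approx(30.0, abs=1e-9)

    def test_azimuth_about_filament_axis_inaccessible(self, lab_frame):
        """(beta, gamma) must not change when the whole system spins about z."""
        frame = frame_from_angles(75.0, -40.0)
        for alpha in (30.0, 123.0, -77.0):
            R = rotation_zyz(alpha, 0.0, 0.0)
            o = domain_orientation(frame.transformed(R), lab_frame)
            assert o.beta == pytest.approx(75.0, abs=1e-9)
            assert o.gamma == pytest.approx(-40.0, abs=1e-9)

    def test_reversed_filament_axis_maps_beta(self, lab_frame):
        frame = frame_from_angles(70.0, 10.0)
        flipped = fk.AxisFrame(lab_frame.origin, -lab_frame.axis, lab_frame.ref_perp)
        o = domain_orientation(frame, flipped)
        assert o.beta == pytest.approx(110.0, abs=1e-9)

    def test_pole_degeneracy_flag(self, lab_frame):
        o = domain_orientation(frame_from_angles(180.0, 55.0), lab_frame)
        assert o.degenerate and o.gamma == 0.0


class TestCanonicalization:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        beta=st.floats(0.0, 180.0, allow_nan=False),
        gamma=st.floats(-179.999, 180.0, allow_nan=False),
    )
    def test_canonical_identifies_dipole_mates(self, beta, gamma):
        o = DomainOrientation(beta, gamma)
        c1 = o.canonical()
        c2 = o.mate().canonical()
        assert c1.beta <= 90.0 + 1e-9
        assert c1.beta == pytest.approx(c2.beta, abs=1e-9)
        if abs(c1.beta - 90.0) > 1e-9:  # beta=90 maps to itself either way
            assert wrap_angle(c1.gamma - c2.gamma) == pytest.approx(0.0, abs=1e-9)

    def test_canonical_idempotent(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            o = DomainOrientation(rng.uniform(0, 180), rng.uniform(-179.9, 180))
            c = o.canonical()
            cc = c.canonical()
            assert (c.beta, c.gamma) == (cc.beta, cc.gamma)


class TestDipole:
    def test_cb_pair_direction(self):
        atoms = [
            Atom("A", 1, "CYS", "CA", (0.5, 0.0, 0.0)),
            Atom("A", 1, "CYS", "CB", (0.0, 0.0, 0.0)),
            Atom("A", 8, "CYS", "CA", (0.5, 0.0, 10.0)),
            Atom("A", 8, "CYS", "CB", (0.0, 0.0, 10.0)),
        ]
        model = StructureModel(atoms=atoms, source_id="pair")
        probe = fk.dipole_from_cys_pair(model, ("A", 1), ("A", 8))
        assert np.allclose(probe.dipole_mol, [0.0, 0.0, 1.0])

    def test_swapped_pair_negates_dipole_order_params_unchanged(self):
        atoms = [
            Atom("A", 1, "CYS", "CB", (0.0, 0.0, 0.0)),
            Atom("A", 8, "CYS", "CB", (3.0, 4.0, 10.0)),
        ]
        model = StructureModel(atoms=atoms, source_id="pair")
        p_fwd = fk.dipole_from_cys_pair(model, ("A", 1), ("A", 8))
        p_rev = fk.dipole_from_cys_pair(model, ("A", 8), ("A", 1))
        assert np.allclose(p_fwd.dipole_mol, -p_rev.dipole_mol)
        o = DomainOrientation(63.0, 25.0)
        ops_f = fk.order_params_from_delta(p_fwd, o)
        ops_r = fk.order_params_from_delta(p_rev, o)
        assert ops_f.p2 == pytest.approx(ops_r.p2, abs=1e-12)
        assert ops_f.p4 == pytest.approx(ops_r.p4, abs=1e-12)

    def test_probe_dipole_tracks_labelled_helix(self, domain5):
        """i, i+7 C-beta pairs on a surface helix run near the helix axis."""
        _, _, probes = domain5
        from fisskit.synthfix import _DOMAIN_HELICES

        for probe, (alpha, beta, _) in zip(probes, _DOMAIN_HELICES):
            helix_dir = rotation_zyz(alpha, beta, 0.0)[:, 2]
            ang = np.degrees(np.arccos(abs(np.dot(probe.dipole_mol, helix_dir))))
            assert ang < 25.0

    def test_missing_cb_raises(self):
        atoms = [Atom("A", 1, "GLY", "CA", (0.0, 0.0, 0.0)),
                 Atom("A", 8, "CYS", "CB", (1.0, 0.0, 0.0))]
        model = StructureModel(atoms=atoms, source_id="gly")
        with pytest.raises(AtomMissingError):
            fk.dipole_from_cys_pair(model, ("A", 1), ("A", 8))


class TestInterhelixAngle:
    def test_identical_and_orthogonal(self, lab_frame):
        assert fk.interhelix_angle(lab_frame, lab_frame) == pytest.approx(0.0)
        other = fk.AxisFrame(np.zeros(3), [0.0, 1.0, 0.0], [1.0, 0.0, 0.0])
        assert fk.interhelix_angle(lab_frame, other) == pytest.approx(90.0)

    def test_direction_sensitive(self, lab_frame):
        anti = fk.AxisFrame(np.zeros(3), [0.0, 0.0, -1.0], [1.0, 0.0, 0.0])
        assert fk.interhelix_angle(lab_frame, anti) == pytest.approx(180.0)
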