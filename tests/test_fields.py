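"""Multipole field kernels against closed-form and finite-charge oracles."""

import math
import warnings

import numpy as np
import pytest

import shellfield as sf
from shellfield.fields import (
    field_from_site,
    quadrupole_from_charges,
)
from shellfield.water import random_quaternion
from tests.conftest import make_frame

# Independent hand oracle for the unit conversion: E = q/(4πε0 r²) in SI,
# then V/m -> MV/cm.  Constants written out, not imported from the package.
_E_SI = 1.602176634e-19
_K_SI = 8.9875517862e9


def hand_coulomb_mv_cm(q_e, r_angstrom):
    e_v_per_m = _K_SI * q_e * _E_SI / (r_angstrom * 1e-10) ** 2
    return e_v_per_m / 1e8


class TestProbe:
    def test_symmetric_geometry(self):
        geom = sf.SoluteGeometry(
            ["P", "O1", "O2"], np.array([[0.0, 0, 0], [1, 1, 0], [1, -1, 0]]),
            np.zeros(3), np.ones(3), np.ones(3), 0, 1, 2,
        )
        probe = sf.c2_probe(geom)
        np.testing.assert_allclose(probe.point, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(probe.axis, [1, 0, 0], atol=1e-12)

    def test_label_swap_invariance(self, dmp):
        swapped = sf.SoluteGeometry(
            dmp.labels, dmp.positions, dmp.charges, dmp.lj_sigma, dmp.lj_epsilon,
            dmp.p_index, dmp.o2_index, dmp.o1_index,
        )
        p1, p2 = sf.c2_probe(dmp), sf.c2_probe(swapped)
        np.testing.assert_allclose(p1.point, p2.point, atol=1e-12)
        np.testing.assert_allclose(p1.axis, p2.axis, atol=1e-12)

    def test_asymmetric_geometry_still_unit_axis(self):
        geom = sf.SoluteGeometry(
            ["P", "O1", "O2"], np.array([[0.0, 0, 0], [1.9, 1.1, 0.2], [1, -1, 0]]),
            np.zeros(3), np.ones(3), np.ones(3), 0, 1, 2,
        )
        probe = sf.c2_probe(geom)
        assert np.linalg.norm(probe.axis) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_atoms_rejected(self):
        geom = sf.SoluteGeometry(
            ["P", "O1", "O2"], np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),
            np.zeros(3), np.ones(3), np.ones(3), 0, 1, 2,
        )
        with pytest.raises(ValueError, match="collinear"):
            sf.c2_probe(geom)

    def test_dmp_probe_on_c2_axis(self, dmp):
        """For the symmetric gg geometry the axis is ⊥ to O1−O2."""
        probe = sf.c2_probe(dmp)
        o1 = dmp.positions[dmp.o1_index]
        o2 = dmp.positions[dmp.o2_index]
        assert abs(probe.axis @ (o1 - o2)) < 1e-9
        np.testing.assert_allclose(probe.point, 0.5 * (o1 + o2), atol=1e-12)


class TestChargeKernel:
    def test_zero_charge(self):
        site = sf.MultipoleSite([0, 0, 0], charge=0.0)
        np.testing.assert_array_equal(sf.field_from_charge(site, [1, 2, 3]), 0.0)

    def test_coulomb_oracle_at_3A(self):
        """Unit conversion pinned by the SI hand computation, 5 sig figs."""
        site = sf.MultipoleSite([0, 0, 0], charge=1.0)
        e = sf.field_from_charge(site, [3.0, 0, 0])
        expected = hand_coulomb_mv_cm(1.0, 3.0)  # 159.9961 MV/cm
        assert expected == pytest.approx(159.996, abs=5e-4)
        assert np.linalg.norm(e) == pytest.approx(expected, rel=1e-5)
        assert e[0] > 0  # away from a positive charge

    def test_inverse_square(self):
        site = sf.MultipoleSite([0, 0, 0], charge=1.0)
        e1 = np.linalg.norm(sf.field_from_charge(site, [1.0, 0, 0]))
        e3 = np.linalg.norm(sf.field_from_charge(site, [3.0, 0, 0]))
        assert e1 / e3 == pytest.approx(9.0, rel=1e-9)

    def test_singularity(self):
        site = sf.MultipoleSite([1, 1, 1], charge=1.0)
        with pytest.raises(ZeroDivisionError):
            sf.field_from_charge(site, [1, 1, 1])


class TestDipoleKernel:
    def test_zero_dipole(self):
        site = sf.MultipoleSite([0, 0, 0])
        np.testing.assert_array_equal(sf.field_from_dipole(site, [1, 0, 0]), 0.0)

    def test_on_axis_magnitude(self):
        mu = np.array([0, 0, 0.5])
        site = sf.MultipoleSite([0, 0, 0], dipole=mu)
        r = 4.0
        e = sf.field_from_dipole(site, [0, 0, r])
        expected = sf.KE_FIELD * 2 * np.linalg.norm(mu) / r**3
        np.testing.assert_allclose(e, [0, 0, expected], atol=1e-12)

    def test_finite_difference_charge_pair_oracle(self):
        """Two opposite charges with qd = |μ| at d = r/1000 reproduce the
        ideal-dipole field to 1e-4 relative."""
        r = 10.0
        d = r / 1000.0
        q = 0.5 / d  # so q·d = 0.5 e·Å
        plus = sf.MultipoleSite([0, 0, d / 2], charge=q)
        minus = sf.MultipoleSite([0, 0, -d / 2], charge=-q)
        point = np.array([6.0, -3.0, 5.0])
        point *= r / np.linalg.norm(point)
        summed = sf.field_from_charge(plus, point) + sf.field_from_charge(minus, point)
        ideal = sf.field_from_dipole(
            sf.MultipoleSite([0, 0, 0], dipole=[0, 0, 0.5]), point
        )
        np.testing.assert_allclose(summed, ideal, rtol=1e-4)


class TestQuadrupoleKernel:
    def test_zero_quadrupole(self):
        site = sf.MultipoleSite([0, 0, 0])
        np.testing.assert_array_equal(sf.field_from_quadrupole(site, [1, 0, 0]), 0.0)

    def test_non_traceless_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            sf.MultipoleSite([0, 0, 0], quadrupole=np.eye(3))

    def test_four_charge_oracle(self):
        """A linear quadrupole (zero net charge and dipole) at 100× its
        size matches the traceless-kernel field within 1e-3 relative."""
        a = 0.05
        charges = [(np.array([0, 0, a]), 1.0), (np.array([0, 0, -a]), 1.0),
                   (np.array([0, 0, 0]), -2.0)]
        theta = quadrupole_from_charges([p for p, _ in charges],
                                        [q for _, q in charges])
        assert abs(np.trace(theta)) < 1e-12
        site = sf.MultipoleSite([0, 0, 0], quadrupole=theta)
        rng = np.random.default_rng(0)
        for _ in range(5):
            point = rng.normal(size=3)
            point *= (100 * 2 * a) / np.linalg.norm(point)
            summed = sum(
                sf.field_from_charge(sf.MultipoleSite(p, charge=q), point)
                for p, q in charges
            )
            kernel = sf.field_from_quadrupole(site, point)
            np.testing.assert_allclose(kernel, summed, rtol=1e-3)

    def test_inverse_fourth_power(self):
        theta = np.diag([1.0, 1.0, -2.0])
        site = sf.MultipoleSite([0, 0, 0], quadrupole=theta)
        e1 = np.linalg.norm(sf.field_from_quadrupole(site, [2.0, 1.0, 0.5]))
        e2 = np.linalg.norm(sf.field_from_quadrupole(site, [4.0, 2.0, 1.0]))
        assert e1 / e2 == pytest.approx(16.0, rel=1e-6)


class TestSolventField:
    def test_zero_waters_warns_and_returns_zero(self, dmp, water_model):
        frame = make_frame(dmp, water_model, np.zeros((0, 3)))
        probe = sf.c2_probe(dmp)
        with pytest.warns(UserWarning, match="no waters"):
            sample = sf.solvent_field(frame, probe)
        np.testing.assert_array_equal(sample.vector, 0.0)

    def test_mirror_symmetric_pair(self, dmp, water_model):
        """Two waters mirror-symmetric about the C2 axis: transverse
        components cancel; E∥ doubles the single-water projection."""
        probe = sf.c2_probe(dmp)
        rng = np.random.default_rng(1)
        # mirror across the xz-plane (axis is +x): reflect y
        pos = np.array([5.0, 2.0, 1.5])
        mirrored = pos * np.array([1, -1, 1])
        # orientation mirrored as well: reflect the H/L geometry by
        # reflecting the quaternion (x,z components of rotated template)
        quat = np.array([0.0, 0.0, 0.0, 1.0])
        f_pair = make_frame(dmp, water_model, [pos, mirrored],
                            [quat, _reflect_y_quat(quat)])
        sample = sf.solvent_field(f_pair, probe)
        assert abs(sample.vector[1]) < 1e-9
        f_single = make_frame(dmp, water_model, [pos], [quat])
        single = sf.solvent_field(f_single, probe)
        assert sample.parallel == pytest.approx(2 * single.parallel, abs=1e-9)

    def test_superposition_oracle_10_waters(self, dmp, water_model):
        """Vectorized frame field equals a brute-force loop over every
        site's closed-form contribution, within 1e-9 MV/cm."""
        rng = np.random.default_rng(4)
        oxy = []
        while len(oxy) < 10:
            p = rng.uniform(-8, 8, 3)
            if 3.5 < np.linalg.norm(p) < 8:
                oxy.append(p)
        quats = np.array([random_quaternion(rng) for _ in range(10)])
        frame = make_frame(dmp, water_model, np.array(oxy), quats)
        probe = sf.c2_probe(dmp)
        fast = sf.solvent_field(frame, probe)
        slow = np.zeros(3)
        for w in frame.waters:
            for pos, q in sf.build_water_sites(w):
                if q:
                    slow += sf.field_from_charge(
                        sf.MultipoleSite(pos, charge=q), probe.point
                    )
        np.testing.assert_allclose(fast.vector, slow, atol=1e-9)
        assert abs(fast.parallel) <= np.linalg.norm(fast.vector) + 1e-9

    def test_projection_bounded_by_magnitude(self, dmp, water_model):
        rng = np.random.default_rng(8)
        probe = sf.c2_probe(dmp)
        for _ in range(20):
            pos = rng.uniform(3.5, 8, size=(3,)) * rng.choice([-1, 1], 3)
            frame = make_frame(dmp, water_model, [pos],
                               [random_quaternion(rng)])
            s = sf.solvent_field(frame, probe)
            assert abs(s.parallel) <= np.linalg.norm(s.vector) + 1e-9

    def test_fragment_multipoles_add(self, dmp, water_model, tmp_path):
        import yaml

        spec_file = tmp_path / "mp.yaml"
        spec_file.write_text(yaml.safe_dump({
            "use_charges": False,
            "dipole": [0.0, 0.0, 0.48],
        }))
        spec = sf.fields.load_fragment_multipoles(spec_file)
        frame = make_frame(dmp, water_model, [[5.0, 0, 0]])
        probe = sf.c2_probe(dmp)
        s = sf.solvent_field(frame, probe, spec)
        manual = sf.field_from_dipole(
            sf.MultipoleSite([5.0, 0, 0], dipole=[0, 0, 0.48]), probe.point
        )
        np.testing.assert_allclose(s.vector, manual, atol=1e-12)


def _reflect_y_quat(quat):
    """Quaternion whose rotation equals reflect-y ∘ R(quat) ∘ reflect-y."""
    from scipy.spatial.transform import Rotation

    m = Rotation.from_quat(quat).as_matrix()
    s = np.diag([1.0, -1.0, 1.0])
    return Rotation.from_matrix(s @ m @ s).as_quat()
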