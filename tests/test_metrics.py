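"""Superposition, RMSDs, TM-score and the interface quality metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tcrpmhc.core import GeometryError, InputError, Role, UndefinedInterfaceError
from tcrpmhc.fixtures import make_decoy_ladder, make_toy_complex
from tcrpmhc.metrics import (
    Component,
    DockQClass,
    component_rmsd,
    dockq,
    dockq_report,
    fnat,
    interface_contacts,
    irms,
    kabsch,
    lrms,
    map_common_residues,
    subset_rmsd,
    tm_d0,
    tm_score,
)


def _random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    return R, t


def quaternion_grid_rmsd(A, B, n_grid=4000, seed=0):
    """Oracle: best superposition RMSD via quaternion sampling + polish."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rmsd_of(quat):
        quat = quat / np.linalg.norm(quat)
        R = Rotation.from_quat(quat).as_matrix()
        return float(np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    ranked = sorted(quats, key=rmsd_of)
    best = np.inf
    for start in ranked[:8]:
        polished = minimize(
            rmsd_of, start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        best = min(best, float(polished.fun))
    return best


class TestKabsch:
    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        R, t = _random_rigid(rng)
        sup = kabsch(X @ R.T + t, X)
        assert sup.rmsd < 1e-12
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_gets_proper_rotation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        mirror = X * np.array([-1.0, 1.0, 1.0])
        sup = kabsch(mirror, X)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(GeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(GeometryError):
            kabsch(line, line)

    @pytest.mark.parametrize("trial", range(10))
    def test_agrees_with_quaternion_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        A = rng.normal(size=(n, 3)) * 3
        B = rng.normal(size=(n, 3)) * 3
        assert kabsch(A, B).rmsd == pytest.approx(
            quaternion_grid_rmsd(A, B, seed=trial), abs=1e-4
        )


class TestPairing:
    def test_identical_structures_pair_every_residue(self, toy_complex):
        xs, ys = map_common_residues(toy_complex.copy(), toy_complex)
        n = sum(len(c) for c in toy_complex.chains.values())
        assert xs.shape == (n, 3)
        np.testing.assert_array_equal(xs, ys)

    def test_residues_without_ca_excluded(self, toy_complex):
        native = toy_complex.copy()
        for res in native.chain(Role.MHC).residues[:2]:
            del res.atoms["CA"]
        xs, _ = map_common_residues(toy_complex, native)
        n = sum(len(c) for c in toy_complex.chains.values())
        assert xs.shape == (n - 2, 3)


class TestComponentRmsd:
    def test_zero_for_identical(self, toy_complex):
        for comp in Component:
            assert component_rmsd(
                toy_complex.copy(), toy_complex, comp
            ) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_tcr_shift_localizes(self, toy_complex):
        model = toy_complex.copy()
        for role in (Role.TCRA, Role.TCRB):
            for res in model.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([5.0, 0, 0])
        assert component_rmsd(model, toy_complex, Component.PMHC) < 1e-9
        assert component_rmsd(model, toy_complex, Component.TCR) < 1e-9
        assert component_rmsd(model, toy_complex, Component.TCRPMHC) > 0.5

    def test_gaussian_noise_gives_sigma_sqrt3(self):
        # a near-identity fit leaves RMSD ~ sigma * sqrt(3) for isotropic
        # per-axis noise
        big = make_toy_complex(seed=3, mhc_length=400, tcr_length=50)
        sigma = 0.3
        rng = np.random.default_rng(0)
        model = big.copy()
        for chain in model.chains.values():
            for res in chain:
                res.atoms["CA"] = res.atoms["CA"] + rng.normal(0, sigma, 3)
        value = component_rmsd(model, big, Component.TCRPMHC)
        assert value == pytest.approx(sigma * np.sqrt(3), rel=0.10)


class TestTmScore:
    def test_identical_is_one(self, toy_complex):
        assert tm_score(toy_complex.copy(), toy_complex) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_d0_formula_and_floor(self):
        assert tm_d0(250) == pytest.approx(1.24 * (235) ** (1 / 3) - 1.8)
        assert tm_d0(15) == 0.5
        assert tm_d0(3) == 0.5

    def test_matches_independent_superposition_route(self, toy_complex):
        """TM-score recomputed with scipy's rotation fit agrees."""
        rng = np.random.default_rng(2)
        model = toy_complex.copy()
        for chain in model.chains.values():
            for res in chain:
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + rng.normal(0, 1.0, 3)
        ours = tm_score(model, toy_complex)
        xs, ys = map_common_residues(model, toy_complex)
        rot, _ = Rotation.align_vectors(
            ys - ys.mean(axis=0), xs - xs.mean(axis=0)
        )
        moved = (xs - xs.mean(axis=0)) @ rot.as_matrix().T
        d = np.linalg.norm(moved - (ys - ys.mean(axis=0)), axis=1)
        L = len(ys)
        expected = float(np.sum(1 / (1 + (d / tm_d0(L)) ** 2)) / L)
        assert ours == pytest.approx(expected, abs=1e-6)

    def test_vanishes_for_distant_structures(self, toy_complex):
        far = toy_complex.copy()
        rng = np.random.default_rng(9)
        for chain in far.chains.values():
            for res in chain:
                for name in res.atoms:
                    res.atoms[name] = rng.uniform(-500, 500, 3)
        assert tm_score(far, toy_complex) < 0.2


class TestInterface:
    def test_contacts_present_by_construction(self, toy_complex):
        assert len(interface_contacts(toy_complex)) >= 10

    def test_distant_tcr_has_no_contacts(self, toy_complex):
        far = toy_complex.copy()
        for role in (Role.TCRA, Role.TCRB):
            for res in far.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([0, 0, 100.0])
        assert interface_contacts(far) == set()

    def test_boundary_distance_counts_as_contact(self, toy_complex):
        """Two residues whose closest heavy atoms sit at exactly the
        cutoff are a contact (inclusive boundary)."""
        probe = toy_complex.copy()
        pep_res = probe.chain(Role.PEPTIDE).residues[0]
        tcr_res = probe.chain(Role.TCRA).residues[0]
        # isolate: move everything far away except these two residues
        for role in (Role.TCRA, Role.TCRB):
            for res in probe.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([0, 0, 500.0])
        tcr_res.atoms.clear()
        tcr_res.atoms["CA"] = pep_res.atoms["CA"] + np.array([0.0, 0.0, 5.0])
        contacts = interface_contacts(probe)
        assert ((Role.PEPTIDE, 0), (Role.TCRA, 0)) in contacts

    def test_fnat_identical_and_removed(self, toy_complex):
        assert fnat(toy_complex.copy(), toy_complex) == 1.0
        far = toy_complex.copy()
        for role in (Role.TCRA, Role.TCRB):
            for res in far.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([0, 0, 100.0])
        assert fnat(far, toy_complex) == 0.0

    def test_fnat_single_chain_removal_fraction(self, toy_complex):
        """Moving only TCRB away preserves exactly the TCRA share of the
        native contacts."""
        native_contacts = interface_contacts(toy_complex)
        share_a = sum(
            1 for _, (role, _) in native_contacts if role is Role.TCRA
        ) / len(native_contacts)
        decoy = toy_complex.copy()
        for res in decoy.chain(Role.TCRB):
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([0, 0, 100.0])
        assert fnat(decoy, toy_complex) == pytest.approx(share_a, abs=1e-12)

    def test_undefined_interface_raises(self, toy_complex):
        far = toy_complex.copy()
        for role in (Role.TCRA, Role.TCRB):
            for res in far.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + np.array([0, 0, 300.0])
        with pytest.raises(UndefinedInterfaceError):
            fnat(toy_complex.copy(), far)
        with pytest.raises(UndefinedInterfaceError):
            irms(toy_complex.copy(), far)


class TestLrmsIrms:
    def test_zero_for_identical(self, toy_complex):
        assert lrms(toy_complex.copy(), toy_complex) == pytest.approx(0, abs=1e-9)
        assert irms(toy_complex.copy(), toy_complex) == pytest.approx(0, abs=1e-9)

    def test_lrms_equals_rigid_translation(self, toy_complex):
        for t in (1.0, 3.5, 12.0):
            decoy = make_decoy_ladder(toy_complex, [t])[0]
            assert lrms(decoy, toy_complex) == pytest.approx(t, abs=1e-6)

    def test_irms_invariant_under_global_motion(self, toy_complex):
        rng = np.random.default_rng(4)
        R, t = _random_rigid(rng)
        moved = toy_complex.copy()
        moved.transform(R, t)
        assert irms(moved, toy_complex) == pytest.approx(0.0, abs=1e-9)

    def test_receptor_noise_keeps_lrms_small_but_positive(self, toy_complex):
        model = toy_complex.copy()
        rng = np.random.default_rng(8)
        for role in (Role.MHC, Role.PEPTIDE):
            for res in model.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + rng.normal(0, 0.4, 3)
        value = lrms(model, toy_complex)
        assert 0.0 < value < 2.0


class TestDockQ:
    def test_perfect_inputs_give_one_high(self):
        score, quality = dockq(1.0, 0.0, 0.0)
        assert score == pytest.approx(1.0)
        assert quality is DockQClass.HIGH

    def test_half_terms_give_half_medium(self):
        # each of the three terms is exactly 1/2 at these inputs
        score, quality = dockq(0.5, 8.5, 1.5)
        assert score == pytest.approx(0.5)
        assert quality is DockQClass.MEDIUM

    def test_limit_to_zero_incorrect(self):
        score, quality = dockq(0.0, 1e6, 1e6)
        assert score < 1e-6
        assert quality is DockQClass.INCORRECT

    def test_negative_rmsd_rejected(self):
        with pytest.raises(InputError):
            dockq(0.5, -1.0, 0.0)

    def test_classes_partition_unit_interval(self):
        from tcrpmhc.metrics import dockq_class

        bands = {
            DockQClass.INCORRECT: (0.0, 0.23),
            DockQClass.ACCEPTABLE: (0.23, 0.49),
            DockQClass.MEDIUM: (0.49, 0.80),
            DockQClass.HIGH: (0.80, 1.0 + 1e-9),
        }
        for value in np.linspace(0, 1, 2001):
            expected = [
                c for c, (lo, hi) in bands.items() if lo <= value < hi
            ]
            assert len(expected) == 1
            assert dockq_class(float(value)) is expected[0]

    def test_class_boundaries_lower_inclusive(self):
        from tcrpmhc.metrics import dockq_class

        assert dockq_class(0.23) is DockQClass.ACCEPTABLE
        assert dockq_class(0.49) is DockQClass.MEDIUM
        assert dockq_class(0.80) is DockQClass.HIGH


class TestSubsetRmsd:
    def test_subset_matches_component_for_full_peptide(self, toy_complex):
        model = toy_complex.copy()
        rng = np.random.default_rng(3)
        for res in model.chain(Role.PEPTIDE):
            res.atoms["CA"] = res.atoms["CA"] + rng.normal(0, 0.5, 3)
        subset = [
            (Role.PEPTIDE, i)
            for i in range(len(toy_complex.chain(Role.PEPTIDE)))
        ]
        assert subset_rmsd(model, toy_complex, subset) == pytest.approx(
            component_rmsd(model, toy_complex, Component.PEPTIDE), abs=1e-9
        )


class TestRigidInvariance:
    def test_all_metrics_invariant_under_common_transform(self, toy_complex):
        decoy = make_decoy_ladder(toy_complex, [4.0])[0]
        before = dockq_report(decoy, toy_complex)
        rng = np.random.default_rng(11)
        R, t = _random_rigid(rng)
        decoy2, native2 = decoy.copy(), toy_complex.copy()
        decoy2.transform(R, t)
        native2.transform(R, t)
        after = dockq_report(decoy2, native2)
        assert after.fnat == before.fnat
        assert after.lrms == pytest.approx(before.lrms, abs=1e-8)
        assert after.irms == pytest.approx(before.irms, abs=1e-8)
        assert after.dockq == pytest.approx(before.dockq, abs=1e-8)
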