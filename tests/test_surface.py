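"""SASA engine, interface burial, lining classification, hydropathy."""

import math

import numpy as np
import pytest

from bltpgeom import (
    GrooveSpec,
    OverlappingGroupsError,
    Selection,
    classify_lining,
    fit_channel_axis,
    golden_spiral_points,
    groove_profile,
    hydropathy_profile,
    interface_bsa,
    make_groove,
    make_sphere_system,
    shrake_rupley_sasa,
)
from conftest import rejection_sasa, spherical_cap_sasa


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        """One atom: SASA = 4*pi*(r+probe)^2, exact to quadrature."""
        m = make_sphere_system([[0, 0, 0]], [1.7])
        res = shrake_rupley_sasa(m, probe_radius=1.4, n_points=960)
        exact = 4.0 * math.pi * 3.1 ** 2
        assert res.total == pytest.approx(exact, rel=0.005)

    def test_disjoint_spheres_additive(self):
        m = make_sphere_system([[0, 0, 0], [100, 0, 0]], [1.7, 1.7])
        res = shrake_rupley_sasa(m)
        exact = 2.0 * 4.0 * math.pi * 3.1 ** 2
        assert res.total == pytest.approx(exact, rel=0.005)

    def test_two_sphere_cap_closed_form(self):
        """Overlapping equal spheres: exposed area from the spherical-cap
        formula 4*pi*R^2 - 2*pi*R*h with h = R - d/2."""
        m = make_sphere_system([[0, 0, 0], [3.1, 0, 0]], [1.7, 1.7])
        res = shrake_rupley_sasa(m)
        exact = spherical_cap_sasa(1.7, 1.4, 3.1)
        for per_atom in res.per_atom:
            assert per_atom == pytest.approx(exact, rel=0.01)
        assert res.total == pytest.approx(2.0 * exact, rel=0.01)

    def test_quadrature_convergence(self):
        """Doubling the point count moves totals by < 0.5% on a cluster."""
        rng = np.random.default_rng(21)
        centers = rng.uniform(0, 12, size=(30, 3))
        m = make_sphere_system(centers, [1.6] * 30)
        a = shrake_rupley_sasa(m, n_points=960).total
        b = shrake_rupley_sasa(m, n_points=1920).total
        assert abs(a - b) / b < 0.005

    def test_rejection_sampling_oracle(self):
        """Agreement within 1% against a seeded random-direction oracle on a
        dense 40-atom cluster."""
        rng = np.random.default_rng(5)
        centers = rng.uniform(0, 14, size=(40, 3))
        m = make_sphere_system(centers, [1.7] * 40)
        res = shrake_rupley_sasa(m, n_points=960)
        oracle_total, _ = rejection_sasa(centers, [1.7] * 40,
                                         n_samples=10_000, seed=7)
        assert res.total == pytest.approx(oracle_total, rel=0.01)

    def test_bit_reproducible(self):
        m = make_sphere_system([[0, 0, 0], [2.5, 1.0, 0]], [1.7, 1.5])
        a = shrake_rupley_sasa(m).per_atom
        b = shrake_rupley_sasa(m).per_atom
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_rejected(self):
        m = make_sphere_system([[0, 0, 0]], [1.7])
        with pytest.raises(ValueError):
            shrake_rupley_sasa(m, n_points=32)

    def test_golden_spiral_quasi_uniform(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        # centroid of a uniform point set is near the origin
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


class TestInterfaceBSA:
    def test_no_contact_zero_bsa(self):
        m = make_sphere_system([[0, 0, 0], [100, 0, 0]], [1.7, 1.7],
                               ["A", "B"])
        rep = interface_bsa(m, Selection("A"), Selection("B"))
        assert rep.bsa_total == pytest.approx(0.0, abs=0.5)

    def test_two_sphere_cap_bsa(self):
        """Buried area of touching equal spheres: 2 caps of 2*pi*R*h each."""
        m = make_sphere_system([[0, 0, 0], [3.1, 0, 0]], [1.7, 1.7],
                               ["A", "B"])
        rep = interface_bsa(m, Selection("A"), Selection("B"))
        R, h = 3.1, 3.1 - 3.1 / 2.0
        exact = 2.0 * 2.0 * math.pi * R * h
        assert rep.bsa_total == pytest.approx(exact, rel=0.01)
        assert rep.bsa_one_sided == pytest.approx(exact / 2.0, rel=0.01)

    def test_symmetry_in_groups(self):
        rng = np.random.default_rng(9)
        centers = np.vstack([rng.uniform(0, 8, size=(10, 3)),
                             rng.uniform(5, 13, size=(10, 3))])
        labels = ["A"] * 10 + ["B"] * 10
        m = make_sphere_system(centers, [1.7] * 20, labels)
        ab = interface_bsa(m, Selection("A"), Selection("B"))
        ba = interface_bsa(m, Selection("B"), Selection("A"))
        assert abs(ab.bsa_total - ba.bsa_total) < 1e-6

    def test_overlapping_groups_rejected(self):
        m = make_sphere_system([[0, 0, 0], [3, 0, 0]], [1.7, 1.7],
                               ["A", "A"])
        with pytest.raises(OverlappingGroupsError):
            interface_bsa(m, Selection("A"), Selection("A"))

    def test_per_residue_delta_sums_to_bsa(self):
        m = make_sphere_system([[0, 0, 0], [3.1, 0, 0]], [1.7, 1.7],
                               ["A", "B"])
        rep = interface_bsa(m, Selection("A"), Selection("B"))
        assert rep.per_residue["delta_sasa_A2"].sum() == pytest.approx(
            rep.bsa_total, abs=1e-6)


@pytest.fixture(scope="module")
def classified(twolayer):
    _, model, truth = twolayer
    prof = groove_profile(model, thickness=5.0)
    labels = classify_lining(model, prof.slabs, prof.sections)
    return model, truth, prof, labels


class TestLiningClassification:
    def test_two_layer_agreement_with_truth(self, classified):
        """>= 95% of inner-layer atoms labelled lining and of outer-layer
        labelled exterior."""
        _, truth, _, labels = classified
        t = np.array(truth.lining_label)
        inner = t == "interior"
        outer = t == "exterior"
        assert (labels.labels[inner] == "lining").mean() >= 0.95
        assert (labels.labels[outer] == "exterior").mean() >= 0.95

    def test_single_layer_all_lining(self, halfpipe):
        _, model, _ = halfpipe
        prof = groove_profile(model, thickness=5.0)
        labels = classify_lining(model, prof.slabs, prof.sections)
        assert (labels.labels == "lining").all()

    def test_atom_at_centroid_is_lining(self):
        """A zero-length sight line cannot be blocked."""
        from bltpgeom.axis import SliceSlab
        from bltpgeom.lumen import lumen_cross_section
        from bltpgeom import AtomRecord, StructureModel

        theta = np.linspace(-np.pi / 2, np.pi / 2, 80)
        ring = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        sec_probe = lumen_cross_section(
            SliceSlab(0, 0, 5, np.arange(len(ring)), ring,
                      np.full(len(ring), 1.0)), grid_resolution=0.25)
        centroid = np.asarray(sec_probe.centroid)
        pts = np.vstack([ring, centroid])
        atoms = [
            AtomRecord(serial=i + 1, name="CA", element="C",
                       residue_name="LEU", chain_id="A", residue_number=i + 1,
                       position=(float(p[0]), float(p[1]), 2.0),
                       vdw_radius=1.0)
            for i, p in enumerate(pts)
        ]
        model = StructureModel(atoms=atoms, source_id="centroid-case")
        slab = SliceSlab(0, 0, 5, np.arange(len(pts)), pts,
                         np.full(len(pts), 1.0))
        sec = lumen_cross_section(slab, grid_resolution=0.25)
        labels = classify_lining(model, [slab], [sec])
        assert labels.labels[-1] == "lining"

    def test_empty_slab_atoms_unassigned(self):
        from bltpgeom.axis import SliceSlab
        from bltpgeom.lumen import lumen_cross_section
        from bltpgeom import AtomRecord, StructureModel

        atoms = [
            AtomRecord(serial=i + 1, name="CA", element="C",
                       residue_name="LEU", chain_id="A", residue_number=i + 1,
                       position=(float(i), 0.0, 0.0), vdw_radius=1.7)
            for i in range(2)
        ]
        model = StructureModel(atoms=atoms, source_id="tiny")
        slab = SliceSlab(0, 0, 5, np.arange(2),
                         np.array([[0.0, 0.0], [1.0, 0.0]]),
                         np.full(2, 1.7))
        sec = lumen_cross_section(slab)   # < 3 atoms -> empty
        labels = classify_lining(model, [slab], [sec])
        assert (labels.labels == "unassigned").all()


class TestHydropathyProfile:
    def test_leu_asp_groove_means_and_ordering(self, twolayer):
        """Leu lining mean 3.8, Asp exterior mean -3.5, lining > exterior in
        every interior slab — the hydrophobic-channel signature."""
        _, model, _ = twolayer
        prof = groove_profile(model, thickness=5.0)
        labels = classify_lining(model, prof.slabs, prof.sections)
        lining, exterior = hydropathy_profile(model, labels,
                                              len(prof.sections))
        interior = slice(1, -1)
        assert np.allclose(lining[interior], 3.8)
        assert np.allclose(exterior[interior], -3.5)
        assert (lining[interior] > exterior[interior]).all()

    def test_missing_class_is_nan_not_zero(self, halfpipe):
        """Single-layer groove has no exterior class anywhere."""
        _, model, _ = halfpipe
        prof = groove_profile(model, thickness=5.0)
        labels = classify_lining(model, prof.slabs, prof.sections)
        _, exterior = hydropathy_profile(model, labels, len(prof.sections))
        assert np.isnan(exterior).all()
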