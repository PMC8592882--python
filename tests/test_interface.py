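"""Shrake-Rupley SASA against analytic oracles; interface burial and contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nacgeo.interface import (
    SasaParams,
    burial,
    fibonacci_sphere,
    interface_contacts,
    sasa,
)
from nacgeo.structio import Structure
from nacgeo.synthetic import gen_toy_structures, toy_dimer_analytic_buried
from oracles import sphere_area, two_sphere_accessible

PARAMS_R16 = SasaParams(radii_table={"C": 1.6})


def _sphere_pair(separation, radius_key="C"):
    return gen_toy_structures("spheres", radii=(1.6, 1.6), separation=separation)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        struct = gen_toy_structures("spheres", radii=(1.6,))
        area = sasa(struct, PARAMS_R16)[0]
        assert area == pytest.approx(sphere_area(1.6, 1.4), rel=0.01)

    def test_distant_spheres_unoccluded(self):
        struct = _sphere_pair(100.0)
        areas = sasa(struct, PARAMS_R16)
        assert np.allclose(areas, sphere_area(1.6, 1.4), rtol=0.01)

    def test_two_sphere_caps_match_closed_form(self):
        struct = _sphere_pair(2.0)
        areas = sasa(struct, PARAMS_R16)
        want = two_sphere_accessible(1.6, 1.6, 2.0, 1.4)
        assert areas[0] == pytest.approx(want[0], rel=0.01)
        assert areas[1] == pytest.approx(want[1], rel=0.01)

    def test_rotation_invariance_within_sampling_noise(self, rng):
        # a small irregular cluster of atoms
        coords = rng.normal(size=(8, 3)) * 2.0
        struct = Structure.from_arrays(
            coords, name=["C"] * 8, element=["C"] * 8, resname=["LIG"] * 8,
            resid=[1] * 8, chain=["A"] * 8,
        )
        base = sasa(struct).sum()
        for seed in range(3):
            R = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
            rotated = struct.with_coords(coords @ R.T)
            assert sasa(rotated).sum() == pytest.approx(base, rel=0.005)

    def test_more_points_reduce_analytic_deviation(self):
        struct = _sphere_pair(2.0)
        want = two_sphere_accessible(1.6, 1.6, 2.0, 1.4)[0]
        devs = []
        for n in (100, 400, 1600):
            got = sasa(struct, SasaParams(n_points=n, radii_table={"C": 1.6}))[0]
            devs.append(abs(got - want))
        assert devs[2] < devs[0]

    def test_unknown_element_strict_mode(self):
        struct = gen_toy_structures("spheres", radii=(1.6,), elements=("XX",))
        with pytest.raises(KeyError, match="XX"):
            sasa(struct, SasaParams(radii_table={"C": 1.6}, fallback_radius=None))
        # with a fallback the same input is fine
        assert sasa(struct, SasaParams(radii_table={"C": 1.6}))[0] > 0


class TestBurial:
    def test_far_apart_chains_bury_nothing(self):
        dimer = gen_toy_structures("toy_dimer", separation=50.0)
        report = burial(dimer, ("A", "B"))
        assert report.total_buried == pytest.approx(0.0, abs=0.5)
        assert report.n_interface_residues == 0

    def test_toy_contact_matches_cap_arithmetic(self):
        dimer = gen_toy_structures("toy_dimer", separation=2.0)
        report = burial(dimer, ("A", "B"))
        want = toy_dimer_analytic_buried(2.0)
        assert report.total_buried == pytest.approx(want, rel=0.02)
        # the burial splits evenly over the two identical chains
        assert report.per_monomer_buried[0] == pytest.approx(want / 2, rel=0.02)
        assert report.n_interface_residues == 2  # one residue per chain

    def test_swap_symmetry(self):
        dimer = gen_toy_structures("toy_dimer", separation=2.5)
        r1 = burial(dimer, ("A", "B"))
        r2 = burial(dimer, ("B", "A"))
        assert r1.total_buried == pytest.approx(r2.total_buried, abs=1e-9)

    def test_total_equals_per_monomer_sum(self):
        dimer = gen_toy_structures("toy_dimer", separation=2.0)
        report = burial(dimer, ("A", "B"))
        assert report.total_buried == pytest.approx(sum(report.per_monomer_buried), abs=1e-9)

    def test_overlapping_groups_rejected(self):
        dimer = gen_toy_structures("toy_dimer")
        with pytest.raises(ValueError, match="overlap"):
            burial(dimer, (("A", "B"), ("B",)))


def _facing_arg_glu(distance):
    """An Arg guanidinium facing a Glu carboxylate across two chains."""
    coords = np.array([
        [0.0, 0.0, 0.0],      # ARG NH1
        [0.0, 2.3, 0.0],      # ARG NH2
        [distance, 0.0, 0.0],  # GLU OE1
        [distance, 2.3, 0.0],  # GLU OE2
    ])
    return Structure.from_arrays(
        coords, name=["NH1", "NH2", "OE1", "OE2"], element=["N", "N", "O", "O"],
        resname=["ARG", "ARG", "GLU", "GLU"], resid=[10, 10, 55, 55],
        chain=["A", "A", "B", "B"],
    )


class TestContacts:
    def test_no_atoms_in_range(self):
        struct = _facing_arg_glu(30.0)
        hb, sb = interface_contacts(struct, ("A", "B"))
        assert len(hb) == 0 and len(sb) == 0

    def test_constructed_salt_bridge(self):
        struct = _facing_arg_glu(3.0)
        hb, sb = interface_contacts(struct, ("A", "B"))
        assert len(sb) == 1  # deduplicated to one contact per residue pair
        assert sb.iloc[0]["distance"] == pytest.approx(3.0, abs=1e-6)

    def test_salt_bridge_pairs_not_double_counted_as_hbonds(self):
        struct = _facing_arg_glu(3.0)
        hb, sb = interface_contacts(struct, ("A", "B"))
        assert len(hb) == 0

    def test_backbone_hbond_detected(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.9, 0.0, 0.0]])
        struct = Structure.from_arrays(
            coords, name=["N", "O"], element=["N", "O"],
            resname=["GLY", "ALA"], resid=[1, 2], chain=["A", "B"],
        )
        hb, sb = interface_contacts(struct, ("A", "B"))
        assert len(hb) == 1
        assert len(sb) == 0


class TestFibonacciSphere:
    def test_points_on_unit_sphere_and_centered(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2

    def test_deterministic(self):
        assert np.array_equal(fibonacci_sphere(500), fibonacci_sphere(500))


@pytest.mark.parametrize("separation", [2.0, 3.0, 4.0])
def test_burial_against_mdtraj_shrake_rupley(separation):
    """Independent cross-check of the SASA engine against mdtraj on the
    two-sphere system (same radii and probe)."""
    import mdtraj

    struct = _sphere_pair(separation)
    ours = sasa(struct, PARAMS_R16)
    import mdtraj.core.element as mde
    top = mdtraj.Topology()
    ch = top.add_chain()
    res = top.add_residue("SPH", ch)
    for i in range(2):
        top.add_atom(f"C{i}", mde.carbon, res)
    traj = mdtraj.Trajectory(struct.coords[None] / 10.0, top)  # nm
    theirs = mdtraj.shrake_rupley(
        traj, probe_radius=0.14, n_sphere_points=960,
        change_radii={"C": 0.16}, mode="atom",
    )[0] * 100.0  # nm^2 -> A^2
    assert np.allclose(ours, theirs, rtol=0.02)
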