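import numpy as np
import pytest
from numpy.testing import assert_allclose

from helixgauge.complexes import (
    ComplexFrame,
    Pose,
    PoseFilterCriteria,
    contact_surface_area,
    count_clashes,
    filter_poses,
    groove_sites_from_structure,
    major_groove_distance,
    shrake_rupley_sasa,
    sliding_bp,
    sliding_window_average,
    translocation_distance,
)
from helixgauge.dna import generate_bdna, major_groove_sites
from helixgauge.fixtures import pseudo_ca_structure
from helixgauge.geometry import AnchorPath, grid_search_orientation
from helixgauge.structure_io import AnchorSpec, Atom, Structure

from oracles import brute_clash_count, two_sphere_contact_area

SEQ22 = "ACGTACGTACGTACGTACGTAC"


@pytest.fixture(scope="module")
def duplex():
    return generate_bdna(SEQ22)


@pytest.fixture(scope="module")
def sites(duplex):
    return major_groove_sites(duplex)


@pytest.fixture(scope="module")
def dna_structure(duplex):
    return duplex.to_structure()


def coaxial_anchors(sites, radius, pitch=33.8, n=9, x_shift=0.0):
    """Nine anchors on a helix coaxial with the generated duplex."""
    s0 = sites.sites[0]
    phase = np.degrees(np.arctan2(s0[1], s0[0]))
    k = np.arange(float(n))
    ang = np.deg2rad(phase + 36.0 * k)
    pts = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), s0[2] + k * pitch * 36.0 / 360.0]
    )
    pts[:, 0] += x_shift
    return pts


def single_atom(element, xyz, name="X", resnum=1, chain="Q"):
    return Structure(
        [Atom(name=name, element=element, res_name="LIG", res_number=resnum, chain_id=chain, coord=np.asarray(xyz, float))]
    )


class TestGrooveDistance:
    def test_anchors_on_sites_give_zero(self, sites):
        assert major_groove_distance(sites.sites[:9], sites) == 0.0

    def test_single_anchor_at_known_distance(self, sites):
        # displace one site radially outward: its own site stays nearest
        s = sites.sites[4]
        radial = s * np.array([1.0, 1.0, 0.0])
        radial /= np.linalg.norm(radial)
        anchor = s + 5.0 * radial
        assert_allclose(major_groove_distance(anchor[None], sites), 5.0, rtol=1e-9)

    def test_exact_five_angstrom_offset(self):
        sites_arr = np.array([[0.0, 0.0, float(z)] for z in range(0, 100, 10)])
        anchor = np.array([[5.0, 0.0, 0.0]])
        from helixgauge.dna import GrooveSites

        gs = GrooveSites(sites=sites_arr, provenance=tuple((i, i) for i in range(10)), cross_offset=0)
        assert_allclose(major_groove_distance(anchor, gs), 5.0)

    def test_empty_rejected(self, sites):
        with pytest.raises(ValueError):
            major_groove_distance(np.empty((0, 3)), sites)


class TestClashes:
    def test_separated_molecules(self, dna_structure):
        far = pseudo_ca_structure(np.arange(27.0).reshape(9, 3) + 500.0)
        assert count_clashes(ComplexFrame(protein=far, dna=dna_structure)) == 0

    def test_single_close_pair(self):
        a = single_atom("C", [0.0, 0.0, 0.0])
        b = single_atom("P", [1.0, 0.0, 0.0], name="P", chain="D")
        assert count_clashes(ComplexFrame(protein=a, dna=b), dist=2.5) == 1

    def test_hydrogens_ignored(self):
        a = single_atom("H", [0.0, 0.0, 0.0], name="H1")
        b = single_atom("P", [1.0, 0.0, 0.0], name="P", chain="D")
        assert count_clashes(ComplexFrame(protein=a, dna=b), dist=2.5) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.0, 20.0, size=(120, 3))
        b = rng.uniform(0.0, 20.0, size=(80, 3))
        frame = ComplexFrame(protein=pseudo_ca_structure(a), dna=pseudo_ca_structure(b, chain_id="D"))
        for dist in (1.0, 2.5, 4.0):
            assert count_clashes(frame, dist) == brute_clash_count(a, b, dist)


class TestContactArea:
    def test_far_apart_is_zero(self):
        a = single_atom("C", [0.0, 0.0, 0.0])
        b = single_atom("C", [50.0, 0.0, 0.0], chain="D")
        assert contact_surface_area(ComplexFrame(protein=a, dna=b)) == 0.0

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_spheres_match_closed_form(self, d):
        a = single_atom("C", [0.0, 0.0, 0.0])
        b = single_atom("P", [d, 0.0, 0.0], name="P", chain="D")
        got = contact_surface_area(ComplexFrame(protein=a, dna=b), n_points=1920)
        expect = two_sphere_contact_area(1.70, 1.80, d, probe=1.4)
        assert abs(got - expect) / expect < 0.02

    def test_quadrature_convergence(self):
        a = single_atom("C", [0.0, 0.0, 0.0])
        b = single_atom("C", [3.0, 0.0, 0.0], chain="D")
        lo = contact_surface_area(ComplexFrame(protein=a, dna=b), n_points=960)
        hi = contact_surface_area(ComplexFrame(protein=a, dna=b), n_points=1920)
        assert abs(hi - lo) / hi < 0.01

    def test_monotone_nonincreasing_with_separation(self, dna_structure):
        # a line of beads entirely on the +x side, pulled further along +x:
        # every intermolecular distance grows, so burial cannot increase
        base = np.column_stack(
            [np.full(9, 10.5), np.zeros(9), 3.38 * np.arange(9.0)]
        )
        areas = []
        for step in range(10):
            pts = base + np.array([1.5 * step, 0.0, 0.0])
            frame = ComplexFrame(protein=pseudo_ca_structure(pts), dna=dna_structure)
            areas.append(contact_surface_area(frame, n_points=240))
        assert areas[0] > 0.0
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(areas, areas[1:]))

    def test_tight_pose_buries_more_than_loose(self, dna_structure, sites):
        tight = ComplexFrame(
            protein=pseudo_ca_structure(coaxial_anchors(sites, radius=8.5)), dna=dna_structure
        )
        loose = ComplexFrame(
            protein=pseudo_ca_structure(coaxial_anchors(sites, radius=10.0)), dna=dna_structure
        )
        assert contact_surface_area(tight, n_points=240) > contact_surface_area(loose, n_points=240)

    def test_unknown_element_listed(self):
        a = single_atom("XX", [0.0, 0.0, 0.0])
        b = single_atom("C", [2.0, 0.0, 0.0], chain="D")
        with pytest.raises(KeyError, match="XX"):
            contact_surface_area(ComplexFrame(protein=a, dna=b))

    def test_isolated_sphere_area_exact(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert_allclose(area[0], 4.0 * np.pi * 3.1**2, rtol=1e-12)


class TestTranslocation:
    def anchor_spec(self, n=9):
        return AnchorSpec(entries=tuple(("P", i + 1, "CA") for i in range(n)))

    def test_zero_when_coms_coincide(self, dna_structure):
        idx = dna_structure.select(exclude_hydrogens=True)
        from helixgauge.complexes import ELEMENT_MASSES

        masses = np.array(
            [ELEMENT_MASSES[dna_structure.atoms[int(i)].element] for i in idx]
        )
        com = (dna_structure.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
        pts = com[None] + np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0],
                                    [0, 0, 1.0], [0, 0, -1.0], [2.0, 0, 0], [-2.0, 0, 0], [0, 0, 0]])
        frame = ComplexFrame(protein=pseudo_ca_structure(pts), dna=dna_structure)
        assert translocation_distance(frame, self.anchor_spec()) < 1e-9

    def test_rigid_translation_invariance(self, dna_structure, sites):
        pts = coaxial_anchors(sites, radius=12.0)
        f1 = ComplexFrame(protein=pseudo_ca_structure(pts), dna=dna_structure)
        d1 = translocation_distance(f1, self.anchor_spec())
        shift = np.array([11.0, -4.0, 2.0])
        moved_dna = dna_structure.copy()
        moved_dna.coords = moved_dna.coords + shift
        f2 = ComplexFrame(protein=pseudo_ca_structure(pts + shift), dna=moved_dna)
        assert_allclose(translocation_distance(f2, self.anchor_spec()), d1, atol=1e-9)

    def test_planted_axial_drift_slope(self, dna_structure):
        from helixgauge.complexes import ELEMENT_MASSES

        idx = dna_structure.select(exclude_hydrogens=True)
        masses = np.array([ELEMENT_MASSES[dna_structure.atoms[int(i)].element] for i in idx])
        com = (dna_structure.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
        base = com[None] + np.linspace(-4.0, 4.0, 9)[:, None] * np.array([1.0, 0.0, 0.0])
        series = []
        for f in range(1, 6):
            pts = base + np.array([0.0, 0.0, 3.0 * f])
            frame = ComplexFrame(protein=pseudo_ca_structure(pts), dna=dna_structure)
            series.append(translocation_distance(frame, self.anchor_spec()))
        slopes = np.diff(series)
        assert np.all(np.abs(slopes - 3.0) / 3.0 < 0.02)

    def test_unresolved_anchor(self, dna_structure, sites):
        frame = ComplexFrame(
            protein=pseudo_ca_structure(coaxial_anchors(sites, radius=12.0)), dna=dna_structure
        )
        bad = AnchorSpec(entries=tuple(("P", i + 100, "CA") for i in range(4)))
        with pytest.raises(KeyError):
            translocation_distance(frame, bad)


class TestSlidingArithmetic:
    def test_paper_printed_cases(self):
        assert sliding_bp(8.0, 17.0, 3.0) == 3.0
        assert sliding_bp(8.0, 11.0, 3.0) == 1.0

    def test_no_motion(self):
        assert sliding_bp(5.0, 5.0) == 0.0

    def test_signed(self):
        assert sliding_bp(17.0, 8.0, 3.0) == -3.0

    def test_bad_rise(self):
        with pytest.raises(ValueError):
            sliding_bp(0.0, 1.0, 0.0)


class TestSlidingWindow:
    def test_window_one_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert_allclose(sliding_window_average(x, 1), x)

    def test_constant_series_unchanged(self):
        assert_allclose(sliding_window_average(np.full(10, 2.5), 5), 2.5)

    def test_ramp_interior_equals_middle(self):
        x = np.arange(10.0)
        out = sliding_window_average(x, 3)
        assert_allclose(out[1:-1], x[1:-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_average(np.array([]), 3)


def build_pose(name, anchors, dna_structure, sites, extra_atom=None):
    atoms = pseudo_ca_structure(anchors).atoms
    if extra_atom is not None:
        atoms = atoms + [extra_atom]
    protein = Structure(atoms)
    frame = ComplexFrame(protein=protein, dna=dna_structure)
    helical = grid_search_orientation(anchors).params
    return Pose(name=name, frame=frame, helical=helical, anchors=AnchorPath(points=anchors), sites=sites)


@pytest.fixture(scope="module")
def five_pose_fixture(duplex, sites, dna_structure):
    clean = build_pose("clean", coaxial_anchors(sites, radius=12.0), dna_structure, sites)
    bad_pitch = build_pose("bad_pitch", coaxial_anchors(sites, radius=12.0, pitch=50.0), dna_structure, sites)
    bad_radius = build_pose("bad_radius", coaxial_anchors(sites, radius=17.0), dna_structure, sites)
    bad_groove = build_pose("bad_groove", coaxial_anchors(sites, radius=12.0, x_shift=14.0), dna_structure, sites)
    clash_atom = Atom(
        name="CB", element="C", res_name="GLY", res_number=99, chain_id="P",
        coord=duplex.strand1["P"][5] + np.array([0.5, 0.0, 0.0]),
    )
    bad_clash = build_pose("bad_clash", coaxial_anchors(sites, radius=12.0), dna_structure, sites, extra_atom=clash_atom)
    return [clean, bad_pitch, bad_radius, bad_groove, bad_clash]


class TestPoseFilter:
    def test_high_pitch_rejected_with_reason(self, five_pose_fixture):
        report = filter_poses([five_pose_fixture[1]])
        assert not report.verdicts[0].accepted
        assert report.verdicts[0].failures == ["pitch"]

    def test_clean_synthetic_pose_accepted(self, five_pose_fixture):
        report = filter_poses([five_pose_fixture[0]])
        assert report.verdicts[0].accepted
        assert report.verdicts[0].failures == []

    def test_funnel_exactly_clean_pose_survives(self, five_pose_fixture):
        report = filter_poses(five_pose_fixture)
        accepted = [v.name for v in report.accepted]
        assert accepted == ["clean"]
        reasons = {v.name: v.failures for v in report.verdicts}
        assert reasons["bad_pitch"] == ["pitch"]
        assert reasons["bad_radius"] == ["radius"]
        assert reasons["bad_groove"] == ["groove_distance"]
        assert reasons["bad_clash"] == ["clashes"]

    def test_order_insensitive(self, five_pose_fixture):
        fwd = filter_poses(five_pose_fixture)
        rev = filter_poses(five_pose_fixture[::-1])
        fwd_map = {v.name: (v.accepted, tuple(v.failures)) for v in fwd.verdicts}
        rev_map = {v.name: (v.accepted, tuple(v.failures)) for v in rev.verdicts}
        assert fwd_map == rev_map
        assert [v.name for v in rev.verdicts] == [p.name for p in five_pose_fixture[::-1]]

    def test_measured_values_reported(self, five_pose_fixture):
        report = filter_poses(five_pose_fixture)
        for v in report.verdicts:
            assert set(v.measured) == {"pitch", "radius", "groove_distance", "clashes"}

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            PoseFilterCriteria(radius_min=16.0, radius_max=9.0)

    def test_default_thresholds(self):
        crit = PoseFilterCriteria()
        assert crit.pitch_max == 42.0
        assert (crit.radius_min, crit.radius_max) == (9.0, 16.0)
        assert crit.groove_dist_max == 11.0
        assert crit.clash_max == 0


class TestGrooveSitesFromStructure:
    def test_matches_fiber_sites_on_generated_duplex(self, duplex, sites):
        s = duplex.to_structure()
        got = groove_sites_from_structure(s, chains=("A", "B"), cross_offset=3)
        assert_allclose(got.sites, sites.sites, atol=1e-5)

    def test_missing_chain(self, duplex):
        with pytest.raises(ValueError):
            groove_sites_from_structure(duplex.to_structure(), chains=("A", "Z"))
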