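import numpy as np
import pytest

from trifil import (ConformationCode, RegionMap, ThetaPair, TopologyGroup,
                    build_from_code, group_populations,
                    make_mixture_trajectory, reference_theta_map,
                    rotation_angle, theta_pair, topology_group)
from trifil.build import GridPlacement, MixtureSpec
from trifil.model import StructureFrame, TopologyError
from trifil.states import RotamerState


def toy_frame_with_cb(angle_deg):
    """Two-residue toy geometry: CA-CA along x, CB vectors perpendicular,
    second CB rotated by ``angle_deg`` about the axis."""
    rad = np.radians(angle_deg)
    atoms = {
        ("CB", 1): (0.0, 0.15, 0.0),
        ("CA", 1): (0.0, 0.0, 0.0),
        ("CA", 2): (0.4, 0.0, 0.0),
        ("CB", 2): (0.4, 0.15 * np.cos(rad), 0.15 * np.sin(rad)),
    }
    names, res, coords = [], [], []
    for (name, r), pos in atoms.items():
        names.append(name)
        res.append(r)
        coords.append(pos)
    return StructureFrame(names, res, ["PHE"] * 4, [0] * 4, np.array(coords))


class TestRotationAngle:
    def test_parallel_cb_vectors_give_zero(self):
        frame = toy_frame_with_cb(0.0)
        assert rotation_angle(frame, 0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_cb_vectors_give_180(self):
        frame = toy_frame_with_cb(180.0)
        assert abs(rotation_angle(frame, 0, 1)) == pytest.approx(180.0,
                                                                 abs=1e-9)

    @pytest.mark.parametrize("angle", [-150.0, -60.0, 30.0, 115.0])
    def test_constructed_angle_is_recovered(self, angle):
        frame = toy_frame_with_cb(angle)
        assert rotation_angle(frame, 0, 1) == pytest.approx(angle, abs=1e-9)

    def test_beta_fixture_is_anti_at_both_angles(self, beta_peptide):
        t = theta_pair(beta_peptide, 0)
        assert abs(t.theta1) > 115.0
        assert abs(t.theta2) > 115.0

    def test_rigid_motion_invariance_and_mirror_flip(self, beta_peptide):
        from trifil.geometry import rotation_about_axis
        t0 = theta_pair(beta_peptide, 0)
        R = rotation_about_axis([3, -1, 2], 123.0)
        moved = beta_peptide.transformed(rotation=R,
                                         translation=np.array([1.0, 2.0, 3.0]))
        t1 = theta_pair(moved, 0)
        assert t1.theta1 == pytest.approx(t0.theta1, abs=1e-9)
        assert t1.theta2 == pytest.approx(t0.theta2, abs=1e-9)
        mirrored = beta_peptide.copy()
        mirrored.coords = mirrored.coords * np.array([1.0, 1.0, -1.0])
        t2 = theta_pair(mirrored, 0)
        assert t2.theta1 == pytest.approx(-t0.theta1, abs=1e-9)

    def test_missing_cb_names_residue(self, beta_peptide):
        frame = beta_peptide.copy()
        keep = ~((frame.residue_indices == 2) & (frame.atom_names == "CB"))
        frame = StructureFrame(frame.atom_names[keep],
                               frame.residue_indices[keep],
                               frame.residue_names[keep],
                               frame.peptide_ids[keep], frame.coords[keep])
        with pytest.raises(TopologyError, match="residue 2"):
            rotation_angle(frame, 0, 1)


class TestTopologyGroup:
    @pytest.mark.parametrize("t1,t2,expected", [
        (170.0, -168.0, TopologyGroup.ALL_ANTI),
        (30.0, -150.0, TopologyGroup.N_SYN),
        (-150.0, 30.0, TopologyGroup.C_SYN),
        (20.0, -45.0, TopologyGroup.ALL_SYN),
        (90.0, 150.0, TopologyGroup.OTHER),
        # closed boundary values belong to the excluded band
        (60.0, 170.0, TopologyGroup.OTHER),
        (115.0, 30.0, TopologyGroup.OTHER),
        (-115.0, -170.0, TopologyGroup.OTHER),
    ])
    def test_threshold_arithmetic(self, t1, t2, expected):
        assert topology_group(ThetaPair(t1, t2)) is expected

    def test_strictly_inside_cuts(self):
        assert topology_group(ThetaPair(115.0001, 115.0001)) is \
            TopologyGroup.ALL_ANTI
        assert topology_group(ThetaPair(59.9999, 59.9999)) is \
            TopologyGroup.ALL_SYN


class TestReferenceThetaMap:
    def test_paper_anchored_codes_land_in_their_quadrants(self, regions):
        table = reference_theta_map(regions)
        assert table.loc["b-b-b", "group"] == "all_anti"
        assert table.loc["aR-aR-b", "group"] == "all_syn"

    def test_map_is_deterministic(self, regions):
        a = reference_theta_map(regions)
        b = reference_theta_map(regions)
        assert a.equals(b)

    def test_covers_all_enumerated_codes(self, regions):
        from trifil import enumerate_codes
        table = reference_theta_map(regions)
        assert len(table) == len(enumerate_codes(regions)) == 48

    def test_anchored_groups_stable_under_center_perturbation(self, regions):
        # +-10 degree perturbations of the realization centres must not
        # flip the well-separated, published group assignments
        for dphi, dpsi in ((10, 0), (-10, 0), (0, 10), (0, -10), (7, -7)):
            centers = {s: (c[0] + dphi, c[1] + dpsi)
                       for s, c in regions.centers.items()}
            perturbed = RegionMap(centers=centers,
                                  reduce_terminal=regions.reduce_terminal)
            table = reference_theta_map(perturbed)
            assert table.loc["b-b-b", "group"] == "all_anti"
            assert table.loc["aR-aR-b", "group"] == "all_syn"


class TestGroupPopulations:
    def test_pure_beta_ensemble_is_all_anti(self, regions):
        mix = MixtureSpec(components=[(ConformationCode.parse("b-b-b"), 1.0)],
                          n_frames=4, n_runs=2, seed=13)
        ens = make_mixture_trajectory("FFF", mix, regions=regions,
                                      placement=GridPlacement(n_peptides=6))
        table = group_populations(ens, regions)
        assert table.loc["all_anti", "mean_fraction"] == 1.0

    def test_53_47_all_syn_mixture_recovered(self, regions):
        # emulates a population with a 53% chance of the all-syn topology
        comps = [(ConformationCode.parse("aR-aR-b"), 0.53),
                 (ConformationCode.parse("b-b-b"), 0.47)]
        mix = MixtureSpec(components=comps, n_frames=40, n_runs=3, seed=17)
        ens = make_mixture_trajectory("FII", mix, regions=regions,
                                      placement=GridPlacement(n_peptides=10))
        table = group_populations(ens, regions)
        n = 40 * 3 * 10
        se = np.sqrt(0.53 * 0.47 / n)
        assert abs(table.loc["all_syn", "mean_fraction"] - 0.53) < 3 * se

    def test_fractions_sum_to_one(self, regions):
        comps = [(ConformationCode.parse("aR-aR-b"), 0.5),
                 (ConformationCode.parse("b-p-aL"), 0.5)]
        mix = MixtureSpec(components=comps, n_frames=5, n_runs=2, seed=23)
        ens = make_mixture_trajectory("IFI", mix, regions=regions,
                                      placement=GridPlacement(n_peptides=5))
        table = group_populations(ens, regions)
        assert table["mean_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_frame_permutation_leaves_fractions_unchanged(self, regions):
        from trifil.model import Ensemble, Trajectory
        comps = [(ConformationCode.parse("aR-aR-b"), 0.5),
                 (ConformationCode.parse("b-b-b"), 0.5)]
        mix = MixtureSpec(components=comps, n_frames=6, n_runs=1, seed=29)
        ens = make_mixture_trajectory("FFF", mix, regions=regions,
                                      placement=GridPlacement(n_peptides=4))
        shuffled = Ensemble(runs=[Trajectory(
            frames=list(reversed(ens.runs[0].frames)), run_id="run0")])
        a = group_populations(ens, regions)
        b = group_populations(shuffled, regions)
        assert np.allclose(a["mean_fraction"], b["mean_fraction"])
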