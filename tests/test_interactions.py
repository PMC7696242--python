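import numpy as np
import pytest

from trifil import (Box, ConformationCode, FilamentSpec, InteractionCriteria,
                    add_solvent_shell, build_filament, build_from_code,
                    core_filter, count_contacts, detect_hbonds,
                    interaction_profile, solvent_exposure)
from trifil.model import Ensemble, StructureFrame, Trajectory
from trifil.interactions import sidechain_indices, water_indices

from oracles import contact_count_oracle, hbond_oracle


def bead_frame(positions, box=None, peptide_ids=None, residue_indices=None):
    n = len(positions)
    pids = peptide_ids if peptide_ids is not None else list(range(n))
    res = residue_indices if residue_indices is not None else [1] * n
    return StructureFrame(["CB"] * n, res, ["PHE"] * n, pids,
                          np.array(positions, float), box=box)


class TestCountContacts:
    def test_cutoff_arithmetic(self):
        crit = InteractionCriteria()
        near = bead_frame([(0, 0, 0), (0.60, 0, 0)])
        far = bead_frame([(0, 0, 0), (0.70, 0, 0)])
        assert count_contacts(near, [0], [1], crit)[0] == 1
        assert count_contacts(far, [0], [1], crit)[0] == 0

    def test_periodic_wrap_counts_as_contact(self):
        frame = bead_frame([(0.0, 0, 0), (5.9, 0, 0)], box=Box(6, 6, 6))
        assert count_contacts(frame, [0], [1])[0] == 1

    def test_intra_residue_pairs_excluded(self):
        frame = bead_frame([(0, 0, 0), (0.2, 0, 0)], peptide_ids=[0, 0],
                           residue_indices=[1, 1])
        assert count_contacts(frame, [0, 1], [0, 1])[0] == 0

    def test_symmetric_in_selections(self, rng):
        coords = rng.uniform(0, 3, (40, 3))
        frame = bead_frame(coords, box=Box(3, 3, 3))
        a, b = np.arange(20), np.arange(20, 40)
        assert count_contacts(frame, a, b)[0] == count_contacts(frame, b, a)[0]

    @pytest.mark.parametrize("with_box", [True, False])
    def test_matches_brute_force_oracle(self, rng, with_box):
        crit = InteractionCriteria()
        for trial in range(12):
            n = 60
            coords = rng.uniform(0, 4, (n, 3))
            box = Box(4, 4, 4) if with_box else None
            pids = rng.integers(0, 6, n)
            res = rng.integers(1, 4, n)
            frame = bead_frame(coords, box=box, peptide_ids=list(pids),
                               residue_indices=list(res))
            sel_a = rng.choice(n, 25, replace=False)
            sel_b = rng.choice(n, 25, replace=False)
            expected = contact_count_oracle(frame, sel_a, sel_b,
                                            crit.contact_cutoff)
            assert count_contacts(frame, sel_a, sel_b, crit)[0] == expected
            # self-contacts
            expected_self = contact_count_oracle(frame, sel_a, sel_a,
                                                 crit.contact_cutoff)
            assert count_contacts(frame, sel_a, sel_a, crit)[0] == expected_self

    def test_lattice_translation_invariance(self, rng):
        box = Box(4, 4, 4)
        coords = rng.uniform(0, 4, (30, 3))
        frame = bead_frame(coords, box=box)
        shifted = bead_frame(coords + np.array([4.0, -8.0, 4.0]), box=box)
        sel = np.arange(30)
        assert count_contacts(frame, sel, sel)[0] == \
            count_contacts(shifted, sel, sel)[0]

    def test_empty_selection_gives_zero(self):
        frame = bead_frame([(0, 0, 0)])
        assert count_contacts(frame, [], [0])[0] == 0


def hb_toy_frame(d_no, angle_deg):
    """Donor N-H on peptide 0, acceptor O on peptide 1 at distance d_no
    from N, with the given N-H-O geometry (H on the N-O axis for 180)."""
    n = np.zeros(3)
    h = np.array([0.1, 0.0, 0.0])
    rad = np.radians(180.0 - angle_deg)
    o_dir = np.array([np.cos(rad), np.sin(rad), 0.0])
    o = h + o_dir * np.linalg.norm(
        _solve_ho(d_no, angle_deg))
    names = ["N", "H", "O"]
    res = [1, 1, 1]
    pids = [0, 0, 1]
    return StructureFrame(names, res, ["PHE"] * 3, pids, np.array([n, h, o]))


def _solve_ho(d_no, angle_deg):
    # law of cosines: |NO|^2 = |NH|^2 + |HO|^2 - 2 |NH||HO| cos(angle at H)
    nh = 0.1
    c = np.cos(np.radians(angle_deg))
    # solve ho^2 - 2 nh c ho + nh^2 - d_no^2 = 0
    disc = (nh * c) ** 2 - (nh ** 2 - d_no ** 2)
    ho = nh * c + np.sqrt(disc)
    return np.array([ho, 0, 0])


class TestDetectHbonds:
    def test_ideal_geometry_detected(self):
        frame = hb_toy_frame(0.30, 175.0)
        assert len(detect_hbonds(frame, reconstruct_h=False)) == 1

    def test_long_distance_rejected(self):
        frame = hb_toy_frame(0.36, 175.0)
        assert detect_hbonds(frame, reconstruct_h=False) == []

    def test_bent_angle_rejected(self):
        frame = hb_toy_frame(0.30, 100.0)
        assert detect_hbonds(frame, reconstruct_h=False) == []

    def test_thresholds_are_strict(self):
        # criteria are strict: < 0.35 nm and > 120 degrees
        # collinear N-H...O puts the donor-acceptor distance exactly at 0.35
        exact = StructureFrame(["N", "H", "O"], [1, 1, 1], ["PHE"] * 3,
                               [0, 0, 1],
                               np.array([[0, 0, 0], [0.1, 0, 0],
                                         [0.35, 0, 0.0]]))
        assert detect_hbonds(exact, reconstruct_h=False) == []
        assert len(detect_hbonds(hb_toy_frame(0.349, 175.0),
                                 reconstruct_h=False)) == 1
        assert detect_hbonds(hb_toy_frame(0.351, 175.0),
                             reconstruct_h=False) == []
        assert len(detect_hbonds(hb_toy_frame(0.30, 121.0),
                                 reconstruct_h=False)) == 1
        assert detect_hbonds(hb_toy_frame(0.30, 119.0),
                             reconstruct_h=False) == []

    def test_intrapeptide_pairs_excluded_by_default(self):
        frame = hb_toy_frame(0.30, 175.0)
        frame.peptide_ids = np.zeros(3, dtype=int)
        assert detect_hbonds(frame, reconstruct_h=False) == []
        assert len(detect_hbonds(frame, include_intra=True,
                                 reconstruct_h=False)) == 1

    def test_filament_hbonds_match_brute_force(self, filament):
        from trifil.model import reconstruct_amide_hydrogens
        crit = InteractionCriteria()
        frame = reconstruct_amide_hydrogens(filament)
        got = {(n, a) for n, _, a in detect_hbonds(frame, crit,
                                                   reconstruct_h=False)}
        expected = hbond_oracle(frame, crit.hb_da_cutoff, crit.hb_angle_min)
        assert got == expected
        assert len(got) >= 5  # one HB ladder per adjacent pair at least


class TestSolventExposure:
    def test_no_water_gives_zero(self, beta_peptide):
        counts = solvent_exposure(beta_peptide)
        assert all(v == 0 for v in counts.values())

    def test_single_bead_in_contact(self, beta_peptide):
        frame = beta_peptide.copy()
        cb = frame.position(0, 1, "CB")
        w_pos = cb + np.array([0.5, 0.0, 0.0])
        frame.atom_names = np.append(frame.atom_names, "W")
        frame.residue_indices = np.append(frame.residue_indices, 0)
        frame.residue_names = np.append(frame.residue_names, "W")
        frame.peptide_ids = np.append(frame.peptide_ids, -1)
        frame.coords = np.vstack([frame.coords, w_pos])
        counts = solvent_exposure(frame)
        assert counts[(0, 1)] >= 1

    def test_buried_residues_see_less_water(self, solvated_bundle):
        """Within each peptide of a solvated fiber, the residue nearest the
        fiber axis must count fewer water contacts than the farthest one,
        on average over the bundle."""
        frame = solvated_bundle
        counts = solvent_exposure(frame)
        axis_xy = frame.coords[frame.peptide_ids >= 0].mean(axis=0)[:2]
        buried, exposed = [], []
        for pid in frame.peptides():
            dist = {}
            for r in (1, 2, 3):
                sc = sidechain_indices(frame)
                sel = sc[(frame.peptide_ids[sc] == pid)
                         & (frame.residue_indices[sc] == r)]
                xy = frame.coords[sel].mean(axis=0)[:2]
                dist[r] = np.linalg.norm(xy - axis_xy)
            r_in = min(dist, key=dist.get)
            r_out = max(dist, key=dist.get)
            buried.append(counts[(int(pid), r_in)])
            exposed.append(counts[(int(pid), r_out)])
        assert np.mean(buried) < np.mean(exposed)


class TestCoreFilter:
    def test_single_filament_fully_retained(self, filament):
        assert core_filter(filament) == sorted(filament.peptides())

    def test_detached_monomer_excluded(self, filament, regions):
        monomer = build_from_code("FFF", ConformationCode.parse("b-b-b"),
                                  regions)
        monomer.coords = monomer.coords - monomer.coords.mean(axis=0) \
            + np.array([3.0, 0.0, 1.0])
        monomer.peptide_ids = np.full(monomer.n_atoms, 6)
        from trifil.model import concatenate_frames
        frame = concatenate_frames([filament, monomer], renumber=False)
        kept = core_filter(frame)
        assert 6 not in kept
        assert kept == sorted(filament.peptides())

    def test_rigid_motion_invariance(self, filament):
        from trifil.geometry import rotation_about_axis
        R = rotation_about_axis([1, 1, 0], 60.0)
        moved = filament.transformed(rotation=R,
                                     translation=np.array([2.0, -3.0, 0.5]))
        assert core_filter(moved) == core_filter(filament)

    def test_no_peptides_is_error(self):
        frame = StructureFrame(["W"], [0], ["W"], [-1], np.zeros((1, 3)))
        with pytest.raises(ValueError, match="no peptides"):
            core_filter(frame)


class TestInteractionProfile:
    def test_stacked_dimer_has_interchain_hbonds(self, beta_peptide):
        dimer = build_filament(beta_peptide, FilamentSpec(n_copies=2, rise=4.8))
        ens = Ensemble(runs=[Trajectory(frames=[dimer])])
        profile = interaction_profile(ens)
        crit = InteractionCriteria()
        from trifil.model import reconstruct_amide_hydrogens
        frame = reconstruct_amide_hydrogens(dimer)
        expected = hbond_oracle(frame, crit.hb_da_cutoff, crit.hb_angle_min)
        # every interchain HB involves both peptides of the dimer
        assert profile.summary.loc["hb", "mean"] == len(expected)
        assert profile.summary.loc["hb", "mean"] >= 1

    def test_water_metrics_rise_with_density(self, bundle):
        box = Box(6, 6, 6)
        frame = bundle.copy()
        frame.coords = frame.coords - frame.coords.mean(axis=0) + box.lengths / 2
        lo = add_solvent_shell(frame, box, density=4.0, seed=2)
        hi = add_solvent_shell(frame, box, density=12.0, seed=2)
        p_lo = interaction_profile(Ensemble(runs=[Trajectory(frames=[lo])]))
        p_hi = interaction_profile(Ensemble(runs=[Trajectory(frames=[hi])]))
        assert p_hi.summary.loc["phe_sc_water", "mean"] > \
            p_lo.summary.loc["phe_sc_water", "mean"]

    def test_pure_solvent_frame_is_error(self):
        frame = StructureFrame(["W", "W"], [0, 0], ["W", "W"], [-1, -1],
                               np.array([[1.0, 1, 1], [2, 2, 2.0]]),
                               box=Box(6, 6, 6))
        ens = Ensemble(runs=[Trajectory(frames=[frame])])
        with pytest.raises((ValueError, RuntimeError), match="peptide"):
            interaction_profile(ens)

    def test_sidechain_selection_excludes_backbone_and_caps(self, beta_peptide):
        sc = sidechain_indices(beta_peptide)
        assert set(beta_peptide.atom_names[sc]) == {"CB"}
        assert len(sc) == 3
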