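import numpy as np
import pytest

from trifil import (Box, BuildSpec, ConformationCode, FilamentSpec,
                    MixtureSpec, add_solvent_shell, backbone_dihedrals,
                    build_bundle, build_filament, build_from_code,
                    build_tripeptide, bundle_arrangement, classify_peptide,
                    fit_bundle_radius, four_filament_arrangement,
                    make_mixture_trajectory)
from trifil.build import BuildError, GridPlacement
from trifil.morphology import aggregate_components
from trifil.states import RotamerState


class TestBuildTripeptide:
    @pytest.mark.parametrize("targets", [
        ((-120.0, 130.0),) * 3,
        ((-80.0, -50.0), (-80.0, -50.0), (-120.0, 130.0)),
        ((57.3, -171.2), (-143.9, 23.0), (101.5, 88.8)),
    ])
    def test_dihedral_round_trip(self, targets):
        frame = build_tripeptide(BuildSpec("FIF", targets))
        d = backbone_dihedrals(frame, 0)
        flat = [x for pair in targets for x in pair]
        assert np.allclose(d, flat, atol=1e-4)

    def test_random_targets_round_trip(self, rng):
        for _ in range(20):
            targets = tuple((float(rng.uniform(-179.9, 180.0)),
                             float(rng.uniform(-179.9, 180.0)))
                            for _ in range(3))
            frame = build_tripeptide(BuildSpec("III", targets))
            d = backbone_dihedrals(frame, 0)
            flat = [x for pair in targets for x in pair]
            assert np.allclose(d, flat, atol=1e-4)

    def test_seeded_noise_is_reproducible(self):
        spec = BuildSpec("FFF", ((-120.0, 130.0),) * 3,
                         noise_sigma=0.01, seed=42)
        a = build_tripeptide(spec)
        b = build_tripeptide(spec)
        assert np.array_equal(a.coords, b.coords)
        c = build_tripeptide(BuildSpec("FFF", ((-120.0, 130.0),) * 3,
                                       noise_sigma=0.01, seed=43))
        assert not np.array_equal(a.coords, c.coords)

    def test_helical_targets_classify_as_helical(self, regions):
        center = regions.centers[RotamerState.ALPHA_R]
        frame = build_tripeptide(BuildSpec("FFF", (center,) * 3))
        code = classify_peptide(frame, 0, regions)
        assert str(code) == "aR-aR-aR"

    def test_invalid_sequence_rejected(self):
        with pytest.raises(BuildError):
            BuildSpec("FAX", ((-120.0, 130.0),) * 3)

    def test_generated_frames_pass_topology_validation(self, regions):
        frame = build_from_code("FIF", ConformationCode.parse("b-p-aL"),
                                regions)
        frame.validate()


class TestBuildFilament:
    def test_rise_is_exact_by_construction(self, filament):
        from trifil.morphology import detect_filaments, interchain_rise
        graph = aggregate_components(filament)
        fils = detect_filaments(graph, filament)
        assert len(fils) == 1
        mean, sd = interchain_rise(fils[0], filament)
        assert mean == pytest.approx(4.8, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_copies_make_one_adjacent_pair(self, beta_peptide):
        dimer = build_filament(beta_peptide, FilamentSpec(n_copies=2, rise=4.8))
        assert dimer.n_peptides == 2
        assert sorted(dimer.peptides()) == [0, 1]

    def test_default_rise_drawn_in_cross_beta_range(self, beta_peptide):
        for seed in range(5):
            spec = FilamentSpec(n_copies=2, rise=None, seed=seed)
            assert 4.6 <= spec.resolve_rise() <= 4.9

    def test_steric_collapse_warns(self, beta_peptide):
        with pytest.warns(UserWarning, match="steric"):
            build_filament(beta_peptide,
                           FilamentSpec(n_copies=2, rise=0.1, orient=False))


class TestBuildBundle:
    def test_three_filaments_form_single_aggregate(self, bundle):
        graph = aggregate_components(bundle)
        assert [len(c) for c in graph.components] == [18]

    def test_single_filament_is_identity(self, filament):
        out = build_bundle([filament], [(0.0, 0.0, 0.0)])
        assert np.allclose(out.coords, filament.coords)

    def test_four_filament_fiber_builds_without_collision(self, filament,
                                                          recwarn):
        arr = four_filament_arrangement(filament, gap=0.3)
        fiber = build_bundle([filament.copy() for _ in range(4)], arr)
        assert not [w for w in recwarn if "steric" in str(w.message)]
        graph = aggregate_components(fiber)
        assert [len(c) for c in graph.components] == [24]


class TestSolventShell:
    def test_zero_density_leaves_frame_unchanged(self, bundle):
        box = Box(6, 6, 6)
        out = add_solvent_shell(bundle, box, density=0.0, seed=1)
        assert out.n_atoms == bundle.n_atoms

    def test_no_bead_violates_exclusion_radius(self, solvated_bundle):
        from trifil.geometry import min_image_distance
        w = solvated_bundle.indices(residue_name="W")
        solute = np.flatnonzero(solvated_bundle.peptide_ids >= 0)
        box = solvated_bundle.box
        w_coords = solvated_bundle.coords[w]
        s_coords = solvated_bundle.coords[solute]
        d = w_coords[:, None, :] - s_coords[None, :, :]
        d -= box.lengths * np.round(d / box.lengths)
        assert np.sqrt((d ** 2).sum(-1)).min() >= 0.45

    def test_bead_count_poisson_in_free_volume(self, bundle, rng):
        box = Box(6, 6, 6)
        frame = bundle.copy()
        frame.coords = frame.coords - frame.coords.mean(axis=0) + box.lengths / 2
        density, excl = 8.35, 0.45
        out = add_solvent_shell(frame, box, density=density,
                                exclusion_radius=excl, seed=3)
        n_beads = int((out.residue_names == "W").sum())
        # Monte-Carlo estimate of the free volume outside the exclusion zone
        probes = rng.uniform(0, 6, (20000, 3))
        from scipy.spatial import cKDTree
        tree = cKDTree(np.mod(frame.coords, box.lengths), boxsize=box.lengths)
        dist, _ = tree.query(probes, k=1)
        free_volume = box.volume * float(np.mean(dist >= excl))
        lam = density * free_volume
        assert abs(n_beads - lam) <= 3.5 * np.sqrt(lam)


class TestMixtureTrajectory:
    def test_pure_mixture_classifies_uniformly(self, regions):
        code = ConformationCode.parse("b-b-b")
        mix = MixtureSpec(components=[(code, 1.0)], n_frames=5, n_runs=1,
                          seed=7)
        ens = make_mixture_trajectory(
            "FFF", mix, regions=regions,
            placement=GridPlacement(n_peptides=8))
        for _, frame in ens.iter_frames():
            for pid in frame.peptides():
                assert str(classify_peptide(frame, pid, regions)) == "b-b-b"

    def test_mixture_recovery_within_binomial_error(self, regions):
        comps = [(ConformationCode.parse("b-b-b"), 0.7),
                 (ConformationCode.parse("aR-aR-b"), 0.3)]
        mix = MixtureSpec(components=comps, n_frames=40, n_runs=2, seed=5)
        ens = make_mixture_trajectory(
            "FFF", mix, regions=regions,
            placement=GridPlacement(n_peptides=10))
        from trifil import population_table
        table = population_table(ens, regions)
        n = 40 * 2 * 10
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(table.summary.loc["b-b-b", "mean_fraction"] - 0.7) < 3 * se

    def test_same_seed_reproduces_bitwise(self, regions):
        comps = [(ConformationCode.parse("b-b-b"), 0.5),
                 (ConformationCode.parse("p-aR-aL"), 0.5)]
        mix = MixtureSpec(components=comps, n_frames=3, n_runs=2, seed=9)
        kwargs = dict(regions=regions, placement=GridPlacement(n_peptides=4))
        e1 = make_mixture_trajectory("FIF", mix, **kwargs)
        e2 = make_mixture_trajectory("FIF", mix, **kwargs)
        for r1, r2 in zip(e1.runs, e2.runs):
            for f1, f2 in zip(r1.frames, r2.frames):
                assert np.array_equal(f1.coords, f2.coords)
        # distinct runs differ
        assert not np.array_equal(e1.runs[0].frames[0].coords,
                                  e1.runs[1].frames[0].coords)

    def test_invalid_weights_rejected(self):
        comps = [(ConformationCode.parse("b-b-b"), 0.7),
                 (ConformationCode.parse("aR-aR-b"), 0.4)]
        with pytest.raises(BuildError, match="sum to 1"):
            MixtureSpec(components=comps)
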