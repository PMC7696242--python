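import numpy as np
import pytest

from trifil import (Box, ConformationCode, FilamentSpec, RegionMap,
                    add_solvent_shell, build_bundle, build_filament,
                    build_from_code, bundle_arrangement, fit_bundle_radius)


@pytest.fixture(scope="session")
def regions():
    return RegionMap.default()


@pytest.fixture(scope="session")
def beta_peptide(regions):
    """Ideal noise-free FFF tripeptide in the extended beta conformation."""
    return build_from_code("FFF", ConformationCode.parse("b-b-b"), regions)


@pytest.fixture(scope="session")
def helical_peptide(regions):
    """Ideal FFF tripeptide in the helical-helical-extended conformation."""
    return build_from_code("FFF", ConformationCode.parse("aR-aR-b"), regions)


@pytest.fixture(scope="session")
def filament(beta_peptide):
    """Six-copy in-register parallel stack at 4.8 angstrom rise."""
    return build_filament(beta_peptide,
                          FilamentSpec(n_copies=6, rise=4.8, twist_per_step=0.0))


@pytest.fixture(scope="session")
def bundle(filament):
    """Three laterally associated filaments forming one fiber."""
    r = fit_bundle_radius(filament, 3, gap=0.3)
    return build_bundle([filament.copy() for _ in range(3)],
                        bundle_arrangement(3, r))


@pytest.fixture(scope="session")
def solvated_bundle(bundle):
    """Bundle centred in a 6 nm periodic box with coarse water around it."""
    frame = bundle.copy()
    box = Box(6.0, 6.0, 6.0)
    frame.coords = frame.coords - frame.coords.mean(axis=0) + box.lengths / 2
    return add_solvent_shell(frame, box, density=8.35,
                             exclusion_radius=0.45, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
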