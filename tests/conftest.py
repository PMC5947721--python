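import numpy as np
import pytest

from anomlik.crystal import (AtomSite, CrystalModel, UnitCell,
                             build_reflection_set, resolution_bins,
                             structure_factors)
from anomlik.simulate import NoiseSpec, generate_ground_truth, simulate_observations


@pytest.fixture(scope="session")
def small_cell():
    return UnitCell(20.0, 22.0, 24.0, 90.0, 95.0, 90.0)


@pytest.fixture(scope="session")
def small_truth(small_cell):
    """60 protein atoms + 3 Se in a triclinic P1 cell."""
    return generate_ground_truth(60, 3, small_cell, "Se", seed=1)


@pytest.fixture(scope="session")
def small_refl(small_cell):
    return build_reflection_set(small_cell, 3.0)


@pytest.fixture(scope="session")
def small_bins(small_refl):
    return resolution_bins(small_refl, 6)


@pytest.fixture(scope="session")
def small_data(small_truth, small_refl):
    return simulate_observations(small_truth, small_refl, NoiseSpec(0.04, seed=4))


@pytest.fixture(scope="session")
def small_truth_sf(small_truth, small_refl):
    return structure_factors(small_truth, small_refl)


@pytest.fixture(scope="session")
def small_truth_no_anom(small_cell, small_truth):
    """The same crystal with every anomalous correction stripped (f'' = 0)."""
    atoms = [AtomSite(a.element, a.frac_xyz, a.occupancy, a.b_iso)
             for a in small_truth.atoms]
    return CrystalModel(small_cell, atoms)
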