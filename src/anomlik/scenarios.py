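"""Standard synthetic test scenarios.

The *standard battery* is the package's stand-in for a real low-resolution
MR-SAD data set: a 27 x 30 x 33 A (beta = 100 deg) P1 micro-crystal with a
200-atom protein-like chain and four selenium scatterers, measured to
3.5 A with Gaussian noise at 4% of the bin-mean amplitude (anomalous
signal-to-noise |dF|/sigma(dF) ~ 1.4-2.3), and a starting model degraded
the way molecular-replacement models are: 40% of protein atoms omitted,
the rest jittered to 1.5 A r.m.s., and two of the four Se missing.

These numbers are fixed study conditions, not tuning knobs; every
consumer (tests, acceptance script, documentation examples) builds the
same scenario through this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import CrystalModel, ReflectionSet, UnitCell, build_reflection_set
from .pipeline import PipelineConfig
from .simulate import (NoiseSpec, ObservedData, PerturbationSpec,
                       generate_ground_truth, perturb_model,
                       simulate_observations, solvent_fraction_of_model)
from .substructure import SubstructureState

__all__ = ["BatteryScenario", "standard_battery", "luzzati_recovery_setup",
           "BATTERY_CELL", "BATTERY_D_MIN"]

BATTERY_CELL = (27.0, 30.0, 33.0, 90.0, 100.0, 90.0)
BATTERY_D_MIN = 3.5
BATTERY_N_PROTEIN = 200
BATTERY_N_SE = 4
BATTERY_NOISE = 0.04
BATTERY_COORD_RMS = 1.5
BATTERY_OMIT_FRACTION = 0.4
BATTERY_OMIT_SE = 2


@dataclass
class BatteryScenario:
    truth: CrystalModel
    refl: ReflectionSet
    data: ObservedData
    start_model: CrystalModel | None
    substructure: SubstructureState
    config: PipelineConfig
    realized_rms: float


def standard_battery(seed: int, wrong_model: bool = False,
                     n_combined_cycles: int = 15) -> BatteryScenario:
    """One seed of the standard battery.

    ``wrong_model=True`` replaces the jittered/omitted starting model by a
    100% wrongly placed one (every protein atom uniformly re-placed), the
    model-bias stress case.
    """
    cell = UnitCell(*BATTERY_CELL)
    truth = generate_ground_truth(BATTERY_N_PROTEIN, BATTERY_N_SE, cell, "Se",
                                  seed=10 * seed + 1)
    refl = build_reflection_set(cell, BATTERY_D_MIN)
    data = simulate_observations(truth, refl, NoiseSpec(BATTERY_NOISE,
                                                        seed=10 * seed + 2))
    if wrong_model:
        spec = PerturbationSpec(0.0, 0.0, 1.0, BATTERY_OMIT_SE, seed=10 * seed + 3)
    else:
        spec = PerturbationSpec(BATTERY_COORD_RMS, BATTERY_OMIT_FRACTION, 0.0,
                                BATTERY_OMIT_SE, seed=10 * seed + 3)
    pert, rms = perturb_model(truth, spec)
    start = CrystalModel(cell, pert.protein_atoms) if pert.protein_atoms else None
    sub0 = SubstructureState([a.copy() for a in pert.anomalous_atoms])
    solvent = float(np.clip(solvent_fraction_of_model(truth), 0.2, 0.8))
    config = PipelineConfig(solvent_fraction=solvent,
                            n_combined_cycles=n_combined_cycles,
                            seed=10 * seed + 4)
    return BatteryScenario(truth, refl, data, start, sub0, config, rms)


def luzzati_recovery_setup(sigma_axis: float, seed: int = 5):
    """Crystal/shell pair for Luzzati-D parameter recovery.

    A uniform random-gas crystal (the regime of the analytic Luzzati
    factor) in a 54 x 56 x 58 A cell, with a per-sigma resolution shell
    chosen so the expected D stays in the statistically identifiable range
    [~0.45, 0.95] (the acentric Rice score degenerates as D -> 0).
    Returns (truth, refl, n_bins).
    """
    shells = {0.3: (2.4, 7.0, 12), 0.7: (3.6, 10.0, 8), 1.2: (6.0, 14.0, 3)}
    if sigma_axis not in shells:
        raise ValueError(f"no shell defined for sigma={sigma_axis}")
    d_lo, d_hi, n_bins = shells[sigma_axis]
    cell = UnitCell(54.0, 56.0, 58.0, 90.0, 100.0, 90.0)
    rng = np.random.default_rng(seed)
    from .crystal import AtomSite
    els = ["C", "N", "O"]
    atoms = [AtomSite(els[i % 3], rng.random(3), 1.0, rng.uniform(15, 35))
             for i in range(350)]
    truth = CrystalModel(cell, atoms)
    full = build_reflection_set(cell, d_lo)
    mask = (full.d_spacing >= d_lo) & (full.d_spacing <= d_hi)
    refl = ReflectionSet(full.miller[mask], full.d_spacing[mask], cell)
    return truth, refl, n_bins
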