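import numpy as np
import pytest
from dataclasses import replace

from thkin.fit import ParameterSet
from thkin.network import RateParams
from thkin.ramp import ExtinctionModel, TemperatureProgram, simulate_program
from thkin.synth import ExperimentDesign, default_truth, generate_dataset


@pytest.fixture(scope="session")
def truth2() -> ParameterSet:
    return default_truth("model2")


@pytest.fixture(scope="session")
def truth1() -> ParameterSet:
    return default_truth("model1")


@pytest.fixture(scope="session")
def ext(truth2) -> ExtinctionModel:
    return truth2.extinction()


@pytest.fixture(scope="session")
def ramp_pair_50uM(truth2, ext):
    """Cooling + heating traces at 5 C/min, 50 uM strand (truth fixture)."""
    model = truth2.to_model()
    cool = simulate_program(
        model, TemperatureProgram.ramp(85, 5, 5.0), 50e-6, ext, "equilibrium"
    )
    heat = simulate_program(
        model, TemperatureProgram.ramp(5, 85, 5.0), 50e-6, ext, cool.species[-1]
    )
    return cool, heat


@pytest.fixture(scope="session")
def noiseless_small_dataset(truth2):
    """4 noiseless traces (50 uM, both rates, both directions) at 0.25 C grid."""
    design = ExperimentDesign(
        concentrations_uM=[50.0], noise_sigma_AU=0.0, seed=11, grid_C=0.25
    )
    traces, manifest = generate_dataset(truth2, design)
    return traces, manifest


def perturb_rates(ps: ParameterSet, factor: float = 2.0) -> ParameterSet:
    """Rate constants scaled by ``factor``; activation energies untouched."""
    steps = {
        n: RateParams(p.k_f_ref * factor, p.Ea_f, p.k_r_ref * factor, p.Ea_r, p.T_ref)
        for n, p in ps.steps.items()
    }
    return replace(ps, steps=steps)
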