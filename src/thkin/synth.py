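"""Synthetic thermal-hysteresis datasets with the study's experimental design.

Two strand concentrations (50 and 250 uM), two scan rates (0.5 and
5 C/min), heating and cooling ramps between 5 and 85 C, additive Gaussian
absorbance noise.  The bundled "truth" parameter sets are fixtures of this
package — documented, versioned stand-ins chosen to reproduce the
qualitative trace phenomenology (biphasic melting, pronounced hysteresis,
a dominant kinetic trap after snap-cooling), not fitted literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fit import ParameterSet
from .network import RateParams
from .ramp import ExtinctionModel, TemperatureProgram, Trace, simulate_program

__all__ = ["ExperimentDesign", "default_truth", "generate_dataset"]

T_REF = 298.15

# Fixture kinetic parameters (NOT literature values; see module docstring).
# Step enthalpy of each step is Ea_f - Ea_r (kcal/mol).
_TRUTH_MODEL2: Dict[str, Tuple[float, float, float, float]] = {
    #                 k_f_ref     Ea_f   k_r_ref    Ea_r
    "dimerization":   (8.0e1,     4.0,   2.0e-3,   44.0),
    "trimerization":  (8.0e1,     4.0,   2.0e-4,   49.0),
    "tetramerization": (3.0e2,    4.0,   2.0e-6,   54.0),
    "trap":           (5.0e-2,   10.0,   5.0e-2,   42.0),
}

_TRUTH_BASELINES = {
    "eps_M_intercept": 5.00e4,   # AU cm^-1 M^-1 (strand)
    "eps_M_slope": 6.0e1,        # per degC
    "eps_T4_intercept": 3.40e4,
    "eps_T4_slope": 4.0e1,
}


def default_truth(model_name: str, dialect: str = "midpoint") -> ParameterSet:
    """Fixture parameter set generating the qualitative trace phenomenology.

    ``model1`` truth is the ``model2`` truth with the trap step zeroed
    (strict nesting).
    """
    if model_name not in ("model1", "model2"):
        raise ValueError(f"unknown model {model_name!r}")
    steps = {
        name: RateParams(*vals, T_REF)
        for name, vals in _TRUTH_MODEL2.items()
        if model_name == "model2" or name != "trap"
    }
    return ParameterSet(model_name, steps, dialect=dialect, T_ref=T_REF,
                        **_TRUTH_BASELINES)


@dataclass
class ExperimentDesign:
    """Trace-set design mirroring the study's TH acquisition conditions."""

    concentrations_uM: Sequence[float] = (50.0, 250.0)
    rates_C_per_min: Sequence[float] = (0.5, 5.0)
    T_span_C: Tuple[float, float] = (5.0, 85.0)
    directions: Sequence[str] = ("cooling", "heating")
    noise_sigma_AU: float = 0.002
    seed: int = 0
    grid_C: float = 0.25
    path_length_cm: float = 0.1
    init_protocols: Dict[str, str] = field(
        default_factory=lambda: {"cooling": "equilibrium", "heating": "anneal_same_rate"}
    )

    def __post_init__(self) -> None:
        if not self.concentrations_uM or not self.rates_C_per_min or not self.directions:
            raise ValueError("design lists must be nonempty")
        if self.noise_sigma_AU < 0:
            raise ValueError("noise sigma must be >= 0")
        for d in self.directions:
            if d not in ("cooling", "heating"):
                raise ValueError(f"unknown direction {d!r}")

    @property
    def n_traces(self) -> int:
        return len(self.concentrations_uM) * len(self.rates_C_per_min) * len(self.directions)


def generate_dataset(
    truth: ParameterSet,
    design: Optional[ExperimentDesign] = None,
    *,
    rtol: float = 1e-8,
) -> Tuple[List[Trace], Dict[str, object]]:
    """Simulate the full trace set of a design and add measurement noise.

    Returns ``(traces, manifest)``; bit-reproducible for a fixed design
    seed, and with ``noise_sigma_AU = 0`` the traces equal the noiseless
    simulator output exactly.
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(design.seed)
    lo, hi = design.T_span_C
    model = truth.to_model()
    ext = truth.extinction(design.path_length_cm)
    ext.validate_range(lo, hi)

    traces: List[Trace] = []
    entries: List[Dict[str, object]] = []
    for conc_uM in design.concentrations_uM:
        c_tot = conc_uM * 1e-6
        for rate in design.rates_C_per_min:
            cool = simulate_program(
                model, TemperatureProgram.ramp(hi, lo, rate), c_tot, ext,
                design.init_protocols.get("cooling", "equilibrium"),
                grid_C=design.grid_C, rtol=rtol,
            )
            per_direction = {"cooling": cool}
            if "heating" in design.directions:
                protocol = design.init_protocols.get("heating", "anneal_same_rate")
                if protocol == "anneal_same_rate":
                    init = cool.species[-1]
                elif protocol == "snap_cool":
                    init = "all_monomer"
                else:
                    init = protocol
                per_direction["heating"] = simulate_program(
                    model, TemperatureProgram.ramp(lo, hi, rate), c_tot, ext,
                    init, grid_C=design.grid_C, rtol=rtol,
                )
            for direction in design.directions:
                tr = per_direction[direction]
                if design.noise_sigma_AU > 0:
                    tr.absorbance_AU = tr.absorbance_AU + rng.normal(
                        0.0, design.noise_sigma_AU, size=len(tr)
                    )
                trace_id = f"c{conc_uM:g}uM_r{rate:g}_{direction}"
                tr.conditions.update(
                    {
                        "trace_id": trace_id,
                        "C_tot_strand": c_tot,
                        "C_tot_strand_uM": conc_uM,
                        "rate_C_per_min": rate,
                        "direction": direction,
                        "path_length_cm": design.path_length_cm,
                        "init_protocol": design.init_protocols.get(
                            direction,
                            "equilibrium" if direction == "cooling" else "anneal_same_rate",
                        ),
                    }
                )
                traces.append(tr)
                entries.append(
                    {
                        "trace_id": trace_id,
                        "file": f"{trace_id}.csv",
                        "C_tot_strand_uM": conc_uM,
                        "rate_C_per_min": rate,
                        "direction": direction,
                        "path_length_cm": design.path_length_cm,
                        "init_protocol": tr.conditions["init_protocol"],
                    }
                )
    manifest = {
        "format": "thkin-dataset-v1",
        "truth_model": truth.model_name,
        "dialect": truth.dialect,
        "noise_sigma_AU": design.noise_sigma_AU,
        "seed": design.seed,
        "T_span_C": list(design.T_span_C),
        "traces": entries,
    }
    return traces, manifest
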