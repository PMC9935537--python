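"""Mass-action reaction networks for stepwise i-motif tetramer assembly.

Two mechanisms are supported:

* ``model1`` — sequential association of monomers: ``M+M <=> D``,
  ``D+M <=> Tri``, ``Tri+M <=> T``.
* ``model2`` — the same chain plus a unimolecular off-pathway
  isomerisation of the on-pathway dimer, ``D <=> Dstar``.

Concentrations are complex molarity (mol/L of each oligomeric species);
the conserved quantity is strand molarity, ``[M] + 2[D] + 2[Dstar] +
3[Tri] + 4[T]``.  Rate constants follow an Arrhenius law referenced to
``T_ref`` so that the step enthalpy is ``Ea_f - Ea_r``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "R_KCAL",
    "SPECIES_MODEL1",
    "SPECIES_MODEL2",
    "STRANDS",
    "SpeciesState",
    "RateParams",
    "ReactionStep",
    "AssemblyModel",
    "arrhenius_rate",
    "build_model",
    "rate_of_change",
    "strand_total",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3

SPECIES_MODEL1: Tuple[str, ...] = ("M", "D", "Tri", "T")
SPECIES_MODEL2: Tuple[str, ...] = ("M", "D", "Dstar", "Tri", "T")

#: strands contributed by one complex of each species
STRANDS: Dict[str, int] = {"M": 1, "D": 2, "Dstar": 2, "Tri": 3, "T": 4}

MODEL1 = "model1"
MODEL2 = "model2"

STEP_DIMER = "dimerization"
STEP_TRIMER = "trimerization"
STEP_TETRAMER = "tetramerization"
STEP_TRAP = "trap"

MODEL1_STEPS = (STEP_DIMER, STEP_TRIMER, STEP_TETRAMER)
MODEL2_STEPS = (STEP_DIMER, STEP_TRIMER, STEP_TETRAMER, STEP_TRAP)

_STEP_SCHEMES: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    STEP_DIMER: (("M", "M"), ("D",)),
    STEP_TRIMER: (("D", "M"), ("Tri",)),
    STEP_TETRAMER: (("Tri", "M"), ("T",)),
    STEP_TRAP: (("D",), ("Dstar",)),
}


@dataclass(frozen=True)
class RateParams:
    """Arrhenius parameters of one reversible elementary step.

    ``k_f_ref``/``k_r_ref`` are the rate constants at ``T_ref`` (M^-1 s^-1
    for bimolecular, s^-1 for unimolecular directions); activation
    energies are in kcal/mol.
    """

    k_f_ref: float
    Ea_f: float
    k_r_ref: float
    Ea_r: float
    T_ref: float = 298.15

    def __post_init__(self) -> None:
        if self.k_f_ref < 0 or self.k_r_ref < 0:
            raise ValueError("rate constants must be nonnegative")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive (kelvin)")

    @property
    def delta_H(self) -> float:
        """Step enthalpy (kcal/mol), Ea_f - Ea_r."""
        return self.Ea_f - self.Ea_r

    def equilibrium_constant(self, T: float) -> float:
        """K(T) = k_f(T)/k_r(T); requires k_r_ref > 0."""
        if self.k_r_ref <= 0:
            raise ValueError("equilibrium constant undefined for k_r_ref == 0")
        return arrhenius_rate(self, "forward", T) / arrhenius_rate(self, "reverse", T)


def arrhenius_rate(params: RateParams, direction: str, T: float) -> float:
    """Rate constant at temperature ``T`` (kelvin).

    ``k(T) = k_ref * exp(-(Ea/R) * (1/T - 1/T_ref))``.
    """
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    if direction == "forward":
        k_ref, ea = params.k_f_ref, params.Ea_f
    elif direction == "reverse":
        k_ref, ea = params.k_r_ref, params.Ea_r
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return k_ref * math.exp(-(ea / R_KCAL) * (1.0 / T - 1.0 / params.T_ref))


@dataclass
class SpeciesState:
    """Concentrations of each oligomeric species (complex molarity)."""

    conc: Dict[str, float]

    def __post_init__(self) -> None:
        for label, value in self.conc.items():
            if label not in STRANDS:
                raise ValueError(f"unknown species {label!r}")
            if value < 0:
                raise ValueError(f"negative concentration for {label}: {value}")

    def get(self, label: str) -> float:
        return self.conc.get(label, 0.0)

    def to_vector(self, species: Sequence[str]) -> np.ndarray:
        return np.array([self.conc.get(s, 0.0) for s in species], dtype=float)

    @classmethod
    def from_vector(cls, vec: Iterable[float], species: Sequence[str]) -> "SpeciesState":
        return cls(dict(zip(species, (float(v) for v in vec))))

    @classmethod
    def all_monomer(cls, c_tot_strand: float, species: Sequence[str]) -> "SpeciesState":
        conc = {s: 0.0 for s in species}
        conc["M"] = float(c_tot_strand)
        return cls(conc)


def strand_total(state: "SpeciesState | Mapping[str, float]") -> float:
    """Total strand molarity of a state."""
    conc = state.conc if isinstance(state, SpeciesState) else state
    return float(sum(STRANDS[s] * c for s, c in conc.items()))


@dataclass(frozen=True)
class ReactionStep:
    """One reversible elementary step with mass-action kinetics."""

    name: str
    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    params: RateParams

    def __post_init__(self) -> None:
        n_r = sum(STRANDS[s] for s in self.reactants)
        n_p = sum(STRANDS[s] for s in self.products)
        if n_r != n_p:
            raise ValueError(
                f"step {self.name!r} does not conserve strands ({n_r} vs {n_p})"
            )
        if len(self.reactants) not in (1, 2):
            raise ValueError("only uni- and bimolecular forward steps supported")

    @property
    def molecularity_f(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class AssemblyModel:
    """A named reaction network over the assembly species."""

    name: str
    species: Tuple[str, ...]
    steps: Tuple[ReactionStep, ...]

    def __post_init__(self) -> None:
        for step in self.steps:
            for s in step.reactants + step.products:
                if s not in self.species:
                    raise ValueError(f"step {step.name} uses unknown species {s}")

    def index(self, label: str) -> int:
        return self.species.index(label)

    def step(self, name: str) -> ReactionStep:
        for step in self.steps:
            if step.name == name:
                return step
        raise KeyError(name)

    def with_params(self, params: Mapping[str, RateParams]) -> "AssemblyModel":
        """Return a copy with per-step rate parameters replaced."""
        steps = tuple(
            replace(step, params=params[step.name]) if step.name in params else step
            for step in self.steps
        )
        return AssemblyModel(self.name, self.species, steps)

    # -- stoichiometry arrays used by the ODE right-hand side ------------

    def arrays(self) -> Dict[str, np.ndarray]:
        """Stoichiometric and Arrhenius arrays (cached per instance)."""
        cached = _ARRAY_CACHE.get(id(self))
        if cached is not None and cached[0] is self:
            return cached[1]
        ns, nr = len(self.species), len(self.steps)
        net = np.zeros((ns, nr))
        r_exp = np.zeros((ns, nr))
        p_exp = np.zeros((ns, nr))
        for j, step in enumerate(self.steps):
            for s in step.reactants:
                i = self.index(s)
                net[i, j] -= 1
                r_exp[i, j] += 1
            for s in step.products:
                i = self.index(s)
                net[i, j] += 1
                p_exp[i, j] += 1
        arrays = {
            "net": net,
            "r_exp": r_exp,
            "p_exp": p_exp,
            "k_f_ref": np.array([s.params.k_f_ref for s in self.steps]),
            "Ea_f": np.array([s.params.Ea_f for s in self.steps]),
            "k_r_ref": np.array([s.params.k_r_ref for s in self.steps]),
            "Ea_r": np.array([s.params.Ea_r for s in self.steps]),
            "inv_T_ref": np.array([1.0 / s.params.T_ref for s in self.steps]),
            "strands": np.array([STRANDS[s] for s in self.species], dtype=float),
        }
        _ARRAY_CACHE[id(self)] = (self, arrays)
        return arrays

    # -- serialisation ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "species": list(self.species),
            "units": {
                "concentration": "mol/L (complex)",
                "k_bimolecular": "M^-1 s^-1",
                "k_unimolecular": "s^-1",
                "Ea": "kcal/mol",
                "T_ref": "K",
            },
            "steps": [
                {
                    "name": s.name,
                    "reactants": list(s.reactants),
                    "products": list(s.products),
                    "params": {
                        "k_f_ref": s.params.k_f_ref,
                        "Ea_f": s.params.Ea_f,
                        "k_r_ref": s.params.k_r_ref,
                        "Ea_r": s.params.Ea_r,
                        "T_ref": s.params.T_ref,
                    },
                }
                for s in self.steps
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssemblyModel":
        payload = json.loads(text)
        steps = tuple(
            ReactionStep(
                name=s["name"],
                reactants=tuple(s["reactants"]),
                products=tuple(s["products"]),
                params=RateParams(**s["params"]),
            )
            for s in payload["steps"]
        )
        return cls(payload["name"], tuple(payload["species"]), steps)


# id() keyed cache; the tuple keeps the model alive so ids cannot collide
_ARRAY_CACHE: Dict[int, Tuple[AssemblyModel, Dict[str, np.ndarray]]] = {}

_ZERO = RateParams(0.0, 0.0, 0.0, 0.0)


def build_model(
    name: str, params: Mapping[str, RateParams] | None = None
) -> AssemblyModel:
    """Construct ``model1`` or ``model2`` with optional per-step parameters.

    Without ``params`` every rate constant is zero (an inert network);
    pass a mapping from step name (``dimerization``, ``trimerization``,
    ``tetramerization``, ``trap``) to :class:`RateParams` to activate it.
    """
    if name == MODEL1:
        step_names, species = MODEL1_STEPS, SPECIES_MODEL1
    elif name == MODEL2:
        step_names, species = MODEL2_STEPS, SPECIES_MODEL2
    else:
        raise ValueError(f"unknown model {name!r}; expected 'model1' or 'model2'")
    params = params or {}
    steps = tuple(
        ReactionStep(
            name=sn,
            reactants=_STEP_SCHEMES[sn][0],
            products=_STEP_SCHEMES[sn][1],
            params=params.get(sn, _ZERO),
        )
        for sn in step_names
    )
    return AssemblyModel(name, species, steps)


def rate_of_change(
    model: AssemblyModel, state: "SpeciesState | np.ndarray", T: float
) -> np.ndarray:
    """Per-species time derivatives (M/s) under mass-action kinetics at ``T``.

    This is the generic (matrix) evaluation; the ramp integrator uses a
    specialised closure that is checked against this function in tests.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    y = state.to_vector(model.species) if isinstance(state, SpeciesState) else np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative concentrations")
    a = model.arrays()
    x = 1.0 / T - a["inv_T_ref"]
    k_f = a["k_f_ref"] * np.exp(-(a["Ea_f"] / R_KCAL) * x)
    k_r = a["k_r_ref"] * np.exp(-(a["Ea_r"] / R_KCAL) * x)
    with np.errstate(divide="ignore"):
        rate_f = k_f * np.prod(y[:, None] ** a["r_exp"], axis=0)
        rate_r = k_r * np.prod(y[:, None] ** a["p_exp"], axis=0)
    return a["net"] @ (rate_f - rate_r)


def net_step_fluxes(
    model: AssemblyModel, state: "SpeciesState | np.ndarray", T: float
) -> np.ndarray:
    """Net (forward - reverse) flux through each step, in event M/s."""
    y = state.to_vector(model.species) if isinstance(state, SpeciesState) else np.asarray(state, dtype=float)
    a = model.arrays()
    x = 1.0 / T - a["inv_T_ref"]
    k_f = a["k_f_ref"] * np.exp(-(a["Ea_f"] / R_KCAL) * x)
    k_r = a["k_r_ref"] * np.exp(-(a["Ea_r"] / R_KCAL) * x)
    rate_f = k_f * np.prod(y[:, None] ** a["r_exp"], axis=0)
    rate_r = k_r * np.prod(y[:, None] ** a["p_exp"], axis=0)
    return rate_f - rate_r
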