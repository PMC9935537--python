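"""Global nonlinear least-squares fitting of thermal-hysteresis trace sets.

A single kinetic parameter set (per-step Arrhenius parameters plus shared
monomer/tetramer baselines) is fitted simultaneously to every trace in a
dataset; each trace is re-simulated under its own recorded conditions
(concentration, scan rate, direction, initial-state protocol).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .network import MODEL1_STEPS, MODEL2_STEPS, AssemblyModel, RateParams, build_model
from .ramp import (
    CELSIUS_OFFSET,
    ExtinctionModel,
    SimulationError,
    TemperatureProgram,
    Trace,
    simulate_program,
)

logger = logging.getLogger(__name__)

__all__ = ["ParameterSet", "FitBounds", "FitResult", "residuals", "fit_global",
           "promote_to_model2", "dataset_rss", "simulate_dataset"]

_BASELINE_FIELDS = ("eps_M_intercept", "eps_M_slope", "eps_T4_intercept", "eps_T4_slope")


def _step_names(model_name: str) -> Tuple[str, ...]:
    if model_name == "model1":
        return MODEL1_STEPS
    if model_name == "model2":
        return MODEL2_STEPS
    raise ValueError(f"unknown model {model_name!r}")


@dataclass
class ParameterSet:
    """Kinetic + baseline parameters shared across a trace set.

    Rate constants are handled in log10 space inside the optimiser;
    activation energies are linear (kcal/mol).  Baselines are the
    per-strand monomer/tetramer extinction intercepts and slopes shared
    by all traces.
    """

    model_name: str
    steps: Dict[str, RateParams]
    eps_M_intercept: float
    eps_M_slope: float
    eps_T4_intercept: float
    eps_T4_slope: float
    dialect: str = "midpoint"
    T_ref: float = 298.15

    def __post_init__(self) -> None:
        missing = set(_step_names(self.model_name)) - set(self.steps)
        if missing:
            raise ValueError(f"missing step parameters: {sorted(missing)}")

    # -- conversions -----------------------------------------------------

    def to_model(self) -> AssemblyModel:
        return build_model(self.model_name, self.steps)

    def extinction(self, path_length_cm: float = 0.1,
                   validate: bool = False) -> ExtinctionModel:
        ext = ExtinctionModel(
            self.eps_M_intercept,
            self.eps_M_slope,
            self.eps_T4_intercept,
            self.eps_T4_slope,
            self.dialect,
            path_length_cm,
        )
        if validate:
            ext.validate_range(0.0, 95.0)
        return ext

    @property
    def n_free(self) -> int:
        return 4 * len(_step_names(self.model_name)) + 4

    def to_vector(self) -> np.ndarray:
        """[log10 kf, Ea_f, log10 kr, Ea_r] per step, then baselines."""
        out: List[float] = []
        for name in _step_names(self.model_name):
            p = self.steps[name]
            out += [np.log10(p.k_f_ref), p.Ea_f, np.log10(p.k_r_ref), p.Ea_r]
        out += [getattr(self, f) for f in _BASELINE_FIELDS]
        return np.array(out, dtype=float)

    @classmethod
    def from_vector(
        cls,
        model_name: str,
        vec: np.ndarray,
        *,
        dialect: str = "midpoint",
        T_ref: float = 298.15,
    ) -> "ParameterSet":
        names = _step_names(model_name)
        if len(vec) != 4 * len(names) + 4:
            raise ValueError("parameter vector has wrong length")
        steps = {}
        for i, name in enumerate(names):
            lkf, eaf, lkr, ear = vec[4 * i : 4 * i + 4]
            steps[name] = RateParams(10.0 ** lkf, eaf, 10.0 ** lkr, ear, T_ref)
        b = vec[4 * len(names) :]
        return cls(model_name, steps, b[0], b[1], b[2], b[3], dialect, T_ref)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> Dict[str, object]:
        return {
            "model_name": self.model_name,
            "T_ref_K": self.T_ref,
            "dialect": self.dialect,
            "steps": {
                name: {
                    "k_f_ref": p.k_f_ref,
                    "Ea_f_kcal_mol": p.Ea_f,
                    "k_r_ref": p.k_r_ref,
                    "Ea_r_kcal_mol": p.Ea_r,
                    "delta_H_kcal_mol": p.delta_H,
                }
                for name, p in self.steps.items()
            },
            "baselines": {f: getattr(self, f) for f in _BASELINE_FIELDS},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "ParameterSet":
        steps = {
            name: RateParams(
                sp["k_f_ref"], sp["Ea_f_kcal_mol"], sp["k_r_ref"],
                sp["Ea_r_kcal_mol"], d.get("T_ref_K", 298.15),
            )
            for name, sp in d["steps"].items()
        }
        b = d["baselines"]
        return cls(
            d["model_name"], steps,
            b["eps_M_intercept"], b["eps_M_slope"],
            b["eps_T4_intercept"], b["eps_T4_slope"],
            d.get("dialect", "midpoint"), d.get("T_ref_K", 298.15),
        )


@dataclass
class FitBounds:
    """Box bounds for the fit vector (log10 rates, linear Ea, baselines)."""

    log10_k_bimolecular: Tuple[float, float] = (-4.0, 9.0)
    log10_k_unimolecular: Tuple[float, float] = (-14.0, 6.0)
    Ea: Tuple[float, float] = (0.0, 100.0)
    eps_intercept: Tuple[float, float] = (1e3, 1e6)
    eps_slope: Tuple[float, float] = (-1e3, 1e3)

    def arrays(self, model_name: str) -> Tuple[np.ndarray, np.ndarray]:
        lo: List[float] = []
        hi: List[float] = []
        for name in _step_names(model_name):
            k_bounds = (
                self.log10_k_unimolecular if name == "trap" else self.log10_k_bimolecular
            )
            lo += [k_bounds[0], self.Ea[0], self.log10_k_unimolecular[0], self.Ea[0]]
            hi += [k_bounds[1], self.Ea[1], self.log10_k_unimolecular[1], self.Ea[1]]
        lo += [self.eps_intercept[0], self.eps_slope[0], self.eps_intercept[0], self.eps_slope[0]]
        hi += [self.eps_intercept[1], self.eps_slope[1], self.eps_intercept[1], self.eps_slope[1]]
        return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# trace re-simulation under recorded conditions
# ---------------------------------------------------------------------------


def _trace_span(trace: Trace) -> Tuple[float, float]:
    return float(trace.temperature_C.min()), float(trace.temperature_C.max())


def simulate_trace(
    params: ParameterSet,
    trace: Trace,
    *,
    rtol: float = 1e-7,
    cooling_cache: Optional[Dict[tuple, np.ndarray]] = None,
) -> np.ndarray:
    """Simulated absorbance at the sample points of a measured trace.

    The trace's ``conditions`` dict must provide ``C_tot_strand``,
    ``rate_C_per_min``, ``direction`` and ``init_protocol`` (one of
    ``equilibrium``, ``anneal_same_rate``, ``all_monomer``, ``snap_cool``).
    """
    cond = trace.conditions
    c_tot = float(cond["C_tot_strand"])
    rate = float(cond["rate_C_per_min"])
    direction = cond["direction"]
    protocol = cond.get("init_protocol", "equilibrium" if direction == "cooling" else "anneal_same_rate")
    path = float(cond.get("path_length_cm", 0.1))
    lo, hi = _trace_span(trace)

    model = params.to_model()
    ext = params.extinction(path)

    if direction == "cooling":
        program = TemperatureProgram.ramp(hi, lo, rate)
        init = "equilibrium" if protocol in ("equilibrium", "anneal_same_rate") else protocol
        sim = simulate_program(model, program, c_tot, ext, init,
                               t_eval=trace.time, rtol=rtol)
        return sim.absorbance_AU
    if direction != "heating":
        raise ValueError(f"unsupported trace direction {direction!r}")

    program = TemperatureProgram.ramp(lo, hi, rate)
    if protocol == "anneal_same_rate":
        key = (c_tot, rate, lo, hi, path)
        y0 = cooling_cache.get(key) if cooling_cache is not None else None
        if y0 is None:
            pre = simulate_program(
                model, TemperatureProgram.ramp(hi, lo, rate), c_tot, ext,
                "equilibrium", grid_C=float(hi - lo), rtol=rtol,
            )
            y0 = pre.species[-1]
            if cooling_cache is not None:
                cooling_cache[key] = y0
        init = y0
    elif protocol == "snap_cool":
        init = "all_monomer"
    else:
        init = protocol
    sim = simulate_program(model, program, c_tot, ext, init,
                           t_eval=trace.time, rtol=rtol)
    return sim.absorbance_AU


def simulate_dataset(
    params: ParameterSet, dataset: Sequence[Trace], *, rtol: float = 1e-7
) -> List[np.ndarray]:
    """Simulated absorbance for every trace (shared cooling cache)."""
    cache: Dict[tuple, np.ndarray] = {}
    return [simulate_trace(params, tr, rtol=rtol, cooling_cache=cache) for tr in dataset]


_PENALTY_AU = 10.0


def dataset_rss(params: ParameterSet, dataset: Sequence[Trace], *,
                rtol: float = 1e-7) -> float:
    """Residual sum of squares over a dataset.

    Per-trace sums are added in sorted order, so the value is exactly
    invariant under permutation of the traces.
    """
    sims = simulate_dataset(params, dataset, rtol=rtol)
    parts = [float(np.dot(tr.absorbance_AU - s, tr.absorbance_AU - s))
             for tr, s in zip(dataset, sims)]
    return float(sum(sorted(parts)))


def residuals(
    params: ParameterSet,
    dataset: Sequence[Trace],
    *,
    rtol: float = 1e-7,
    strict: bool = False,
) -> np.ndarray:
    """Concatenated (observed - simulated) absorbance over all traces.

    In non-strict mode a failed simulation yields large penalty residuals
    (keeps optimisers alive) with a logged warning.
    """
    out: List[np.ndarray] = []
    cache: Dict[tuple, np.ndarray] = {}
    for tr in dataset:
        try:
            sim = simulate_trace(params, tr, rtol=rtol, cooling_cache=cache)
            out.append(tr.absorbance_AU - sim)
        except (SimulationError, ValueError) as exc:
            if strict or not isinstance(exc, SimulationError):
                raise
            logger.warning("simulation failed during residuals: %s", exc)
            out.append(np.full(len(tr), _PENALTY_AU))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: ParameterSet
    rss: float
    n_points: int
    n_params: int
    converged: bool
    residuals_by_trace: List[np.ndarray] = field(repr=False, default_factory=list)
    n_starts: int = 1
    best_start: int = 0

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")
        if self.n_points <= self.n_params:
            raise ValueError("need more residual points than free parameters")

    def to_dict(self) -> Dict[str, object]:
        return {
            "params": self.params.to_dict(),
            "rss_AU2": self.rss,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_start": self.best_start,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _random_start(rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # vector entries are already log10 for rates, linear otherwise;
    # uniform draws in the box are log-uniform for the rate constants
    return rng.uniform(lo, hi)


def promote_to_model2(params: ParameterSet, k_trap: float = 1e-12) -> ParameterSet:
    """Model1 parameter set embedded in model2 with a near-inert trap step.

    Used to warm-start the complex fit from the simple optimum, which
    guarantees rss(model2) <= rss(model1) up to optimizer noise.
    """
    if params.model_name != "model1":
        raise ValueError("expected a model1 parameter set")
    steps = dict(params.steps)
    steps["trap"] = RateParams(k_trap, 10.0, k_trap, 10.0, params.T_ref)
    return replace(params, model_name="model2", steps=steps)


def fit_global(
    dataset: Sequence[Trace],
    init: "ParameterSet | Sequence[ParameterSet]",
    *,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 8,
    seed: int = 0,
    rtol: float = 1e-7,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    max_nfev: Optional[int] = None,
    diff_step: float = 1e-4,
    max_restarts: int = 2,
    verbose: int = 0,
) -> FitResult:
    """Best-of-``n_starts`` trust-region least-squares global fit.

    ``init`` is one parameter set or a sequence of them; the given inits
    are the first starts and further starts (up to ``n_starts``) are
    seeded uniform draws within the bounds (log-uniform for rate
    constants).  Deterministic for a fixed seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    inits = [init] if isinstance(init, ParameterSet) else list(init)
    first = inits[0]
    if any(ps.model_name != first.model_name for ps in inits):
        raise ValueError("all inits must target the same model")
    bounds = bounds or FitBounds()
    lo, hi = bounds.arrays(first.model_name)
    model_name, dialect, T_ref = first.model_name, first.dialect, first.T_ref
    n_points = sum(len(tr) for tr in dataset)
    n_params = first.n_free
    if n_points <= n_params:
        raise ValueError(
            f"dataset has {n_points} points for {n_params} free parameters"
        )

    def objective(vec: np.ndarray) -> np.ndarray:
        ps = ParameterSet.from_vector(model_name, vec, dialect=dialect, T_ref=T_ref)
        return residuals(ps, dataset, rtol=rtol)

    rng = np.random.default_rng(seed)
    x0s = [np.clip(ps.to_vector(), lo, hi) for ps in inits]
    for _ in range(n_starts - len(x0s)):
        x0s.append(_random_start(rng, lo, hi))

    def run_ls(x0, jac):
        return least_squares(
            objective, x0, bounds=(lo, hi), method="trf", jac=jac,
            x_scale="jac", ftol=ftol, xtol=xtol, gtol=1e-14,
            diff_step=diff_step, max_nfev=max_nfev, verbose=verbose,
        )

    def solve_from(x0):
        # cheap forward-difference descent first, then restart polishing
        # (central- and forward-difference) until neither improves: the
        # returned point is then a fixed point of this very procedure, so
        # refitting from it reproduces the rss exactly
        sol = run_ls(x0, "2-point")
        for _ in range(max_restarts):
            improved = False
            for jac in ("3-point", "2-point"):
                again = run_ls(sol.x, jac)
                if again.cost < sol.cost:
                    sol = again
                    improved = True
            if not improved:
                break
        return sol

    best = None
    best_idx = -1
    n_ok = 0
    for idx, x0 in enumerate(x0s):
        try:
            sol = solve_from(x0)
        except Exception as exc:  # noqa: BLE001 - keep multi-start alive
            logger.warning("start %d failed: %s", idx, exc)
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best, best_idx = sol, idx
    if best is None:
        raise RuntimeError("no start converged")

    params = ParameterSet.from_vector(model_name, best.x, dialect=dialect, T_ref=T_ref)
    res = residuals(params, dataset, rtol=rtol)
    per_trace: List[np.ndarray] = []
    pos = 0
    for tr in dataset:
        per_trace.append(res[pos : pos + len(tr)])
        pos += len(tr)
    return FitResult(
        params=params,
        rss=float(sum(sorted(float(np.dot(r, r)) for r in per_trace))),
        n_points=n_points,
        n_params=n_params,
        converged=bool(best.status > 0) and n_ok > 0,
        residuals_by_trace=per_trace,
        n_starts=len(x0s),
        best_start=best_idx,
    )
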