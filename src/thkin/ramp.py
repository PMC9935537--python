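"""Temperature-programmed integration of assembly networks and UV traces.

Integrates the mass-action ODEs of an :class:`~thkin.network.AssemblyModel`
along linear temperature ramps and isothermal holds, converts species
populations to 265 nm absorbance through a linear-baseline extinction
model, and provides the thermodynamic-equilibrium reference curve used to
quantify hysteresis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq
from scipy.signal import find_peaks, savgol_filter

from .network import (
    R_KCAL,
    STRANDS,
    AssemblyModel,
    SpeciesState,
    arrhenius_rate,
    strand_total,
)

logger = logging.getLogger(__name__)

CELSIUS_OFFSET = 273.15

__all__ = [
    "RampSegment",
    "HoldSegment",
    "TemperatureProgram",
    "ExtinctionModel",
    "Trace",
    "SimulationError",
    "simulate_program",
    "equilibrium_state",
    "equilibrium_trace",
    "absorbance",
    "isothermal_course",
    "hysteresis_width",
    "midpoint_temperature",
    "melting_peak_temperatures",
]


class SimulationError(RuntimeError):
    """Integrator failure; carries the last good state and time."""

    def __init__(self, message: str, last_time: float = math.nan, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


# ---------------------------------------------------------------------------
# temperature programs
# ---------------------------------------------------------------------------

_T_MIN_C, _T_MAX_C = -10.0, 110.0


@dataclass(frozen=True)
class RampSegment:
    """Linear ramp from ``start_C`` to ``end_C`` at ``rate_C_per_min`` (> 0)."""

    start_C: float
    end_C: float
    rate_C_per_min: float

    def __post_init__(self) -> None:
        if self.rate_C_per_min <= 0:
            raise ValueError("ramp rate must be positive (direction from start/end)")
        if self.start_C == self.end_C:
            raise ValueError("ramp must change temperature")
        for t in (self.start_C, self.end_C):
            if not _T_MIN_C <= t <= _T_MAX_C:
                raise ValueError(f"temperature {t} degC outside sane bounds")

    @property
    def duration_s(self) -> float:
        return abs(self.end_C - self.start_C) / self.rate_C_per_min * 60.0

    @property
    def slope_C_per_s(self) -> float:
        sign = 1.0 if self.end_C > self.start_C else -1.0
        return sign * self.rate_C_per_min / 60.0


@dataclass(frozen=True)
class HoldSegment:
    """Isothermal hold at ``T_C`` for ``duration_s`` seconds."""

    T_C: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("hold duration must be positive")
        if not _T_MIN_C <= self.T_C <= _T_MAX_C:
            raise ValueError(f"temperature {self.T_C} degC outside sane bounds")


Segment = Union[RampSegment, HoldSegment]


@dataclass(frozen=True)
class TemperatureProgram:
    segments: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("program needs at least one segment")

    @property
    def start_C(self) -> float:
        s = self.segments[0]
        return s.start_C if isinstance(s, RampSegment) else s.T_C

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    @classmethod
    def ramp(cls, start_C: float, end_C: float, rate_C_per_min: float) -> "TemperatureProgram":
        return cls((RampSegment(start_C, end_C, rate_C_per_min),))

    @classmethod
    def hold(cls, T_C: float, duration_s: float) -> "TemperatureProgram":
        return cls((HoldSegment(T_C, duration_s),))


# ---------------------------------------------------------------------------
# extinction model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtinctionModel:
    """Linear-in-T per-strand extinction coefficients at the probe wavelength.

    The monomer and tetramer carry their own baselines; dimer, trap and
    trimer coefficients are derived from them according to ``dialect``:

    * ``midpoint`` — per-strand eps(D) = eps(Dstar) = (eps_M + eps_T4)/2 and
      eps(Tri) = (eps_M + 3 eps_T4)/4 (dimer half-way between monomer and
      tetramer).
    * ``tetramer_fraction`` — per-complex coefficients equal to 1/2 and 3/4
      of the tetramer complex, i.e. per-strand eps(D) = eps(Dstar) =
      eps(Tri) = eps_T4.

    Units: AU cm^-1 M^-1 of strand; slopes are per degC.
    """

    eps_M_intercept: float
    eps_M_slope: float
    eps_T4_intercept: float
    eps_T4_slope: float
    dialect: Optional[str] = "midpoint"
    path_length_cm: float = 0.1

    def __post_init__(self) -> None:
        if self.dialect is None:
            logger.warning(
                "extinction dialect not set explicitly; defaulting to 'midpoint' "
                "('tetramer_fraction' is the alternative reading)"
            )
            object.__setattr__(self, "dialect", "midpoint")
        if self.dialect not in ("midpoint", "tetramer_fraction"):
            raise ValueError(f"unknown extinction dialect {self.dialect!r}")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")

    def eps_monomer(self, T_C):
        return self.eps_M_intercept + self.eps_M_slope * np.asarray(T_C, dtype=float)

    def eps_tetramer(self, T_C):
        return self.eps_T4_intercept + self.eps_T4_slope * np.asarray(T_C, dtype=float)

    def per_strand(self, species: Sequence[str], T_C) -> np.ndarray:
        """Per-strand coefficients, shape ``(n_species,) + shape(T_C)``."""
        em = self.eps_monomer(T_C)
        et = self.eps_tetramer(T_C)
        if self.dialect == "midpoint":
            table = {
                "M": em,
                "D": 0.5 * (em + et),
                "Dstar": 0.5 * (em + et),
                "Tri": 0.25 * (em + 3.0 * et),
                "T": et,
            }
        else:  # tetramer_fraction
            table = {"M": em, "D": et, "Dstar": et, "Tri": et, "T": et}
        return np.stack([np.broadcast_to(table[s], np.shape(et)) if np.ndim(et) else np.asarray(table[s]) for s in species])

    def validate_range(self, T_lo_C: float, T_hi_C: float) -> None:
        """Check positivity and folded-state hypochromicity over a T range."""
        for T in (T_lo_C, T_hi_C):
            em, et = float(self.eps_monomer(T)), float(self.eps_tetramer(T))
            if em <= 0 or et <= 0:
                raise ValueError(f"nonpositive extinction coefficient at {T} degC")
            if et > em:
                raise ValueError(
                    f"tetramer coefficient exceeds monomer at {T} degC "
                    "(folded state must be hypochromic)"
                )


def absorbance(
    state: "SpeciesState | np.ndarray",
    T_C,
    ext: ExtinctionModel,
    species: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Absorbance (AU) of a state: ``l * sum_i strands_i * eps_i(T) * [S_i]``.

    ``state`` may be a :class:`SpeciesState` or a concentration array laid
    out as ``species`` (``(n_species,)`` or ``(n_species, n_points)``).
    """
    if isinstance(state, SpeciesState):
        species = list(state.conc.keys())
        y = state.to_vector(species)
    else:
        if species is None:
            raise ValueError("species order required for array states")
        y = np.asarray(state, dtype=float)
    eps = ext.per_strand(species, T_C)
    strands = np.array([STRANDS[s] for s in species], dtype=float)
    if y.ndim == 1 and eps.ndim == 1:
        return float(ext.path_length_cm * np.sum(strands * eps * y))
    strands = strands.reshape((-1,) + (1,) * (eps.ndim - 1))
    return ext.path_length_cm * np.sum(strands * eps * y, axis=0)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """An absorbance series with its temperature program and conditions."""

    time: np.ndarray
    temperature_C: np.ndarray
    absorbance_AU: np.ndarray
    species: Optional[np.ndarray] = None  # (n_points, n_species), complex M
    species_labels: Optional[Tuple[str, ...]] = None
    conditions: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.absorbance_AU = np.asarray(self.absorbance_AU, dtype=float)
        n = len(self.time)
        if len(self.temperature_C) != n or len(self.absorbance_AU) != n:
            raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=float)
            if self.species.shape[0] != n:
                raise ValueError("species array length mismatch")

    def __len__(self) -> int:
        return len(self.time)

    def strand_fractions(self) -> Dict[str, np.ndarray]:
        """Strand-normalised fraction of each species along the trace."""
        if self.species is None or self.species_labels is None:
            raise ValueError("trace carries no species populations")
        totals = np.zeros(len(self))
        for i, s in enumerate(self.species_labels):
            totals += STRANDS[s] * self.species[:, i]
        return {
            s: STRANDS[s] * self.species[:, i] / totals
            for i, s in enumerate(self.species_labels)
        }


# ---------------------------------------------------------------------------
# fast mass-action right-hand sides
# ---------------------------------------------------------------------------


def _chain_params(model: AssemblyModel):
    by_name = {s.name: s.params for s in model.steps}
    try:
        p1 = by_name["dimerization"]
        p2 = by_name["trimerization"]
        p3 = by_name["tetramerization"]
    except KeyError as exc:  # pragma: no cover - guarded by build_model
        raise ValueError("model lacks the canonical assembly chain") from exc
    return p1, p2, p3, by_name.get("trap")


def _make_rhs(model: AssemblyModel, temp_K_of_t: Callable[[float], float]):
    """Hand-specialised RHS for the assembly chain (fast path).

    Equivalent to :func:`thkin.network.rate_of_change`; the equivalence is
    asserted by the test suite on random states.
    """
    p1, p2, p3, p4 = _chain_params(model)
    exp = math.exp
    kf1, cf1, kr1, cr1, iT1 = p1.k_f_ref, -p1.Ea_f / R_KCAL, p1.k_r_ref, -p1.Ea_r / R_KCAL, 1.0 / p1.T_ref
    kf2, cf2, kr2, cr2, iT2 = p2.k_f_ref, -p2.Ea_f / R_KCAL, p2.k_r_ref, -p2.Ea_r / R_KCAL, 1.0 / p2.T_ref
    kf3, cf3, kr3, cr3, iT3 = p3.k_f_ref, -p3.Ea_f / R_KCAL, p3.k_r_ref, -p3.Ea_r / R_KCAL, 1.0 / p3.T_ref

    if p4 is None:
        def rhs(t, y):
            x1 = 1.0 / temp_K_of_t(t)
            m, d, tri, te = y
            r1 = kf1 * exp(cf1 * (x1 - iT1)) * m * m - kr1 * exp(cr1 * (x1 - iT1)) * d
            r2 = kf2 * exp(cf2 * (x1 - iT2)) * d * m - kr2 * exp(cr2 * (x1 - iT2)) * tri
            r3 = kf3 * exp(cf3 * (x1 - iT3)) * tri * m - kr3 * exp(cr3 * (x1 - iT3)) * te
            return (-2.0 * r1 - r2 - r3, r1 - r2, r2 - r3, r3)
        return rhs

    kf4, cf4, kr4, cr4, iT4 = p4.k_f_ref, -p4.Ea_f / R_KCAL, p4.k_r_ref, -p4.Ea_r / R_KCAL, 1.0 / p4.T_ref

    def rhs2(t, y):
        x1 = 1.0 / temp_K_of_t(t)
        m, d, ds, tri, te = y
        r1 = kf1 * exp(cf1 * (x1 - iT1)) * m * m - kr1 * exp(cr1 * (x1 - iT1)) * d
        r2 = kf2 * exp(cf2 * (x1 - iT2)) * d * m - kr2 * exp(cr2 * (x1 - iT2)) * tri
        r3 = kf3 * exp(cf3 * (x1 - iT3)) * tri * m - kr3 * exp(cr3 * (x1 - iT3)) * te
        r4 = kf4 * exp(cf4 * (x1 - iT4)) * d - kr4 * exp(cr4 * (x1 - iT4)) * ds
        return (-2.0 * r1 - r2 - r3, r1 - r2 - r4, r4, r2 - r3, r3)

    return rhs2


# ---------------------------------------------------------------------------
# equilibrium solver
# ---------------------------------------------------------------------------


def _equilibrium_constants(model: AssemblyModel, T_K: float) -> Dict[str, float]:
    out = {}
    for step in model.steps:
        p = step.params
        if p.k_r_ref == 0.0:
            if p.k_f_ref == 0.0:
                out[step.name] = 0.0
                continue
            raise ValueError(
                f"step {step.name!r} is irreversible; no finite equilibrium"
            )
        out[step.name] = arrhenius_rate(p, "forward", T_K) / arrhenius_rate(p, "reverse", T_K)
    return out


def equilibrium_state(model: AssemblyModel, T_K: float, c_tot_strand: float) -> SpeciesState:
    """Equilibrium populations at fixed ``T_K`` for total strand ``c_tot_strand``.

    Solves the coupled step equilibria under the strand-mass constraint by
    root-finding on the free-monomer concentration (the mass function is
    strictly increasing in ``[M]``, so the physical root is unique).
    """
    if c_tot_strand <= 0:
        raise ValueError("total strand concentration must be positive")
    K = _equilibrium_constants(model, T_K)
    K1, K2, K3 = K["dimerization"], K["trimerization"], K["tetramerization"]
    K4 = K.get("trap", 0.0)

    def mass(m: float) -> float:
        d = K1 * m * m
        return (
            m
            + 2.0 * (1.0 + K4) * d
            + 3.0 * K2 * d * m
            + 4.0 * K3 * K2 * d * m * m
            - c_tot_strand
        )

    if mass(c_tot_strand) <= 0.0:  # all association constants ~ 0
        m = c_tot_strand
    else:
        m = brentq(mass, 0.0, c_tot_strand, xtol=1e-300, rtol=8.9e-16)
    d = K1 * m * m
    conc = {"M": m, "D": d, "Tri": K2 * d * m, "T": K3 * K2 * d * m * m}
    if "Dstar" in model.species:
        conc["Dstar"] = K4 * d
    ordered = {s: conc.get(s, 0.0) for s in model.species}
    return SpeciesState(ordered)


def equilibrium_trace(
    model: AssemblyModel,
    temps_C: np.ndarray,
    c_tot_strand: float,
    ext: ExtinctionModel,
) -> Trace:
    """Equilibrium absorbance curve over a temperature grid (reference)."""
    temps_C = np.asarray(temps_C, dtype=float)
    species = model.species
    y = np.empty((len(temps_C), len(species)))
    for i, tc in enumerate(temps_C):
        y[i] = equilibrium_state(model, tc + CELSIUS_OFFSET, c_tot_strand).to_vector(species)
    A = absorbance(y.T, temps_C, ext, species)
    return Trace(
        time=np.arange(len(temps_C), dtype=float),
        temperature_C=temps_C,
        absorbance_AU=A,
        species=y,
        species_labels=tuple(species),
        conditions={
            "C_tot_strand": c_tot_strand,
            "direction": "equilibrium",
            "path_length_cm": ext.path_length_cm,
        },
    )


# ---------------------------------------------------------------------------
# programmed simulation
# ---------------------------------------------------------------------------


def _resolve_init(
    model: AssemblyModel,
    init,
    c_tot_strand: float,
    start_T_K: float,
) -> np.ndarray:
    if isinstance(init, str):
        if init == "all_monomer":
            state = SpeciesState.all_monomer(c_tot_strand, model.species)
        elif init == "equilibrium":
            state = equilibrium_state(model, start_T_K, c_tot_strand)
        else:
            raise ValueError(f"unknown init protocol {init!r}")
    elif isinstance(init, SpeciesState):
        state = init
    else:
        state = SpeciesState.from_vector(init, model.species)
    total = strand_total(state)
    if abs(total - c_tot_strand) > 1e-6 * c_tot_strand:
        raise ValueError(
            f"initial state strand total {total} inconsistent with C_tot {c_tot_strand}"
        )
    return state.to_vector(model.species)


def _segment_grid(seg: Segment, grid_C: float, grid_s: Optional[float]) -> np.ndarray:
    """Output times (local to the segment) for one program segment."""
    if isinstance(seg, RampSegment):
        span = abs(seg.end_C - seg.start_C)
        n = max(int(round(span / grid_C)), 1)
        temps = np.linspace(0.0, span, n + 1)
        return temps / seg.rate_C_per_min * 60.0
    step = grid_s if grid_s is not None else seg.duration_s / 400.0
    n = max(int(round(seg.duration_s / step)), 1)
    return np.linspace(0.0, seg.duration_s, n + 1)


def simulate_program(
    model: AssemblyModel,
    program: TemperatureProgram,
    c_tot_strand: float,
    ext: ExtinctionModel,
    init="all_monomer",
    *,
    grid_C: float = 0.25,
    grid_s: Optional[float] = None,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: Optional[float] = None,
    conditions: Optional[Dict[str, object]] = None,
) -> Trace:
    """Integrate the network along a temperature program; return a Trace.

    ``init`` is ``"all_monomer"``, ``"equilibrium"`` (at the program start
    temperature), a :class:`SpeciesState`, or a concentration vector in
    model species order.  The output grid is uniform in temperature for
    ramps (``grid_C``) and in time for holds (``grid_s``), unless an
    explicit global ``t_eval`` (seconds from program start) is given.
    Integration uses the LSODA stiff/non-stiff switching solver.
    """
    if atol is None:
        atol = 1e-10 * c_tot_strand
    start_T_K = program.start_C + CELSIUS_OFFSET
    y0 = _resolve_init(model, init, c_tot_strand, start_T_K)

    times: List[np.ndarray] = []
    temps: List[np.ndarray] = []
    states: List[np.ndarray] = []
    t_offset = 0.0
    for seg in program.segments:
        if isinstance(seg, RampSegment):
            T0 = seg.start_C + CELSIUS_OFFSET
            slope = seg.slope_C_per_s
            temp_fun = (lambda T0=T0, slope=slope: (lambda t: T0 + slope * t))()
        else:
            Tc = seg.T_C + CELSIUS_OFFSET
            temp_fun = (lambda Tc=Tc: (lambda t: Tc))()
        if t_eval is not None:
            mask = (t_eval >= t_offset - 1e-9) & (
                t_eval <= t_offset + seg.duration_s + 1e-9
            )
            local = np.clip(np.asarray(t_eval, dtype=float)[mask] - t_offset, 0.0, seg.duration_s)
        else:
            local = _segment_grid(seg, grid_C, grid_s)
        rhs = _make_rhs(model, temp_fun)
        # solve on the union of {0}, the output grid and the segment end so
        # the carried-over state is the true end state
        t_solve = np.unique(np.concatenate(([0.0], local, [seg.duration_s])))
        sol, info = odeint(
            rhs,
            y0,
            t_solve,
            rtol=rtol,
            atol=atol,
            tfirst=True,
            full_output=True,
            mxstep=50000,
        )
        if info["message"] != "Integration successful.":
            n_ok = int(np.searchsorted(t_solve[1:], float(info["tcur"][-1])))
            last_y = sol[max(n_ok, 0)] if sol.size else y0
            raise SimulationError(
                f"integration failed in segment {seg}: {info['message']}",
                last_time=float(info["tcur"][-1]) + t_offset,
                last_state=SpeciesState.from_vector(np.maximum(last_y, 0.0), model.species),
            )
        sol = np.maximum(sol, 0.0)
        if len(local):
            idx = np.searchsorted(t_solve, local)
            times.append(local + t_offset)
            temps.append(np.array([temp_fun(t) - CELSIUS_OFFSET for t in local]))
            states.append(sol[idx].T)
        y0 = sol[-1]
        t_offset += seg.duration_s

    t_all = np.concatenate(times)
    T_all = np.concatenate(temps)
    y_all = np.concatenate(states, axis=1)
    # drop duplicated segment-boundary points
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    t_all, T_all, y_all = t_all[keep], T_all[keep], y_all[:, keep]
    A = absorbance(y_all, T_all, ext, model.species)
    cond = {
        "C_tot_strand": c_tot_strand,
        "path_length_cm": ext.path_length_cm,
        "direction": "program",
    }
    if len(program.segments) == 1 and isinstance(program.segments[0], RampSegment):
        seg0 = program.segments[0]
        cond["direction"] = "heating" if seg0.end_C > seg0.start_C else "cooling"
        cond["rate_C_per_min"] = seg0.rate_C_per_min
    if conditions:
        cond.update(conditions)
    return Trace(
        time=t_all,
        temperature_C=T_all,
        absorbance_AU=np.asarray(A, dtype=float),
        species=y_all.T,
        species_labels=tuple(model.species),
        conditions=cond,
    )


def isothermal_course(
    model: AssemblyModel,
    T_C: float,
    c_tot_strand: float,
    init,
    duration_s: float,
    ext: Optional[ExtinctionModel] = None,
    *,
    n_points: int = 500,
    log_time: bool = False,
    rtol: float = 1e-8,
) -> Trace:
    """Constant-temperature time course with species populations.

    Supports long horizons (days/weeks of simulated time).  ``ext`` is
    optional; without it the absorbance column is filled with zeros and
    only species populations are meaningful.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if log_time:
        grid = np.concatenate(([0.0], np.geomspace(duration_s * 1e-8, duration_s, n_points)))
    else:
        grid = np.linspace(0.0, duration_s, n_points + 1)
    program = TemperatureProgram.hold(T_C, duration_s)
    ext_eff = ext or ExtinctionModel(1.0, 0.0, 0.5, 0.0, "midpoint", 1.0)
    trace = simulate_program(
        model,
        program,
        c_tot_strand,
        ext_eff,
        init,
        t_eval=grid,
        rtol=rtol,
        conditions={"direction": "isothermal", "T_C": T_C},
    )
    if ext is None:
        trace.absorbance_AU = np.zeros(len(trace))
    return trace


# ---------------------------------------------------------------------------
# hysteresis metrics
# ---------------------------------------------------------------------------


def _normalized_vs_T(trace: Trace, smooth: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(trace.temperature_C, kind="stable")
    T = trace.temperature_C[order]
    A = trace.absorbance_AU[order]
    if smooth and len(A) >= 15:
        win = min(11, len(A) // 2 * 2 - 1)
        A = savgol_filter(A, win, 3)
    lo, hi = A.min(), A.max()
    if hi <= lo:
        return T, np.full_like(A, 0.5)
    return T, (A - lo) / (hi - lo)


def midpoint_temperature(trace: Trace) -> float:
    """Temperature at half of the total normalised absorbance change."""
    T, An = _normalized_vs_T(trace)
    below = An < 0.5
    crossings = np.nonzero(below[:-1] & ~below[1:])[0]
    if len(crossings) == 0:
        # fall back to the point closest to 0.5
        return float(T[np.argmin(np.abs(An - 0.5))])
    i = crossings[0]
    f = (0.5 - An[i]) / (An[i + 1] - An[i])
    return float(T[i] + f * (T[i + 1] - T[i]))


def hysteresis_width(heating: Trace, cooling: Trace) -> float:
    """Difference of heating and cooling mid-transition temperatures (degC)."""
    h_lo, h_hi = heating.temperature_C.min(), heating.temperature_C.max()
    c_lo, c_hi = cooling.temperature_C.min(), cooling.temperature_C.max()
    if h_hi <= c_lo or c_hi <= h_lo:
        raise ValueError("traces do not overlap in temperature")
    return midpoint_temperature(heating) - midpoint_temperature(cooling)


def melting_peak_temperatures(
    trace: Trace,
    *,
    smooth_window_C: float = 4.0,
    min_prominence: float = 0.08,
) -> np.ndarray:
    """Temperatures of local maxima of the smoothed dA/dT of a ramp trace.

    Prominence is measured on dA/dT of the normalised (0..1) absorbance,
    so ``min_prominence`` is a fraction of the total transition amplitude
    per unit of the derivative's range.
    """
    T, An = _normalized_vs_T(trace, smooth=False)
    dT = np.median(np.diff(T))
    win = max(int(round(smooth_window_C / max(dT, 1e-9))) | 1, 5)
    win = min(win, len(An) // 2 * 2 - 1)
    As = savgol_filter(An, win, 3)
    dAdT = np.gradient(As, T)
    span = dAdT.max() - dAdT.min()
    peaks, _ = find_peaks(dAdT, prominence=min_prominence * span)
    return T[peaks]
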