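"""Public cell-model API: types, single-step operations, and integrate().

The science lives in :mod:`paceopt.model.formulation` (rates, currents,
parameters) and :mod:`paceopt.model._kernel` (compiled fixed-step
integrator); this module wraps both behind validated domain types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..exceptions import QuiescentModelError, RosterError, StateIntegrityError
from ..trace import GRID_DT, Trace
from . import _kernel, formulation as fm

CURRENT_NAMES = fm.CURRENT_NAMES
CHANNEL_NAMES = fm.CHANNEL_NAMES
GATE_NAMES = fm.GATE_NAMES


# ------------------------------------------------------------------ sf mapping
class ScalingFactors(Mapping):
    """Dimensionless conductance multipliers ``G_x = Gbar_x * sf_x``.

    Channels absent from the mapping are implicitly frozen at sf = 1.
    Immutable; all values must be positive and finite.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float] | None = None, **kw):
        merged = dict(values or {})
        merged.update(kw)
        for name, v in merged.items():
            if name not in CHANNEL_NAMES:
                raise RosterError(
                    f"sf_{name}: not a scalable roster channel "
                    f"(channels: {', '.join(CHANNEL_NAMES)})")
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"sf_{name} must be finite and > 0, got {v}")
        self._values = {k: float(merged[k]) for k in CHANNEL_NAMES if k in merged}

    def __getitem__(self, key):
        if key not in CHANNEL_NAMES:
            raise RosterError(f"unknown channel {key!r}")
        return self._values.get(key, 1.0)

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def __repr__(self):
        inner = ", ".join(f"{k}={v:.6g}" for k, v in self._values.items())
        return f"ScalingFactors({inner})"

    def __eq__(self, other):
        if not isinstance(other, ScalingFactors):
            return NotImplemented
        return all(self[c] == other[c] for c in CHANNEL_NAMES)

    def vector(self) -> np.ndarray:
        """Full 9-channel vector in roster order (implicit channels at 1)."""
        return fm.sf_vector(self._values)

    def updated(self, **changes) -> "ScalingFactors":
        merged = dict(self._values)
        merged.update(changes)
        return ScalingFactors(merged)

    @classmethod
    def from_vector(cls, names, values) -> "ScalingFactors":
        return cls(dict(zip(names, np.asarray(values, dtype=float))))


# ------------------------------------------------------------------ parameters
@dataclass
class ModelParameters:
    """Physical parameters plus integrator settings.

    ``overrides`` patches :data:`formulation.DEFAULT_PARAMS` (unknown keys
    rejected).  The integrator settings encode the quasi-stability rule:
    integration stops at the first cycle boundary where ``stab_win``
    consecutive cycle lengths agree within ``stab_tol`` (relative), capped
    at ``max_cycles``.
    """

    overrides: dict = field(default_factory=dict)
    dt: float = 0.02                 # ms, kernel step; output is GRID_DT
    stab_tol: float = 1e-5
    stab_win: int = 4
    na_tol: float = 3e-4       # mM; setpoint convergence gates stability
    ca_tol: float = 3e-3       # amol
    min_cycles: int = 5
    max_cycles: int = 100
    quiesce_ms: float = 4000.0
    homeostasis: bool = True

    def __post_init__(self):
        unknown = set(self.overrides) - set(fm.DEFAULT_PARAMS)
        if unknown:
            raise KeyError(f"unknown model parameters: {sorted(unknown)}")
        for key in ("C_m", "std_Nai", "std_Catot"):
            if self[key] <= 0:
                raise ValueError(f"{key} must be positive")
        if self.dt <= 0 or GRID_DT % self.dt > 1e-12 and abs(
                GRID_DT / self.dt - round(GRID_DT / self.dt)) > 1e-9:
            raise ValueError("dt must divide the 0.1 ms output grid")

    def __getitem__(self, key):
        return self.overrides.get(key, fm.DEFAULT_PARAMS[key])

    def as_dict(self) -> dict:
        d = dict(fm.DEFAULT_PARAMS)
        d.update(self.overrides)
        return d

    def vector(self) -> np.ndarray:
        return fm.param_vector(self.overrides)

    @property
    def out_stride(self) -> int:
        return int(round(GRID_DT / self.dt))


@dataclass(frozen=True)
class CurrentSpec:
    """Descriptor of one roster current."""

    name: str
    limiting_conductance: float | None  # nS; None for transporters
    gating_scheme: tuple
    reversal_rule: str  # "nernst:Na", "nernst:K" or "fixed:<param>"

    def __post_init__(self):
        if self.name not in CURRENT_NAMES:
            raise RosterError(f"{self.name!r} is not in the current roster")
        if self.limiting_conductance is not None and self.limiting_conductance < 0:
            raise ValueError("limiting conductance must be >= 0")


def roster(params: ModelParameters | None = None) -> tuple[CurrentSpec, ...]:
    """The eleven CurrentSpec entries of the total-current sum, in order."""
    p = params or ModelParameters()
    reversal = {"Na": "nernst:Na", "CaL": "fixed:E_CaL", "ha": "fixed:E_ha",
                "K1": "nernst:K", "Kr": "nernst:K", "Ks": "nernst:K",
                "Kur": "nernst:K", "Kto": "nernst:K", "bNSC": "fixed:E_bNSC"}
    specs = [CurrentSpec(n, p[f"G_{n}"], tuple(fm.CHANNEL_GATES[n]), reversal[n])
             for n in CHANNEL_NAMES]
    specs.append(CurrentSpec("NaK", None, (), "cycle"))
    specs.append(CurrentSpec("NCX", None, (), "cycle"))
    return tuple(specs)


# ------------------------------------------------------------------ cell state
class CellState:
    """Full dynamical state: V_m, gates, ion concentrations, crf factors."""

    __slots__ = ("y",)

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.shape != (fm.N_STATE,):
            raise ValueError(f"state vector must have length {fm.N_STATE}")
        self.y = y.copy()

    @classmethod
    def initial(cls, params: ModelParameters | None = None) -> "CellState":
        p = params or ModelParameters()
        return cls(fm.initial_state(p.overrides))

    def __getattr__(self, name):
        try:
            idx = fm.STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.y[idx]

    @property
    def gates(self) -> dict:
        return {g: self.y[1 + i] for i, g in enumerate(GATE_NAMES)}

    def validate(self):
        """Raise StateIntegrityError on any violated state invariant."""
        if not np.all(np.isfinite(self.y)):
            raise StateIntegrityError("non-finite state component")
        for i, g in enumerate(GATE_NAMES):
            if not 0.0 <= self.y[1 + i] <= 1.0:
                raise StateIntegrityError(f"gate {g} outside [0, 1]")
        for name in ("Na_i", "K_i", "Ca_jnc", "Ca_iz", "Ca_blk",
                     "Ca_SRup", "Ca_SRrl", "crf_NaK", "crf_NCX"):
            if getattr(self, name) <= 0:
                raise StateIntegrityError(f"{name} must be positive")
        return self

    def copy(self) -> "CellState":
        return CellState(self.y)

    def as_dict(self) -> dict:
        return dict(zip(fm.STATE_NAMES, self.y.tolist()))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CellState":
        return cls(np.array([float(d[n]) for n in fm.STATE_NAMES]))


# ------------------------------------------------------------------ operations
def channel_current(spec: CurrentSpec, sf: ScalingFactors, state: CellState,
                    params: ModelParameters | None = None) -> float:
    """Single channel current ``sf * Gbar * pO * (V - E)`` in pA (outward +)."""
    if spec.name in ("NaK", "NCX"):
        raise RosterError(f"{spec.name} is a transporter, not a channel")
    p = params or ModelParameters()
    for g, po in state.gates.items():
        if not 0.0 <= po <= 1.0:
            raise StateIntegrityError(f"gate {g} outside [0, 1]")
    return fm.currents(state.y, dict(sf), p.overrides)[spec.name]


def gate_derivative(po: float, vm: float, scheme: str) -> float:
    """dpO/dt = alpha(V)(1-pO) - beta(V)pO for the named gate scheme."""
    if not 0.0 <= po <= 1.0:
        raise StateIntegrityError("pO outside [0, 1]")
    alpha, beta = fm.gate_rates(scheme, vm)
    if alpha < 0 or beta < 0:
        raise ValueError(f"scheme {scheme} produced a negative rate")
    return float(alpha) * (1.0 - po) - float(beta) * po


def total_current(state: CellState, sf: ScalingFactors,
                  params: ModelParameters | None = None):
    """(I_tot_cell, per-current breakdown dict); the total is the exact sum."""
    p = params or ModelParameters()
    breakdown = fm.currents(state.y, dict(sf), p.overrides)
    return sum(breakdown.values()), breakdown


def ca_total(state: CellState, params: ModelParameters | None = None) -> float:
    """Total cell Ca in amol (volume-weighted sum of the five compartments)."""
    p = params or ModelParameters()
    return fm.ca_total_amol(state.y, p.overrides)


def homeostasis_update(state: CellState,
                       params: ModelParameters | None = None) -> CellState:
    """Apply the per-cycle feedback increments to crf_NaK and crf_NCX.

    ``dcrf_NaK = -(std_Nai - Na_i) * g_NaK_fb`` and
    ``dcrf_NCX = -(std_Catot - Ca_tot) * g_NCX_fb``; results are clipped at
    the configured floor (a warning-level degenerate regime).
    """
    p = params or ModelParameters()
    out = state.copy()
    out.y[fm.ICRFNAK] += -(p["std_Nai"] - state.Na_i) * p["g_NaK_fb"]
    out.y[fm.ICRFNCX] += -(p["std_Catot"] - ca_total(state, p)) * p["g_NCX_fb"]
    floor = p["crf_floor"]
    if out.y[fm.ICRFNAK] < floor or out.y[fm.ICRFNCX] < floor:
        import warnings
        warnings.warn("homeostasis correction factor clipped at floor "
                      "(degenerate regime)", stacklevel=2)
    out.y[fm.ICRFNAK] = max(out.y[fm.ICRFNAK], floor)
    out.y[fm.ICRFNCX] = max(out.y[fm.ICRFNCX], floor)
    return out


def state_derivative(state: CellState, sf: ScalingFactors,
                     params: ModelParameters | None = None) -> np.ndarray:
    """Full analytic d(state)/dt (crf entries, piecewise constant, get 0).

    Reference (numpy) counterpart of the compiled kernel's update rule,
    used for validation and for external ODE solvers.
    """
    p = params or ModelParameters()
    y = state.y
    itot, cur = total_current(state, sf, p)
    if not np.isfinite(itot):
        bad = [k for k, v in cur.items() if not np.isfinite(v)]
        raise StateIntegrityError(f"non-finite current component(s): {bad}")
    dy = np.zeros_like(y)
    dy[fm.IV] = -itot / p["C_m"]
    for i, g in enumerate(GATE_NAMES):
        dy[1 + i] = gate_derivative(y[1 + i], y[fm.IV], g)

    f = _kernel.F_CONST
    vol_cyt = p["vol_jnc"] + p["vol_iz"] + p["vol_blk"]
    na_cur = (cur["Na"] + p["fNa_ha"] * cur["ha"] + p["fNa_bNSC"] * cur["bNSC"]
              + 3.0 * cur["NaK"] + 3.0 * cur["NCX"])
    k_cur = (cur["K1"] + cur["Kr"] + cur["Ks"] + cur["Kur"] + cur["Kto"]
             + (1 - p["fNa_ha"]) * cur["ha"] + (1 - p["fNa_bNSC"]) * cur["bNSC"]
             - 2.0 * cur["NaK"])
    dy[fm.INAI] = -na_cur / (f * vol_cyt)
    dy[fm.IKI] = -k_cur / (f * vol_cyt)

    caj_f = y[fm.ICAJNC] / p["beta_jnc"]
    cai_f = y[fm.ICAIZ] / p["beta_iz"]
    cab_f = y[fm.ICABLK] / p["beta_blk"]
    cau_f = y[fm.ICAUP] / p["beta_SRup"]
    car_f = y[fm.ICARL] / p["beta_SRrl"]
    a_ji = (caj_f - cai_f) * p["vol_jnc"] / p["tau_jnc_iz"]
    a_ib = (cai_f - cab_f) * p["vol_iz"] / p["tau_iz_blk"]
    j_up = p["v_up"] * cab_f ** 2 / (cab_f ** 2 + p["Km_up"] ** 2)
    a_up = j_up * p["vol_blk"]
    a_tr = (cau_f - car_f) * p["vol_SRup"] / p["tau_tr"]
    a_rel = p["k_rel"] * y[fm.ID] * (car_f - caj_f) * p["vol_SRrl"]
    a_leak = p["k_leak"] * (cau_f - cab_f) * p["vol_SRup"]
    dy[fm.ICAJNC] = (-a_ji + a_rel) / p["vol_jnc"] - cur["CaL"] / (2 * f * p["vol_jnc"])
    dy[fm.ICAIZ] = (a_ji - a_ib) / p["vol_iz"] + cur["NCX"] / (f * p["vol_iz"])
    dy[fm.ICABLK] = (a_ib - a_up + a_leak) / p["vol_blk"]
    dy[fm.ICAUP] = (a_up - a_tr - a_leak) / p["vol_SRup"]
    dy[fm.ICARL] = (a_tr - a_rel) / p["vol_SRrl"]
    return dy


# ------------------------------------------------------------------ integrate
_TABLE_CACHE: dict = {}


def _rate_table(dt: float) -> np.ndarray:
    if dt not in _TABLE_CACHE:
        _TABLE_CACHE[dt] = fm.build_rate_table(dt)
    return _TABLE_CACHE[dt]


def integrate(initial: CellState, sf: ScalingFactors,
              params: ModelParameters | None = None,
              n_cycles: int | None = None,
              max_ms: float | None = None,
              record_states: bool = False,
              raise_on_quiescent: bool = False):
    """Integrate the model to quasi-stability (or ``n_cycles``).

    Returns ``(trace, final_state, cycle_times)``.  A quiescent model is
    signalled through ``trace.quiescent`` (callers assign the penalty MSE)
    unless ``raise_on_quiescent`` is set.  V_m is recorded on the exact
    0.1 ms grid; homeostasis increments are applied once per detected
    cycle when enabled in ``params``.
    """
    p = params or ModelParameters()
    max_cycles = int(n_cycles) if n_cycles is not None else p.max_cycles
    if max_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    # generous wall: expected CL is O(1 s); cap the simulated span
    if max_ms is None:
        max_ms = max(2.0 * p.quiesce_ms, 1600.0 * max_cycles)
    stride = p.out_stride
    n_buf = int(max_ms / (p.dt * stride)) + 2
    vm = np.empty(n_buf)
    states = np.empty((n_buf if record_states else 1, fm.N_STATE))
    ctimes = np.empty(max_cycles + 2)
    y = initial.copy().validate().y
    n_out, n_cyc, status = _kernel.integrate_kernel(
        y, p.vector(), sf.vector(), _rate_table(p.dt), p.dt, stride, max_ms,
        max_cycles, p.min_cycles, p.stab_tol, p.stab_win, p.na_tol,
        p.ca_tol, p.quiesce_ms, p.homeostasis, vm, states, record_states,
        ctimes)
    if status == _kernel.NONFINITE:
        raise StateIntegrityError(
            "integration aborted on non-finite state; last finite V_m "
            f"= {vm[max(n_out - 2, 0)]:.3f} mV")
    quiescent = status == _kernel.QUIESCENT
    if quiescent and raise_on_quiescent:
        raise QuiescentModelError(
            f"no upstroke within {p.quiesce_ms:.0f} ms")
    trace = Trace(
        vm=vm[:n_out].copy(),
        dt=GRID_DT,
        cycle_times=ctimes[:n_cyc].copy(),
        stable=status == _kernel.OK,
        quiescent=quiescent,
        meta={"sf": dict(sf), "status": int(status), "n_cycles": int(n_cyc)},
    )
    out = (trace, CellState(y), ctimes[:n_cyc].copy())
    if record_states:
        trace.meta["states"] = states[:n_out].copy()
    return out
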