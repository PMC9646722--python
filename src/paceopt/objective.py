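"""MSE objective between an adaptive model trace and a target trace.

``MSE = sum((V_m,a - V_m,t)^2) / N`` over samples on the common 0.1 ms
grid, after registering the last complete cycle of each trace at its
upstroke.  Phase windows (plateau / repolarization / SDD) partition the
cycle exactly, so the full-cycle MSE is the sample-count-weighted mean of
the phase MSEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, InsufficientCyclesError
from .trace import Trace

PHASES = ("plateau", "repol", "sdd")


@dataclass
class ObjectiveSpec:
    """Window selection, per-phase weights and the quiescence penalty.

    window: "full" or a subset of {"plateau", "repol", "sdd"}.
    weights: optional per-phase weights (full-cycle mode weighs the three
    phases by these when given; default unit weights everywhere).
    penalty_mse: finite stand-in cost for quiescent candidates; must
    dominate any physiological MSE.
    """

    window: str | tuple = "full"
    weights: dict = field(default_factory=dict)
    penalty_mse: float = 1.0e4

    def __post_init__(self):
        if self.penalty_mse < 1.0e3:
            raise ConfigError("penalty_mse must be >= 1e3 mV^2")
        if isinstance(self.window, str):
            if self.window != "full" and self.window not in PHASES:
                raise ConfigError(f"unknown window {self.window!r}")
        else:
            bad = set(self.window) - set(PHASES)
            if bad:
                raise ConfigError(f"unknown phases {sorted(bad)}")
            if len(self.window) == 0:
                raise ConfigError("window selects no phases")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("phase weights must be >= 0")
        if self.weights and all(w == 0 for w in self.weights.values()):
            raise ConfigError("phase weights must not all be zero")


def _phase_bounds(v: np.ndarray) -> dict:
    """Partition one cycle (starting at the upstroke) into the three phases.

    plateau: upstroke to the downward -20 mV crossing; repol: down to the
    first sample within 0.5 mV of the cycle minimum; sdd: the rest.  The
    three half-open sample ranges tile [0, N) exactly.
    """
    n = v.size
    below = np.flatnonzero((v[:-1] >= -20.0) & (v[1:] < -20.0))
    c1 = int(below[0] + 1) if below.size else n
    if c1 < n:
        mdp = v[c1:].min()
        near = np.flatnonzero(v[c1:] <= mdp + 0.5)
        c2 = c1 + int(near[0]) if near.size else n
    else:
        c2 = n
    return {"plateau": (0, c1), "repol": (c1, c2), "sdd": (c2, n)}


def align(adaptive: Trace, target: Trace, spec: ObjectiveSpec | None = None):
    """Register the last complete cycles at their upstrokes.

    Returns ``(va, vt)`` paired sample arrays over ``min(CL_a, CL_t)``
    samples, or ``None`` when either trace is quiescent (the caller then
    applies the penalty).  The adaptive trace is shifted by the fractional
    part of the upstroke-time difference (linear interpolation) so that
    registration is not quantized to the grid.
    """
    if adaptive.quiescent or target.quiescent:
        return None
    try:
        a0, a1 = adaptive.last_cycle()
        t0, t1 = target.last_cycle()
    except InsufficientCyclesError:
        # oscillations too shallow to register an upstroke are treated
        # like quiescent candidates: penalty, not an exception
        return None
    n = min(a1 - a0, t1 - t0)
    # fractional registration: sub-sample part of each upstroke time
    fa = adaptive.upstroke_times()[-2] / adaptive.dt - a0
    ft = target.upstroke_times()[-2] / target.dt - t0
    shift = fa - ft  # in samples, |shift| < 1
    idx = a0 + np.arange(n) + shift
    va = np.interp(idx, np.arange(adaptive.vm.size), adaptive.vm)
    vt = target.vm[t0:t0 + n]
    return va, vt


def mse(adaptive: Trace, target: Trace,
        spec: ObjectiveSpec | None = None) -> float:
    """Mean squared V_m difference (mV^2) over the configured window."""
    spec = spec or ObjectiveSpec()
    pair = align(adaptive, target, spec)
    if pair is None:
        return float(spec.penalty_mse)
    va, vt = pair
    sq = (va - vt) ** 2
    if spec.window == "full" and not spec.weights:
        return float(sq.mean())
    bounds = _phase_bounds(vt)
    if isinstance(spec.window, str) and spec.window != "full":
        phases = (spec.window,)
    elif spec.window == "full":
        phases = PHASES
    else:
        phases = tuple(spec.window)
    num = den = 0.0
    for ph in phases:
        lo, hi = bounds[ph]
        w = spec.weights.get(ph, 1.0)
        if hi > lo:
            num += w * sq[lo:hi].sum()
            den += w * (hi - lo)
    if den == 0:
        raise ConfigError("window selects zero samples")
    return float(num / den)
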