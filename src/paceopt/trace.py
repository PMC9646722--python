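"""Membrane-potential traces on the uniform 0.1 ms grid.

A :class:`Trace` is the universal currency between the simulator, the MSE
objective and file I/O: membrane potential sampled at exactly ``dt`` ms
(0.1 by default), together with detected cycle boundaries and stability
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientCyclesError, QuiescentModelError

GRID_DT = 0.1  # ms

#: V_m threshold whose upward crossing marks a candidate upstroke (mV)
UPSTROKE_GATE = -20.0

#: half-width (ms) of the derivative window used to refine upstroke times
REFINE_HALF_MS = 15.0


@dataclass
class Trace:
    """Uniformly sampled V_m time series.

    Parameters
    ----------
    vm : ndarray
        Membrane potential in mV, one sample per ``dt`` ms.
    dt : float
        Sample interval in ms (0.1 unless deliberately refined).
    cycle_times : ndarray
        Times (ms, relative to the first sample) of upward -20 mV
        crossings, one per detected cycle boundary.
    stable : bool
        True when the producing integration reached its quasi-stability
        criterion (consecutive cycle lengths matching within tolerance).
    quiescent : bool
        True when no upstroke was detected; such traces carry the penalty
        MSE in the objective instead of being compared sample-wise.
    meta : dict
        Free-form provenance (generating scaling factors, seed, window).
    """

    vm: np.ndarray
    dt: float = GRID_DT
    cycle_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    stable: bool = False
    quiescent: bool = False
    meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vm = np.asarray(self.vm, dtype=float)
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)
        if self.vm.ndim != 1:
            raise ValueError("vm must be one-dimensional")
        if not self.quiescent and not np.all(np.isfinite(self.vm)):
            raise ValueError("trace contains non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def t(self) -> np.ndarray:
        """Time axis in ms, starting at 0."""
        return np.arange(self.vm.size) * self.dt

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_times.size)

    # ------------------------------------------------------------- upstrokes
    def upstroke_indices(self) -> np.ndarray:
        """Sample index of each upward crossing of the -20 mV gate.

        Hysteresis: a crossing counts only if V_m visited the diastolic
        range (below -40 mV) since the previous accepted upstroke, which
        rejects noise wiggles around the gate during the plateau.
        Crossings too close to either trace end are dropped: their
        upstroke cannot be refined from a complete derivative window.
        """
        if "up_idx" in self._cache:
            return self._cache["up_idx"]
        v = self.vm
        up = np.flatnonzero((v[:-1] < UPSTROKE_GATE) & (v[1:] >= UPSTROKE_GATE)) + 1
        accepted = []
        last = 0
        for i in up:
            if v[last:i].min() < -40.0:
                accepted.append(i)
                last = i
        up = np.asarray(accepted, dtype=int)
        half = max(int(round(REFINE_HALF_MS / self.dt)), 2)
        out = up[(up - half >= 1) & (up + half <= v.size - 2)]
        self._cache["up_idx"] = out
        return out

    def upstroke_times(self) -> np.ndarray:
        """Sub-sample upstroke times (ms): the maximal-dV/dt instant.

        Each upward -20 mV crossing gates a candidate; the upstroke is the
        peak of the discrete derivative within +/-15 ms of it, refined by
        parabolic interpolation.  Unlike a fixed-level crossing this
        landmark is invariant to constant voltage offsets, and identical
        waveforms register exactly, which keeps the MSE floor of aligned
        identical rhythms at zero.
        """
        if "up_times" in self._cache:
            return self._cache["up_times"]
        v = self.vm
        idx = self.upstroke_indices()
        if idx.size == 0:
            self._cache["up_times"] = np.empty(0)
            return self._cache["up_times"]
        d = np.diff(v)
        half = max(int(round(REFINE_HALF_MS / self.dt)), 2)
        times = np.empty(idx.size)
        for k, i in enumerate(idx):
            lo = max(i - half, 1)
            hi = min(i + half, d.size - 1)
            j = lo + int(np.argmax(d[lo:hi]))
            dm, d0, dp = d[j - 1], d[j], d[j + 1]
            den = dm - 2.0 * d0 + dp
            frac = 0.5 * (dm - dp) / den if den != 0.0 else 0.0
            frac = float(np.clip(frac, -0.5, 0.5))
            # forward difference d[j] sits at sample time j + 1/2
            times[k] = (j + 0.5 + frac) * self.dt
        self._cache["up_times"] = times
        return times

    def cycle_lengths(self) -> np.ndarray:
        """Intervals between successive upstrokes, ms."""
        return np.diff(self.upstroke_times())

    def last_cycle(self) -> tuple[int, int]:
        """(start, stop) sample indices of the last complete cycle.

        Bounds are the integer parts of the two last refined upstroke
        times, so the fractional remainders register sub-sample phase.
        """
        if self.quiescent:
            raise QuiescentModelError("quiescent trace has no cycles")
        times = self.upstroke_times()
        if times.size < 2:
            raise InsufficientCyclesError(
                f"need >= 2 upstrokes, found {times.size}")
        return int(times[-2] // self.dt), int(times[-1] // self.dt)

    def shifted(self, offset_ms: float) -> np.ndarray:
        """V_m resampled at t + offset_ms by linear interpolation."""
        return np.interp(self.t + offset_ms, self.t, self.vm)

    def __len__(self) -> int:
        return int(self.vm.size)
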