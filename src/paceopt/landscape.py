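"""Global MSE-landscape mapping for identifiability analysis.

Scaling-factor vectors are drawn log-uniformly over wide multiplicative
ranges (default 1/10 to 10 times baseline), scored against a fixed target,
and summarized as per-axis minimum-MSE envelopes whose interior minima
locate candidate optima.  A well-identified model shows exactly one sharp
depression, in the bin containing sf = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ConfigError
from .model.cell import ModelParameters, ScalingFactors
from .objective import ObjectiveSpec
from .optimize import TraceMSECost
from .trace import Trace


@dataclass
class LandscapeSample:
    """One scored point of the scan."""

    sf: dict
    mse: float
    quiescent: bool


@dataclass
class EnvelopeBin:
    """Per-bin minimum MSE along one sf axis (others marginalized)."""

    sf_name: str
    lo: float
    hi: float
    min_mse: float       # nan when the bin is empty
    count: int

    @property
    def center(self) -> float:
        return float(np.sqrt(self.lo * self.hi))  # geometric bin center


@dataclass
class LandscapeScan:
    """Result container: samples plus the provenance of the scan."""

    samples: list
    names: tuple
    ranges: dict
    seed: int
    meta: dict = field(default_factory=dict)

    def table(self, sf_cap: float | None = None) -> np.ndarray:
        """(n, p+2) array: sf columns, mse, quiescent flag.

        ``sf_cap`` is a presentation filter (rows with any sf above the
        cap dropped), applied only here, never during analysis.
        """
        rows = []
        for s in self.samples:
            vals = [s.sf[n] for n in self.names]
            if sf_cap is not None and max(vals) > sf_cap:
                continue
            rows.append(vals + [s.mse, float(s.quiescent)])
        return np.asarray(rows, dtype=float)


def sample_landscape(target: Trace, ranges: dict, n_samples: int, seed: int,
                     params: ModelParameters | None = None,
                     objective: ObjectiveSpec | None = None,
                     include_baseline: bool = True) -> LandscapeScan:
    """Score ``n_samples`` log-uniform sf draws against ``target``.

    ``ranges`` maps channel name -> (lo, hi) multiplicative interval;
    unlisted channels stay at 1.  The exact baseline point (all ones) is
    injected deterministically when ``include_baseline`` so the global
    minimum by construction is present in every scan.  Quiescent samples
    carry the penalty MSE and a flag; they never enter envelopes.
    """
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    names = tuple(ranges)
    for n, (lo, hi) in ranges.items():
        if not 0 < lo < hi:
            raise ConfigError(f"invalid range for {n}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    spec = objective or ObjectiveSpec()
    cost = TraceMSECost(target, names, params, objective=spec)
    draws = np.exp(rng.uniform(
        np.log([ranges[n][0] for n in names]),
        np.log([ranges[n][1] for n in names]),
        size=(n_samples, len(names))))
    if include_baseline:
        draws = np.vstack([np.ones(len(names)), draws])
    samples = []
    for x in draws:
        c = cost(x)
        samples.append(LandscapeSample(
            sf=dict(zip(names, x.tolist())),
            mse=float(c),
            quiescent=bool(c >= spec.penalty_mse)))
    return LandscapeScan(samples=samples, names=names, ranges=dict(ranges),
                         seed=seed)


def envelope(scan: LandscapeScan, sf_name: str, n_bins: int = 50) -> list:
    """Minimum-MSE envelope along one sf axis, log-spaced bins.

    Penalty-flagged samples are excluded; empty bins carry NaN.
    """
    if sf_name not in scan.names:
        raise ConfigError(f"{sf_name!r} was not a scanned axis")
    lo, hi = scan.ranges[sf_name]
    edges = np.geomspace(lo, hi, n_bins + 1)
    mins = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for s in scan.samples:
        if s.quiescent:
            continue
        b = int(np.searchsorted(edges, s.sf[sf_name], side="right") - 1)
        b = min(max(b, 0), n_bins - 1)
        counts[b] += 1
        if np.isnan(mins[b]) or s.mse < mins[b]:
            mins[b] = s.mse
    if counts.sum() == 0:
        raise ConfigError(f"no non-quiescent samples along {sf_name}")
    return [EnvelopeBin(sf_name, float(edges[i]), float(edges[i + 1]),
                        float(mins[i]), int(counts[i]))
            for i in range(n_bins)]


def detect_local_minima(bins: list, prominence: float = 0.2) -> list:
    """Interior strict minima of the log10 envelope with given prominence.

    Returns the detected EnvelopeBin objects.  ``prominence`` is in log10
    MSE units; NaN (empty) bins are ignored.  A single-depression
    landscape yields exactly one detection, in the bin containing sf = 1
    when the target is the baseline output.
    """
    filled = [b for b in bins if np.isfinite(b.min_mse)]
    if len(filled) < 5:
        raise ConfigError("need >= 5 non-empty bins to detect minima")
    logm = np.log10(np.maximum([b.min_mse for b in filled], 1e-12))
    peaks, _ = find_peaks(-logm, prominence=prominence)
    return [filled[i] for i in peaks]
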