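"""Model/Results front end for conductance recovery from AP waveforms.

:class:`ConductanceModel` bundles a target trace with the optimization
protocol; ``fit()`` runs one Pattern Search, ``fit_multirun()`` the
randomized multi-run (orp) protocol.  The Results objects carry the
estimates, their uncertainties and diagnostics, statsmodels-style.

Example
-------
>>> model = ConductanceModel.from_sf_true(
...     ScalingFactors(), selected=("Kr", "CaL", "Na", "bNSC"))
>>> res = model.fit_multirun(n_runs=30, range_pct=0.10, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model.cell import ModelParameters, ScalingFactors
from .objective import ObjectiveSpec
from .optimize import (OrpResult, PSConfig, PSRun, TraceMSECost,
                       constrained_orp, orp_test, ps_optimize, top_k_stats)
from .targets import ap_metrics, make_cell_specific_target
from .trace import Trace


class ConductanceModel:
    """Whole-cell conductance estimation problem for one target AP.

    Parameters
    ----------
    target : Trace
        The cell-specific AP waveform to fit (noise-free model output in
        recovery experiments, or a manually pre-fitted recording).
    selected : sequence of str
        The currents whose scaling factors are optimized (typically the
        4-6 currents of largest conductance); all others stay at sf = 1.
    params, objective, ps_config
        Model parameters, MSE window specification, and Pattern Search
        settings; defaults follow the package's standard protocol.
    """

    def __init__(self, target: Trace, selected,
                 params: ModelParameters | None = None,
                 objective: ObjectiveSpec | None = None,
                 ps_config: PSConfig | None = None,
                 eval_cycles: int = 12):
        self.target = target
        self.selected = tuple(selected)
        self.params = params or ModelParameters()
        self.objective = objective or ObjectiveSpec()
        self.ps_config = ps_config or PSConfig(self.selected, crtstp=2e-5)
        self.eval_cycles = eval_cycles
        if set(self.ps_config.selected_currents) != set(self.selected):
            raise ValueError("ps_config.selected_currents must match selected")

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_sf_true(cls, sf_true: ScalingFactors, selected,
                     params: ModelParameters | None = None, **kw):
        """Build the recovery problem whose target is generated by sf_true."""
        target = make_cell_specific_target(sf_true, params)
        return cls(target, selected, params=params, **kw)

    # ------------------------------------------------------------------- fits
    def _cost(self, base_sf=None):
        return TraceMSECost(self.target, self.selected, self.params,
                            base_sf=base_sf, objective=self.objective,
                            fixed_cycles=self.eval_cycles)

    def fit(self, start: ScalingFactors | None = None,
            seed: int | None = None) -> "PatternSearchResults":
        """One Pattern Search run from ``start`` (default: all ones)."""
        cost = self._cost()
        run = ps_optimize(cost, start or ScalingFactors(), self.ps_config,
                          seed=seed)
        return PatternSearchResults(self, run, cost)

    def fit_multirun(self, n_runs: int = 30, range_pct: float = 0.10,
                     seed: int = 0, frozen: dict | None = None,
                     ) -> "MultiRunResults":
        """Randomized multi-run optimization (the orp protocol)."""
        sf_true = ScalingFactors(self.target.meta.get("sf_true", {}))
        if frozen:
            res = constrained_orp(self.target, sf_true, n_runs, range_pct,
                                  self.ps_config, seed, frozen,
                                  params=self._eval_params(),
                                  objective=self.objective)
        else:
            res = orp_test(self.target, sf_true, n_runs, range_pct,
                           self.ps_config, seed,
                           params=self._eval_params(),
                           objective=self.objective)
        return MultiRunResults(self, res)

    def _eval_params(self) -> ModelParameters:
        from dataclasses import replace
        return replace(self.params, min_cycles=self.eval_cycles,
                       max_cycles=self.eval_cycles)

    def target_metrics(self):
        return ap_metrics(self.target)


class PatternSearchResults:
    """Estimates and audit trail of a single Pattern Search run."""

    def __init__(self, model: ConductanceModel, run: PSRun,
                 cost: TraceMSECost | None = None):
        self.model = model
        self.run = run
        self._cost = cost

    @property
    def params(self) -> pd.Series:
        return pd.Series({n: self.run.final_sf[n] for n in self.run.names},
                         name="sf")

    @property
    def mse(self) -> float:
        return self.run.final_mse

    @property
    def log10_mse(self) -> float:
        return float(np.log10(max(self.run.final_mse, 1e-30)))

    @property
    def converged(self) -> bool:
        return self.run.converged

    @property
    def n_evals(self) -> int:
        return self.run.n_evals

    def bp_trajectory(self) -> pd.DataFrame:
        """BP renewals as a DataFrame (one row per accepted base point)."""
        rows = [list(x) + [c] for x, c in self.run.bp_history]
        return pd.DataFrame(rows, columns=list(self.run.names) + ["mse"])

    def summary(self) -> str:
        lines = ["Pattern Search fit",
                 "==================",
                 f"evaluations: {self.n_evals}   converged: {self.converged}",
                 f"final MSE: {self.mse:.4e} mV^2  (log10 {self.log10_mse:.2f})",
                 "",
                 "scaling factors:"]
        for n in self.run.names:
            lines.append(f"  sf_{n:<5s} {self.run.final_sf[n]:.5f}")
        return "\n".join(lines)


class MultiRunResults:
    """Aggregate estimates of the multi-run randomized-start protocol.

    ``params``/``bse`` expose the top-k (default 20) per-current mean and
    standard error; ``summary()`` prints the familiar per-current table
    with the homeostasis endpoints.
    """

    def __init__(self, model: ConductanceModel, result: OrpResult, k: int = 20):
        self.model = model
        self.result = result
        self.k = min(k, result.n_runs)

    # ------------------------------------------------------------- statistics
    def stats(self, k: int | None = None) -> dict:
        return top_k_stats(self.result, k or self.k, self.model.params)

    @property
    def params(self) -> pd.Series:
        st = self.stats()
        return pd.Series(st["sf_mean"], name="sf_mean")

    @property
    def bse(self) -> pd.Series:
        st = self.stats()
        return pd.Series(st["sf_se"], name="sf_se")

    def top_k(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.k
        idx = self.result.top_k_indices(k)
        table = self.result.final_table()[idx]
        df = pd.DataFrame(table, columns=list(self.result.names) + ["mse"])
        df["log10_mse"] = np.log10(df["mse"].clip(lower=1e-30))
        df["run"] = idx
        return df

    def final_log10_mse(self) -> np.ndarray:
        return np.log10(np.maximum(
            [r.final_mse for r in self.result.runs], 1e-30))

    # -------------------------------------------------------------- analytics
    def pca(self, top: int = 200):
        """Deflation PCA of the top-``top`` final sf vectors."""
        from .analysis import pca as _pca
        k = min(top, self.result.n_runs)
        idx = self.result.top_k_indices(k)
        X = self.result.final_table()[idx][:, :len(self.result.names)]
        return _pca(X)

    def complementarity(self, currents, k: int | None = None):
        """Plane fit exposing trade-offs among the chosen currents."""
        from .analysis import complementarity_report
        return complementarity_report(self.result, currents, k or self.k)

    def envelope_widths(self, name: str, n_slices: int = 5) -> np.ndarray:
        """Width of the pooled sf scatter per log10(MSE) slice, descending.

        Pools every BP renewal of every run, orders by MSE, splits into
        ``n_slices`` equal groups from worst to best, and returns the
        per-group sf range for ``name``.  Identifiable currents show
        monotonically shrinking widths toward small MSE.
        """
        pts = self.result.pooled_bp_points()
        j = self.result.names.index(name)
        order = np.argsort(-pts[:, -1], kind="stable")
        groups = np.array_split(order, n_slices)
        return np.array([pts[g, j].max() - pts[g, j].min() for g in groups])

    def summary(self, k: int | None = None) -> str:
        st = self.stats(k)
        lines = [
            "Multi-run (orp) conductance recovery",
            "====================================",
            f"runs: {self.result.n_runs}   randomization: "
            f"+/-{100 * self.result.range_pct:.0f}%   top-k: {st['k']}",
            f"mean final log10(MSE): {st['mean_log10_mse']:.3f}",
            "",
            f"{'current':<8}{'mean sf':>10}{'SE':>10}",
        ]
        for n in self.result.names:
            lines.append(
                f"{n:<8}{st['sf_mean'][n]:>10.5f}{st['sf_se'][n]:>10.5f}")
        if "mean_Nai" in st:
            lines += ["",
                      f"final [Na+]_i: {st['mean_Nai']:.4f} mM   "
                      f"Ca_tot: {st['mean_Catot']:.3f} amol"]
        return "\n".join(lines)
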