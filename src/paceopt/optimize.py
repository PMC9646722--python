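"""Base-point / new-point Pattern Search and the multi-run (orp) driver.

The optimizer probes each selected scaling factor one coordinate at a
time: from the current base point BP it evaluates BP +/- stp on that
coordinate and keeps the best of the three.  When a full sweep over the
coordinates fails to improve the cost, the step is contracted by redFct;
the run terminates once stp falls below crtstp.  The orp ("optimization
with randomized parameters") driver repeats the search from independently
randomized initial sets and pools the results for convergence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, QuiescentModelError, ShortfallError
from .model.cell import CellState, ModelParameters, ScalingFactors
from .model.cell import integrate
from .objective import ObjectiveSpec, mse
from .targets import randomize_sf
from .trace import Trace


@dataclass
class PSConfig:
    """Pattern-search settings.

    stp0: initial coordinate step in sf units; redFct: geometric step
    reduction on a failed sweep; crtstp: terminal step (the search stops
    when stp < crtstp); sweep_order: coordinate order (defaults to the
    roster order of the selected currents); max_evals: evaluation budget.
    """

    selected_currents: tuple
    stp0: float = 0.04
    redFct: float = 0.25
    crtstp: float = 5.0e-5
    sweep_order: tuple | None = None
    max_evals: int = 100_000

    def __post_init__(self):
        from .model.cell import CHANNEL_NAMES
        self.selected_currents = tuple(self.selected_currents)
        bad = set(self.selected_currents) - set(CHANNEL_NAMES)
        if bad:
            raise ConfigError(f"unknown currents in selection: {sorted(bad)}")
        if len(self.selected_currents) == 0:
            raise ConfigError("no currents selected")
        if not 0.0 < self.redFct < 1.0:
            raise ConfigError("redFct must lie in (0, 1)")
        if not 0.0 < self.crtstp < self.stp0:
            raise ConfigError("need 0 < crtstp < stp0")
        if self.sweep_order is None:
            self.sweep_order = self.selected_currents
        if set(self.sweep_order) != set(self.selected_currents):
            raise ConfigError("sweep_order must permute selected_currents")

    @property
    def n_reductions_bound(self) -> int:
        """Upper bound on step reductions before termination."""
        return int(np.ceil(np.log(self.crtstp / self.stp0)
                           / np.log(self.redFct)))


@dataclass
class PSRun:
    """Audit trail of a single Pattern Search run."""

    names: tuple
    bp_history: list          # [(sf vector, cost)] at every BP renewal
    eval_log: list            # [(sf vector, cost, stp)] every evaluation
    final_sf: ScalingFactors
    final_mse: float
    converged: bool
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_evals(self) -> int:
        return len(self.eval_log)


def ps_optimize(cost, bp0: ScalingFactors, config: PSConfig,
                seed: int | None = None) -> PSRun:
    """Minimize ``cost`` (sf-vector -> scalar) by coordinate Pattern Search.

    ``cost`` must be total: quiescent or otherwise invalid candidates must
    return a finite penalty, never raise.  Non-positive candidate factors
    are rejected as automatic non-improvements without evaluation.
    Ties between +stp and -stp moves keep the +stp candidate.
    """
    names = config.sweep_order
    x0 = np.array([bp0[n] for n in names], dtype=float)
    quantum = config.crtstp / 10.0
    cache: dict = {}
    eval_log: list = []
    budget_left = [config.max_evals]

    def ev(x):
        if np.any(x <= 0.0):
            return np.inf
        key = tuple(np.round(x / quantum).astype(np.int64))
        if key in cache:
            return cache[key]
        if budget_left[0] <= 0:
            raise _BudgetExhausted
        budget_left[0] -= 1
        c = float(cost(x))
        cache[key] = c
        eval_log.append((x.copy(), c, stp))
        return c

    stp = config.stp0
    converged = True
    try:
        bp = x0.copy()
        f_bp = ev(bp)
        bp_history = [(bp.copy(), f_bp)]
        while stp >= config.crtstp:
            np_vec = bp.copy()
            f_np = f_bp
            for j in range(len(names)):
                for sign in (+1.0, -1.0):
                    cand = np_vec.copy()
                    cand[j] += sign * stp
                    f_c = ev(cand)
                    if f_c < f_np:
                        np_vec, f_np = cand, f_c
            if f_np < f_bp:
                bp, f_bp = np_vec, f_np
                bp_history.append((bp.copy(), f_bp))
            else:
                stp *= config.redFct
    except _BudgetExhausted:
        converged = False

    return PSRun(
        names=tuple(names),
        bp_history=bp_history,
        eval_log=eval_log,
        final_sf=ScalingFactors.from_vector(names, bp),
        final_mse=float(f_bp),
        converged=converged,
        seed=seed,
    )


class _BudgetExhausted(Exception):
    pass


# --------------------------------------------------------------- model cost
class TraceMSECost:
    """MSE of the model output against a fixed target, as a function of sf.

    By default every candidate is integrated from the same reference
    state (the target's stored settled state), which makes the cost a
    deterministic function of the scaling factors: at the true factors the
    trajectory stays on the target's limit cycle and the MSE sits at the
    numerical floor.  ``warm_start=True`` instead chains evaluations from
    the previous final state (faster, but path-dependent).  The final
    Na_i and total Ca of the last evaluation are recorded for Table-style
    reporting.
    """

    def __init__(self, target: Trace, names, params: ModelParameters | None = None,
                 base_sf: ScalingFactors | None = None,
                 objective: ObjectiveSpec | None = None,
                 warm_start: bool = False, fixed_cycles: int | None = 12):
        self.target = target
        self.names = tuple(names)
        self.params = params or ModelParameters()
        self.fixed_cycles = fixed_cycles
        if fixed_cycles is not None:
            from dataclasses import replace
            # exact cycle count: stability cannot stop the run early, so the
            # cost is a continuous function of the scaling factors
            self.params = replace(self.params, min_cycles=fixed_cycles,
                                  max_cycles=fixed_cycles)
        self.base_sf = base_sf or ScalingFactors()
        self.objective = objective or ObjectiveSpec()
        self.warm_start = warm_start
        if "final_state" in target.meta:
            self._state0 = CellState.from_dict(target.meta["final_state"])
        else:
            self._state0 = CellState.initial(self.params)
        self._warm = self._state0
        self.n_evals = 0
        self.last_final_state: CellState | None = None

    def sf_of(self, x) -> ScalingFactors:
        sf = self.base_sf
        return sf.updated(**dict(zip(self.names, np.asarray(x, dtype=float))))

    def __call__(self, x) -> float:
        sf = self.sf_of(x)
        start = self._warm if self.warm_start else self._state0
        try:
            trace, final, _ = integrate(start, sf, self.params,
                                        n_cycles=self.fixed_cycles)
        except QuiescentModelError:  # pragma: no cover - integrate signals via trace
            return float(self.objective.penalty_mse)
        self.n_evals += 1
        if trace.quiescent:
            # do not adopt the quiescent state as the next warm start
            return float(self.objective.penalty_mse)
        if self.warm_start:
            self._warm = final
        self.last_final_state = final
        return mse(trace, self.target, self.objective)


# ----------------------------------------------------------------- orp driver
@dataclass
class OrpResult:
    """Aggregate of a multi-run randomized-start optimization."""

    runs: list
    names: tuple
    sf_true: ScalingFactors
    range_pct: float
    seed: int
    final_states: list = field(default_factory=list)  # CellState per run
    frozen: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def final_table(self) -> np.ndarray:
        """(n_runs, p+1) array of final sf values and final MSE."""
        rows = [[run.final_sf[n] for n in self.names] + [run.final_mse]
                for run in self.runs]
        return np.asarray(rows, dtype=float)

    def pooled_bp_points(self) -> np.ndarray:
        """All BP-renewal points of all runs as (sf..., mse) rows."""
        rows = []
        for run in self.runs:
            for x, c in run.bp_history:
                rows.append(list(x) + [c])
        return np.asarray(rows, dtype=float)

    def top_k_indices(self, k: int = 20) -> np.ndarray:
        finals = np.array([r.final_mse for r in self.runs])
        usable = np.flatnonzero(np.isfinite(finals))
        if usable.size < k:
            raise ShortfallError(
                f"top-{k} statistics need {k} usable runs, have {usable.size}")
        order = usable[np.argsort(finals[usable], kind="stable")]
        return order[:k]


def orp_test(target: Trace, sf_true: ScalingFactors, n_runs: int,
             range_pct: float, config: PSConfig, seed: int,
             params: ModelParameters | None = None,
             objective: ObjectiveSpec | None = None,
             base_sf: ScalingFactors | None = None) -> OrpResult:
    """Multi-run Pattern Search from randomized initial parameter sets.

    Each run draws its initial point from ``sf_true`` randomized by
    ``+/- range_pct`` on the selected currents, with its own child seed so
    the whole experiment is reproducible from ``seed``.  Failures of
    individual runs are recorded, not fatal.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    if target.quiescent:
        raise QuiescentModelError("orp target must beat")
    rng_root = np.random.default_rng(seed)
    child_seeds = rng_root.integers(0, 2 ** 31 - 1, size=n_runs)
    runs, states = [], []
    for i in range(n_runs):
        rng = np.random.default_rng(child_seeds[i])
        start = randomize_sf(sf_true, config.selected_currents, range_pct, rng)
        if base_sf is not None:
            start = base_sf.updated(
                **{n: start[n] for n in config.selected_currents})
        cost = TraceMSECost(target, config.selected_currents, params,
                            base_sf=base_sf or sf_true,
                            objective=objective)
        run = ps_optimize(cost, start, config, seed=int(child_seeds[i]))
        runs.append(run)
        states.append(cost.last_final_state)
    return OrpResult(runs=runs, names=tuple(config.selected_currents),
                     sf_true=sf_true, range_pct=range_pct, seed=seed,
                     final_states=states)


def constrained_orp(target: Trace, sf_true: ScalingFactors, n_runs: int,
                    range_pct: float, config: PSConfig, seed: int,
                    frozen: dict, params: ModelParameters | None = None,
                    objective: ObjectiveSpec | None = None) -> OrpResult:
    """orp test with a subset of factors frozen at given values.

    Frozen currents are removed from the search vector; freezing a current
    that is also selected is a configuration error.
    """
    overlap = set(frozen) & set(config.selected_currents)
    if overlap:
        raise ConfigError(f"currents both frozen and selected: {sorted(overlap)}")
    base = sf_true.updated(**{k: float(v) for k, v in frozen.items()})
    result = orp_test(target, sf_true, n_runs, range_pct, config, seed,
                      params=params, objective=objective, base_sf=base)
    result.frozen = dict(frozen)
    return result


def top_k_stats(result: OrpResult, k: int = 20,
                params: ModelParameters | None = None) -> dict:
    """Mean and SE of each sf over the k smallest-final-MSE runs.

    Also reports the mean final log10(MSE) and, when final states were
    recorded, the mean final Na_i (mM) and total Ca (amol).
    SE = sample standard deviation / sqrt(k).
    """
    from .model.cell import ca_total

    idx = result.top_k_indices(k)
    table = result.final_table()[idx]
    p = len(result.names)
    means = table[:, :p].mean(axis=0)
    ses = table[:, :p].std(axis=0, ddof=1) / np.sqrt(k)
    out = {
        "k": int(k),
        "sf_mean": dict(zip(result.names, means.tolist())),
        "sf_se": dict(zip(result.names, ses.tolist())),
        "mean_log10_mse": float(np.mean(np.log10(np.maximum(
            table[:, p], 1e-30)))),
    }
    states = [result.final_states[i] for i in idx
              if result.final_states and result.final_states[i] is not None]
    if states:
        out["mean_Nai"] = float(np.mean([s.Na_i for s in states]))
        out["mean_Catot"] = float(np.mean([ca_total(s, params) for s in states]))
    return out
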