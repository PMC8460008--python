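"""Experiment protocols: strategy scans, maximum mutation rate, sweeps.

Three protocols drive the simulator:

* :func:`strategy_scan` — run the community to steady state for every
  admissible point of a strategy grid and tabulate equilibrium group count,
  productivity (total cells) and wild-type fraction;
* :func:`max_mutation_rate` — per replicate, start at the highest possible
  mutation rate (mu = 1) and descend a geometric schedule until the first mu
  at which the community reaches a non-zero steady state; that mu is the
  maximum mutation rate the strategy withstands before mutational meltdown.
  The aggregate is the mean across replicates of log10(mu_max);
* :func:`sensitivity_sweep` — repeat the mu_max protocol over a strategy set
  for several values of the fission-size-dependence slope sigma or of the
  migration rate nu.

All outputs are tidy tables: one row per atomic observation (strategy x
replicate [x mu]), with excluded runs flagged rather than dropped, plus an
aggregate table recomputable from the atomic rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    REASON_EXTINCT,
    REASON_STEADY,
    run,
    _steady_values as window_means,
)
from .fragmentation import FragmentationStrategy, validate_strategy
from .model_core import ModelParams

__all__ = [
    "ExperimentResult",
    "upper_transect",
    "strategy_grid",
    "default_mu_schedule",
    "strategy_scan",
    "max_mutation_rate",
    "sensitivity_sweep",
    "neighbour_average",
]


@dataclass
class ExperimentResult:
    """Tidy record of one experiment: atomic rows plus their aggregate."""

    kind: str
    params: ModelParams
    seed: int
    table: pd.DataFrame
    aggregate: pd.DataFrame
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# strategy sets
# ---------------------------------------------------------------------------

def upper_transect(n_points: int = 6, s_min: float = 0.02,
                   s_max: float = 0.5) -> list[FragmentationStrategy]:
    """Strategies along the upper diagonal n = 1 - s, from (near) complete
    fragmentation on the left to binary fission at s = 0.5."""
    ss = np.linspace(s_min, s_max, n_points)
    return [FragmentationStrategy(float(s), float(1.0 - s)) for s in ss]


def strategy_grid(ns: int = 5, nn: int = 9) -> list[FragmentationStrategy]:
    """Rectangular (s, n) lattice over (0, 0.5] x (0, 1]; includes
    inadmissible points (scans flag and skip them)."""
    ss = (np.arange(ns) + 0.5) * 0.5 / ns
    nnv = (np.arange(nn) + 0.5) * 1.0 / nn
    return [FragmentationStrategy(float(s), float(n)) for s in ss for n in nnv]


def default_mu_schedule(ratio: float = 10 ** (-0.25),
                        floor: float = 1e-4) -> np.ndarray:
    """Geometric mu schedule descending from 1 to ``floor``."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    n = int(np.floor(np.log(floor) / np.log(ratio) + 1e-9))
    return np.power(ratio, np.arange(n + 1))


# ---------------------------------------------------------------------------
# equilibrium scans
# ---------------------------------------------------------------------------

def strategy_scan(
    strategies: list[FragmentationStrategy],
    params: ModelParams,
    *,
    replicates: int = 1,
    seed: int = 0,
    n_groups: int = 100,
    t_max: float = 5_000.0,
    **run_kwargs,
) -> ExperimentResult:
    """Equilibrium population size per strategy.

    One run per (strategy, replicate); equilibrium values are the means of
    the moving-averaged series over the final window.  Extinct runs report
    zeros; runs that neither equilibrated nor died are flagged ``excluded``.
    Inadmissible strategies are kept in the table with ``valid = False`` and
    NaN outputs.
    """
    master = np.random.Generator(np.random.PCG64(seed))
    ma_w = run_kwargs.get("ma_window", 200)
    ck_w = run_kwargs.get("check_window", 200)
    rows = []
    for strat in strategies:
        valid = validate_strategy(strat)
        for rep in range(replicates):
            if not valid:
                rows.append({"s": strat.s, "n": strat.n, "valid": False,
                             "replicate": rep, "seed": -1, "reason": "skipped",
                             "excluded": True, "N_total": np.nan, "G": np.nan,
                             "wt": np.nan, "mut": np.nan,
                             "wt_fraction": np.nan})
                continue
            run_seed = int(master.integers(1, 2**31 - 1))
            res = run(params, strat, n_groups=n_groups, seed=run_seed,
                      t_max=t_max, **run_kwargs)
            if res.reason == REASON_EXTINCT:
                vals = {"wt": 0.0, "mut": 0.0, "N_total": 0.0, "G": 0.0,
                        "wt_fraction": np.nan}
            elif res.steady is not None:
                vals = res.steady
            else:
                vals = window_means(res.trajectory, ma_w, ck_w) if len(
                    res.trajectory) else {"wt": np.nan, "mut": np.nan,
                                          "N_total": np.nan, "G": np.nan,
                                          "wt_fraction": np.nan}
            rows.append({"s": strat.s, "n": strat.n, "valid": True,
                         "replicate": rep, "seed": run_seed,
                         "reason": res.reason, "excluded": res.excluded,
                         "N_total": vals["N_total"], "G": vals["G"],
                         "wt": vals["wt"], "mut": vals["mut"],
                         "wt_fraction": vals["wt_fraction"]})
    table = pd.DataFrame(rows)
    agg = (table[table["valid"]]
           .groupby(["s", "n"], as_index=False)[["N_total", "G", "wt",
                                                 "wt_fraction"]]
           .mean(numeric_only=True))
    return ExperimentResult("scan", params, seed, table, agg)


# ---------------------------------------------------------------------------
# maximum mutation rate
# ---------------------------------------------------------------------------

def max_mutation_rate(
    strategy: FragmentationStrategy,
    params: ModelParams,
    *,
    schedule: np.ndarray | None = None,
    replicates: int = 10,
    seed: int = 0,
    n_groups: int = 100,
    t_max: float = 5_000.0,
    persistence: str = "steady",
    **run_kwargs,
) -> ExperimentResult:
    """Largest mutation rate the strategy survives, per replicate.

    Descends the mu schedule from its top; the first mu at which the
    community persists is that replicate's mu_max ("ceiling" flag when the
    community already persists at the top of the schedule; "below_floor"
    when it goes extinct everywhere on the schedule).  Aggregate: mean over
    replicates of log10(mu_max), NaN-skipping.

    ``persistence`` selects the operational survival criterion:
    ``"steady"`` (default) requires a detected non-zero steady state;
    ``"alive"`` accepts any run that still holds wild-type cells when
    ``t_max`` is reached — the appropriate reading at small community sizes,
    where the strict 1%-fluctuation criterion can outlast any affordable
    ``t_max`` even though the population is plainly viable.
    """
    if persistence not in ("steady", "alive"):
        raise ValueError("persistence must be 'steady' or 'alive'")
    if not validate_strategy(strategy):
        raise ValueError(f"invalid strategy {strategy}")
    sched = default_mu_schedule() if schedule is None else np.asarray(schedule, float)
    if len(sched) == 0 or np.any(np.diff(sched) >= 0):
        raise ValueError("mu schedule must be strictly decreasing")
    master = np.random.Generator(np.random.PCG64(seed))
    rows = []
    rep_rows = []
    for rep in range(replicates):
        mu_max = np.nan
        flag = "below_floor"
        for k, mu in enumerate(sched):
            run_seed = int(master.integers(1, 2**31 - 1))
            res = run(params.with_(mu=float(mu)), strategy, n_groups=n_groups,
                      seed=run_seed, t_max=t_max, **run_kwargs)
            if persistence == "steady":
                persisted = res.reason == REASON_STEADY
            else:
                alive_wt = (len(res.trajectory) > 0
                            and res.trajectory["wt_total"].iloc[-1] > 0)
                persisted = res.reason == REASON_STEADY or (
                    res.reason == "t_max" and alive_wt)
            rows.append({"s": strategy.s, "n": strategy.n, "replicate": rep,
                         "mu": float(mu), "seed": run_seed,
                         "reason": res.reason, "excluded": res.excluded,
                         "persisted": persisted})
            if persisted:
                mu_max = float(mu)
                flag = "ceiling" if k == 0 else "ok"
                break
        rep_rows.append({"s": strategy.s, "n": strategy.n, "replicate": rep,
                         "mu_max": mu_max, "flag": flag,
                         "log10_mu_max": np.log10(mu_max) if mu_max == mu_max
                         else np.nan})
    table = pd.DataFrame(rows)
    per_rep = pd.DataFrame(rep_rows)
    with np.errstate(invalid="ignore"):
        mean_log = float(np.nanmean(per_rep["log10_mu_max"].to_numpy())) if (
            per_rep["log10_mu_max"].notna().any()) else np.nan
    agg = pd.DataFrame([{
        "s": strategy.s, "n": strategy.n,
        "mean_log10_mu_max": mean_log,
        "n_replicates": replicates,
        "n_persisting": int(per_rep["mu_max"].notna().sum()),
        "n_ceiling": int((per_rep["flag"] == "ceiling").sum()),
        "n_below_floor": int((per_rep["flag"] == "below_floor").sum()),
    }])
    return ExperimentResult("maxmu", params, seed, table, agg,
                            meta={"per_replicate": per_rep,
                                  "schedule": sched.tolist()})


# ---------------------------------------------------------------------------
# sigma / nu sensitivity
# ---------------------------------------------------------------------------

def sensitivity_sweep(
    axis: str,
    values,
    strategies: list[FragmentationStrategy],
    params: ModelParams,
    *,
    schedule: np.ndarray | None = None,
    replicates: int = 3,
    seed: int = 0,
    **kwargs,
) -> ExperimentResult:
    """mu_max over a strategy set for each value of ``sigma`` or ``nu``.

    With a single value equal to the baseline this reduces exactly to
    repeated :func:`max_mutation_rate` calls (regression identity).
    """
    if axis not in ("sigma", "nu"):
        raise ValueError("axis must be 'sigma' or 'nu'")
    master = np.random.Generator(np.random.PCG64(seed))
    tables = []
    aggs = []
    for v in values:
        p = params.with_(**{axis: float(v)})
        for strat in strategies:
            sub_seed = int(master.integers(1, 2**31 - 1))
            res = max_mutation_rate(strat, p, schedule=schedule,
                                    replicates=replicates, seed=sub_seed,
                                    **kwargs)
            t = res.table.copy()
            t[axis] = float(v)
            tables.append(t)
            a = res.aggregate.copy()
            a[axis] = float(v)
            aggs.append(a)
    table = pd.concat(tables, ignore_index=True)
    agg = pd.concat(aggs, ignore_index=True)
    return ExperimentResult(f"sweep_{axis}", params, seed, table, agg,
                            meta={"axis": axis, "values": list(values)})


# ---------------------------------------------------------------------------
# nearest-neighbour smoothing of grid tables
# ---------------------------------------------------------------------------

def neighbour_average(table: pd.DataFrame, value_col: str,
                      s_col: str = "s", n_col: str = "n") -> pd.DataFrame:
    """Replace each grid point's value by the mean over itself and its
    von Neumann neighbours present in the table with a finite value.

    Points absent from the table (e.g. outside the strategy triangle) never
    contribute; a point whose own value is NaN stays NaN.
    """
    df = table.copy()
    s_vals = np.sort(np.unique(np.round(df[s_col].to_numpy(), 12)))
    n_vals = np.sort(np.unique(np.round(df[n_col].to_numpy(), 12)))
    i_s = np.searchsorted(s_vals, np.round(df[s_col].to_numpy(), 12))
    i_n = np.searchsorted(n_vals, np.round(df[n_col].to_numpy(), 12))
    lookup = {(int(a), int(b)): v
              for a, b, v in zip(i_s, i_n, df[value_col].to_numpy())}
    out = np.empty(len(df))
    for row, (a, b) in enumerate(zip(i_s, i_n)):
        centre = lookup[(int(a), int(b))]
        if not np.isfinite(centre):
            out[row] = np.nan
            continue
        vals = [centre]
        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            v = lookup.get((int(a) + da, int(b) + db))
            if v is not None and np.isfinite(v):
                vals.append(v)
        out[row] = float(np.mean(vals))
    df[value_col] = out
    return df
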