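"""Replicate orchestration: niche succession, fixation and second-hit studies.

The drivers here reproduce the simulator's headline computational
experiments:

* mean niche-succession period as a function of the symmetric-division
  probability ``Ps`` (and of the bias factor ``B``);
* stem-cell-count dynamics under the homeostatic feedback, with the
  ``B < 0.5`` regime of unbounded niche growth;
* the probability that a marked (sporadically mutated) stem-cell lineage wins
  niche succession under different heterozygous phenotypes;
* the mean time to the somatic second hit on the remaining APC allele in an
  all-heterozygous (FAP) niche.

Replicates are seeded from a master seed through a
:class:`numpy.random.SeedSequence` counter scheme, so every experiment is
reproducible end to end.  A reduced *stem-only oracle* — an event-driven
birth/death simulation of just the niche, exploiting the fact that
division-type draws depend only on the stem count and never on the transit
lattice — provides an independent route to the succession-period
distribution and is checked against the full lattice model in the tests.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import RunResult, run_engine
from .grid_core import SimulationParams
from .mutation import HetEffect, Mode, MutationConfig, SecondHitScope

__all__ = [
    "derive_seeds",
    "run_simulation",
    "ReplicateSummary",
    "FixationEstimate",
    "SecondHitEstimate",
    "StemCountSummary",
    "OracleResult",
    "succession_period_vs_ps",
    "stem_count_dynamics",
    "estimate_fixation_probability",
    "mean_time_to_second_hit",
    "stem_only_oracle",
    "table3_variants",
    "table4_variants",
    "run_fig3",
    "run_table2",
    "run_table3",
    "run_table4",
]


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Derive ``n`` replicate seeds (< 2**31) from a master seed.

    ``stream`` separates independent experiments run from the same master
    seed.  The scheme is stable across runs and versions.
    """
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_simulation(
    params: SimulationParams,
    mutation_config: Optional[MutationConfig] = None,
    seed: int = 0,
    **kwargs,
) -> RunResult:
    """Single-run driver; see :func:`cryptdrift.engine.run_engine`."""
    return run_engine(params, mutation_config, seed, **kwargs)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ReplicateSummary:
    """Aggregate statistics over seeded replicates of one experiment."""

    n_replicates: int
    mean_stem_count: Optional[float] = None
    stem_count_p5_p95: Optional[Tuple[float, float]] = None
    mean_succession_period_days: Optional[float] = None
    fixation_fraction: Optional[float] = None
    mean_iterations_to_second_hit: Optional[float] = None
    n_censored: int = 0
    outcome_flags: Dict[str, int] = field(default_factory=dict)


@dataclass
class FixationEstimate:
    fraction: float
    n_fixed: int
    n_reps: int
    n_flagged: int          # runs not ending in a clean succession (overflow etc.)
    outcome_flags: Dict[str, int]


@dataclass
class SecondHitEstimate:
    mean_iterations: Optional[float]
    times: np.ndarray       # uncensored second-hit iterations
    n_censored: int
    n_reps: int


@dataclass
class StemCountSummary:
    mean: float
    p5: float
    p95: float
    classification: str     # homeostatic | elevated | unbounded
    per_replicate_means: np.ndarray
    n_overflow: int
    n_reps: int


# ---------------------------------------------------------------------------
# full-lattice experiments


def succession_period_vs_ps(
    ps_values: Sequence[float],
    n_reps: int = 20,
    master_seed: int = 0,
    *,
    bias: float = 1.0,
    params_base: Optional[SimulationParams] = None,
    backend: str = "abm",
) -> pd.DataFrame:
    """Mean niche-succession period (days) for each symmetric-division probability.

    Runs with no succession (overflow, censoring at ``max_iterations``,
    extinction) are excluded from the mean and counted in ``n_censored``.
    With a single replicate the table is still produced but flagged low-power.
    """
    base = params_base or SimulationParams()
    rows = []
    for j, ps in enumerate(ps_values):
        params = SimulationParams(
            **{**_params_dict(base), "ps": float(ps), "bias": float(bias)}
        )
        if backend == "oracle":
            oracle = stem_only_oracle(
                ps, bias=bias, n0=params.n0, n_reps=n_reps,
                master_seed=master_seed, params=params, stream=100 + j,
            )
            periods = oracle.periods_days
            n_censored = oracle.n_censored
        elif backend == "abm":
            periods_l = []
            n_censored = 0
            for seed in derive_seeds(master_seed, n_reps, stream=100 + j):
                r = run_engine(params, seed=seed, stop_on=("succession",))
                if r.stop_reason == "succession":
                    periods_l.append(r.succession_iteration * params.dt / 24.0)
                else:
                    n_censored += 1
            periods = np.asarray(periods_l)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        rows.append(
            {
                "ps": ps,
                "bias": bias,
                "n_reps": n_reps,
                "n_censored": n_censored,
                "mean_period_days": float(np.mean(periods)) if len(periods) else np.nan,
                "sd_period_days": float(np.std(periods, ddof=1)) if len(periods) > 1 else np.nan,
                "low_power": n_reps < 5,
            }
        )
    return pd.DataFrame(rows)


def stem_count_dynamics(
    ps: float,
    bias: float,
    n_reps: int = 20,
    horizon: int = 5000,
    master_seed: int = 0,
    *,
    burn_in: int = 0,
    params_base: Optional[SimulationParams] = None,
    stream: int = 200,
) -> StemCountSummary:
    """Mean and 5th-95th percentile band of the stem count over replicate runs.

    Runs continue to ``horizon`` iterations (they do not stop at succession);
    the band pools all post-burn-in iterations of all replicates.  Growth is
    classified ``unbounded`` if any replicate trips the stem-overflow guard,
    ``homeostatic`` if the pooled mean stays within 15% of the niche target,
    and ``elevated`` otherwise.
    """
    base = params_base or SimulationParams()
    params = SimulationParams(**{**_params_dict(base), "ps": float(ps), "bias": float(bias)})
    pooled = []
    rep_means = []
    n_overflow = 0
    for seed in derive_seeds(master_seed, n_reps, stream=stream):
        r = run_engine(params, seed=seed, stop_on=(), max_iterations=horizon)
        if r.stop_reason == "stem_overflow":
            n_overflow += 1
        series = r.stem_counts[burn_in:] if len(r.stem_counts) > burn_in else r.stem_counts
        pooled.append(series)
        rep_means.append(series.mean())
    pooled_arr = np.concatenate(pooled)
    mean = float(pooled_arr.mean())
    if n_overflow > 0:
        cls = "unbounded"
    elif mean <= 1.15 * params.n0:
        cls = "homeostatic"
    else:
        cls = "elevated"
    return StemCountSummary(
        mean=mean,
        p5=float(np.percentile(pooled_arr, 5)),
        p95=float(np.percentile(pooled_arr, 95)),
        classification=cls,
        per_replicate_means=np.asarray(rep_means),
        n_overflow=n_overflow,
        n_reps=n_reps,
    )


def estimate_fixation_probability(
    het_effect: Optional[HetEffect] = None,
    n_reps: int = 100,
    master_seed: int = 0,
    *,
    params: Optional[SimulationParams] = None,
    stream: int = 300,
    backend: str = "abm",
) -> FixationEstimate:
    """Fraction of replicates in which the marked stem lineage wins succession.

    One of the ``n0`` founding stem cells is heterozygous (sporadic first
    hit) and expresses ``het_effect``; the second hit is disabled.  Runs that
    end without a clean succession (stem overflow / censoring / extinction)
    count as non-fixation and are flagged.
    """
    params = params or SimulationParams(ps=0.1, bias=1.0)
    mc = MutationConfig(mode=Mode.SPORADIC, mutation_prob=0.0, het_effect=het_effect)
    n_fixed = 0
    flags: Dict[str, int] = {}
    for seed in derive_seeds(master_seed, n_reps, stream=stream):
        if backend == "oracle":
            o = _oracle_single(params, seed, mode=Mode.SPORADIC, het_effect=het_effect)
            if o["stop"] == "succession" and o["winner"] == o["marked"]:
                n_fixed += 1
            elif o["stop"] != "succession":
                flags[o["stop"]] = flags.get(o["stop"], 0) + 1
        else:
            r = run_engine(params, mc, seed=seed, stop_on=("succession",))
            if r.fixed_by_marked:
                n_fixed += 1
            elif r.stop_reason != "succession":
                flags[r.stop_reason] = flags.get(r.stop_reason, 0) + 1
    n_flagged = sum(flags.values())
    return FixationEstimate(
        fraction=n_fixed / n_reps,
        n_fixed=n_fixed,
        n_reps=n_reps,
        n_flagged=n_flagged,
        outcome_flags=flags,
    )


def mean_time_to_second_hit(
    het_effect: Optional[HetEffect] = None,
    mu: float = 0.001,
    n_reps: int = 20,
    master_seed: int = 0,
    *,
    params: Optional[SimulationParams] = None,
    scope: SecondHitScope = SecondHitScope.STEM_ONLY,
    stream: int = 400,
) -> SecondHitEstimate:
    """Mean iteration of the first somatic second hit in an all-heterozygous niche.

    Every replicate starts with all founding stem cells heterozygous (FAP)
    expressing ``het_effect``, runs until the remaining wild-type allele
    mutates in a cell within ``scope``, and reports that iteration; runs
    reaching ``max_iterations`` without a hit are censored and excluded from
    the mean.
    """
    params = params or SimulationParams(ps=0.1, bias=1.0)
    mc = MutationConfig(
        mode=Mode.FAP, mutation_prob=mu, het_effect=het_effect, second_hit_scope=scope
    )
    times = []
    n_censored = 0
    for seed in derive_seeds(master_seed, n_reps, stream=stream):
        r = run_engine(params, mc, seed=seed, stop_on=("second_hit",))
        if r.second_hit_iteration is not None:
            times.append(r.second_hit_iteration)
        else:
            n_censored += 1
    times_arr = np.asarray(times, dtype=float)
    return SecondHitEstimate(
        mean_iterations=float(times_arr.mean()) if len(times_arr) else None,
        times=times_arr,
        n_censored=n_censored,
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# stem-only oracle


@dataclass
class OracleResult:
    periods_days: np.ndarray
    winners: np.ndarray
    n_censored: int
    n_extinct: int
    n_overflow: int
    n_reps: int


def _oracle_single(
    params: SimulationParams,
    seed: int,
    *,
    mode: Mode = Mode.NORMAL,
    het_effect: Optional[HetEffect] = None,
    synchronized_start: bool = False,
    max_steps: Optional[int] = None,
) -> dict:
    """One event-driven run of the reduced stem-compartment model.

    Mirrors the lattice engine's timing exactly: a founder whose G1 clock
    starts at ``t0`` steps first divides at step ``TC - t0 + 2`` and every
    inter-division interval is ``TC + 3`` steps (the transitions through
    quiescence, G1 entry and mitosis each consume one step).  Division-type
    draws use the stem count at the start of the division's time step, as in
    the full model.
    """
    rng = np.random.default_rng(int(seed))
    n0 = params.n0
    tg1s = params.tg1_stem_steps
    tcs = params.tc_stem_steps
    max_steps = int(max_steps if max_steps is not None else params.max_iterations)
    het = het_effect or HetEffect()
    het_ps = het.ps if het.ps is not None else params.ps
    het_bias = het.bias if het.bias is not None else params.bias
    het_tcs = int(round(tcs * het.cycle_time_multiplier))
    het_tg1s = int(round(tg1s * het.cycle_time_multiplier))

    anc: List[int] = list(range(n0))
    het_flag: List[bool] = [False] * n0
    marked = -1
    if mode == Mode.FAP:
        het_flag = [True] * n0
    elif mode == Mode.SPORADIC:
        marked = int(rng.integers(0, n0))
        het_flag[marked] = True
    alive = set(range(n0))
    anc_counts = np.zeros(n0, dtype=int)
    anc_counts[:n0] = 1
    heap: List[Tuple[int, int, int]] = []
    seq = n0
    for i in range(n0):
        t0 = 0 if synchronized_start else int(rng.integers(0, het_tg1s if het_flag[i] else tg1s))
        tc_i = het_tcs if het_flag[i] else tcs
        heapq.heappush(heap, (tc_i - t0 + 2, i, i))

    def finish(stop, step):
        survivors = np.nonzero(anc_counts)[0]
        return {
            "stop": stop,
            "step": step,
            "winner": int(survivors[0]) if stop == "succession" else None,
            "marked": marked if marked >= 0 else None,
        }

    if n0 == 1:
        return finish("succession", 0)
    while heap:
        step = heap[0][0]
        if step > max_steps:
            return finish("max_iterations", max_steps)
        ns0 = len(alive)
        pdc = min(1.0, max(0.0, ns0 / n0 - 0.5))
        batch = []
        while heap and heap[0][0] == step:
            _, _, cell = heapq.heappop(heap)
            if cell in alive:
                batch.append(cell)
        for cell in batch:
            if cell not in alive:
                continue
            ps_i = het_ps if het_flag[cell] else params.ps
            b_i = het_bias if het_flag[cell] else params.bias
            tc_i = het_tcs if het_flag[cell] else tcs
            pdb = min(1.0, pdc * b_i)
            if rng.random() < ps_i:
                if rng.random() < pdb:
                    alive.discard(cell)
                    anc_counts[anc[cell]] -= 1
                    continue
                # self-renewal: a second stem daughter on the same clock
                anc.append(anc[cell])
                het_flag.append(het_flag[cell])
                new = len(anc) - 1
                alive.add(new)
                anc_counts[anc[cell]] += 1
                heapq.heappush(heap, (step + tc_i + 3, seq, new))
                seq += 1
            heapq.heappush(heap, (step + tc_i + 3, seq, cell))
            seq += 1
        if not alive:
            return finish("extinction", step)
        if int(np.count_nonzero(anc_counts)) == 1:
            return finish("succession", step)
        if len(alive) > params.max_stem_cells:
            return finish("stem_overflow", step)
    return finish("extinction", max_steps)  # pragma: no cover


def stem_only_oracle(
    ps: float,
    bias: float = 1.0,
    n0: int = 10,
    n_reps: int = 100,
    master_seed: int = 0,
    *,
    params: Optional[SimulationParams] = None,
    synchronized_start: bool = False,
    stream: int = 500,
) -> OracleResult:
    """Succession-period distribution from the reduced stem-only model.

    With ``ps = 0`` no lineage can go extinct and every run is censored.
    """
    base = params or SimulationParams()
    params = SimulationParams(
        **{**_params_dict(base), "ps": float(ps), "bias": float(bias), "n0": n0,
           "n_cols": max(base.n_cols, n0)}
    )
    periods = []
    winners = []
    n_censored = n_extinct = n_overflow = 0
    for seed in derive_seeds(master_seed, n_reps, stream=stream):
        o = _oracle_single(params, seed, synchronized_start=synchronized_start)
        if o["stop"] == "succession":
            periods.append(o["step"] * params.dt / 24.0)
            winners.append(o["winner"])
        elif o["stop"] == "extinction":
            n_extinct += 1
        elif o["stop"] == "stem_overflow":
            n_overflow += 1
        else:
            n_censored += 1
    return OracleResult(
        periods_days=np.asarray(periods),
        winners=np.asarray(winners, dtype=int),
        n_censored=n_censored,
        n_extinct=n_extinct,
        n_overflow=n_overflow,
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# named reproductions


def table3_variants() -> Dict[str, Optional[HetEffect]]:
    """Heterozygous-phenotype variants of the fixation experiment.

    The control symmetric-division probability is 0.1; "doubled" means the
    mutant stem cell uses 0.2.
    """
    return {
        "no_effect": None,
        "ps_doubled": HetEffect(ps=0.2),
        "ps_doubled_bias_0.6": HetEffect(ps=0.2, bias=0.6),
        "ps_doubled_bias_0.5": HetEffect(ps=0.2, bias=0.5),
        "rate_doubled": HetEffect(cycle_time_multiplier=0.5),
    }


def table4_variants() -> Dict[str, Optional[HetEffect]]:
    """Heterozygous-phenotype variants of the second-hit experiment."""
    return {
        "no_effect": None,
        "increased_symmetric": HetEffect(ps=0.2),
        "increased_biased_symmetric": HetEffect(ps=0.2, bias=0.5),
    }


def run_fig3(
    ps_values: Sequence[float] = (0.02, 0.05, 0.1, 0.2),
    n_reps: int = 20,
    master_seed: int = 0,
    backend: str = "abm",
) -> pd.DataFrame:
    """Succession period vs symmetric-division probability (no bias)."""
    return succession_period_vs_ps(
        ps_values, n_reps=n_reps, master_seed=master_seed, backend=backend
    )


def run_table2(
    ps_values: Sequence[float] = (0.2, 0.1),
    bias_values: Sequence[float] = (1.0, 0.8, 0.6),
    n_reps: int = 20,
    master_seed: int = 0,
    horizon: int = 5000,
) -> pd.DataFrame:
    """Stem-count statistics and succession periods over a Ps x B grid."""
    rows = []
    k = 0
    for ps in ps_values:
        for b in bias_values:
            k += 1
            dyn = stem_count_dynamics(
                ps, b, n_reps=n_reps, horizon=horizon,
                master_seed=master_seed, burn_in=480, stream=600 + k,
            )
            per = succession_period_vs_ps(
                [ps], n_reps=n_reps, master_seed=master_seed, bias=b,
            ).iloc[0]
            rows.append(
                {
                    "ps": ps,
                    "bias": b,
                    "mean_stem_count": dyn.mean,
                    "stem_p5": dyn.p5,
                    "stem_p95": dyn.p95,
                    "classification": dyn.classification,
                    "mean_period_days": per["mean_period_days"],
                    "n_censored": int(per["n_censored"]),
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def run_table3(
    n_reps: int = 100, master_seed: int = 0, backend: str = "abm"
) -> pd.DataFrame:
    """Fixation probability of the marked lineage per phenotype variant."""
    rows = []
    for k, (name, het) in enumerate(table3_variants().items()):
        est = estimate_fixation_probability(
            het, n_reps=n_reps, master_seed=master_seed, stream=300 + k, backend=backend
        )
        rows.append(
            {
                "variant": name,
                "fixation_fraction": est.fraction,
                "fixation_percent": 100.0 * est.fraction,
                "n_fixed": est.n_fixed,
                "n_flagged": est.n_flagged,
                "n_reps": est.n_reps,
            }
        )
    return pd.DataFrame(rows)


def run_table4(
    n_reps: int = 20, mu: float = 0.001, master_seed: int = 0
) -> pd.DataFrame:
    """Mean iterations to the second hit per phenotype variant."""
    rows = []
    for k, (name, het) in enumerate(table4_variants().items()):
        est = mean_time_to_second_hit(
            het, mu=mu, n_reps=n_reps, master_seed=master_seed, stream=400 + k
        )
        rows.append(
            {
                "variant": name,
                "mean_iterations": est.mean_iterations,
                "n_censored": est.n_censored,
                "n_reps": est.n_reps,
            }
        )
    return pd.DataFrame(rows)


def _params_dict(p: SimulationParams) -> dict:
    return {
        "n_cols": p.n_cols,
        "n_rows": p.n_rows,
        "n0": p.n0,
        "tc_stem": p.tc_stem,
        "tc_transit": p.tc_transit,
        "tg1_stem": p.tg1_stem,
        "tg1_transit": p.tg1_transit,
        "num_div_max": p.num_div_max,
        "dt": p.dt,
        "ps": p.ps,
        "bias": p.bias,
        "max_iterations": p.max_iterations,
        "max_stem_cells": p.max_stem_cells,
        "wrap_columns": p.wrap_columns,
    }
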