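"""Array-based crypt simulator (numba-jitted) behind the experiment drivers.

Runs exactly the lattice rules of :mod:`cryptdrift.grid_core` — synchronous
cell-cycle transitions, division with insertion priorities, mitotic-pressure
migration, top-row shedding — plus the division-type model of
:mod:`cryptdrift.division_niche` and the APC layer of
:mod:`cryptdrift.mutation`, over flat typed arrays so that replicate studies
(hundreds of runs of thousands of iterations) complete in seconds.  Time is
kept in integer steps of ``dt``; all randomness comes from numba's
Mersenne-Twister stream seeded once per run, so a (parameters, seed) pair
reproduces bit-identically.

The object model in ``grid_core`` is the readable reference; the test suite
checks this engine against it statistically and on exact invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .grid_core import SimulationParams
from .mutation import HetEffect, Mode, MutationConfig, SecondHitScope

__all__ = ["RunResult", "run_engine", "STOP_REASONS"]

# cell-cycle states
_Q, _G1, _SG2, _MIT = 0, 1, 2, 3
# stop codes
STOP_REASONS = {
    0: "max_iterations",
    1: "succession",
    2: "second_hit",
    3: "stem_overflow",
    4: "extinction",
}


@dataclass
class RunResult:
    """Outcome and per-iteration time series of one simulation run."""

    seed: int
    n_iterations: int
    stop_reason: str
    succession_iteration: Optional[int]
    winner: Optional[int]
    second_hit_iteration: Optional[int]
    marked_ancestor: Optional[int]
    stem_counts: np.ndarray
    lineage_counts: Optional[np.ndarray]
    n_born: int
    n_shed: int
    n_final: int
    final_cells: Optional[dict] = field(default=None, repr=False)

    @property
    def fixed_by_marked(self) -> bool:
        """Did the marked lineage win a completed niche succession?"""
        return (
            self.stop_reason == "succession"
            and self.marked_ancestor is not None
            and self.winner == self.marked_ancestor
        )


@njit(cache=True)
def _insertion_site(cnt, n_cols, n_rows, xm, ym):
    """Insertion priorities for a non-stem daughter; returns (x, y)."""
    xe = (xm + 1) % n_cols
    xw = (xm - 1) % n_cols
    # 1. empty north
    if ym + 1 < n_rows and cnt[xm, ym + 1] == 0:
        return xm, ym + 1
    # 2. empty east/west
    e_empty = cnt[xe, ym] == 0
    w_empty = cnt[xw, ym] == 0
    if e_empty and w_empty:
        return (xe, ym) if np.random.randint(0, 2) == 0 else (xw, ym)
    if e_empty:
        return xe, ym
    if w_empty:
        return xw, ym
    # 3. empty south
    if ym - 1 >= 0 and cnt[xm, ym - 1] == 0:
        return xm, ym - 1
    # 4. occupied north/east/west, uniform
    if ym + 1 < n_rows:
        k = np.random.randint(0, 3)
        if k == 0:
            return xm, ym + 1
        elif k == 1:
            return xe, ym
        return xw, ym
    return (xe, ym) if np.random.randint(0, 2) == 0 else (xw, ym)


@njit(cache=True)
def _run_kernel(
    seed,
    n_cols, n_rows, n0, K,
    tcs, tg1s, tct, tg1t,          # timings in steps
    htcs, htg1s,                   # heterozygous stem timings in steps
    ps, bias, het_ps, het_bias, het_on,
    mu, hit_unit, scope_any,
    mode,                          # 0 normal, 1 fap, 2 sporadic
    stop_on_succession, stop_on_second_hit,
    max_iter, max_stem,
    record_lineage,
    alive, state, x, y, tis, age, ndiv, stk, anc, al,
    cnt, free_stack, mit_buf, tie_buf, anc_counts,
    stem_series, anc_series,
):
    np.random.seed(seed)
    C = alive.shape[0]
    n_free = 0
    for i in range(C - 1, n0 - 1, -1):
        free_stack[n_free] = i
        n_free += 1
    # founders: one stem per column, desynchronised within G1
    for k in range(n0):
        alive[k] = 1
        state[k] = _G1
        x[k] = k
        y[k] = 0
        tis[k] = np.random.randint(0, tg1s)
        age[k] = 0
        ndiv[k] = 0
        stk[k] = K
        anc[k] = k
        al[k] = 0
        anc_counts[k] = 1
    marked = -1
    if mode == 1:       # FAP: germ-line first hit in every founder
        for k in range(n0):
            al[k] = 1
    elif mode == 2:     # sporadic: one seeded heterozygote
        marked = np.random.randint(0, n0)
        al[marked] = 1
    ns = n0
    stem_series[0] = ns
    if record_lineage:
        for k in range(n0):
            anc_series[0, k] = anc_counts[k]
    n_born = 0
    n_shed = 0
    succ_iter = -1
    winner = -1
    hit_iter = -1
    stop_code = 0
    n_iter = 0
    if n0 == 1 and stop_on_succession:
        return (0, 1, 0, 0, -1, 0, 0, ns, marked)

    for it in range(1, max_iter + 1):
        ns0 = ns
        pdc = ns0 / n0 - 0.5
        if pdc < 0.0:
            pdc = 0.0
        elif pdc > 1.0:
            pdc = 1.0
        # --- cell-cycle transitions (synchronous: one rule per cell) ---
        n_mit = 0
        for i in range(C):
            if alive[i] == 0:
                continue
            age[i] += 1
            s = state[i]
            if s == _Q:
                if stk[i] > 0:
                    state[i] = _G1
                    tis[i] = 0
            else:
                if stk[i] == K:
                    if het_on and al[i] == 1:
                        tg1 = htg1s
                        tc = htcs
                    else:
                        tg1 = tg1s
                        tc = tcs
                else:
                    tg1 = tg1t
                    tc = tct
                if s == _G1:
                    if tis[i] < tg1:
                        tis[i] += 1
                    else:
                        state[i] = _SG2
                        tis[i] = 0
                elif s == _SG2:
                    if tis[i] < tc - tg1:
                        tis[i] += 1
                    else:
                        state[i] = _MIT
                        tis[i] = 0
                        mit_buf[n_mit] = i
                        n_mit += 1
                else:  # resolves within the step it was entered; never persists
                    mit_buf[n_mit] = i
                    n_mit += 1
        # --- commit divisions in stable index order ---
        for m in range(n_mit):
            i = mit_buf[m]
            if stk[i] == K:
                if het_on and al[i] == 1:
                    psi = het_ps
                    bi = het_bias
                else:
                    psi = ps
                    bi = bias
                pdb = pdc * bi
                if pdb > 1.0:
                    pdb = 1.0
                if np.random.random() < psi:
                    if np.random.random() < pdb:
                        dtype = 1  # symmetric differentiation
                    else:
                        dtype = 2  # symmetric self-renewal
                else:
                    dtype = 0      # asymmetric
            else:
                dtype = 1
            # per-division second-hit draw: mother's wild allele flips pre-split
            if hit_unit == 0 and mu > 0.0 and al[i] == 1:
                if np.random.random() < mu:
                    al[i] = 2
            # in-place daughter (the mother agent continues)
            state[i] = _Q
            tis[i] = 0
            ndiv[i] += 1
            if stk[i] == K:
                if dtype == 1:
                    stk[i] = K - 1
                    ns -= 1
                    anc_counts[anc[i]] -= 1
                    stk_b = K - 1
                elif dtype == 2:
                    stk_b = K
                else:
                    stk_b = K - 1
            else:
                stk[i] -= 1
                stk_b = stk[i]
            # new daughter agent
            j = free_stack[n_free - 1]
            n_free -= 1
            alive[j] = 1
            state[j] = _Q
            tis[j] = 0
            age[j] = 0
            ndiv[j] = 0
            stk[j] = stk_b
            anc[j] = anc[i]
            al[j] = al[i]
            if stk_b == K:
                # stem daughter: east or west in the niche row, occupancy ignored
                if np.random.randint(0, 2) == 0:
                    x[j] = (x[i] + 1) % n_cols
                else:
                    x[j] = (x[i] - 1) % n_cols
                y[j] = 0
                ns += 1
                anc_counts[anc[j]] += 1
            else:
                xj, yj = _insertion_site(cnt, n_cols, n_rows, x[i], y[i])
                x[j] = xj
                y[j] = yj
            cnt[x[j], y[j]] += 1
            n_born += 1
            # per-daughter second-hit draws
            if hit_unit == 1 and mu > 0.0:
                if al[i] == 1 and np.random.random() < mu:
                    al[i] = 2
                if al[j] == 1 and np.random.random() < mu:
                    al[j] = 2
            if hit_iter < 0:
                if scope_any:
                    if al[i] == 2 or al[j] == 2:
                        hit_iter = it
                else:
                    if (al[i] == 2 and stk[i] == K) or (al[j] == 2 and stk[j] == K):
                        hit_iter = it
        # --- migration: resolve crowding column by column ---
        for c in range(n_cols):
            crowded = False
            for yy in range(n_rows):
                if cnt[c, yy] > 1:
                    crowded = True
                    break
            if not crowded:
                continue
            while True:
                ty = -1
                for yy in range(n_rows):
                    if cnt[c, yy] > 1:
                        if yy == 0:
                            has_nonstem = False
                            for i in range(C):
                                if alive[i] == 1 and x[i] == c and y[i] == 0 and stk[i] < K:
                                    has_nonstem = True
                                    break
                            if not has_nonstem:
                                continue  # all-stem niche site may crowd
                        ty = yy
                        break
                if ty < 0:
                    break
                # oldest non-stem resident; age ties broken uniformly
                best_age = -1
                n_tie = 0
                for i in range(C):
                    if alive[i] == 1 and x[i] == c and y[i] == ty and stk[i] < K:
                        if age[i] > best_age:
                            best_age = age[i]
                            tie_buf[0] = i
                            n_tie = 1
                        elif age[i] == best_age:
                            tie_buf[n_tie] = i
                            n_tie += 1
                if n_tie > 1:
                    mover = tie_buf[np.random.randint(0, n_tie)]
                else:
                    mover = tie_buf[0]
                # first empty row strictly above; the contiguous block shifts up
                top = ty + 1
                while top < n_rows and cnt[c, top] > 0:
                    top += 1
                for i in range(C):
                    if alive[i] == 1 and x[i] == c and ty < y[i] < top:
                        cnt[c, y[i]] -= 1
                        y[i] += 1
                        if y[i] >= n_rows:
                            alive[i] = 0
                            free_stack[n_free] = i
                            n_free += 1
                            n_shed += 1
                        else:
                            cnt[c, y[i]] += 1
                cnt[c, ty] -= 1
                y[mover] += 1
                if y[mover] >= n_rows:
                    alive[mover] = 0
                    free_stack[n_free] = mover
                    n_free += 1
                    n_shed += 1
                else:
                    cnt[c, y[mover]] += 1
        # --- end-of-iteration bookkeeping, stop conditions ---
        n_iter = it
        stem_series[it] = ns
        if record_lineage:
            for k in range(n0):
                anc_series[it, k] = anc_counts[k]
        if ns == 0:
            stop_code = 4
            break
        if hit_iter >= 0 and stop_on_second_hit:
            stop_code = 2
            break
        n_alive_lineages = 0
        last = -1
        for k in range(n0):
            if anc_counts[k] > 0:
                n_alive_lineages += 1
                last = k
        if n_alive_lineages == 1:
            if succ_iter < 0:
                succ_iter = it
                winner = last
            if stop_on_succession:
                stop_code = 1
                break
        if ns > max_stem:
            stop_code = 3
            break
    return (n_iter, stop_code, succ_iter, winner, hit_iter, n_born, n_shed, ns, marked)


def run_engine(
    params: SimulationParams,
    mutation_config: Optional[MutationConfig] = None,
    seed: int = 0,
    *,
    stop_on: Tuple[str, ...] = ("succession",),
    max_iterations: Optional[int] = None,
    record_lineage: bool = False,
    return_final_state: bool = False,
) -> RunResult:
    """Run one seeded simulation to its stop condition.

    ``stop_on`` may contain ``"succession"`` and/or ``"second_hit"``; the
    overflow guard and ``max_iterations`` always apply.  Identical
    ``(params, mutation_config, seed)`` give bit-identical results.
    """
    mc = mutation_config or MutationConfig()
    unknown = set(stop_on) - {"succession", "second_hit"}
    if unknown:
        raise ValueError(f"unknown stop conditions: {sorted(unknown)}")
    max_iter = int(max_iterations if max_iterations is not None else params.max_iterations)
    het = mc.het_effect or HetEffect()
    het_ps = het.ps if het.ps is not None else params.ps
    het_bias = het.bias if het.bias is not None else params.bias
    htcs = int(round(params.tc_stem_steps * het.cycle_time_multiplier))
    htg1s = int(round(params.tg1_stem_steps * het.cycle_time_multiplier))
    if not 0 < htg1s < htcs:
        raise ValueError("heterozygous cycle multiplier collapses the stem cycle")
    mode = {Mode.NORMAL: 0, Mode.FAP: 1, Mode.SPORADIC: 2}[mc.mode]
    capacity = params.n_cols * params.n_rows + 2 * params.max_stem_cells + 64

    alive = np.zeros(capacity, dtype=np.uint8)
    state = np.zeros(capacity, dtype=np.uint8)
    x = np.zeros(capacity, dtype=np.int32)
    y = np.zeros(capacity, dtype=np.int32)
    tis = np.zeros(capacity, dtype=np.int32)
    age = np.zeros(capacity, dtype=np.int32)
    ndiv = np.zeros(capacity, dtype=np.int32)
    stk = np.zeros(capacity, dtype=np.int32)
    anc = np.zeros(capacity, dtype=np.int32)
    al = np.zeros(capacity, dtype=np.uint8)
    cnt = np.zeros((params.n_cols, params.n_rows), dtype=np.int32)
    cnt[: params.n0, 0] = 1
    free_stack = np.zeros(capacity, dtype=np.int32)
    mit_buf = np.zeros(capacity, dtype=np.int32)
    tie_buf = np.zeros(capacity, dtype=np.int32)
    anc_counts = np.zeros(params.n0, dtype=np.int32)
    stem_series = np.zeros(max_iter + 1, dtype=np.int32)
    anc_series = (
        np.zeros((max_iter + 1, params.n0), dtype=np.int32)
        if record_lineage
        else np.zeros((1, params.n0), dtype=np.int32)
    )

    (n_iter, stop_code, succ_iter, winner, hit_iter, n_born, n_shed, ns, marked) = _run_kernel(
        np.uint32(seed),
        params.n_cols, params.n_rows, params.n0, params.num_div_max,
        params.tc_stem_steps, params.tg1_stem_steps,
        params.tc_transit_steps, params.tg1_transit_steps,
        htcs, htg1s,
        params.ps, params.bias, het_ps, het_bias,
        mc.het_effect is not None,
        mc.mutation_prob,
        0 if mc.hit_unit == "division" else 1,
        mc.second_hit_scope == SecondHitScope.ANY_CELL,
        mode,
        "succession" in stop_on, "second_hit" in stop_on,
        max_iter, params.max_stem_cells,
        record_lineage,
        alive, state, x, y, tis, age, ndiv, stk, anc, al,
        cnt, free_stack, mit_buf, tie_buf, anc_counts,
        stem_series, anc_series,
    )

    final_cells = None
    if return_final_state:
        live = alive.astype(bool)
        final_cells = {
            "state": state[live].copy(),
            "x": x[live].copy(),
            "y": y[live].copy(),
            "time_in_state": tis[live].copy(),
            "age": age[live].copy(),
            "num_divisions": ndiv[live].copy(),
            "stemness_index": stk[live].copy(),
            "ancestor": anc[live].copy(),
            "n_mutated_alleles": al[live].copy(),
        }
    return RunResult(
        seed=int(seed),
        n_iterations=int(n_iter),
        stop_reason=STOP_REASONS[int(stop_code)],
        succession_iteration=int(succ_iter) if succ_iter >= 0 else None,
        winner=int(winner) if winner >= 0 else None,
        second_hit_iteration=int(hit_iter) if hit_iter >= 0 else None,
        marked_ancestor=int(marked) if marked >= 0 else None,
        stem_counts=stem_series[: n_iter + 1].copy(),
        lineage_counts=anc_series[: n_iter + 1].copy() if record_lineage else None,
        n_born=int(n_born),
        n_shed=int(n_shed),
        n_final=int(alive.sum()),
        final_cells=final_cells,
    )
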