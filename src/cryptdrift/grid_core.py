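"""The 2-D lattice crypt: cell agents, cell-cycle rules, insertion, migration, shedding.

The crypt is modelled as an ``N x M`` lattice, as if the cylindrical crypt were
slit open and rolled out flat: row 0 is the stem-cell niche at the crypt base,
row ``M-1`` is the luminal top where cells are shed.  Columns wrap laterally
(cylinder topology) by default.  More than one cell may transiently occupy a
lattice site; mitotic pressure (the :func:`migrate` rule) resolves crowding by
pushing the oldest resident upward, and cells pushed past the top row are
removed by :func:`shed`.

Each cell is an agent with a cell-cycle state machine
(``QUIESCENT -> G1 -> S_G2 -> MITOSIS``), a position, a ``stemness`` level
quantised in steps of ``1/Num_div_max`` (1 = stem cell, 0 = terminally
differentiated), the identity of its founding stem-cell lineage, and a pair of
APC allele flags.  Stem cells (stemness 1) live in the niche row and never
leave it; every division of a non-stem cell lowers the daughters' stemness by
one quantum until they become post-mitotic.

This module is the plain-object reference implementation of the lattice rules;
:mod:`cryptdrift.engine` runs the same rules over flat arrays for speed and is
cross-validated against this implementation in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np

from .division_niche import (
    DivisionType,
    biased_differentiation_probability,
    corrected_differentiation_probability,
    sample_division_type,
)

__all__ = [
    "CellState",
    "CellAgent",
    "SimulationParams",
    "CryptState",
    "init_crypt",
    "step_cell_cycle",
    "choose_insertion_site",
    "perform_division",
    "migrate",
    "shed",
    "step_crypt",
    "snapshot_tsv",
]

Site = Tuple[int, int]


class CellState(enum.IntEnum):
    QUIESCENT = 0
    G1 = 1
    S_G2 = 2
    MITOSIS = 3


@dataclass(frozen=True)
class SimulationParams:
    """All lattice, timing and division-model parameters.

    Defaults are the reference parameter set: a 10 x 50 lattice holding a
    niche of 10 stem cells, stem-cell cycle 24 h (12 h of it in G1),
    transit-cell cycle 12 h (4 h in G1), at most 6 transit divisions before
    terminal differentiation, and a 30-minute time step.
    """

    n_cols: int = 10
    n_rows: int = 50
    n0: int = 10
    tc_stem: float = 24.0       # stem-cell cycle time, hours
    tc_transit: float = 12.0    # transit-cell cycle time, hours
    tg1_stem: float = 12.0      # stem-cell G1 duration, hours
    tg1_transit: float = 4.0    # transit-cell G1 duration, hours
    num_div_max: int = 6
    dt: float = 0.5             # time step, hours
    ps: float = 0.1             # symmetric-division probability
    bias: float = 1.0           # bias factor B on the differentiation probability
    max_iterations: int = 200_000
    max_stem_cells: int = 200   # overflow guard on the niche population
    wrap_columns: bool = True

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("lattice dimensions must be positive")
        if not 0 < self.n0 <= self.n_cols:
            raise ValueError(
                f"n0={self.n0} must be in 1..n_cols={self.n_cols} "
                "(one founding stem cell per niche column)"
            )
        if not 0.0 <= self.ps <= 1.0:
            raise ValueError(f"ps={self.ps} outside [0, 1]")
        if self.bias <= 0:
            raise ValueError(f"bias={self.bias} must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.tg1_stem < self.tc_stem):
            raise ValueError("need 0 < TG1_stem < TC_stem")
        if not (0 < self.tg1_transit < self.tc_transit):
            raise ValueError("need 0 < TG1_transit < TC_transit")
        if self.num_div_max < 1:
            raise ValueError("num_div_max must be >= 1")
        for name in ("tc_stem", "tc_transit", "tg1_stem", "tg1_transit"):
            v = getattr(self, name)
            if abs(v / self.dt - round(v / self.dt)) > 1e-9:
                raise ValueError(f"{name}={v} h is not a multiple of dt={self.dt} h")
        if self.max_iterations < 1 or self.max_stem_cells < 1:
            raise ValueError("max_iterations and max_stem_cells must be >= 1")

    # timing in integer time steps, used by both implementations
    def steps(self, hours: float) -> int:
        return int(round(hours / self.dt))

    @property
    def tg1_stem_steps(self) -> int:
        return self.steps(self.tg1_stem)

    @property
    def tc_stem_steps(self) -> int:
        return self.steps(self.tc_stem)

    @property
    def tg1_transit_steps(self) -> int:
        return self.steps(self.tg1_transit)

    @property
    def tc_transit_steps(self) -> int:
        return self.steps(self.tc_transit)


@dataclass(eq=False)
class CellAgent:
    """One epithelial cell anchored to the lattice."""

    state: CellState
    x: int
    y: int
    time_in_state: float = 0.0   # hours
    age: float = 0.0             # hours since birth
    num_divisions: int = 0
    stemness: Fraction = Fraction(1)
    ancestor: int = 0
    apc_alleles: Tuple[int, int] = (0, 0)

    @property
    def is_stem(self) -> bool:
        return self.stemness == 1

    @property
    def n_mutated_alleles(self) -> int:
        return self.apc_alleles[0] + self.apc_alleles[1]

    @property
    def position(self) -> Site:
        return (self.x, self.y)


@dataclass
class CryptState:
    """Lattice occupancy plus all live cells and the iteration clock."""

    n_cols: int
    n_rows: int
    cells: List[CellAgent] = field(default_factory=list)
    occupancy: Dict[Site, List[CellAgent]] = field(default_factory=dict)
    iteration: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    n_born: int = 0
    n_shed: int = 0
    _pending_shed: List[CellAgent] = field(default_factory=list)

    def residents(self, x: int, y: int) -> List[CellAgent]:
        return self.occupancy.get((x, y), [])

    def add_cell(self, cell: CellAgent) -> None:
        self.cells.append(cell)
        self.occupancy.setdefault((cell.x, cell.y), []).append(cell)

    def move_cell(self, cell: CellAgent, x: int, y: int) -> None:
        """Move a cell; a destination above the top row marks it for shedding."""
        res = self.occupancy[(cell.x, cell.y)]
        res.remove(cell)
        if not res:
            del self.occupancy[(cell.x, cell.y)]
        cell.x, cell.y = x, y
        if y >= self.n_rows:
            self._pending_shed.append(cell)
        else:
            self.occupancy.setdefault((x, y), []).append(cell)

    def stem_cells(self) -> List[CellAgent]:
        return [c for c in self.cells if c.is_stem]

    def stem_ancestor_counts(self, n0: Optional[int] = None) -> Dict[int, int]:
        counts: Dict[int, int] = {k: 0 for k in range(n0)} if n0 else {}
        for c in self.cells:
            if c.is_stem:
                counts[c.ancestor] = counts.get(c.ancestor, 0) + 1
        return counts

    def check_consistency(self) -> None:
        """Assert occupancy and cell positions agree (used by tests)."""
        seen = 0
        for (x, y), res in self.occupancy.items():
            if not (0 <= x < self.n_cols and 0 <= y < self.n_rows):
                raise AssertionError(f"occupied site {(x, y)} outside lattice")
            for c in res:
                if (c.x, c.y) != (x, y):
                    raise AssertionError("occupancy/position mismatch")
            seen += len(res)
        if seen != len(self.cells):
            raise AssertionError("occupancy does not cover all live cells")
        for c in self.cells:
            if c.is_stem and c.y != 0:
                raise AssertionError("stem cell outside the niche row")


def init_crypt(params: SimulationParams, seed: int) -> CryptState:
    """Seed the niche with ``n0`` founding stem cells, one per column.

    All founders start in G1 with independently drawn times already spent in
    that state (a whole number of time steps below TG1), so their divisions
    desynchronise from the first cycle onward.
    """
    rng = np.random.default_rng(seed)
    crypt = CryptState(n_cols=params.n_cols, n_rows=params.n_rows, rng=rng)
    for k in range(params.n0):
        t0 = int(rng.integers(0, params.tg1_stem_steps)) * params.dt
        crypt.add_cell(
            CellAgent(
                state=CellState.G1,
                x=k,
                y=0,
                time_in_state=t0,
                stemness=Fraction(1),
                ancestor=k,
            )
        )
    return crypt


def step_cell_cycle(
    cell: CellAgent,
    params: SimulationParams,
    tc: Optional[float] = None,
    tg1: Optional[float] = None,
) -> CellAgent:
    """Advance one cell's cycle state machine by one time step (in place).

    Stem cells use the stem timings, all other cycling cells the transit
    timings; ``tc``/``tg1`` override both (used for mutant phenotypes).
    Terminally differentiated cells (stemness 0) stay quiescent forever.
    Mitosis itself is resolved by :func:`perform_division`, not here.
    """
    if tc is None:
        tc = params.tc_stem if cell.is_stem else params.tc_transit
    if tg1 is None:
        tg1 = params.tg1_stem if cell.is_stem else params.tg1_transit
    cell.age += params.dt
    eps = 1e-9
    if cell.state == CellState.QUIESCENT:
        if cell.stemness > 0:
            cell.state = CellState.G1
            cell.time_in_state = 0.0
    elif cell.state == CellState.G1:
        if cell.time_in_state < tg1 - eps:
            cell.time_in_state += params.dt
        else:
            cell.state = CellState.S_G2
            cell.time_in_state = 0.0
    elif cell.state == CellState.S_G2:
        if cell.time_in_state < tc - tg1 - eps:
            cell.time_in_state += params.dt
        else:
            cell.state = CellState.MITOSIS
            cell.time_in_state = 0.0
    elif cell.state == CellState.MITOSIS:
        pass
    else:  # pragma: no cover - enum exhausts the states
        raise ValueError(f"unknown cell state {cell.state!r}")
    return cell


def choose_insertion_site(
    crypt: CryptState,
    mother_pos: Site,
    daughter_is_stem: bool,
    rng: np.random.Generator,
) -> Site:
    """Pick the lattice site for a newly created daughter cell.

    Non-stem daughters follow the priority list: (1) empty north neighbour,
    (2) empty east/west neighbour (coin flip if both empty), (3) empty south
    neighbour, (4) a uniformly chosen occupied neighbour among north, east and
    west.  Stem daughters go east or west within the niche row (coin flip),
    regardless of occupancy, so they never leave the niche.  Neighbours off
    the grid (north of the top row, south of the niche) are not candidates.
    """
    xm, ym = mother_pos
    east = ((xm + 1) % crypt.n_cols, ym)
    west = ((xm - 1) % crypt.n_cols, ym)
    if daughter_is_stem:
        return east if rng.integers(0, 2) == 0 else west
    north = (xm, ym + 1) if ym + 1 < crypt.n_rows else None
    south = (xm, ym - 1) if ym - 1 >= 0 else None
    if north is not None and not crypt.residents(*north):
        return north
    lateral_empty = [s for s in (east, west) if not crypt.residents(*s)]
    if lateral_empty:
        return lateral_empty[int(rng.integers(0, len(lateral_empty)))]
    if south is not None and not crypt.residents(*south):
        return south
    occupied = [s for s in (north, east, west) if s is not None]
    return occupied[int(rng.integers(0, len(occupied)))]


def perform_division(
    crypt: CryptState,
    mother: CellAgent,
    division_type: Optional[DivisionType],
    rng: np.random.Generator,
    params: SimulationParams,
) -> Tuple[CellAgent, CellAgent]:
    """Resolve one mitosis into two daughters.

    The mother agent continues as the first daughter at its own site (its age
    and division count carry over); the second daughter is a new agent placed
    through :func:`choose_insertion_site`.  Stem mothers follow the sampled
    ``division_type``; non-stem mothers always produce two daughters one
    differentiation quantum below themselves (``division_type`` is ignored).
    Dividing a terminally differentiated cell is a programming fault.
    """
    if mother.state != CellState.MITOSIS:
        raise ValueError("mother is not in mitosis")
    if mother.stemness == 0:
        raise ValueError("a terminally differentiated cell cannot divide")
    quantum = Fraction(1, params.num_div_max)
    if mother.is_stem:
        if division_type is None:
            raise ValueError("stem division requires a division type")
        if division_type == DivisionType.ASYMMETRIC:
            stem_a, stem_b = Fraction(1), Fraction(1) - quantum
        elif division_type == DivisionType.SYM_SELF:
            stem_a, stem_b = Fraction(1), Fraction(1)
        else:  # SYM_DIFF
            stem_a, stem_b = Fraction(1) - quantum, Fraction(1) - quantum
    else:
        stem_a = stem_b = mother.stemness - quantum
    daughter_is_stem = stem_b == 1
    site = choose_insertion_site(crypt, mother.position, daughter_is_stem, rng)
    mother.state = CellState.QUIESCENT
    mother.time_in_state = 0.0
    mother.num_divisions += 1
    mother.stemness = stem_a
    daughter = CellAgent(
        state=CellState.QUIESCENT,
        x=site[0],
        y=site[1],
        time_in_state=0.0,
        age=0.0,
        num_divisions=0,
        stemness=stem_b,
        ancestor=mother.ancestor,
        apc_alleles=mother.apc_alleles,
    )
    crypt.add_cell(daughter)
    crypt.n_born += 1
    return mother, daughter


def migrate(crypt: CryptState) -> CryptState:
    """Resolve mitotic pressure column by column.

    Scanning each column bottom-to-top, any site holding more than one cell
    has its oldest non-stem resident pushed up one row; the contiguous run of
    occupied sites above shifts up with it, the topmost cell absorbing the
    push at the first gap or being pushed past the top row (marked for
    shedding).  Repeats until no site is over-occupied, except that the niche
    row may hold any number of stem cells per site.  Stem cells are never
    displaced.  Age ties are broken uniformly at random from the run's stream.
    """
    for c in range(crypt.n_cols):
        while True:
            target = None
            for yy in range(crypt.n_rows):
                res = crypt.residents(c, yy)
                if len(res) > 1:
                    movable = [cell for cell in res if not cell.is_stem]
                    if not movable:
                        continue  # all-stem niche site: allowed to crowd
                    target = (yy, movable)
                    break
            if target is None:
                break
            yy, movable = target
            max_age = max(cell.age for cell in movable)
            ties = [cell for cell in movable if cell.age == max_age]
            mover = ties[int(crypt.rng.integers(0, len(ties)))] if len(ties) > 1 else ties[0]
            # first empty row strictly above the crowded site
            top = yy + 1
            while top < crypt.n_rows and crypt.residents(c, top):
                top += 1
            for row in range(top - 1, yy, -1):
                for cell in list(crypt.residents(c, row)):
                    crypt.move_cell(cell, c, row + 1)
            crypt.move_cell(mover, c, yy + 1)
    return crypt


def shed(crypt: CryptState) -> Tuple[CryptState, int]:
    """Delete every cell pushed past the top row; return the count.

    Cells resident in the top row itself persist until a further push from
    below moves them off the lattice.
    """
    n = len(crypt._pending_shed)
    if n:
        doomed = set(id(c) for c in crypt._pending_shed)
        crypt.cells = [c for c in crypt.cells if id(c) not in doomed]
        crypt._pending_shed.clear()
        crypt.n_shed += n
    return crypt, n


def step_crypt(
    crypt: CryptState,
    params: SimulationParams,
    mutation_config=None,
) -> dict:
    """Advance the whole crypt by one synchronous time step.

    Order of play: snapshot the stem count, advance every cell's cycle, commit
    all divisions (in stable cell order, against the live occupancy; crowding
    created by simultaneous insertions is legal and resolved next), then
    migrate and shed.  Returns event counts for the step.
    """
    from . import mutation as mut  # local import to avoid a cycle

    ns0 = sum(1 for c in crypt.cells if c.is_stem)
    pd_corr = corrected_differentiation_probability(ns0, params.n0)
    mothers: List[CellAgent] = []
    for cell in crypt.cells:
        tc = tg1 = None
        if mutation_config is not None:
            eff = mut.effective_params(cell, params, mutation_config)
            tc, tg1 = (eff.tc_stem, eff.tg1_stem) if cell.is_stem else (eff.tc_transit, eff.tg1_transit)
        step_cell_cycle(cell, params, tc=tc, tg1=tg1)
        if cell.state == CellState.MITOSIS and cell.stemness > 0:
            mothers.append(cell)
    n_divisions = len(mothers)
    n_hits = 0
    for mother in mothers:
        if mother.is_stem:
            ps, bias = params.ps, params.bias
            if mutation_config is not None:
                eff = mut.effective_params(mother, params, mutation_config)
                ps, bias = eff.ps, eff.bias
            pd_b = biased_differentiation_probability(pd_corr, bias)
            dtype = sample_division_type(ps, pd_b, crypt.rng)
        else:
            dtype = DivisionType.SYM_DIFF
        if mutation_config is not None:
            n_hits += mut.apply_division_hit(mother, mutation_config, crypt.rng)
        a, b = perform_division(crypt, mother, dtype, crypt.rng, params)
        if mutation_config is not None:
            n_hits += mut.apply_daughter_hits((a, b), mutation_config, crypt.rng)
    migrate(crypt)
    _, n_shed = shed(crypt)
    crypt.iteration += 1
    return {
        "divisions": n_divisions,
        "births": n_divisions,
        "shed": n_shed,
        "second_hits": n_hits,
    }


_STATE_CODE = {
    CellState.QUIESCENT: "Q",
    CellState.G1: "G",
    CellState.S_G2: "S",
    CellState.MITOSIS: "M",
}


def snapshot_tsv(crypt: CryptState, num_div_max: int = 6) -> str:
    """Render the lattice as TSV text, top row first.

    Each occupied site is ``state:stemness:ancestor`` (stemness as the
    quantised numerator over ``num_div_max``); empty sites are ``.``;
    co-resident cells are joined with ``|``.
    """
    lines = []
    for y in range(crypt.n_rows - 1, -1, -1):
        row = []
        for x in range(crypt.n_cols):
            res = crypt.residents(x, y)
            if not res:
                row.append(".")
            else:
                row.append(
                    "|".join(
                        f"{_STATE_CODE[c.state]}:{int(c.stemness * num_div_max)}/{num_div_max}:SC{c.ancestor}"
                        for c in res
                    )
                )
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
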