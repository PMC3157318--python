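"""Two-allele APC genotype dynamics and the heterozygous phenotype.

Every cell carries two APC allele flags that can only flip from wild-type (0)
to mutated (1).  Three initial conditions are modelled:

* ``NORMAL`` — all alleles wild-type;
* ``FAP`` — every founding stem cell is heterozygous (germ-line first hit);
* ``SPORADIC`` — exactly one founding stem cell is heterozygous.

The remaining wild-type allele of a heterozygous cell can acquire a somatic
"second hit" during division: one Bernoulli(mu) draw per division flips the
dividing cell's wild allele so both daughters inherit the homozygous genotype
(``hit_unit="division"``, the default); alternatively one independent draw per
daughter (``hit_unit="daughter"``).  First hits in wild-type cells are
disabled by default: the experiments all start from a pre-existing
heterozygote.

A heterozygous *stem* cell may express an altered division phenotype
(:class:`HetEffect`): an overridden symmetric-division probability, an
overridden bias factor, and/or a scaled cell-cycle time.  Homozygous-mutant
cells carry no further phenotype here; reaching homozygosity is the endpoint
the second-hit experiments measure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .grid_core import CellAgent, CryptState, SimulationParams

__all__ = [
    "Mode",
    "SecondHitScope",
    "HetEffect",
    "MutationConfig",
    "EffectiveParams",
    "init_genotypes",
    "effective_params",
    "attempt_second_hit",
    "apply_division_hit",
    "apply_daughter_hits",
    "detect_second_hit",
]


class Mode(enum.Enum):
    NORMAL = "normal"
    FAP = "fap"
    SPORADIC = "sporadic"


class SecondHitScope(enum.Enum):
    """Which cells count for the second-hit endpoint.

    Only stem-cell lineages persist in the crypt (non-stem cells are shed
    within days), so ``STEM_ONLY`` is the default endpoint; ``ANY_CELL`` is
    available for sensitivity analysis and is always the earlier endpoint.
    """

    STEM_ONLY = "stem_only"
    ANY_CELL = "any_cell"


@dataclass(frozen=True)
class HetEffect:
    """Phenotype of a cell with exactly one mutated APC allele.

    ``None`` overrides inherit the wild-type value.  The cycle-time
    multiplier scales both TC and TG1 of heterozygous *stem* cells (0.5
    doubles the division rate).
    """

    ps: Optional[float] = None
    bias: Optional[float] = None
    cycle_time_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.ps is not None and not 0.0 <= self.ps <= 1.0:
            raise ValueError(f"het ps={self.ps} outside [0, 1]")
        if self.bias is not None and self.bias <= 0:
            raise ValueError(f"het bias={self.bias} must be positive")
        if self.cycle_time_multiplier <= 0:
            raise ValueError("cycle_time_multiplier must be positive")

    @property
    def is_neutral(self) -> bool:
        return self.ps is None and self.bias is None and self.cycle_time_multiplier == 1.0


@dataclass(frozen=True)
class MutationConfig:
    mode: Mode = Mode.NORMAL
    mutation_prob: float = 0.0
    het_effect: Optional[HetEffect] = None
    second_hit_scope: SecondHitScope = SecondHitScope.STEM_ONLY
    hit_unit: str = "division"   # "division" | "daughter"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError(f"mutation_prob={self.mutation_prob} outside [0, 1]")
        if self.hit_unit not in ("division", "daughter"):
            raise ValueError(f"unknown hit_unit {self.hit_unit!r}")
        if self.mode == Mode.NORMAL and self.het_effect is not None and not self.het_effect.is_neutral:
            raise ValueError("NORMAL mode forbids a heterozygous phenotype effect")


@dataclass(frozen=True)
class EffectiveParams:
    """Division-relevant parameters a given cell actually uses."""

    ps: float
    bias: float
    tc_stem: float
    tg1_stem: float
    tc_transit: float
    tg1_transit: float


def init_genotypes(
    crypt: CryptState, config: MutationConfig, rng: np.random.Generator
) -> CryptState:
    """Stamp initial APC genotypes onto a freshly initialised crypt."""
    stems = crypt.stem_cells()
    if config.mode == Mode.FAP:
        for c in stems:
            c.apc_alleles = (1, 0)
    elif config.mode == Mode.SPORADIC:
        marked = int(rng.integers(0, len(stems)))
        stems[marked].apc_alleles = (1, 0)
    return crypt


def effective_params(
    cell: CellAgent, base: SimulationParams, config: Optional[MutationConfig]
) -> EffectiveParams:
    """Resolve the parameters this cell divides under.

    Wild-type and homozygous-mutant cells use the base parameters; a
    heterozygous cell expresses the configured :class:`HetEffect`.  The
    cycle-time multiplier is a stem-cell phenotype: transit timings are never
    scaled.
    """
    eff = EffectiveParams(
        ps=base.ps,
        bias=base.bias,
        tc_stem=base.tc_stem,
        tg1_stem=base.tg1_stem,
        tc_transit=base.tc_transit,
        tg1_transit=base.tg1_transit,
    )
    if config is None or config.het_effect is None:
        return eff
    if cell.n_mutated_alleles != 1:
        return eff
    h = config.het_effect
    return EffectiveParams(
        ps=h.ps if h.ps is not None else base.ps,
        bias=h.bias if h.bias is not None else base.bias,
        tc_stem=base.tc_stem * h.cycle_time_multiplier,
        tg1_stem=base.tg1_stem * h.cycle_time_multiplier,
        tc_transit=base.tc_transit,
        tg1_transit=base.tg1_transit,
    )


def attempt_second_hit(
    daughter: CellAgent, mu: float, rng: np.random.Generator
) -> CellAgent:
    """One Bernoulli(mu) draw on a just-created daughter's wild-type allele.

    Only heterozygous cells are eligible; flips are permanent (0 -> 1 only).
    """
    if mu > 0.0 and daughter.n_mutated_alleles == 1 and rng.random() < mu:
        daughter.apc_alleles = (1, 1)
    return daughter


def apply_division_hit(
    mother: CellAgent, config: MutationConfig, rng: np.random.Generator
) -> int:
    """Per-division hit draw, taken on the mother as she divides.

    A hit flips the mother's remaining wild allele before the split, so both
    daughters inherit the homozygous genotype.  Returns the number of hits
    (0 or 1).  No-op unless ``hit_unit == "division"``.
    """
    if config.hit_unit != "division" or config.mutation_prob <= 0.0:
        return 0
    if mother.n_mutated_alleles == 1 and rng.random() < config.mutation_prob:
        mother.apc_alleles = (1, 1)
        return 1
    return 0


def apply_daughter_hits(
    daughters: Sequence[CellAgent], config: MutationConfig, rng: np.random.Generator
) -> int:
    """Per-daughter hit draws after a division.  No-op unless ``hit_unit == "daughter"``."""
    if config.hit_unit != "daughter" or config.mutation_prob <= 0.0:
        return 0
    n = 0
    for d in daughters:
        before = d.n_mutated_alleles
        attempt_second_hit(d, config.mutation_prob, rng)
        n += int(d.n_mutated_alleles == 2 and before == 1)
    return n


def detect_second_hit(
    crypt: CryptState, scope: SecondHitScope = SecondHitScope.STEM_ONLY
) -> Optional[int]:
    """Return the current iteration if a cell in scope is homozygous-mutant."""
    for c in crypt.cells:
        if c.n_mutated_alleles == 2 and (
            scope == SecondHitScope.ANY_CELL or c.is_stem
        ):
            return crypt.iteration
    return None
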