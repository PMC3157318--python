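"""Stochastic stem-cell division-type model and niche-succession bookkeeping.

A stem-cell division produces 0, 1 or 2 stem-cell daughters.  With symmetric-
division probability ``Ps`` a division is symmetric; a symmetric division then
differentiates (0 stem daughters) with the *differentiation probability* ``Pd``
or self-renews (2 stem daughters) with ``1 - Pd``.  The outcome probabilities
are therefore

    P0 = Ps * Pd        (two differentiated daughters)
    P1 = 1 - Ps         (asymmetric: one stem, one differentiated)
    P2 = Ps * (1 - Pd)  (two stem daughters)

Homeostasis of the niche is enforced through a corrected differentiation
probability that responds linearly to the current stem count ``Ns`` relative
to the target niche size ``N0``:

    Pd_corrected = clip(Ns/N0 - 1/2, 0, 1)

so that ``Pd = 1/2`` at ``Ns = N0``, falling to 0 at ``Ns/N0 = 1/2`` and
saturating at 1 at ``Ns/N0 = 3/2``.  A multiplicative bias factor ``B``
(applied after clipping, so the attainable range is ``[0, B]`` for ``B <= 1``)
models a cell-intrinsic shift of symmetric divisions towards stem-cell progeny:
``B < 1`` favours self-renewal and inflates the niche.

Niche succession is the stochastic takeover of the whole niche by the
descendants of a single founding stem cell; it is detected from per-ancestor
stem counts and timed in days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DivisionType",
    "DivisionOutcomeProbs",
    "NicheTrace",
    "corrected_differentiation_probability",
    "biased_differentiation_probability",
    "division_outcome_probabilities",
    "sample_division_type",
    "detect_succession",
    "succession_period",
]


class DivisionType(enum.Enum):
    """Fate of a stem-cell division."""

    ASYMMETRIC = "asymmetric"  # one stem daughter, one differentiated
    SYM_DIFF = "sym_diff"      # two differentiated daughters (lineage may die)
    SYM_SELF = "sym_self"      # two stem daughters (lineage expands)


@dataclass(frozen=True)
class DivisionOutcomeProbs:
    """Probabilities that a stem-cell division yields 0, 1 or 2 stem daughters."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name, p in (("p0", self.p0), ("p1", self.p1), ("p2", self.p2)):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(self.p0 + self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p0, self.p1, self.p2)


def corrected_differentiation_probability(ns: int, n0: int) -> float:
    """Homeostatic differentiation probability ``clip(ns/n0 - 1/2, 0, 1)``.

    Parameters
    ----------
    ns:
        Current number of stem cells in the niche (snapshot at the start of
        the iteration in which the division occurs).
    n0:
        Target (initial) niche size.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be positive, got {n0}")
    if ns < 0:
        raise ValueError(f"ns must be non-negative, got {ns}")
    return float(min(1.0, max(0.0, ns / n0 - 0.5)))


def biased_differentiation_probability(pd_corrected: float, bias: float) -> float:
    """Apply the bias factor ``B`` to an already-clipped differentiation probability.

    The product ``B * Pd`` is clipped to ``[0, 1]``; for ``B <= 1`` the
    attainable range is ``[0, B]``.
    """
    if bias <= 0:
        raise ValueError(f"bias factor must be positive, got {bias}")
    if not 0.0 <= pd_corrected <= 1.0:
        raise ValueError(f"pd_corrected={pd_corrected} outside [0, 1]")
    return float(min(1.0, bias * pd_corrected))


def division_outcome_probabilities(ps: float, pd_biased: float) -> DivisionOutcomeProbs:
    """Outcome probabilities ``(P0, P1, P2) = (Ps*Pd, 1-Ps, Ps*(1-Pd))``."""
    if not 0.0 <= ps <= 1.0:
        raise ValueError(f"ps={ps} outside [0, 1]")
    if not 0.0 <= pd_biased <= 1.0:
        raise ValueError(f"pd_biased={pd_biased} outside [0, 1]")
    return DivisionOutcomeProbs(
        p0=ps * pd_biased,
        p1=1.0 - ps,
        p2=ps * (1.0 - pd_biased),
    )


def sample_division_type(
    ps: float, pd_biased: float, rng: np.random.Generator
) -> DivisionType:
    """Draw the fate of one stem-cell division.

    A first uniform draw decides symmetric vs asymmetric (symmetric iff
    ``Ps`` exceeds the draw); a second decides differentiation vs
    self-renewal (differentiation iff ``Pd`` exceeds the draw).
    """
    if rng.random() < ps:
        if rng.random() < pd_biased:
            return DivisionType.SYM_DIFF
        return DivisionType.SYM_SELF
    return DivisionType.ASYMMETRIC


def detect_succession(stem_ancestor_counts: Mapping) -> Optional[object]:
    """Return the dominant ancestor if exactly one lineage holds the niche.

    Returns ``None`` while two or more founding lineages still have live stem
    cells.  A niche with zero stem cells is a degenerate outcome (niche
    extinction), not a succession, and raises ``ValueError``.
    """
    survivors = [a for a, n in stem_ancestor_counts.items() if n > 0]
    if not survivors:
        raise ValueError("no stem cells alive: niche extinction, not succession")
    if len(survivors) == 1:
        return survivors[0]
    return None


def succession_period(trace: "NicheTrace | int", dt: float = 0.5) -> float:
    """Convert a succession iteration into a period in days.

    Parameters
    ----------
    trace:
        Either a :class:`NicheTrace` whose ``succession_iteration`` is set, or
        the succession iteration itself.
    dt:
        Simulation time step in hours.
    """
    if isinstance(trace, NicheTrace):
        if trace.succession_iteration is None:
            raise ValueError("trace has no succession event")
        it = trace.succession_iteration
    else:
        it = int(trace)
    if it < 0:
        raise ValueError("succession iteration must be non-negative")
    return it * dt / 24.0


@dataclass
class NicheTrace:
    """Per-iteration record of the stem compartment of one run.

    ``lineage_counts[t, k]`` is the number of live stem cells descending from
    founding stem cell ``k`` at iteration ``t``; rows sum to ``n_stem[t]``.
    """

    n_stem: np.ndarray
    lineage_counts: np.ndarray
    ancestors: Sequence[str] = field(default_factory=list)
    succession_iteration: Optional[int] = None
    dominant_ancestor: Optional[str] = None

    def __post_init__(self) -> None:
        self.n_stem = np.asarray(self.n_stem)
        self.lineage_counts = np.asarray(self.lineage_counts)
        if self.lineage_counts.ndim != 2:
            raise ValueError("lineage_counts must be 2-D (iterations x ancestors)")
        if len(self.n_stem) != len(self.lineage_counts):
            raise ValueError("n_stem and lineage_counts length mismatch")
        if not self.ancestors:
            self.ancestors = [f"SC{k}" for k in range(self.lineage_counts.shape[1])]
        if self.lineage_counts.sum(axis=1).tolist() != self.n_stem.tolist():
            raise ValueError("per-ancestor counts must sum to n_stem at every iteration")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.lineage_counts, columns=list(self.ancestors))
        df.insert(0, "n_stem", self.n_stem)
        df.insert(0, "iteration", np.arange(len(self.n_stem)))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
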