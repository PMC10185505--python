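"""Pareto-stratified model selection with a controlled lookahead.

Each candidate configuration's validation performance is a point in 3D:
(number of hits, quality score, fraction of answers), all three
larger-is-better.  Iterating maximal (non-dominated) front extraction
yields a Pareto stratification; sorting each stratum by quality gives a
total order.  Walking that order, the validation quality is compared with
the test quality of the same configuration, stopping as soon as the test
quality is at least as good or within a relative displacement of 0.2.  The
number of comparisons performed is the *lookahead number*: it measures the
controlled information leak from the test set (1 = the classical,
leak-free selection; values above 4 are flagged as not acceptable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ParetoPoint",
    "LookaheadResult",
    "pareto_stratify",
    "total_order",
    "lookahead_select",
]

LOOKAHEAD_ACCEPTABLE_MAX = 4
RELATIVE_DISPLACEMENT = 0.2


@dataclass(frozen=True)
class ParetoPoint:
    """One configuration's validation performance profile."""

    hits: float
    quality: float
    answered_fraction: float
    config_id: int

    def __post_init__(self) -> None:
        if self.hits < 0:
            raise ValueError("hits must be >= 0")
        if not 0 <= self.answered_fraction <= 1:
            raise ValueError("answered_fraction must lie in [0, 1]")

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.hits, self.quality, self.answered_fraction)


@dataclass
class LookaheadResult:
    """The configuration picked by the lookahead walk."""

    chosen_config: int
    lookahead_number: int

    def __post_init__(self) -> None:
        if self.lookahead_number < 1:
            raise ValueError("lookahead_number must be >= 1")

    @property
    def acceptable(self) -> bool:
        return self.lookahead_number <= LOOKAHEAD_ACCEPTABLE_MAX


def dominates(a: ParetoPoint, b: ParetoPoint) -> bool:
    """True when ``a`` is at least as good in all three coordinates and
    strictly better in at least one."""
    ge = all(x >= y for x, y in zip(a.coords, b.coords))
    return ge and a.coords != b.coords


def pareto_stratify(points: Sequence[ParetoPoint]) -> list[list[ParetoPoint]]:
    """Iterated maximal-front extraction.

    Duplicated coordinates are removed first (the lowest config_id survives);
    stratum 1 is the set of non-dominated points, and the computation is
    iterated on the residual until no points remain.
    """
    if not points:
        raise ValueError("pareto_stratify needs at least one point")
    dedup: dict[tuple, ParetoPoint] = {}
    for p in sorted(points, key=lambda p: p.config_id):
        dedup.setdefault(p.coords, p)
    remaining = list(dedup.values())
    strata: list[list[ParetoPoint]] = []
    while remaining:
        front = [
            p
            for p in remaining
            if not any(dominates(q, p) for q in remaining if q is not p)
        ]
        strata.append(sorted(front, key=lambda p: p.config_id))
        kept = {p.config_id for p in front}
        remaining = [p for p in remaining if p.config_id not in kept]
    return strata


def total_order(strata: Sequence[Sequence[ParetoPoint]]) -> list[int]:
    """Concatenate strata; within a stratum sort by quality descending,
    ties by config_id ascending.  Returns config ids."""
    out: list[int] = []
    for stratum in strata:
        ordered = sorted(stratum, key=lambda p: (-p.quality, p.config_id))
        out.extend(p.config_id for p in ordered)
    return out


def lookahead_select(
    ordered: Sequence[int],
    val_quality: Mapping[int, float],
    test_quality: Mapping[int, float],
    relative_displacement: float = RELATIVE_DISPLACEMENT,
) -> LookaheadResult:
    """Walk the total order comparing validation and test quality.

    Stops at the first position where the test quality is at least the
    validation quality, or within ``relative_displacement`` of it
    (relative to the validation quality; absolute when it is zero).  If the
    walk exhausts the order, the last configuration is returned with a
    warning.
    """
    if not ordered:
        raise ValueError("empty configuration order")
    for k, cfg in enumerate(ordered, start=1):
        val = val_quality[cfg]
        test = test_quality[cfg]
        if test >= val:
            return LookaheadResult(chosen_config=cfg, lookahead_number=k)
        gap = abs(val - test) / abs(val) if val != 0 else abs(val - test)
        if gap <= relative_displacement:
            return LookaheadResult(chosen_config=cfg, lookahead_number=k)
    warnings.warn(
        "lookahead walk exhausted the configuration order without a stop; "
        "returning the last configuration"
    )
    return LookaheadResult(chosen_config=ordered[-1], lookahead_number=len(ordered))
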