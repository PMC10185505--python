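"""Generalized LOOCVCV model selection for the many-hypotheses regime.

Picking the hypothesis with the best validation score out of hundreds
overfits the validation set: the winner's score is an extreme order
statistic, not an unbiased estimate.  LOOCVCV counters this by estimating
the subset size n-hat such that taking the best hypothesis inside a
uniformly random subset of that size maximizes the *expected* held-out
performance, and the selection probabilities involved are computed exactly
from binomial coefficients (rank r is best in a random size-n' subset with
probability C(H-r, n'-1)/C(H, n')).

This implementation generalizes the procedure in four ways: the optimized
functional is arbitrary (accuracy, any of the four abstention-aware kappa
variants, ...), ranking ties are broken lexicographically by hypothesis
index so the order is always total, the final hypothesis is extracted
directly as the one accumulating the largest probability-weighted held-out
contribution at n-hat (no index-scaling step), and all probabilities are
exact rationals until the final float conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Callable, Sequence

import numpy as np

from cvnprog.metrics import (
    CALL_HIGH,
    CALL_LOW,
    CALL_NO_ANSWER,
    ConfusionSummary,
    kappa_gwet,
    kappa_mixed,
    kappa_scaled,
    kappa_standard,
)

__all__ = [
    "HypothesisRecord",
    "SelectionResult",
    "Target",
    "accuracy_target",
    "kappa_target",
    "record_confusion",
    "arbitrate_kappa_variant",
    "rank_hypotheses",
    "selection_probability",
    "expected_target",
    "loocvcv_select",
]

OUTCOME_CORRECT = "correct"
OUTCOME_INCORRECT = "incorrect"


@dataclass
class HypothesisRecord:
    """One (fingerprint, hyperparameter configuration) with its validation
    outcomes.

    ``outcomes`` holds one entry per validation patient in
    {"correct", "incorrect", "no_answer"}.  ``calls`` / ``truths`` are
    optional but required by agreement-based targets (kappa needs the full
    2x2 table, not just correctness).
    """

    hypothesis_id: int
    outcomes: tuple[str, ...]
    calls: tuple[str, ...] | None = None
    truths: tuple[str, ...] | None = None
    config: object | None = None
    fingerprint: object | None = None
    target_value: float | None = None

    def __post_init__(self) -> None:
        valid = {OUTCOME_CORRECT, OUTCOME_INCORRECT, CALL_NO_ANSWER}
        bad = set(self.outcomes) - valid
        if bad:
            raise ValueError(f"invalid outcomes {sorted(bad)}")
        for name in ("calls", "truths"):
            seq = getattr(self, name)
            if seq is not None and len(seq) != len(self.outcomes):
                raise ValueError(f"{name} length does not match outcomes")

    @classmethod
    def from_predictions(
        cls,
        hypothesis_id: int,
        calls: Sequence[str],
        truths: Sequence[str],
        **kwargs,
    ) -> "HypothesisRecord":
        outcomes = []
        for call, truth in zip(calls, truths, strict=True):
            if call == CALL_NO_ANSWER:
                outcomes.append(CALL_NO_ANSWER)
            elif call == truth:
                outcomes.append(OUTCOME_CORRECT)
            else:
                outcomes.append(OUTCOME_INCORRECT)
        return cls(
            hypothesis_id=hypothesis_id,
            outcomes=tuple(outcomes),
            calls=tuple(calls),
            truths=tuple(truths),
            **kwargs,
        )


@dataclass
class SelectionResult:
    """Outcome of a LOOCVCV run: the subset size and the extracted winner."""

    n_hat: int
    chosen: HypothesisRecord
    expected_target_at_n_hat: float
    per_size_expectation: dict[int, float] = field(default_factory=dict)


Target = Callable[[HypothesisRecord, Sequence[int]], float]


def accuracy_target(record: HypothesisRecord, idx: Sequence[int]) -> float:
    """Fraction of the selected validation patients called correctly
    (abstentions count as misses)."""
    if len(idx) == 0:
        return 0.0
    correct = sum(1 for i in idx if record.outcomes[i] == OUTCOME_CORRECT)
    return correct / len(idx)


KAPPA_FUNCTIONS = {
    "standard": kappa_standard,
    "scaled": kappa_scaled,
    "gwet": kappa_gwet,
    "mixed": kappa_mixed,
}


def record_confusion(record: HypothesisRecord, idx: Sequence[int] | None = None) -> ConfusionSummary:
    """Confusion table of a hypothesis on a subset of validation patients."""
    if record.calls is None or record.truths is None:
        raise ValueError("confusion needs calls and truths on the record")
    if idx is None:
        idx = range(len(record.outcomes))
    c = ConfusionSummary()
    for i in idx:
        call, truth = record.calls[i], record.truths[i]
        if call == CALL_NO_ANSWER:
            c.na += 1
        elif call == CALL_HIGH:
            c.tp += truth == CALL_HIGH
            c.fp += truth == CALL_LOW
        else:
            c.tn += truth == CALL_LOW
            c.fn += truth == CALL_HIGH
    return c


def kappa_target(variant: str = "standard") -> Target:
    """Build a target computing one abstention-aware kappa variant on a
    subset of the validation patients (requires calls and truths)."""
    fn = KAPPA_FUNCTIONS[variant]

    def target(record: HypothesisRecord, idx: Sequence[int]) -> float:
        c = record_confusion(record, idx)
        if c.answered == 0:
            return 0.0
        return fn(c)

    return target


def arbitrate_kappa_variant(
    records: Sequence[HypothesisRecord],
) -> tuple[str, np.ndarray]:
    """Choose one of the four kappa variants by z-score displacement.

    Each variant is evaluated on the full validation set for every
    hypothesis; the variant whose best hypothesis stands furthest above that
    variant's own empirical distribution (largest z-score) wins.  This is
    the dynamic arbitration that guards the selection target against
    abstention artifacts: a variant whose top value is routine for its own
    distribution carries no signal.  Returns the variant name and the
    (4, H) value matrix in the order standard / scaled / gwet / mixed.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 hypotheses to arbitrate")
    names = list(KAPPA_FUNCTIONS)
    kmat = np.zeros((4, len(records)))
    for h, rec in enumerate(records):
        c = record_confusion(rec)
        if c.answered > 0:
            for vi, name in enumerate(names):
                kmat[vi, h] = KAPPA_FUNCTIONS[name](c)
    means = kmat.mean(axis=1)
    sds = kmat.std(axis=1)
    z = np.zeros(4)
    ok = sds > 0
    z[ok] = (kmat[ok].max(axis=1) - means[ok]) / sds[ok]
    return names[int(np.argmax(z))], kmat


def rank_hypotheses(
    records: Sequence[HypothesisRecord],
    direction: str = "maximize",
) -> list[HypothesisRecord]:
    """Total order of hypotheses: by target value, best first, ties broken
    by hypothesis index (lexicographic sorting leaves no ties)."""
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"direction must be maximize/minimize, got {direction!r}")
    sign = -1.0 if direction == "maximize" else 1.0
    for r in records:
        if r.target_value is None:
            raise ValueError(f"hypothesis {r.hypothesis_id} has no target_value")
    return sorted(records, key=lambda r: (sign * r.target_value, r.hypothesis_id))


def selection_probability(rank: int, H: int, subset_size: int) -> float:
    """Exact probability that the rank-r hypothesis (1-based, best first) is
    the best inside a uniformly random subset of ``subset_size`` hypotheses.

    Equals C(H - r, n' - 1) / C(H, n'): the subset must contain rank r plus
    n' - 1 hypotheses ranked strictly worse.  Computed in exact rational
    arithmetic before the final float conversion.
    """
    if not 1 <= subset_size <= H:
        raise ValueError(f"subset_size {subset_size} outside [1, {H}]")
    if not 1 <= rank <= H:
        raise ValueError(f"rank {rank} outside [1, {H}]")
    return float(Fraction(comb(H - rank, subset_size - 1), comb(H, subset_size)))


def _probability_row(H: int, subset_size: int) -> np.ndarray:
    denom = comb(H, subset_size)
    return np.array(
        [Fraction(comb(H - r, subset_size - 1), denom) for r in range(1, H + 1)],
        dtype=float,
    )


def expected_target(ordered_values: Sequence[float], subset_size: int) -> float:
    """Expected target of best-in-random-subset selection.

    ``ordered_values`` must be sorted best-first; the result is the
    probability-weighted mean over ranks.
    """
    H = len(ordered_values)
    probs = _probability_row(H, subset_size)
    return float(np.dot(probs, np.asarray(ordered_values, dtype=float)))


def loocvcv_select(
    records: Sequence[HypothesisRecord],
    target: Target = accuracy_target,
    direction: str = "maximize",
) -> SelectionResult:
    """Leave-one-out cross-validation of cross-validation, generalized.

    For every held-out validation patient i the hypotheses are re-ranked by
    the target computed on the remaining patients; the held-out contribution
    of hypothesis h on i is the jackknife pseudo-value
    ``n T(V) - (n-1) T(V \\ i)`` -- the change in the target attributable to
    including i, which reduces to per-sample correctness for decomposable
    targets.  Because the ranking in fold i never sees i, a hypothesis that
    leads the full-validation ranking only through luck on a few patients
    gets little weight exactly where its luck lies.  For each candidate subset size n' the expected
    held-out contribution under exact selection probabilities is averaged
    across patients; n-hat optimizes that curve, and the chosen hypothesis
    is the one accumulating the largest (smallest, when minimizing)
    probability-weighted contribution at n-hat.  Fully deterministic.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"direction must be maximize/minimize, got {direction!r}")
    H = len(records)
    if H < 2:
        raise ValueError("LOOCVCV needs at least 2 hypotheses")
    n_val = len(records[0].outcomes)
    if n_val < 2:
        raise ValueError("LOOCVCV needs at least 2 validation patients")
    if any(len(r.outcomes) != n_val for r in records):
        raise ValueError("hypotheses disagree on validation size")

    all_idx = list(range(n_val))
    sign = 1.0 if direction == "maximize" else -1.0
    ids = np.array([r.hypothesis_id for r in records])

    t_full = np.array([target(r, all_idx) for r in records])
    t_minus = np.empty((H, n_val))
    for i in range(n_val):
        idx = all_idx[:i] + all_idx[i + 1 :]
        for h, r in enumerate(records):
            t_minus[h, i] = target(r, idx)
    # held-out contribution of patient i to hypothesis h: the jackknife
    # pseudo-value n*T(V) - (n-1)*T(V \ {i}), i.e. the per-sample value for
    # decomposable targets (exactly Ng's per-sample correctness for accuracy)
    contrib = n_val * t_full[:, None] - (n_val - 1) * t_minus

    # per-fold rank permutation: perm[i][r] = hypothesis index at rank r+1,
    # ranking by the target without patient i, ties by hypothesis id
    perms = np.empty((n_val, H), dtype=int)
    for i in range(n_val):
        order = np.lexsort((ids, -sign * t_minus[:, i]))
        perms[i] = order

    prob = np.vstack([_probability_row(H, n) for n in range(1, H + 1)])  # (n', rank)

    # expectation[n'-1] = mean over folds of sum_r P(r | n') * contrib(rank r, fold)
    contrib_by_rank = np.empty((n_val, H))
    for i in range(n_val):
        contrib_by_rank[i] = contrib[perms[i], i]
    per_fold = prob @ contrib_by_rank.T  # (n', fold)
    expectation = per_fold.mean(axis=1)

    if direction == "maximize":
        n_hat = int(np.argmax(expectation)) + 1
    else:
        n_hat = int(np.argmin(expectation)) + 1

    # accumulated probability-weighted contribution of each hypothesis at n-hat
    score = np.zeros(H)
    p_row = prob[n_hat - 1]
    for i in range(n_val):
        score[perms[i]] += p_row * contrib[perms[i], i]
    best = np.argmax(sign * score)
    # ties -> lowest hypothesis id
    tied = np.flatnonzero(sign * score == sign * score[best])
    chosen_pos = tied[np.argmin(ids[tied])]
    chosen = records[int(chosen_pos)]

    return SelectionResult(
        n_hat=n_hat,
        chosen=chosen,
        expected_target_at_n_hat=float(expectation[n_hat - 1]),
        per_size_expectation={n + 1: float(v) for n, v in enumerate(expectation)},
    )
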