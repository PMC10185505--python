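"""Independent-cohort validation: LOO hyperparameter search + bootstrap.

Validation cohorts are too small to split three ways, so the fingerprint is
frozen and only the hyperparameters are tuned, by leave-one-out prediction
over a configuration grid under a cap on the abstention rate.  The tuned
configuration is then evaluated by bootstrapping: each round samples
``m = multiplier * n`` patients with replacement, trains on the distinct
sampled patients (the in-set) and predicts the unsampled rest (the
out-set).  With m = 3n the expected out-set fraction is
(1 - 1/n)^(3n) -> e^-3 (small but variable out-sets); m = 1.38n makes the
expected out-set about a quarter of the cohort, mirroring a
train/validate/test split.

Per-patient error indicators averaged over the rounds in which the patient
was out-of-sample give the smoothed leave-one-out bootstrap estimates of
TP/FP/TN/FN/NA (any linear functional of the indicators inherits the
smoothing); the odds ratio and kappa are computed from those expected
counts.  The AUC is not such a linear functional, so it is instead computed
on the *consensus* prediction map -- the per-patient majority over all
rounds -- via the Mann-Whitney U equivalence, scoring each patient by the
fraction of high calls among its answered calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cvnprog.cohort_io import Cohort, RiskLabel
from cvnprog.cvn import (
    CVNConfig,
    Fingerprint,
    coherent_filter,
    discretize,
    loo_predict,
    mine_bicliques,
    predict,
)
from cvnprog.metrics import (
    CALL_HIGH,
    CALL_LOW,
    CALL_NO_ANSWER,
    ConfusionSummary,
    auc_u_statistic,
    confusion,
    kappa_standard,
    odds_ratio,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "loo_hyperparameter_search",
    "bootstrap_rounds",
    "efron_tibshirani_estimate",
    "consensus_auc",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap evaluation settings.

    ``sample_multiplier`` 3.0 is the default validation protocol; 1.38 is
    the variant whose expected out-set is a quarter of the cohort.
    ``na_cap`` bounds the abstention fraction during LOO selection (strict);
    ``report_na_cap`` is the reporting filter applied to bootstrap rows.
    """

    B: int = 200
    sample_multiplier: float = 3.0
    seed: int = 0
    na_cap: float = 0.15
    report_na_cap: float = 0.20

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.sample_multiplier <= 0:
            raise ValueError("sample_multiplier must be > 0")


@dataclass
class BootstrapResult:
    """Smoothed bootstrap estimates plus the consensus prediction map."""

    expected_confusion: ConfusionSummary
    or_estimate: float
    or_ci_low: float
    or_ci_high: float
    or_pvalue: float
    kappa_estimate: float
    consensus_map: dict[str, str]
    vote_fraction: dict[str, float]
    auc: float
    auc_pvalue: float
    rounds_out_per_patient: dict[str, int]
    n_rounds_used: int = 0
    excluded_patients: list[str] = field(default_factory=list)

    @property
    def meets_report_cap(self) -> bool:
        return self.expected_confusion.na_fraction < 0.20


def _check_fingerprint(cohort: Cohort, fingerprint: Fingerprint) -> None:
    missing = [f for f in fingerprint.feature_ids if f not in cohort.matrix.values.columns]
    if missing:
        raise KeyError(f"fingerprint features absent from cohort: {missing}")


def loo_hyperparameter_search(
    cohort: Cohort,
    fingerprint: Fingerprint,
    grid: Sequence[CVNConfig],
    na_cap: float = 0.15,
) -> CVNConfig:
    """Leave-one-out search over a hyperparameter grid with a fixed
    fingerprint.

    Configurations whose LOO abstention fraction reaches ``na_cap`` are
    discarded; among the survivors the best odds ratio wins (ties: larger
    kappa, then the lowest grid index).  If every configuration violates the
    cap the best-OR configuration is returned with a warning.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    _check_fingerprint(cohort, fingerprint)
    labeled = cohort.labeled_ids()
    sub = cohort.subset(labeled)
    scored: list[tuple[float, float, int]] = []
    for gi, config in enumerate(grid):
        states = discretize(sub.matrix, config.discretization)
        outcomes = loo_predict(states, sub.labels, fingerprint, config)
        c = confusion(outcomes, sub.labels)
        try:
            or_value = odds_ratio(c)[0]
        except ValueError:
            or_value = 0.0
        kappa = kappa_standard(c) if c.answered > 0 else 0.0
        scored.append((c.na_fraction, or_value, kappa, gi))
    survivors = [s for s in scored if s[0] < na_cap]
    pool = survivors
    if not survivors:
        warnings.warn(
            "every configuration exceeds the abstention cap; "
            "falling back to the best odds ratio overall"
        )
        pool = scored
    best = max(pool, key=lambda s: (s[1], s[2], -s[3]))
    return grid[best[3]]


def bootstrap_rounds(
    cohort: Cohort,
    fingerprint: Fingerprint,
    config: CVNConfig,
    bconfig: BootstrapConfig,
) -> list[dict[str, str]]:
    """Run B bootstrap rounds; returns one {patient: call} map per round,
    covering that round's out-of-sample patients only.

    Rounds with an empty out-set or a single-class in-set are skipped (and
    logged); the partition sequence is deterministic given the seed.
    """
    _check_fingerprint(cohort, fingerprint)
    rng = np.random.default_rng(bconfig.seed)
    labeled = cohort.labeled_ids()
    n = len(labeled)
    if n < 4:
        raise ValueError(f"too few labeled patients to bootstrap: {n}")
    labels = {p: cohort.labels[p] for p in labeled}
    values = cohort.matrix.values.loc[labeled, list(fingerprint.feature_ids)]
    m = int(round(bconfig.sample_multiplier * n))
    maps: list[dict[str, str]] = []
    skipped = 0
    for _ in range(bconfig.B):
        sampled = rng.integers(0, n, size=m)
        in_mask = np.zeros(n, dtype=bool)
        in_mask[np.unique(sampled)] = True
        in_ids = [labeled[i] for i in np.flatnonzero(in_mask)]
        out_ids = [labeled[i] for i in np.flatnonzero(~in_mask)]
        if not out_ids:
            skipped += 1
            continue
        in_labels = {p: labels[p] for p in in_ids}
        if len({l.value for l in in_labels.values()}) < 2:
            skipped += 1
            continue
        states = discretize(values, config.discretization, train_ids=in_ids)
        structural = mine_bicliques(states, fingerprint, config)
        communities = coherent_filter(structural, in_labels, config.purity_threshold)
        maps.append(
            {pid: predict(pid, communities, config).call for pid in out_ids}
        )
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap round(s)")
    return maps


def efron_tibshirani_estimate(
    round_maps: Sequence[Mapping[str, str]],
    labels: Mapping[str, RiskLabel | str],
) -> BootstrapResult:
    """Smoothed leave-one-out bootstrap estimates of the confusion counts.

    Each patient's TP/FP/TN/FN/NA indicators are averaged over the rounds in
    which the patient was out-of-sample; the expected counts are the sums of
    those averages (so they total exactly the number of ever-out patients).
    The odds ratio and kappa are evaluated on the expected table; patients
    never out-of-sample are excluded (with a warning).
    """
    per_patient: dict[str, np.ndarray] = {}
    counts_out: dict[str, int] = {}
    for rmap in round_maps:
        for pid, call in rmap.items():
            truth = labels[pid]
            truth = truth.value if isinstance(truth, RiskLabel) else str(truth)
            ind = np.zeros(5)  # tp, fp, tn, fn, na
            if call == CALL_NO_ANSWER:
                ind[4] = 1
            elif call == CALL_HIGH:
                ind[0 if truth == CALL_HIGH else 1] = 1
            elif call == CALL_LOW:
                ind[2 if truth == CALL_LOW else 3] = 1
            else:
                raise ValueError(f"unknown call {call!r}")
            per_patient[pid] = per_patient.get(pid, np.zeros(5)) + ind
            counts_out[pid] = counts_out.get(pid, 0) + 1
    excluded = [
        p
        for p in labels
        if p not in per_patient
        and (labels[p].value if isinstance(labels[p], RiskLabel) else labels[p])
        in (CALL_HIGH, CALL_LOW)
    ]
    if excluded:
        warnings.warn(
            f"{len(excluded)} patient(s) never out-of-sample; excluded from "
            "the bootstrap expectations"
        )
    if not per_patient:
        raise ValueError("no out-of-sample predictions at all")
    totals = np.zeros(5)
    for pid, acc in per_patient.items():
        totals += acc / counts_out[pid]
    c = ConfusionSummary(tp=totals[0], fp=totals[1], tn=totals[2], fn=totals[3], na=totals[4])
    if c.answered > 0:
        or_est, ci_lo, ci_hi, or_p = odds_ratio(c)
        kappa_est = kappa_standard(c)
    else:
        or_est = ci_lo = ci_hi = float("nan")
        or_p = 1.0
        kappa_est = 0.0
    consensus, vote_fraction, auc, auc_p = consensus_auc(round_maps, labels)
    return BootstrapResult(
        expected_confusion=c,
        or_estimate=or_est,
        or_ci_low=ci_lo,
        or_ci_high=ci_hi,
        or_pvalue=or_p,
        kappa_estimate=kappa_est,
        consensus_map=consensus,
        vote_fraction=vote_fraction,
        auc=auc,
        auc_pvalue=auc_p,
        rounds_out_per_patient=counts_out,
        n_rounds_used=len(round_maps),
        excluded_patients=excluded,
    )


def consensus_auc(
    round_maps: Sequence[Mapping[str, str]],
    labels: Mapping[str, RiskLabel | str],
) -> tuple[dict[str, str], dict[str, float], float, float]:
    """Majority-vote consensus over the bootstrap rounds, scored by AUC.

    Consensus is the most frequent of a patient's out-of-sample predictions
    (no_answer included as a category); any tie for the top yields
    no_answer, as does never being predicted.  The AUC score is the fraction
    of high calls among the answered calls (0.5 when a patient never
    answered), compared between the true classes via the Mann-Whitney U
    statistic.
    """
    tallies: dict[str, dict[str, int]] = {}
    for rmap in round_maps:
        for pid, call in rmap.items():
            tallies.setdefault(pid, {CALL_HIGH: 0, CALL_LOW: 0, CALL_NO_ANSWER: 0})
            tallies[pid][call] += 1
    consensus: dict[str, str] = {}
    vote_fraction: dict[str, float] = {}
    for pid, tally in tallies.items():
        top = max(tally.values())
        winners = [c for c, k in tally.items() if k == top]
        consensus[pid] = winners[0] if len(winners) == 1 else CALL_NO_ANSWER
        answered = tally[CALL_HIGH] + tally[CALL_LOW]
        vote_fraction[pid] = tally[CALL_HIGH] / answered if answered else 0.5
    auc, auc_p = auc_u_statistic(vote_fraction, labels)
    return consensus, vote_fraction, auc, auc_p
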