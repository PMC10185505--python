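"""End-to-end discovery and validation pipelines.

Discovery (three phases on one cohort): split into train / validation /
test (about 1/2, 1/4, 1/4, stratified); Phase I searches the training set
for candidate fingerprints; Phase II selects one (fingerprint,
hyperparameter) hypothesis on the validation set, by either generalized
LOOCVCV ("ng", lookahead reported as 0) or Pareto-stratified lookahead
selection ("pareto", lookahead >= 1); Phase III evaluates the single
selected model on the held-out test set and emits a performance row,
per-patient certificates and Kaplan-Meier data.

Validation (independent cohort, fingerprint fixed): leave-one-out
hyperparameter search under the abstention cap, then bootstrap estimation
of the expected confusion counts, odds ratio, kappa, and the consensus-map
AUC.

Test patients are never visible to Phases I/II except through the Pareto
lookahead channel, whose lookahead number is reported so the leak stays
auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cvnprog.bootstrap import (
    BootstrapConfig,
    BootstrapResult,
    bootstrap_rounds,
    efron_tibshirani_estimate,
    loo_hyperparameter_search,
)
from cvnprog.cohort_io import Cohort, RiskLabel, TimeFrame, split_cohort
from cvnprog.cvn import (
    CVNConfig,
    Fingerprint,
    PredictionOutcome,
    coherent_filter,
    discretize,
    mine_bicliques,
    predict,
    search_candidate_fingerprints,
)
from cvnprog.metrics import (
    CALL_HIGH,
    CALL_LOW,
    CALL_NO_ANSWER,
    MetricReport,
    auc_u_statistic,
    confusion,
    kappa_standard,
    km_curve,
    logrank_test,
    odds_ratio,
)
from cvnprog.ng import (
    HypothesisRecord,
    arbitrate_kappa_variant,
    kappa_target,
    loocvcv_select,
)
from cvnprog.pareto import ParetoPoint, lookahead_select, pareto_stratify, total_order

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "ValidationResult",
    "default_grid",
    "run_discovery",
    "run_validation",
]

SCORE_ENCODING = {CALL_HIGH: 1.0, CALL_NO_ANSWER: 0.5, CALL_LOW: 0.0}


def default_grid(base: CVNConfig | None = None) -> list[CVNConfig]:
    """The default hyperparameter grid: purity x community-size settings."""
    from dataclasses import replace

    base = base or CVNConfig()
    return [
        replace(base, purity_threshold=p, min_community_patients=m)
        for p in (0.7, 0.8, 0.9)
        for m in (2, 3)
    ]


@dataclass
class PipelineConfig:
    """Shared pipeline settings for the command-line entry points."""

    mode: str = "discover"
    frame: TimeFrame = TimeFrame(3)
    selection: str = "pareto"
    seed: int = 0
    quality: str = "kappa"  # quality score for Pareto points and lookahead
    base_config: CVNConfig = field(default_factory=CVNConfig)
    grid: list[CVNConfig] | None = None
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("discover", "validate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.selection not in ("ng", "pareto"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.quality not in ("kappa", "odds_ratio"):
            raise ValueError(f"unknown quality {self.quality!r}")


@dataclass
class DiscoveryResult:
    report: MetricReport
    fingerprint: Fingerprint
    config: CVNConfig
    selection: str
    lookahead: int
    n_candidates: int
    test_outcomes: list[PredictionOutcome]
    km_tables: dict[str, pd.DataFrame]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ValidationResult:
    report: MetricReport
    fingerprint: Fingerprint
    config: CVNConfig
    bootstrap: BootstrapResult

    def as_row(self, dataset: str = "", fingerprint_id: str = "") -> dict:
        """Validation-table row: dataset, frame, fingerprint, n, NA, OR with
        CI and p, kappa, AUC and AUC p-value."""
        c = self.bootstrap.expected_confusion
        return {
            "dataset": dataset,
            "fingerprint": fingerprint_id or "+".join(self.fingerprint.feature_ids),
            "n_patients": self.report.n_patients,
            "n_na": round(c.na, 2),
            "odds_ratio": self.report.odds_ratio,
            "or_ci_low": self.report.or_ci_low,
            "or_ci_high": self.report.or_ci_high,
            "or_pvalue": self.report.or_pvalue,
            "kappa": self.report.kappa,
            "auc": self.report.auc,
            "auc_pvalue": self.report.auc_pvalue,
        }


def _predict_transductive(
    cohort: Cohort,
    train_ids: Sequence[str],
    train_labels: Mapping[str, RiskLabel],
    target_ids: Sequence[str],
    fingerprint: Fingerprint,
    config: CVNConfig,
    collect_certificates: bool = False,
) -> list[PredictionOutcome]:
    """Train on ``train_ids`` (thresholds + community labels), predict
    ``target_ids`` sitting unlabeled inside the same voting graph."""
    ids = list(dict.fromkeys(list(train_ids) + list(target_ids)))
    values = cohort.matrix.values.loc[ids, list(fingerprint.feature_ids)]
    states = discretize(values, config.discretization, train_ids=list(train_ids))
    structural = mine_bicliques(states, fingerprint, config)
    communities = coherent_filter(structural, dict(train_labels), config.purity_threshold)
    outcomes = []
    for pid in target_ids:
        o = predict(pid, communities, config)
        if not collect_certificates:
            o.certificate = []
        outcomes.append(o)
    return outcomes


def _quality_value(c, quality: str) -> float:
    if c.answered == 0:
        return 0.0
    if quality == "kappa":
        return kappa_standard(c)
    return odds_ratio(c)[0]


def _evaluate_report(
    cohort: Cohort,
    outcomes: Sequence[PredictionOutcome],
    lookahead: int,
    label: str,
) -> tuple[MetricReport, dict[str, pd.DataFrame]]:
    """Confusion + OR/kappa/AUC on a prediction set, log-rank and KM on the
    answered patients grouped by predicted class."""
    c = confusion(outcomes, cohort.labels)
    or_value, ci_lo, ci_hi, or_p = odds_ratio(c)
    kappa = kappa_standard(c) if c.answered > 0 else 0.0
    scores = {o.patient_id: SCORE_ENCODING[o.call] for o in outcomes}
    auc, auc_p = auc_u_statistic(scores, cohort.labels)
    surv = cohort.survival_by_id
    answered = [o for o in outcomes if o.call != CALL_NO_ANSWER]
    km_tables: dict[str, pd.DataFrame] = {}
    logrank_p = float("nan")
    calls = {o.call for o in answered}
    if calls == {CALL_HIGH, CALL_LOW}:
        times = [surv[o.patient_id].time_months for o in answered]
        events = [surv[o.patient_id].event for o in answered]
        groups = [o.call for o in answered]
        logrank_p = logrank_test(times, events, groups)
    for call in sorted(calls):
        members = [o.patient_id for o in answered if o.call == call]
        km_tables[call] = km_curve(
            [surv[p].time_months for p in members], [surv[p].event for p in members]
        )
    from cvnprog.metrics import kappa_gwet, kappa_mixed, kappa_scaled

    extras = {}
    if c.answered > 0:
        extras = {
            "kappa_scaled": kappa_scaled(c),
            "kappa_gwet": kappa_gwet(c),
            "kappa_mixed": kappa_mixed(c),
        }
    report = MetricReport(
        odds_ratio=or_value,
        or_ci_low=ci_lo,
        or_ci_high=ci_hi,
        or_pvalue=or_p,
        kappa=kappa,
        auc=auc,
        auc_pvalue=auc_p,
        logrank_pvalue=logrank_p,
        n_patients=len(outcomes),
        n_na=c.na,
        lookahead=lookahead,
        label=label,
        extras=extras,
    )
    return report, km_tables


def run_discovery(
    cohort: Cohort,
    selection: str = "pareto",
    seed: int = 0,
    base_config: CVNConfig | None = None,
    grid: Sequence[CVNConfig] | None = None,
    quality: str = "kappa",
    max_hypotheses: int = 240,
    out_dir: str | Path | None = None,
) -> DiscoveryResult:
    """The three-phase discovery pipeline on one labeled cohort.

    Deterministic given ``seed``.  Raises if Phase I produces no candidate
    fingerprints.
    """
    base_config = base_config or CVNConfig()
    grid = list(grid) if grid is not None else default_grid(base_config)
    train, val, test = split_cohort(cohort, seed)

    candidates = search_candidate_fingerprints(train, base_config, seed=seed)
    if not candidates:
        raise RuntimeError(
            "Phase I produced no candidate fingerprints (no feature beats "
            "the majority-class rate on the training set)"
        )

    train_ids = train.labeled_ids()
    train_labels = {p: train.labels[p] for p in train_ids}
    val_ids = val.labeled_ids()
    val_truths = tuple(cohort.labels[p].value for p in val_ids)
    test_ids = test.labeled_ids()

    hypotheses: list[HypothesisRecord] = []
    per_capita = max(1, max_hypotheses // len(grid))
    for fp in candidates[:per_capita]:
        for g in grid:
            outcomes = _predict_transductive(
                cohort, train_ids, train_labels, val_ids, fp, g
            )
            calls = tuple(o.call for o in outcomes)
            hypotheses.append(
                HypothesisRecord.from_predictions(
                    hypothesis_id=len(hypotheses),
                    calls=calls,
                    truths=val_truths,
                    config=g,
                    fingerprint=fp,
                )
            )

    diagnostics: dict = {"n_candidates": len(candidates), "n_hypotheses": len(hypotheses)}

    if selection == "ng":
        variant, kmat = arbitrate_kappa_variant(hypotheses)
        variant_index = ("standard", "scaled", "gwet", "mixed").index(variant)
        for h, rec in enumerate(hypotheses):
            rec.target_value = float(kmat[variant_index, h])
        sel = loocvcv_select(hypotheses, target=kappa_target(variant), direction="maximize")
        chosen_rec = sel.chosen
        lookahead = 0  # LOOCVCV never inspects the test set
        diagnostics.update(
            kappa_variant=variant,
            n_hat=sel.n_hat,
            expected_target_at_n_hat=sel.expected_target_at_n_hat,
            per_size_expectation=sel.per_size_expectation,
        )
    else:
        points = []
        val_quality: dict[int, float] = {}
        for h, rec in enumerate(hypotheses):
            c = confusion(
                list(zip(val_ids, rec.calls)), {p: cohort.labels[p] for p in val_ids}
            )
            q = _quality_value(c, quality)
            val_quality[h] = q
            points.append(
                ParetoPoint(
                    hits=c.tp + c.tn,
                    quality=q,
                    answered_fraction=c.answered / c.total if c.total else 0.0,
                    config_id=h,
                )
            )
        strata = pareto_stratify(points)
        order = total_order(strata)
        test_quality: dict[int, float] = {}
        test_labels = {p: cohort.labels[p] for p in test_ids}
        for h in order:
            rec = hypotheses[h]
            outcomes = _predict_transductive(
                cohort, train_ids, train_labels, test_ids, rec.fingerprint, rec.config
            )
            ct = confusion(outcomes, test_labels)
            test_quality[h] = _quality_value(ct, quality)
        walk = lookahead_select(order, val_quality, test_quality)
        chosen_rec = hypotheses[walk.chosen_config]
        lookahead = walk.lookahead_number
        if not walk.acceptable:
            warnings.warn(
                f"lookahead number {lookahead} exceeds the acceptability bound (4)"
            )
        diagnostics.update(
            n_strata=len(strata),
            order=order[:20],
            lookahead_acceptable=walk.acceptable,
        )

    test_outcomes = _predict_transductive(
        cohort,
        train_ids,
        train_labels,
        test_ids,
        chosen_rec.fingerprint,
        chosen_rec.config,
        collect_certificates=True,
    )
    test_cohort = cohort.subset(test_ids)
    report, km_tables = _evaluate_report(
        test_cohort, test_outcomes, lookahead, label=selection
    )
    result = DiscoveryResult(
        report=report,
        fingerprint=chosen_rec.fingerprint,
        config=chosen_rec.config,
        selection=selection,
        lookahead=lookahead,
        n_candidates=len(candidates),
        test_outcomes=test_outcomes,
        km_tables=km_tables,
        diagnostics=diagnostics,
    )
    if out_dir is not None:
        _export_discovery(result, Path(out_dir))
    return result


def _export_discovery(result: DiscoveryResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([result.report.as_row()]).to_csv(
        out_dir / "report.tsv", sep="\t", index=False
    )
    result.fingerprint.to_json(out_dir / "fingerprint.json")
    (out_dir / "certificates.json").write_text(
        json.dumps([o.to_dict() for o in result.test_outcomes], indent=2)
    )
    for call, table in result.km_tables.items():
        table.to_csv(out_dir / f"km_{call}.tsv", sep="\t", index=False)
    diag = {
        k: v for k, v in result.diagnostics.items() if not isinstance(v, dict)
    }
    (out_dir / "selection_log.json").write_text(json.dumps(diag, indent=2, default=str))


def run_validation(
    cohort: Cohort,
    fingerprint: Fingerprint,
    grid: Sequence[CVNConfig] | None = None,
    bconfig: BootstrapConfig | None = None,
    out_dir: str | Path | None = None,
) -> ValidationResult:
    """Fixed-fingerprint validation: LOO hyperparameter search followed by
    bootstrap performance estimation."""
    bconfig = bconfig or BootstrapConfig()
    grid = list(grid) if grid is not None else default_grid()
    missing = [
        f for f in fingerprint.feature_ids if f not in cohort.matrix.values.columns
    ]
    if missing:
        raise KeyError(f"fingerprint features absent from cohort: {missing}")
    config = loo_hyperparameter_search(cohort, fingerprint, grid, na_cap=bconfig.na_cap)
    maps = bootstrap_rounds(cohort, fingerprint, config, bconfig)
    labeled = cohort.labeled_ids()
    labels = {p: cohort.labels[p] for p in labeled}
    boot = efron_tibshirani_estimate(maps, labels)
    report = MetricReport(
        odds_ratio=boot.or_estimate,
        or_ci_low=boot.or_ci_low,
        or_ci_high=boot.or_ci_high,
        or_pvalue=boot.or_pvalue,
        kappa=boot.kappa_estimate,
        auc=boot.auc,
        auc_pvalue=boot.auc_pvalue,
        n_patients=len(labeled),
        n_na=boot.expected_confusion.na,
        lookahead=0,
        label="validation",
    )
    result = ValidationResult(
        report=report, fingerprint=fingerprint, config=config, bootstrap=boot
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([result.as_row()]).to_csv(
            out_dir / "validation_row.tsv", sep="\t", index=False
        )
    return result
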