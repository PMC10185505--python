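"""Performance functionals for abstaining risk classifiers.

Everything downstream of a prediction run lands here: confusion summaries
that keep abstentions (no answers) as a first-class count, the odds ratio
with a Haldane-Anscombe-corrected Wald interval and Fisher exact p-value,
four chance-corrected agreement coefficients that differ in how they treat
abstentions, the Mann-Whitney U formulation of the AUC, and the survival
statistics (log-rank test, Kaplan-Meier curves) used to judge a
stratification.  The positive class is fixed as *high risk* throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cvnprog.cohort_io import RiskLabel

__all__ = [
    "ConfusionSummary",
    "MetricReport",
    "confusion",
    "odds_ratio",
    "kappa_standard",
    "kappa_scaled",
    "kappa_gwet",
    "kappa_mixed",
    "kappa_zscore_select",
    "auc_u_statistic",
    "logrank_test",
    "km_curve",
    "summarize_table",
]

CALL_HIGH = "high"
CALL_LOW = "low"
CALL_NO_ANSWER = "no_answer"


@dataclass
class ConfusionSummary:
    """TP/FP/TN/FN/NA counts with high risk as the positive class.

    Counts are reals rather than integers so that bootstrap *expected*
    confusion tables (averages of indicators) use the same type.
    """

    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0
    na: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"negative count {f.name}={v}")

    @property
    def answered(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def total(self) -> float:
        return self.answered + self.na

    @property
    def na_fraction(self) -> float:
        return self.na / self.total if self.total > 0 else 0.0

    def as_table(self) -> np.ndarray:
        """2x2 table, rows = truth (high, low), cols = call (high, low)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


def _call_of(outcome) -> tuple[str, str]:
    """Duck-typed access: accepts (patient_id, call) pairs or objects."""
    if isinstance(outcome, tuple):
        return str(outcome[0]), str(outcome[1])
    return str(outcome.patient_id), str(outcome.call)


def confusion(outcomes: Iterable, labels: Mapping[str, RiskLabel | str]) -> ConfusionSummary:
    """Cross-tabulate predictions against true risk labels.

    ``outcomes`` may be :class:`~cvnprog.cvn.PredictionOutcome` objects or
    plain ``(patient_id, call)`` pairs with call in
    {"high", "low", "no_answer"}.  Patients with an indeterminate label are
    rejected: they must be excluded before evaluation.
    """
    c = ConfusionSummary()
    for outcome in outcomes:
        pid, call = _call_of(outcome)
        truth = labels[pid]
        truth = truth.value if isinstance(truth, RiskLabel) else str(truth)
        if truth not in (CALL_HIGH, CALL_LOW):
            raise ValueError(
                f"patient {pid!r} has label {truth!r}; only high/low patients "
                "can be scored"
            )
        if call == CALL_NO_ANSWER:
            c.na += 1
        elif call == CALL_HIGH:
            if truth == CALL_HIGH:
                c.tp += 1
            else:
                c.fp += 1
        elif call == CALL_LOW:
            if truth == CALL_LOW:
                c.tn += 1
            else:
                c.fn += 1
        else:
            raise ValueError(f"unknown call {call!r} for patient {pid!r}")
    return c


def odds_ratio(c: ConfusionSummary) -> tuple[float, float, float, float]:
    """Odds ratio of the answered 2x2 table with 95% CI and p-value.

    OR = (TP*TN)/(FP*FN); when any cell is zero the Haldane-Anscombe +0.5
    correction is applied to every cell.  The confidence interval is the
    Wald interval on log(OR); the p-value is the two-sided Fisher exact
    test on the (rounded) table.
    """
    if c.answered <= 0:
        raise ValueError("odds ratio undefined with zero answered predictions")
    cells = np.array([c.tp, c.fn, c.fp, c.tn], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    tp, fn, fp, tn = cells
    or_value = (tp * tn) / (fp * fn)
    se = math.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(0.975)
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    table = np.round([[c.tp, c.fn], [c.fp, c.tn]]).astype(int)
    _, pvalue = stats.fisher_exact(table, alternative="two-sided")
    return or_value, ci_low, ci_high, float(pvalue)


def _po_pe(c: ConfusionSummary) -> tuple[float, float]:
    n = c.answered
    po = (c.tp + c.tn) / n
    p_truth_high = (c.tp + c.fn) / n
    p_call_high = (c.tp + c.fp) / n
    pe = p_truth_high * p_call_high + (1 - p_truth_high) * (1 - p_call_high)
    return po, pe


def kappa_standard(c: ConfusionSummary) -> float:
    """Cohen's kappa on the answered table, ignoring abstentions."""
    if c.answered <= 0:
        raise ValueError("kappa undefined with zero answered predictions")
    po, pe = _po_pe(c)
    if pe >= 1.0:
        warnings.warn("degenerate confusion table (pe = 1); kappa set to 0")
        return 0.0
    return (po - pe) / (1 - pe)


def kappa_scaled(c: ConfusionSummary) -> float:
    """Cohen's kappa scaled by the fraction of answered predictions.

    Abstaining on everything yields 0 by convention.
    """
    if c.answered <= 0:
        return 0.0
    return kappa_standard(c) * c.answered / c.total


def kappa_gwet(c: ConfusionSummary) -> float:
    """Gwet's AC1 on the answered table.

    Chance agreement is ``2 q (1 - q)`` with ``q`` the mean of the two
    high-risk marginals; more stable than Cohen's kappa under skewed
    marginals.
    """
    if c.answered <= 0:
        raise ValueError("AC1 undefined with zero answered predictions")
    n = c.answered
    po = (c.tp + c.tn) / n
    q = ((c.tp + c.fn) + (c.tp + c.fp)) / (2 * n)
    pe = 2 * q * (1 - q)
    if pe >= 1.0:
        warnings.warn("degenerate confusion table (pe = 1); AC1 set to 0")
        return 0.0
    return (po - pe) / (1 - pe)


def kappa_mixed(c: ConfusionSummary) -> float:
    """Scaled kappa up to 15% abstention, Gwet's AC1 beyond.

    The 15% boundary itself takes the scaled branch.
    """
    if c.total <= 0:
        return 0.0
    if c.na_fraction <= 0.15:
        return kappa_scaled(c)
    return kappa_gwet(c)


KAPPA_VARIANTS = (kappa_standard, kappa_scaled, kappa_gwet, kappa_mixed)
KAPPA_VARIANT_NAMES = ("standard", "scaled", "gwet", "mixed")


def kappa_zscore_select(values: np.ndarray, target_index: int) -> int:
    """Arbitrate between agreement variants by z-score displacement.

    ``values`` is a (4, H) matrix of the four kappa variants over H
    hypotheses.  Each variant is normalized against its own empirical
    distribution across the hypotheses, and the variant whose z-score at
    ``target_index`` is largest wins (ties go to the lowest variant index;
    a variant that is constant across hypotheses gets z = 0).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a (n_variants, n_hypotheses) matrix")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 hypotheses to form a z-score")
    if not 0 <= target_index < values.shape[1]:
        raise IndexError(f"target_index {target_index} out of range")
    means = values.mean(axis=1)
    sds = values.std(axis=1)
    z = np.zeros(values.shape[0])
    ok = sds > 0
    z[ok] = (values[ok, target_index] - means[ok]) / sds[ok]
    return int(np.argmax(z))  # argmax returns the first (lowest) index on ties


def auc_u_statistic(
    scores: Mapping[str, float],
    labels: Mapping[str, RiskLabel | str],
) -> tuple[float, float]:
    """AUC from the Wilcoxon-Mann-Whitney U statistic, with ties worth 1/2.

    Higher scores should indicate high risk.  The p-value is the two-sided
    normal approximation of U with the tie correction; when every score is
    identical the AUC is 0.5 and the p-value 1.
    """
    hi, lo = [], []
    for pid, s in scores.items():
        truth = labels[pid]
        truth = truth.value if isinstance(truth, RiskLabel) else str(truth)
        if truth == CALL_HIGH:
            hi.append(float(s))
        elif truth == CALL_LOW:
            lo.append(float(s))
        else:
            raise ValueError(f"patient {pid!r} has non-binary label {truth!r}")
    if not hi or not lo:
        raise ValueError("AUC requires both risk classes among scored patients")
    hi_a, lo_a = np.asarray(hi), np.asarray(lo)
    ranks = stats.rankdata(np.concatenate([hi_a, lo_a]))
    n1, n0 = len(hi_a), len(lo_a)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    if np.ptp(np.concatenate([hi_a, lo_a])) == 0:
        return 0.5, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.mannwhitneyu(hi_a, lo_a, alternative="two-sided", method="asymptotic")
            pvalue = float(res.pvalue)
        except ValueError:
            pvalue = 1.0
    if math.isnan(pvalue):
        pvalue = 1.0
    return float(auc), pvalue


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> float:
    """Two-group log-rank test p-value (chi-square, 1 df).

    ``groups`` assigns each patient to one of exactly two strata (e.g. the
    predicted risk class).  With no events at all the test is vacuous and
    p = 1.
    """
    from lifelines.statistics import logrank_test as _lifelines_logrank

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(uniq)}")
    if events.sum() == 0:
        return 1.0
    mask = groups == uniq[0]
    res = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(res.p_value)


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a step table.

    Returns a frame with columns (time, survival, at_risk, censored) --
    one row per distinct observed time, suitable for TSV export and
    external plotting.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
            "censored": table["censored"].to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class MetricReport:
    """One evaluation row: stratification strength plus survival separation."""

    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    or_pvalue: float
    kappa: float
    auc: float
    auc_pvalue: float
    logrank_pvalue: float = float("nan")
    n_patients: int = 0
    n_na: float = 0.0
    lookahead: int = 0
    label: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("or_pvalue", "auc_pvalue", "logrank_pvalue"):
            v = getattr(self, name)
            if not math.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "n_patients": self.n_patients,
            "n_na": self.n_na,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "or_pvalue": self.or_pvalue,
            "kappa": self.kappa,
            "auc": self.auc,
            "auc_pvalue": self.auc_pvalue,
            "logrank_pvalue": self.logrank_pvalue,
            "lookahead": self.lookahead,
        }


def _is_pvalue_column(name: str) -> bool:
    lowered = name.lower()
    return "pval" in lowered or "p_value" in lowered


def summarize_table(reports: Sequence[MetricReport] | pd.DataFrame) -> pd.Series:
    """Average a table of metric rows: geometric means for p-value columns,
    arithmetic means for everything else numeric.

    Accepts either a list of :class:`MetricReport` or a DataFrame whose
    p-value columns are recognizable by name ("...pval..." / "...p_value...").
    """
    if isinstance(reports, pd.DataFrame):
        df = reports
    else:
        df = pd.DataFrame([r.as_row() for r in reports])
    if df.empty:
        raise ValueError("cannot summarize an empty table")
    out: dict[str, float] = {}
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce").dropna()
        if series.empty:
            continue
        if _is_pvalue_column(col):
            if (series <= 0).any():
                raise ValueError(f"non-positive p-value in column {col!r}")
            out[col] = float(stats.gmean(series))
        else:
            out[col] = float(series.mean())
    return pd.Series(out)
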