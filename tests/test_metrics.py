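import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvnprog.metrics import (
    ConfusionSummary,
    MetricReport,
    auc_u_statistic,
    confusion,
    kappa_gwet,
    kappa_mixed,
    kappa_scaled,
    kappa_standard,
    kappa_zscore_select,
    km_curve,
    logrank_test,
    odds_ratio,
    summarize_table,
)

# the worked 2x2 example used throughout: 8 TP, 2 FN, 3 FP, 12 TN
EXAMPLE = ConfusionSummary(tp=8, fn=2, fp=3, tn=12)

counts = st.integers(min_value=0, max_value=40)


class TestConfusion:
    def test_mixed_toy_hand_tabulated(self):
        labels = {"a": "high", "b": "high", "c": "high", "d": "low", "e": "low", "f": "low"}
        outcomes = [
            ("a", "high"),  # tp
            ("b", "low"),  # fn
            ("c", "no_answer"),  # na
            ("d", "low"),  # tn
            ("e", "high"),  # fp
            ("f", "no_answer"),  # na
        ]
        c = confusion(outcomes, labels)
        assert (c.tp, c.fn, c.fp, c.tn, c.na) == (1, 1, 1, 1, 2)
        assert c.answered == 4 and c.total == 6

    def test_all_abstentions(self):
        c = confusion([("a", "no_answer")], {"a": "high"})
        assert c.na == 1 and c.answered == 0

    def test_indeterminate_label_rejected(self):
        with pytest.raises(ValueError, match="indeterminate"):
            confusion([("a", "high")], {"a": "indeterminate"})


class TestOddsRatio:
    def test_direct_formula(self):
        or_value, lo, hi, p = odds_ratio(EXAMPLE)
        assert or_value == pytest.approx(16.0)
        assert lo <= or_value <= hi
        assert 0 <= p <= 1

    def test_haldane_correction_with_zero_cell(self):
        or_value, *_ = odds_ratio(ConfusionSummary(tp=5, fn=0, fp=2, tn=10))
        assert or_value == pytest.approx((5.5 * 10.5) / (0.5 * 2.5))

    def test_symmetric_table_is_null(self):
        or_value, lo, hi, p = odds_ratio(ConfusionSummary(tp=5, fn=5, fp=5, tn=5))
        assert or_value == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    @given(tp=counts, fn=counts, fp=counts, tn=counts)
    def test_swap_invariance(self, tp, fn, fp, tn):
        """OR is invariant under simultaneously swapping tp<->tn, fp<->fn."""
        if tp + fn + fp + tn == 0:
            return
        a = odds_ratio(ConfusionSummary(tp=tp, fn=fn, fp=fp, tn=tn))
        b = odds_ratio(ConfusionSummary(tp=tn, fn=fp, fp=fn, tn=tp))
        assert a[0] == pytest.approx(b[0])
        assert a[3] == pytest.approx(b[3])

    def test_no_answers_only_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ConfusionSummary(na=10))


class TestKappaVariants:
    def test_hand_computed_values_on_example(self):
        # po = 0.8, pe = 0.512 -> kappa = 0.288/0.488
        assert kappa_standard(EXAMPLE) == pytest.approx(0.5902, abs=1e-4)
        # q = 0.42, pe = 0.4872 -> AC1 = 0.3128/0.5128
        assert kappa_gwet(EXAMPLE) == pytest.approx(0.6100, abs=1e-4)

    @given(tp=counts, tn=counts, na=counts)
    def test_all_variants_one_on_perfect_agreement_and_bounded(self, tp, tn, na):
        if tp == 0 or tn == 0:
            return
        c = ConfusionSummary(tp=tp, tn=tn, na=0)
        for fn in (kappa_standard, kappa_scaled, kappa_gwet, kappa_mixed):
            assert fn(c) == pytest.approx(1.0)
        mixed = ConfusionSummary(tp=tp, tn=tn, fp=1, fn=1, na=na)
        for fn in (kappa_standard, kappa_scaled, kappa_gwet, kappa_mixed):
            assert fn(mixed) <= 1.0 + 1e-12

    def test_independence_gives_zero(self):
        # cells proportional to the product of the marginals
        c = ConfusionSummary(tp=8, fn=12, fp=2, tn=3)
        assert kappa_standard(c) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_kappa_shrinks_by_answer_fraction(self):
        c = ConfusionSummary(tp=8, fn=2, fp=3, tn=12, na=25)
        assert kappa_scaled(c) == pytest.approx(kappa_standard(c) * 0.5)
        assert kappa_scaled(ConfusionSummary(na=10)) == 0.0

    @pytest.mark.parametrize(
        "na,branch",
        [(2, "scaled"), (15, "gwet"), (0, "scaled")],
    )
    def test_mixed_branches_at_15_percent(self, na, branch):
        c = ConfusionSummary(tp=10, fn=5, fp=5, tn=10, na=na)
        expected = kappa_scaled(c) if branch == "scaled" else kappa_gwet(c)
        assert kappa_mixed(c) == pytest.approx(expected)

    def test_mixed_boundary_exactly_15_percent_takes_scaled(self):
        c = ConfusionSummary(tp=8, fn=4, fp=3, tn=2, na=3)  # na/total = 0.15
        assert c.na_fraction == pytest.approx(0.15)
        assert kappa_mixed(c) == pytest.approx(kappa_scaled(c))


class TestKappaZscoreSelect:
    def test_constructed_matrix_argmax_by_direct_z(self):
        values = np.array(
            [
                [0.1, 0.2, 0.3, 0.4, 0.9],
                [0.5, 0.5, 0.5, 0.5, 0.6],
                [0.3, 0.3, 0.3, 0.3, 0.3],
                [0.0, 0.4, 0.2, 0.1, 0.5],
            ]
        )
        target = 4
        z = []
        for row in values:
            sd = row.std()
            z.append((row[target] - row.mean()) / sd if sd > 0 else 0.0)
        assert kappa_zscore_select(values, target) == int(np.argmax(z))

    def test_all_identical_returns_first_variant(self):
        values = np.ones((4, 5))
        assert kappa_zscore_select(values, 2) == 0

    def test_dominant_displacement_wins(self):
        values = np.array([[0.0, 0.0, 10.0], [0.0, 0.0, 0.1], [0, 0, 0.1], [0, 0, 0.1]])
        assert kappa_zscore_select(values, 2) == 0


class TestAUC:
    def test_pair_enumeration_example(self):
        scores = {"h1": 0.9, "h2": 0.7, "l1": 0.8, "l2": 0.1}
        labels = {"h1": "high", "h2": "high", "l1": "low", "l2": "low"}
        auc, p = auc_u_statistic(scores, labels)
        assert auc == pytest.approx(0.75)  # U = 3 of 4 pairs

    def test_perfect_and_flat(self):
        labels = {"a": "high", "b": "high", "c": "low", "d": "low"}
        auc, _ = auc_u_statistic({"a": 2, "b": 3, "c": 0, "d": 1}, labels)
        assert auc == 1.0
        auc, p = auc_u_statistic({k: 0.5 for k in labels}, labels)
        assert auc == 0.5 and p == 1.0

    @given(
        hi=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
        lo=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
    )
    def test_matches_roc_integration_oracle(self, hi, lo):
        """The U-statistic AUC must equal trapezoidal ROC integration."""
        from sklearn.metrics import roc_auc_score

        scores = {f"h{i}": v for i, v in enumerate(hi)}
        scores.update({f"l{i}": v for i, v in enumerate(lo)})
        labels = {k: ("high" if k.startswith("h") else "low") for k in scores}
        auc, _ = auc_u_statistic(scores, labels)
        y = [1 if k.startswith("h") else 0 for k in scores]
        s = [scores[k] for k in scores]
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_u_statistic({"a": 1.0}, {"a": "high"})


class TestSurvivalStats:
    def test_logrank_identical_groups_null(self):
        times = [5, 10, 15, 5, 10, 15]
        events = [True, True, False, True, True, False]
        groups = ["a", "a", "a", "b", "b", "b"]
        assert logrank_test(times, events, groups) == pytest.approx(1.0)

    def test_logrank_no_events_vacuous(self):
        assert logrank_test([1, 2, 3, 4], [False] * 4, ["a", "a", "b", "b"]) == 1.0

    def test_logrank_matches_manual_oe_tabulation(self):
        """Six-patient toy checked against a direct observed-vs-expected
        log-rank computation over the pooled event times."""
        times = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        events = np.array([True, True, True, True, False, True])
        groups = np.array(["a", "a", "a", "b", "b", "b"])

        o_minus_e = 0.0
        var = 0.0
        for t in sorted(set(times[events])):
            at_risk = times >= t
            d = ((times == t) & events).sum()
            n = at_risk.sum()
            n_a = (at_risk & (groups == "a")).sum()
            d_a = ((times == t) & events & (groups == "a")).sum()
            e_a = d * n_a / n
            o_minus_e += d_a - e_a
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        from scipy import stats

        chi2 = o_minus_e**2 / var
        expected_p = stats.chi2.sf(chi2, df=1)
        assert logrank_test(times, events, groups) == pytest.approx(expected_p, rel=1e-6)

    def test_separated_groups_significant(self):
        times = list(range(1, 21)) + list(range(100, 120))
        events = [True] * 40
        groups = ["a"] * 20 + ["b"] * 20
        assert logrank_test(times, events, groups) < 1e-6

    def test_km_steps(self):
        km = km_curve([1.0, 2.0], [True, True])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[1.0] == pytest.approx(0.5)
        assert surv[2.0] == pytest.approx(0.0)

    def test_km_no_events_flat(self):
        km = km_curve([5.0, 10.0, 15.0], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_km_early_censoring_shrinks_risk_set(self):
        # product-limit by hand: censor at 1, events at 2 and 3
        km = km_curve([1.0, 2.0, 3.0], [False, True, True])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[2.0] == pytest.approx(0.5)  # 1 * (1 - 1/2)
        assert surv[3.0] == pytest.approx(0.0)


class TestSummarizeTable:
    def test_printed_average_conventions(self):
        ors = [13, 20, 21, 12, 18.75, 17.14, 16]
        ps = [0.03, 0.01, 0.01, 0.1, 0.01, 0.008, 0.001]
        df = pd.DataFrame({"odds_ratio": ors, "or_pvalue": ps})
        s = summarize_table(df)
        assert s["odds_ratio"] == pytest.approx(16.8, abs=0.05)
        # geometric, not arithmetic, for the p-value column
        assert s["or_pvalue"] == pytest.approx(np.exp(np.mean(np.log(ps))))

    def test_equal_pvalues_geometric_mean_is_itself(self):
        df = pd.DataFrame({"kappa": [0.5, 0.7], "auc_pvalue": [0.02, 0.02]})
        s = summarize_table(df)
        assert s["auc_pvalue"] == pytest.approx(0.02)
        assert s["kappa"] == pytest.approx(0.6)

    def test_single_report_is_itself(self):
        r = MetricReport(
            odds_ratio=4.0,
            or_ci_low=1.0,
            or_ci_high=16.0,
            or_pvalue=0.04,
            kappa=0.5,
            auc=0.8,
            auc_pvalue=0.01,
            logrank_pvalue=0.02,
            n_patients=30,
        )
        s = summarize_table([r])
        assert s["odds_ratio"] == 4.0 and s["logrank_pvalue"] == pytest.approx(0.02)
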