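import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvnprog.cohort_io import RiskLabel
from cvnprog.cvn import (
    CVNConfig,
    Community,
    Fingerprint,
    build_voting_graph,
    discretize,
    find_coherent_communities,
    loo_accuracy,
    loo_predict,
    mine_bicliques,
    predict,
    search_candidate_fingerprints,
    single_feature_loo_accuracy,
)


def states_frame(rows, pids=None, features=None):
    rows = np.asarray(rows, dtype=object)
    pids = pids or [f"p{i}" for i in range(rows.shape[0])]
    features = features or [f"f{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=pids, columns=features)


class TestDiscretize:
    def test_median_split_definition(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        states = discretize(df, "median_2state")
        assert list(states["f"]) == ["down", "down", "up", "up"]

    def test_tertiles_of_nine(self):
        df = pd.DataFrame({"f": list(range(1, 10))}, index=[f"p{i}" for i in range(9)])
        states = discretize(df, "tertile_3state")
        assert list(states["f"]) == ["down"] * 3 + ["mid"] * 3 + ["up"] * 3

    def test_constant_feature_collapses_with_warning(self):
        df = pd.DataFrame({"f": [2.0, 2.0, 2.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            states = discretize(df, "median_2state")
        assert set(states["f"]) == {"down"}

    def test_thresholds_frozen_on_training_rows(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 100.0]}, index=list("abcd"))
        states = discretize(df, "median_2state", train_ids=["a", "b", "c"])
        # median of train = 2; patient d uses the frozen threshold
        assert list(states["f"]) == ["down", "down", "up", "up"]

    def test_missing_stays_missing(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 3.0, 4.0]}, index=list("abcd"))
        states = discretize(df, "median_2state")
        assert states.loc["b", "f"] is None or pd.isna(states.loc["b", "f"])


class TestVotingGraph:
    def test_edge_count_equals_nonmissing_cells(self):
        df = pd.DataFrame(
            {"f1": [1.0, 2.0, 3.0, 4.0], "f2": [4.0, 3.0, np.nan, 1.0]},
            index=list("abcd"),
        )
        states = discretize(df, "median_2state")
        fp = Fingerprint(("f1", "f2"))
        g = build_voting_graph(states, fp)
        assert g.number_of_edges() == 7

    def test_bipartite_two_colorable(self):
        import networkx as nx

        df = pd.DataFrame(
            {"f1": [1.0, 2.0, 3.0, 4.0], "f2": [4.0, 3.0, 2.0, 1.0]}, index=list("abcd")
        )
        g = build_voting_graph(discretize(df), Fingerprint(("f1", "f2")))
        assert nx.is_bipartite(g)

    def test_empty_fingerprint_rejected(self):
        with pytest.raises(ValueError):
            Fingerprint(())


def brute_force_bicliques(states, min_patients, min_features):
    """Exhaustive maximal-biclique oracle over all item subsets."""
    trans = {
        pid: frozenset(
            (f, s) for f, s in zip(states.columns, row) if s is not None and not pd.isna(s)
        )
        for pid, row in zip(states.index, states.to_numpy(object))
    }
    items = sorted({i for t in trans.values() for i in t})
    found = set()
    for k in range(1, len(items) + 1):
        for subset in itertools.combinations(items, k):
            sub = frozenset(subset)
            support = frozenset(p for p, t in trans.items() if sub <= t)
            if len(support) < min_patients:
                continue
            closure = frozenset.intersection(*(trans[p] for p in support))
            if len(closure) >= min_features:
                found.add((support, closure))
    return found


class TestCommunityMining:
    def test_planted_block_is_one_pure_community(self):
        # 5 patients all 'up' on 3 features, all labeled high
        rows = [["up"] * 3 for _ in range(5)]
        states = states_frame(rows)
        labels = {f"p{i}": "high" for i in range(5)}
        cfg = CVNConfig(min_community_patients=2, purity_threshold=0.8)
        g = build_voting_graph_from_states(states)
        coms = find_coherent_communities(g, labels, cfg)
        top = max(coms, key=lambda c: len(c.patients) * len(c.feature_states))
        assert top.patients == frozenset(states.index)
        assert len(top.feature_states) == 3
        assert top.label == "high" and top.purity == 1.0

    def test_impure_block_rejected_by_threshold(self):
        rows = [["up"] * 3 for _ in range(5)]
        states = states_frame(rows)
        labels = {"p0": "high", "p1": "high", "p2": "high", "p3": "low", "p4": "low"}
        cfg = CVNConfig(min_community_patients=2, purity_threshold=0.8)
        coms = find_coherent_communities(build_voting_graph_from_states(states), labels, cfg)
        assert coms == []  # purity 0.6 < 0.8 for every sub-block of this block

    def test_empty_graph_no_communities(self):
        import networkx as nx

        cfg = CVNConfig(min_community_patients=2)
        assert find_coherent_communities(nx.Graph(), {}, cfg) == []

    @given(
        data=st.lists(
            st.lists(st.sampled_from(["up", "down"]), min_size=3, max_size=3),
            min_size=2,
            max_size=10,
        ),
        minp=st.integers(min_value=2, max_value=3),
    )
    @settings(max_examples=40)
    def test_matches_exhaustive_biclique_oracle(self, data, minp):
        """On small graphs the mined communities must be exactly the maximal
        bicliques meeting the size thresholds."""
        states = states_frame(data)
        cfg = CVNConfig(min_community_patients=minp, min_community_features=1)
        mined = {
            (c.patients, c.feature_states)
            for c in mine_bicliques(states, Fingerprint(tuple(states.columns)), cfg)
        }
        assert mined == brute_force_bicliques(states, minp, 1)

    def test_every_community_satisfies_thresholds(self, planted_cohort):
        cohort, sig, _ = planted_cohort
        cfg = CVNConfig(min_community_patients=3, min_community_features=2)
        states = discretize(cohort.matrix)
        for c in mine_bicliques(states, sig, cfg):
            assert len(c.patients) >= 3
            assert len(c.feature_states) >= 2


def build_voting_graph_from_states(states):
    return build_voting_graph(states, Fingerprint(tuple(states.columns)))


class TestPredict:
    def _community(self, pids, label, purity, n_states=1):
        return Community(
            patients=frozenset(pids),
            feature_states=frozenset((f"f{k}", "up") for k in range(n_states)),
            label=label,
            purity=purity,
        )

    def test_unanimous_high_vote(self):
        coms = [self._community(["x", "a"], "high", 1.0) for _ in range(1)]
        out = predict("x", coms * 3, CVNConfig())
        assert out.call == "high"
        assert len(out.certificate) == 3

    def test_no_communities_abstains(self):
        assert predict("x", [], CVNConfig()).call == "no_answer"

    def test_margin_rule_on_constructed_weights(self):
        # weights 2.0 high vs 1.9 low -> margin 0.1/3.9 ~= 0.0256 < 0.1
        high = Community(frozenset(["x", "a"]), frozenset([("f1", "up")]), "high", 1.0)
        low = Community(frozenset(["x", "b"]), frozenset([("f2", "up")]), "low", 0.95)
        cfg = CVNConfig(vote_margin=0.1)
        assert predict("x", [high, low], cfg).call == "no_answer"
        assert predict("x", [high, low], CVNConfig(vote_margin=0.0)).call == "high"

    @given(margins=st.lists(st.floats(0, 1), min_size=2, max_size=2))
    def test_abstention_monotone_in_margin(self, margins):
        lo_m, hi_m = sorted(margins)
        high = Community(frozenset(["x", "a", "b"]), frozenset([("f1", "up")]), "high", 0.9)
        low = Community(frozenset(["x", "c"]), frozenset([("f2", "up")]), "low", 1.0)
        call_lo = predict("x", [high, low], CVNConfig(vote_margin=lo_m)).call
        call_hi = predict("x", [high, low], CVNConfig(vote_margin=hi_m)).call
        if call_lo == "no_answer":
            assert call_hi == "no_answer"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        coms = [
            Community(frozenset(["x", f"a{i}"]), frozenset([(f"f{i}", "up")]),
                      "high" if i % 2 else "low", 0.8 + 0.02 * i)
            for i in range(6)
        ]
        calls = set()
        for _ in range(5):
            order = list(rng.permutation(len(coms)))
            calls.add(predict("x", [coms[j] for j in order], CVNConfig()).call)
        assert len(calls) == 1


class TestFingerprintSearch:
    def test_single_feature_screen_finds_planted_features(self, planted_cohort):
        cohort, sig, _ = planted_cohort
        states = discretize(cohort.matrix)
        acc = single_feature_loo_accuracy(states, cohort.labels, CVNConfig())
        top10 = set(acc.sort_values(ascending=False).index[:10])
        assert len(top10 & set(sig.feature_ids)) >= 3

    def test_vectorized_screen_agrees_with_generic_loo(self, planted_cohort):
        """The fast single-feature path must agree with the generic
        community-mining leave-one-out evaluation."""
        cohort, sig, _ = planted_cohort
        states = discretize(cohort.matrix)
        cfg = CVNConfig()
        fast = single_feature_loo_accuracy(states, cohort.labels, cfg)
        for f in list(sig.feature_ids)[:2] + list(states.columns[:2]):
            slow = loo_accuracy(states, cohort.labels, Fingerprint((f,)), cfg)
            assert fast[f] == pytest.approx(slow)

    def test_candidates_recover_planted_signature(self, planted_cohort):
        cohort, sig, _ = planted_cohort
        from cvnprog.cohort_io import split_cohort

        train, _, _ = split_cohort(cohort, seed=1)
        cands = search_candidate_fingerprints(train, CVNConfig(), seed=1)
        assert cands
        assert max(fp.jaccard(sig) for fp in cands[:10]) >= 0.6

    def test_candidate_cap_respected(self, planted_cohort):
        cohort, sig, _ = planted_cohort
        from cvnprog.cohort_io import split_cohort

        train, _, _ = split_cohort(cohort, seed=1)
        cfg = CVNConfig(max_candidates=7)
        assert len(search_candidate_fingerprints(train, cfg, seed=1)) <= 7

    def test_null_cohort_accuracies_within_chance_band(self):
        from cvnprog.cohort_io import split_cohort
        from cvnprog.synthetic import SimulationConfig, generate_cohort

        cohort, _ = generate_cohort(
            SimulationConfig(n_patients=120, n_features=300, effect_size=0.0, seed=13)
        )
        train, _, _ = split_cohort(cohort, seed=13)
        labs = [l.value for p, l in train.labels.items() if l.value in ("high", "low")]
        n = len(labs)
        chance = max(labs.count("high"), labs.count("low")) / n
        states = discretize(train.matrix)
        acc = single_feature_loo_accuracy(states, train.labels, CVNConfig())
        # max over 300 null features stays within a multiplicity-adjusted
        # binomial band around chance
        band = 4.0 * np.sqrt(chance * (1 - chance) / n)
        assert acc.max() <= chance + band
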