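"""The coherent voting network (CVN) classifier.

Continuous features are discretized into states (median split or tertiles,
thresholds always frozen on the training patients), patients and
(feature, state) nodes form a bipartite voting graph, and *coherent voting
communities* -- maximal bicliques whose labeled patients agree on one risk
class above a purity threshold -- vote on each unlabeled patient.  A patient
with no decisive vote receives ``no_answer``; a called patient carries the
voting communities as a certificate.

Candidate fingerprints (small feature subsets on which the coherent vote is
accurate) are found by a greedy forward search seeded from a single-feature
accuracy ranking, producing the 30-60 candidates the discovery pipeline
hands to model selection.

Community mining is exact: communities are the closed itemsets of the
patient x (feature, state) incidence relation (equivalently, the maximal
bicliques of the voting graph), enumerated by closure-based depth-first
search.  This is tractable because fingerprints stay small (at most ~15
features); an optional density knob relaxes the bicliques to quasi-bicliques
by one augmentation pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cvnprog.cohort_io import Cohort, OmicsMatrix, RiskLabel
from cvnprog.metrics import CALL_HIGH, CALL_LOW, CALL_NO_ANSWER

__all__ = [
    "CVNConfig",
    "Fingerprint",
    "Community",
    "PredictionOutcome",
    "discretize",
    "build_voting_graph",
    "mine_bicliques",
    "find_coherent_communities",
    "coherent_filter",
    "predict",
    "loo_predict",
    "loo_score",
    "single_feature_loo_accuracy",
    "search_candidate_fingerprints",
]

STATE_UP = "up"
STATE_MID = "mid"
STATE_DOWN = "down"


@dataclass(frozen=True)
class CVNConfig:
    """Hyperparameters of the coherent voting network.

    purity_threshold is the minimum majority-label frequency (among labeled
    members) for a community to be allowed to vote; vote_margin is the
    minimum normalized weight difference between the high and low vote for
    a call to be issued (below it the classifier abstains).  min_density < 1
    relaxes exact bicliques to quasi-bicliques.
    """

    discretization: str = "median_2state"
    min_community_patients: int = 3
    min_community_features: int = 1
    purity_threshold: float = 0.8
    vote_margin: float = 0.0
    max_candidates: int = 60
    max_fingerprint_size: int = 8
    min_density: float = 1.0

    def __post_init__(self) -> None:
        if self.discretization not in ("median_2state", "tertile_3state"):
            raise ValueError(f"unknown discretization {self.discretization!r}")
        if self.min_community_patients < 2:
            raise ValueError("min_community_patients must be >= 2")
        if self.min_community_features < 1:
            raise ValueError("min_community_features must be >= 1")
        if not 0.5 < self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must lie in (0.5, 1]")
        if self.vote_margin < 0:
            raise ValueError("vote_margin must be >= 0")
        if not 0 < self.min_density <= 1.0:
            raise ValueError("min_density must lie in (0, 1]")


@dataclass(frozen=True)
class Fingerprint:
    """An ordered small set of feature identifiers (a candidate signature)."""

    feature_ids: tuple[str, ...]
    data_kinds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError("fingerprint cannot be empty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("fingerprint has duplicate features")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def jaccard(self, other: "Fingerprint") -> float:
        a, b = set(self.feature_ids), set(other.feature_ids)
        return len(a & b) / len(a | b)

    @classmethod
    def from_features(cls, feature_ids: Iterable[str], matrix: OmicsMatrix | None = None) -> "Fingerprint":
        ids = tuple(str(f) for f in feature_ids)
        kinds: frozenset[str] = frozenset()
        if matrix is not None:
            kinds = frozenset(matrix.feature_kinds.loc[list(ids)].unique())
        return cls(feature_ids=ids, data_kinds=kinds)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"feature_ids": list(self.feature_ids), "data_kinds": sorted(self.data_kinds)},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Fingerprint":
        obj = json.loads(Path(path).read_text())
        return cls(tuple(obj["feature_ids"]), frozenset(obj.get("data_kinds", [])))


@dataclass(frozen=True)
class Community:
    """A coherent voting community: a (quasi-)biclique with a majority label.

    ``patients`` includes unlabeled members; ``purity`` is the majority-label
    frequency among the labeled members only.
    """

    patients: frozenset
    feature_states: frozenset
    label: str | None = None
    purity: float = 0.0

    @property
    def weight(self) -> float:
        return len(self.patients) * self.purity

    def to_dict(self) -> dict:
        return {
            "patients": sorted(self.patients),
            "feature_states": sorted([list(fs) for fs in self.feature_states]),
            "label": self.label,
            "purity": self.purity,
        }


@dataclass
class PredictionOutcome:
    """A call (or abstention) for one patient, with its certificate."""

    patient_id: str
    call: str
    certificate: list[Community] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "call": self.call,
            "certificate": [c.to_dict() for c in self.certificate],
        }


# ---------------------------------------------------------------------------
# Discretization


def discretize(
    matrix: OmicsMatrix | pd.DataFrame,
    scheme: str = "median_2state",
    train_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Map continuous values to states; thresholds from training rows only.

    median_2state: above the training median -> ``up``, otherwise ``down``.
    tertile_3state: training tertiles split into ``down`` / ``mid`` / ``up``.
    Missing values stay missing.  A constant feature collapses into a single
    state (``down``) and therefore carries no voting power; a warning is
    emitted once per call.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    if scheme not in ("median_2state", "tertile_3state"):
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    train = values if train_ids is None else values.loc[list(train_ids)]
    arr = values.to_numpy(dtype=float)
    tarr = train.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if scheme == "median_2state":
            med = np.nanmedian(tarr, axis=0)
            states = np.where(arr > med, STATE_UP, STATE_DOWN).astype(object)
        else:
            q1 = np.nanquantile(tarr, 1 / 3, axis=0)
            q2 = np.nanquantile(tarr, 2 / 3, axis=0)
            states = np.full(arr.shape, STATE_MID, dtype=object)
            states[arr <= q1] = STATE_DOWN
            states[arr > q2] = STATE_UP
        col_min = np.nanmin(tarr, axis=0)
        col_max = np.nanmax(tarr, axis=0)
    constant = col_min == col_max
    if constant.any():
        names = list(values.columns[constant][:5])
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) (e.g. {names}); "
            "they collapse to a single state and carry no voting power"
        )
    states[np.isnan(arr)] = None
    return pd.DataFrame(states, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Voting graph and community mining


def _transactions(states: pd.DataFrame, feature_ids: Sequence[str]) -> dict[str, frozenset]:
    """Per-patient sets of (feature, state) items, skipping missing cells."""
    sub = states[list(feature_ids)]
    out: dict[str, frozenset] = {}
    for pid, row in zip(sub.index, sub.to_numpy()):
        items = [
            (f, s) for f, s in zip(sub.columns, row) if s is not None and not pd.isna(s)
        ]
        out[str(pid)] = frozenset(items)
    return out


def build_voting_graph(states: pd.DataFrame, fingerprint: Fingerprint):
    """Bipartite patient <-> (feature, state) graph restricted to a fingerprint.

    Each patient connects to exactly one state node per non-missing feature,
    so the edge count equals the number of non-missing (patient, feature)
    pairs.
    """
    import networkx as nx

    missing = [f for f in fingerprint.feature_ids if f not in states.columns]
    if missing:
        raise KeyError(f"fingerprint features absent from matrix: {missing}")
    g = nx.Graph()
    trans = _transactions(states, fingerprint.feature_ids)
    for pid, items in trans.items():
        g.add_node(pid, bipartite=0)
        for item in items:
            g.add_node(item, bipartite=1)
            g.add_edge(pid, item)
    return g


def _graph_transactions(graph) -> dict[str, frozenset]:
    out = {}
    for node, data in graph.nodes(data=True):
        if data.get("bipartite") == 0:
            out[node] = frozenset(graph.neighbors(node))
    return out


def _closed_itemsets(
    trans: Mapping[str, frozenset],
    min_patients: int,
    min_features: int,
) -> list[tuple[frozenset, frozenset]]:
    """Enumerate all (patient set, item set) pairs where the item set is
    closed with support >= min_patients -- i.e. the maximal bicliques.

    Depth-first over closures: start from each item's support set, repeatedly
    intersect with further items, and take the closure (all items common to
    the current patient set).  Every maximal biclique is the closure of some
    intersection of item supports, so the traversal is exhaustive.
    """
    item_tids: dict[object, frozenset] = {}
    for pid, items in trans.items():
        for it in items:
            item_tids.setdefault(it, set()).add(pid)
    item_tids = {it: frozenset(p) for it, p in item_tids.items() if len(p) >= min_patients}
    all_items = sorted(item_tids)

    def closure_of(tids: frozenset) -> frozenset:
        it = iter(tids)
        common = set(trans[next(it)])
        for pid in it:
            common &= trans[pid]
            if not common:
                break
        return frozenset(common)

    seen: set[frozenset] = set()
    results: list[tuple[frozenset, frozenset]] = []
    stack: list[frozenset] = []
    for it in all_items:
        tids = item_tids[it]
        c = closure_of(tids)
        if c not in seen:
            seen.add(c)
            stack.append(tids)
    while stack:
        tids = stack.pop()
        items = closure_of(tids)
        if len(items) >= min_features:
            results.append((tids, items))
        for it in all_items:
            if it in items:
                continue
            t2 = tids & item_tids[it]
            if len(t2) < min_patients:
                continue
            c2 = closure_of(t2)
            if c2 not in seen:
                seen.add(c2)
                stack.append(t2)
    results.sort(key=lambda pc: (-len(pc[0]), sorted(map(repr, pc[1]))))
    return results


def mine_bicliques(graph_or_states, fingerprint: Fingerprint | None, config: CVNConfig) -> list[Community]:
    """Structural communities (no labels yet): maximal bicliques meeting the
    size thresholds, as unlabeled :class:`Community` objects.

    Accepts either a voting graph or a state matrix plus fingerprint.
    """
    if fingerprint is None:
        trans = _graph_transactions(graph_or_states)
    else:
        trans = _transactions(graph_or_states, fingerprint.feature_ids)
    closed = _closed_itemsets(trans, config.min_community_patients, config.min_community_features)
    communities = [Community(patients=p, feature_states=frozenset(items)) for p, items in closed]
    if config.min_density < 1.0:
        communities = _densify(communities, trans, config.min_density)
    return communities


def _densify(
    communities: list[Community],
    trans: Mapping[str, frozenset],
    min_density: float,
) -> list[Community]:
    """Quasi-biclique relaxation: one pass admitting patients adjacent to at
    least ``min_density`` of a community's feature states."""
    out: dict[tuple, Community] = {}
    for com in communities:
        need = min_density * len(com.feature_states)
        extra = {
            pid
            for pid, items in trans.items()
            if pid not in com.patients and len(items & com.feature_states) >= need
        }
        patients = com.patients | frozenset(extra)
        key = (patients, com.feature_states)
        out[key] = Community(patients=patients, feature_states=com.feature_states)
    return list(out.values())


def coherent_filter(
    communities: Iterable[Community],
    labels: Mapping[str, RiskLabel | str],
    purity_threshold: float,
) -> list[Community]:
    """Keep communities whose labeled patients agree above the purity
    threshold; annotate each survivor with its majority label and purity."""
    out: list[Community] = []
    for com in communities:
        n_high = n_low = 0
        for pid in com.patients:
            lab = labels.get(pid)
            lab = lab.value if isinstance(lab, RiskLabel) else lab
            if lab == CALL_HIGH:
                n_high += 1
            elif lab == CALL_LOW:
                n_low += 1
        labeled = n_high + n_low
        if labeled == 0 or n_high == n_low:
            continue
        purity = max(n_high, n_low) / labeled
        if purity >= purity_threshold:
            out.append(
                replace(com, label=CALL_HIGH if n_high > n_low else CALL_LOW, purity=purity)
            )
    return out


def find_coherent_communities(
    graph,
    labels: Mapping[str, RiskLabel | str],
    config: CVNConfig,
) -> list[Community]:
    """Coherent voting communities of a voting graph.

    Mines the maximal bicliques meeting the size thresholds and keeps those
    whose labeled patients share one risk class with frequency at or above
    ``config.purity_threshold``.
    """
    structural = mine_bicliques(graph, None, config)
    return coherent_filter(structural, labels, config.purity_threshold)


def predict(patient_id: str, communities: Iterable[Community], config: CVNConfig) -> PredictionOutcome:
    """Aggregate the weighted vote of the communities containing a patient.

    Each community votes its majority label with weight size x purity; the
    call is issued only when the normalized weight difference exceeds
    ``config.vote_margin``, otherwise the classifier abstains.
    """
    votes = [c for c in communities if patient_id in c.patients and c.label is not None]
    w_high = sum(c.weight for c in votes if c.label == CALL_HIGH)
    w_low = sum(c.weight for c in votes if c.label == CALL_LOW)
    total = w_high + w_low
    if total <= 0:
        return PredictionOutcome(patient_id, CALL_NO_ANSWER, [])
    margin = abs(w_high - w_low) / total
    if margin > config.vote_margin:
        call = CALL_HIGH if w_high > w_low else CALL_LOW
        return PredictionOutcome(patient_id, call, votes)
    return PredictionOutcome(patient_id, CALL_NO_ANSWER, votes)


# ---------------------------------------------------------------------------
# Leave-one-out evaluation helpers


def _labels_as_str(labels: Mapping[str, RiskLabel | str]) -> dict[str, str]:
    out = {}
    for pid, lab in labels.items():
        lab = lab.value if isinstance(lab, RiskLabel) else str(lab)
        if lab in (CALL_HIGH, CALL_LOW):
            out[pid] = lab
    return out


def loo_predict(
    states: pd.DataFrame,
    labels: Mapping[str, RiskLabel | str],
    fingerprint: Fingerprint,
    config: CVNConfig,
    collect_certificates: bool = False,
) -> list[PredictionOutcome]:
    """Leave-one-out coherent-vote predictions for every labeled patient.

    The bipartite structure is mined once on the full state matrix; for each
    held-out patient only the label information is withheld (purity and
    majority are recomputed without it), which matches how an unlabeled
    patient sits inside the voting graph at prediction time.  Certificates
    are collected only on request (they are bulky and the search loop does
    not need them).
    """
    labs = _labels_as_str(labels)
    structural = mine_bicliques(states, fingerprint, config)
    counts = []
    membership: dict[str, list[int]] = {}
    for ci, com in enumerate(structural):
        nh = nl = 0
        for pid in com.patients:
            lab = labs.get(pid)
            if lab == CALL_HIGH:
                nh += 1
            elif lab == CALL_LOW:
                nl += 1
            membership.setdefault(pid, []).append(ci)
        counts.append((nh, nl))
    outcomes = []
    for pid in states.index:
        pid = str(pid)
        if pid not in labs:
            continue
        held_high = labs[pid] == CALL_HIGH
        w_high = w_low = 0.0
        voting: list[Community] = []
        for ci in membership.get(pid, ()):
            nh, nl = counts[ci]
            if held_high:
                nh -= 1
            else:
                nl -= 1
            labeled = nh + nl
            if labeled <= 0 or nh == nl:
                continue
            purity = max(nh, nl) / labeled
            if purity < config.purity_threshold:
                continue
            com = structural[ci]
            w = len(com.patients) * purity
            if nh > nl:
                w_high += w
            else:
                w_low += w
            if collect_certificates:
                voting.append(
                    replace(com, label=CALL_HIGH if nh > nl else CALL_LOW, purity=purity)
                )
        total = w_high + w_low
        if total <= 0 or abs(w_high - w_low) / total <= config.vote_margin:
            outcomes.append(PredictionOutcome(pid, CALL_NO_ANSWER, voting))
        else:
            call = CALL_HIGH if w_high > w_low else CALL_LOW
            outcomes.append(PredictionOutcome(pid, call, voting))
    return outcomes


def loo_accuracy(
    states: pd.DataFrame,
    labels: Mapping[str, RiskLabel | str],
    fingerprint: Fingerprint,
    config: CVNConfig,
) -> float:
    """Fraction of labeled patients whose held-out call matches their label
    (abstentions count as misses)."""
    return loo_score(states, labels, fingerprint, config)[0]


def loo_score(
    states: pd.DataFrame,
    labels: Mapping[str, RiskLabel | str],
    fingerprint: Fingerprint,
    config: CVNConfig,
) -> tuple[float, float]:
    """(accuracy, mean signed vote margin) of the held-out coherent vote.

    Accuracy counts abstentions as misses.  The margin term is the
    normalized weight difference of each patient's vote, signed by
    correctness (abstentions contribute 0): a continuous measure of how
    confidently the communities vote, used to order fingerprints that tie
    on the discrete accuracy.
    """
    labs = _labels_as_str(labels)
    if not labs:
        raise ValueError("no labeled patients")
    structural = mine_bicliques(states, fingerprint, config)
    counts = []
    membership: dict[str, list[int]] = {}
    for ci, com in enumerate(structural):
        nh = nl = 0
        for pid in com.patients:
            lab = labs.get(pid)
            if lab == CALL_HIGH:
                nh += 1
            elif lab == CALL_LOW:
                nl += 1
            membership.setdefault(pid, []).append(ci)
        counts.append((nh, nl))
    n = 0
    correct = 0
    margin_sum = 0.0
    for pid, truth in labs.items():
        n += 1
        held_high = truth == CALL_HIGH
        w_high = w_low = 0.0
        for ci in membership.get(pid, ()):
            nh, nl = counts[ci]
            if held_high:
                nh -= 1
            else:
                nl -= 1
            labeled = nh + nl
            if labeled <= 0 or nh == nl:
                continue
            purity = max(nh, nl) / labeled
            if purity < config.purity_threshold:
                continue
            w = len(structural[ci].patients) * purity
            if nh > nl:
                w_high += w
            else:
                w_low += w
        total = w_high + w_low
        if total <= 0:
            continue
        margin = abs(w_high - w_low) / total
        right = (w_high > w_low) == held_high and w_high != w_low
        if margin > config.vote_margin and right:
            correct += 1
        margin_sum += margin if right else -margin
    return correct / n, margin_sum / n


def single_feature_loo_accuracy(
    states: pd.DataFrame,
    labels: Mapping[str, RiskLabel | str],
    config: CVNConfig,
) -> pd.Series:
    """Vectorized held-out coherent-vote accuracy of every single feature.

    With one feature the communities are exactly the per-state patient
    groups, so the leave-one-out vote reduces to the majority label of the
    patient's own state group with that patient's label removed, subject to
    the community-size and purity thresholds.  Used to screen and seed the
    greedy fingerprint search.
    """
    labs = _labels_as_str(labels)
    pids = [p for p in states.index if p in labs]
    if not pids:
        raise ValueError("no labeled patients")
    y = np.array([1 if labs[p] == CALL_HIGH else 0 for p in pids])
    n_lab = len(pids)
    acc = np.zeros(states.shape[1])
    state_codes = {STATE_DOWN: 0, STATE_MID: 1, STATE_UP: 2}
    sub = states.loc[pids]
    all_arr = states.to_numpy()
    for j in range(states.shape[1]):
        col = sub.iloc[:, j].to_numpy()
        full_col = all_arr[:, j]
        correct = 0
        for s, code in state_codes.items():
            in_state = col == s
            n_members = int((full_col == s).sum())  # all patients, incl. unlabeled
            if n_members < config.min_community_patients:
                continue
            h = int(y[in_state].sum())
            l = int(in_state.sum()) - h
            # leave-one-out counts per member
            for is_high in (1, 0):
                k = (h - 1, l) if is_high else (h, l - 1)
                hh, ll = k
                labeled = hh + ll
                if labeled <= 0 or hh == ll:
                    continue
                purity = max(hh, ll) / labeled
                if purity < config.purity_threshold:
                    continue
                call_high = hh > ll
                n_such = h if is_high else l
                if call_high == bool(is_high):
                    correct += n_such
        acc[j] = correct / n_lab
    return pd.Series(acc, index=states.columns)


# ---------------------------------------------------------------------------
# Phase I: greedy candidate-fingerprint search


def search_candidate_fingerprints(
    train: Cohort,
    config: CVNConfig,
    seed: int = 0,
    screen_top_k: int = 40,
) -> list[Fingerprint]:
    """Greedy forward search with seeded restarts for candidate fingerprints.

    Features are first ranked by single-feature held-out coherent-vote
    accuracy on the training set; the top ``screen_top_k`` form the
    candidate pool.  Each restart seeds the fingerprint with one ranked
    feature and grows it greedily by the feature whose addition maximizes
    the held-out (accuracy, vote-margin) score -- the continuous margin term
    orders additions once the discrete accuracy saturates -- stopping when
    no addition improves the score or the size cap is reached.  Distinct
    fingerprints are returned ordered by that score (smaller fingerprints
    first among ties), at most ``config.max_candidates`` of them.
    Deterministic given ``seed``.
    """
    labs = _labels_as_str(train.labels)
    classes = set(labs.values())
    if len(classes) < 2:
        raise ValueError("training cohort must contain both risk classes")
    states = discretize(train.matrix, config.discretization)
    single = single_feature_loo_accuracy(states, labs, config)
    chance = max(
        sum(1 for v in labs.values() if v == CALL_HIGH),
        sum(1 for v in labs.values() if v == CALL_LOW),
    ) / len(labs)
    ranked = single.sort_values(ascending=False, kind="mergesort")
    ranked = ranked.loc[sorted(ranked.index, key=lambda f: (-ranked[f], f))]
    if ranked.iloc[0] <= chance:
        warnings.warn(
            "no single feature beats the majority-class rate; returning no candidates"
        )
        return []
    # only individually informative features enter the pool: a feature that
    # cannot beat the majority rate on its own contributes spurious
    # micro-communities rather than coherent votes
    pool = [f for f in ranked.index[:screen_top_k] if ranked[f] > chance]
    rng = np.random.default_rng(seed)

    found: dict[frozenset, tuple[tuple[float, float], Fingerprint]] = {}
    cache: dict[frozenset, tuple[float, float]] = {}

    def score_of(feats: tuple[str, ...]) -> tuple[float, float]:
        key = frozenset(feats)
        if key not in cache:
            fp = Fingerprint.from_features(feats, train.matrix)
            cache[key] = loo_score(states, labs, fp, config)
        return cache[key]

    n_restarts = min(config.max_candidates, len(pool))
    for restart in range(n_restarts):
        seed_feature = pool[restart]
        current = (seed_feature,)
        current_score = score_of(current)
        # shuffled pool order only diversifies tie resolution across restarts
        order = list(rng.permutation(pool))
        while len(current) < config.max_fingerprint_size:
            best_feat, best_score = None, current_score
            for feat in order:
                if feat in current:
                    continue
                s = score_of(current + (feat,))
                if s > best_score or (
                    s == best_score and best_feat is not None and feat < best_feat
                ):
                    best_feat, best_score = feat, s
            if best_feat is None:
                break
            current = current + (best_feat,)
            current_score = best_score
        key = frozenset(current)
        if key not in found:
            found[key] = (current_score, Fingerprint.from_features(current, train.matrix))
        if len(found) >= config.max_candidates:
            break
    # among candidates tied on (accuracy, margin), prefer fewer genes
    ordered = sorted(
        found.values(),
        key=lambda pair: (
            -pair[0][0],
            -pair[0][1],
            len(pair[1]),
            tuple(sorted(pair[1].feature_ids)),
        ),
    )
    return [fp for _, fp in ordered[: config.max_candidates]]
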