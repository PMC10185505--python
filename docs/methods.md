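# Methods

## The model

`cvnprog` stratifies cancer patients into high/low risk of disease
progression inside a *time frame* `(t, t+1)` (years): a patient who
progresses at or before `12t` months is high-risk, one who remains
progression-free at or beyond `12(t+1)` months is low-risk, and everything
in between — censoring before the low threshold, or an event inside the
open gap `(12t, 12(t+1))` — is *indeterminate* and excluded from training
and evaluation.  Both boundary comparisons are non-strict by default and
configurable (`strict_boundaries`), since tie handling at exact month
multiples is a convention, not part of the rule; events inside the gap can
optionally be folded into the high-risk class (`gap_events="high"`).

The classifier is a **coherent voting network (CVN)**.  Continuous features
are discretized into states (median split, or tertiles), always with
thresholds computed on the training patients and frozen, so no information
leaks from validation or test patients through the discretization.
Patients and `(feature, state)` pairs form a bipartite voting graph; a
*community* is a maximal biclique of that graph — a set of patients who all
share the same state on a set of features — with at least
`min_community_patients` members and `min_community_features` feature
states.  A community is *coherent* when its labeled members agree on one
risk class with frequency at least `purity_threshold`.  An unlabeled
patient is predicted by the communities containing them: each coherent
community votes its majority label with weight `size × purity`, and a call
is issued only when the normalized weight difference exceeds `vote_margin`;
otherwise the classifier abstains (`no_answer`).  The voting communities of
a call are returned as a per-patient certificate.

Community mining is exact.  Maximal bicliques are the closed itemsets of
the patient × (feature, state) incidence relation, and are enumerated by a
closure-based depth-first search.  Each patient carries at most one state
per feature, so with fingerprints of at most ~15 features the item universe
is at most ~45 items and enumeration is fast; a brute-force subset
enumeration serves as the oracle in the test suite.  `min_density < 1`
relaxes exact bicliques to quasi-bicliques by a single augmentation pass
(patients adjacent to at least that fraction of a community's feature
states are admitted); the default is exact.

### Default hyperparameters

| parameter | default | rationale |
|---|---|---|
| `discretization` | median split | robust two-state voting; tertiles available for dose-like signals |
| `min_community_patients` | 3 | smaller blocks are dominated by chance agreement |
| `min_community_features` | 1 | single-feature state groups are legitimate voters |
| `purity_threshold` | 0.8 | a clear supermajority without demanding unanimity |
| `vote_margin` | 0.0 | any nonzero weight difference yields a call; raising it trades coverage for precision (abstention is monotone in the margin) |
| `max_fingerprint_size` | 8 | fingerprints are meant to be small gene panels |
| `max_candidates` | 60 | upper end of the typical 30–60 candidate range |

## Phase I — candidate fingerprints

The search for candidate fingerprints is greedy forward selection with
seeded restarts.  Features are first screened by *single-feature held-out
coherent-vote accuracy* (a vectorized computation: with one feature the
communities are exactly the per-state patient groups, so the held-out vote
is the majority of the patient's own group with their label removed).
Only features that individually beat the majority-class rate enter the
candidate pool (capped at the top 40): a feature that cannot beat the
majority rate on its own contributes spurious micro-communities rather
than coherent votes.  Each restart seeds a fingerprint with one ranked
feature and grows it by the feature whose addition maximizes the held-out
`(accuracy, mean signed vote margin)` score.  The margin term matters:
on well-separated data the discrete leave-one-out accuracy saturates at
1.0 with two or three features, and the continuous margin then orders
additions by how much they strengthen the coherent vote, stopping when
additions dilute it.  Among candidates tied on score, smaller fingerprints
rank first — the method seeks minimal gene sets.

Leave-one-out evaluation inside the search withholds only the held-out
patient's *label*: the biclique structure is mined once per fingerprint
and the purity/majority of each community is recomputed without the
held-out label.  This matches prediction time, where the unlabeled patient
sits inside the voting graph structurally but contributes no label.

## Phase II — model selection under many hypotheses

Each (fingerprint, hyperparameter) pair evaluated on the validation set is
one hypothesis; with dozens of candidates times a hyperparameter grid, the
best validation score is an extreme order statistic and a poor estimate of
generalization.  Two procedures address this.

### Generalized LOOCVCV

For a uniformly random subset of `n'` of the `H` hypotheses, the
probability that the rank-`r` hypothesis (best first, ties broken by
index so the order is total) is the subset's best is exactly
`C(H−r, n'−1) / C(H, n')`; these probabilities are computed in exact
rational arithmetic and sum to one exactly.  For every held-out validation
patient `i`, hypotheses are re-ranked by the target computed without `i`,
and the held-out contribution of hypothesis `h` on `i` is the jackknife
pseudo-value `n·T(V) − (n−1)·T(V∖i)`.  For a decomposable target
(accuracy) this is exactly the per-sample correctness; for
non-decomposable targets (the kappa variants) it is the standard
well-defined notion of one observation's contribution.  (The plain
difference `T(V) − T(V∖i)` is *not* usable here: by the jackknife identity
it sums to zero over folds for any mean-type target, which makes every
hypothesis's accumulated contribution vanish.)  The expected held-out
contribution under the selection probabilities, averaged over patients,
gives a curve over `n'`; `n̂` is its argmax, and the chosen hypothesis is
the one accumulating the largest probability-weighted contribution at
`n̂` (ties to the lowest index).  Because the ranking in fold `i` never
sees patient `i`, a hypothesis that leads the full ranking only through
luck on a few patients receives little weight exactly where its luck lies.

The target functional is arbitrated once per selection run among four
abstention-aware agreement measures: Cohen's kappa ignoring no-answers,
that kappa scaled by the answered fraction, Gwet's AC1, and a mixed rule
(scaled up to 15% abstention — boundary inclusive — and AC1 beyond).
Each variant is normalized against its own empirical distribution across
hypotheses, and the variant whose best hypothesis has the largest z-score
displacement wins.  This guards the target against abstention artifacts:
plain kappa awards a perfect score to a hypothesis that answers five
patients and gets all five right, and such hypotheses are routine under
its own distribution, so the arbitration discounts it.

A note on what this procedure can and cannot buy: when hypothesis outcomes
are exchangeable Bernoulli draws (every noise hypothesis answering every
patient at chance), best-by-validation is the maximum-a-posteriori selector
and *no* procedure can beat it.  The overfitting the method targets arises
when validation scores have winner's-curse variance — precisely the
abstention regime above — and there the full procedure (arbitrated target
plus LOOCVCV) selects a genuine signal hypothesis out of 50 abstaining
noise hypotheses roughly twice as often as classical best-by-validation
kappa (about 0.6 vs about 0.25 over 200 replicates; recomputed by the
acceptance script).

### Pareto-stratified lookahead

Each hypothesis maps to a 3D point (validation hits, quality score,
answered fraction), all larger-is-better; quality is Cohen's kappa by
default, the odds ratio optionally, and the same functional is used in the
walk below.  Duplicate points are removed (lowest configuration index
kept).  Iterated extraction of the non-dominated front yields a Pareto
stratification; sorting each stratum by quality (ties by index) gives a
total order.  Walking that order, the validation quality is compared with
the test quality of the same configuration, stopping as soon as the test
quality is at least as good or within a relative displacement of 0.2
(relative to validation quality; absolute when it is zero).  The number of
comparisons is the *lookahead number*: a measured, controlled information
leak from the test set (1 = classical leak-free selection; values above 4
are flagged as not acceptable).  Ng-based selection never inspects the
test set and reports lookahead 0 by convention.

## Phase III — evaluation

The selected model is trained on the training split (the same training the
lookahead channel used, so the reported test quality means what the walk
measured) and applied to the test split.  The report contains the odds
ratio of the answered 2×2 table (Haldane–Anscombe +0.5 on all cells when
any is zero), its Wald 95% CI on the log scale and two-sided Fisher exact
p-value (the exact test is the defensible default at test-set sizes of a
few dozen; the CI method is a package choice, as is reporting all four
kappa variants alongside the standard one), the AUC via the
Mann–Whitney U equivalence with ties counted ½ (binary predictions are
scored high = 1, no-answer = ½, low = 0; bootstrap vote fractions are used
as scores when available), its tie-corrected asymptotic p-value, the
two-group log-rank p-value of the induced stratification, and Kaplan–Meier
step tables per predicted group (via lifelines).  Summary rows over
multiple reports use arithmetic means for values and geometric means for
p-value columns.

## Validation on independent cohorts

Independent cohorts are too small to split three ways.  The fingerprint is
frozen; hyperparameters are tuned by leave-one-out prediction over a small
grid, discarding configurations whose abstention fraction reaches 15%
(strict, configurable) and choosing the best odds ratio (ties: kappa, then
grid order).  The tuned configuration is evaluated by bootstrapping:
each of `B = 200` rounds samples `m = 3n` patients with replacement,
trains on the distinct sampled patients and predicts the unsampled rest
(expected out-set fraction `(1−1/n)^{3n} → e⁻³ ≈ 0.050`); `m = 1.38n`
makes the expected out-set about a quarter of the cohort, mirroring a
train/validate/test split.  Per-patient TP/FP/TN/FN/NA indicators averaged
over the rounds in which the patient was out-of-sample give the smoothed
leave-one-out bootstrap estimates of the expected confusion counts (their
total equals the number of ever-out patients exactly; patients never
out-of-sample are excluded with a warning).  The odds ratio and kappa are
evaluated on the expected table, with the CI from the Wald formula on the
expected counts (a bootstrap-distribution CI would also be computable; the
Wald one is reported).  The AUC is not a linear functional of the
indicators, so it is computed on the *consensus* map instead: each
patient's most frequent out-of-sample prediction (ties, including
high/low ties, yield no-answer), scored by the fraction of high calls
among answered calls (½ when a patient never answered).

## The synthetic cohort generator

The generator emulates the structure the CVN assumes: two latent risk
classes (high prevalence 0.5 by default, matching the balanced cohorts on
which the published validations perform best), a planted signature of 5
features shifted by `effect_size` standard deviations (default 3 — a
strong, recoverable marker; 0 gives the null), 2000 total features at the
discovery scale, and survival times that respect the frame: high-class
event times uniform on `(2, 12t]`, low-class times uniform on
`[12(t+1), 12(t+1)+60)` with a 50/50 mix of late events and late
censoring.  A censoring pass then truncates 15% of patients uniformly over
their follow-up, exercising the indeterminate paths.  By construction
every non-censored patient's frame label equals the latent class, which
the tests assert.  Three optional clinical covariates (two ordinals and a
log-normal marker, all class-correlated) exercise mixed clinical + omic
fingerprints.

What the generator does *not* emulate: real platform noise and batch
effects, correlated co-expression modules, informative censoring, or the
marginal distributions of real clinical covariates.  Passing the recovery
tests therefore shows the machinery is correct and self-consistent, not
that any particular gene panel generalizes to real cohorts.

## Numerical and procedural choices

- Positive class is high risk everywhere.
- Ties are broken lexicographically (feature id, patient id, hypothesis
  index, configuration index) after the primary criterion, so every run is
  deterministic given its seed.
- Splits are stratified by label (about 1/2, 1/4, 1/4 per stratum, each
  piece within one patient of its target); a class with fewer than four
  members goes entirely to training with a warning.
- Label equalization subsamples only the majority class, down to
  `max_ratio` times the minority.
- Constant features collapse to a single state (warned) and carry no votes.
- Missing measurements stay missing: the patient simply has no edge for
  that feature and the corresponding communities exclude them.
- Binomial coefficients use exact integer arithmetic; probability ratios
  are reduced before float conversion.
- Degenerate agreement tables (chance agreement of 1) define kappa as 0
  with a warning; an all-abstaining confusion defines scaled kappa as 0.

## Problem sizes

The test suite and acceptance script run at the scale the method is
specified for where that is cheap (summary conventions, probability
exactness, Pareto/LOOCVCV oracles, 200-patient × 2000-feature recovery)
and at reduced but structurally identical sizes elsewhere (e.g. 100–160
patients and 60–400 features for bootstrap and pipeline checks), chosen so
the whole suite runs in well under an hour on one CPU.

## Known limitations

- The biclique enumeration is exponential in the worst case; it is
  intended for fingerprint-restricted graphs (≤ ~15 features), not for
  mining communities over whole omics matrices.
- The quasi-biclique relaxation is a single augmentation pass, not a full
  quasi-biclique miner.
- The LOOCVCV hypothesis-extraction rule ("largest accumulated
  probability-weighted contribution") is one concrete reading of a
  procedure usually described only qualitatively; it is confined to
  `loocvcv_select` so alternatives can be swapped in.
- No multivariable Cox modeling, calibration analysis, or batch-effect
  correction; cohorts are assumed pre-normalized.
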