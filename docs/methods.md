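# Methods

This note records the modeling choices, numerical conventions and known
limitations of the `giddi` implementation. All quantities mentioned here
are computed by code in this repository (tests, examples, or
`scripts/acceptance.py`); none are imported claims.

## Features

Sixteen features per unordered drug pair, in four groups:

- **Indication similarity (4).** Each drug's indication PT set is mapped
  to MedDRA level L ∈ {PT, HLT, HLGT, SOC} by taking the union of
  ancestors over all hierarchy paths (multi-axial placements contribute
  all their parents), then the Jaccard index |A∩B|/|A∪B| is computed at
  each level. An empty term set makes all four features unavailable.
- **Side-effect similarity (4).** Identical construction on side-effect
  PT sets.
- **Target similarity (4).** For every cross pair (gₐ, g_b) of the two
  drugs' target proteins, the normalized local-alignment similarity
  SW(a,b) / √(SW(a,a)·SW(b,b)) is computed; min/mean/median/max summarize
  the cross-pair values. A shared identical target contributes 1.0. With
  no targets on either side the features are unavailable.
- **Genetic interaction (4).** Allele-level yeast GI measurements are
  filtered at p < 0.05 (strict) and averaged per unordered gene pair.
  A human target pair (gₐ, g_b) is scored as the mean collapsed GI score
  over scored homolog pairs (x, y), x ≠ y; unscored candidate pairs are
  omitted rather than zero-filled. Cross pairs where both drugs share the
  same gene are excluded (a gene has no GI with itself).
  Min/mean/median/max over scored cross pairs; no scored pair ⇒
  unavailable.

Unavailability is explicit end to end: `None` at the scalar API, `NaN` in
the feature table. Only pairs with all 16 features available are used for
training and evaluation (`filter_complete`).

## Alignment conventions

Smith–Waterman local alignment with affine gaps; a gap of length L costs
`gap_open + (L−1)·gap_extend`, i.e. the first gapped residue is charged
the opening cost, and `gap_extend = gap_open` recovers linear gaps.
Default scoring is BLOSUM62 with gap open 11 / extend 1; a
match/mismatch pair may be substituted. The production path is Biopython's
`PairwiseAligner`; the test suite carries an independent plain Gotoh DP
and checks exact score equality on hundreds of random protein pairs.

## Labels, splits and leakage

Positives are labeled interacting pairs; every other pair over the drug
universe is a negative unless listed as an exclusion (evidence too
ambiguous to trust either way), in which case it is omitted. Drugs are
split 2:1 into training and test drugs; pairs are routed by membership
and cross pairs dropped (≈ 4/9 of a complete graph; measured mean 0.452
at 60 drugs). A split is accepted when
|prev_train − prev_test| / prev_all ≤ 0.25, resampling with derived seeds
up to 1,000 attempts. Hold-out validation trials re-split the training
drugs with the same rules. The file pipeline's evaluate stage re-checks
that no model training drug appears among the test drugs and aborts
otherwise.

## Group-MCP selection

MCP penalty: λ|t| − t²/(2γ) for |t| ≤ γλ, constant γλ²/2 beyond; group
form penalizes each group's coefficient norm scaled by √(group size),
γ = 3 by default. Solver: proximal gradient (ISTA) on the standardized
design with warm starts along a 100-point log-spaced λ path, step
1/Lipschitz with the logistic majorization constant 1/4, unpenalized
intercept updated by one-dimensional Newton steps.

The group prox uses firm thresholding when γ·v > 1 (v = curvature). For
logistic loss v can make the firm denominator non-positive; the prox of
the majorized objective is then concave between its endpoints and is
resolved exactly by endpoint comparison, yielding a hard threshold at
λ√(γ/v). The λ-path entry point is inflated accordingly so the path
starts at the all-zero solution. On orthonormal designs with squared loss
the solver matches the closed-form firm threshold to < 1e−6 (verified in
tests with `fit_intercept=False`; with a fitted intercept non-centered
orthonormal columns couple and the identity is only approximate).

λ is chosen by mean held-out deviance over 5 drug-based 2:1 row splits
(random row splits when pair identities are not supplied). If selection
returns an empty set, the downstream model falls back to all 16 features.

## Classifier and tuning

XGBoost binary classifier (`tree_method=hist`, single thread,
deterministic given seed). Nine tuned dimensions: learning_rate
(log 0.01–0.3), max_depth (2–8), min_child_weight (1–10), subsample and
colsample_bytree (0.5–1), gamma (0–5), n_estimators (20–150), reg_alpha
(log 1e−3–10), reg_lambda (log 1e−2–10).

The tuner is an in-package TPE: 10 random warm-up trials, then per
iteration the history is split at the 0.25 loss quantile, 1-D truncated
Gaussian Parzen densities (bandwidth max(σ·n^−0.2, span/50)) are fitted
to the good and bad sets per dimension, 24 candidates are drawn from the
good density and the one maximizing Σ log g(x) − log b(x) is evaluated.
The loss is 1 − mean AUPR over hold-out trials that are pre-generated
once and shared across all trials, so losses are comparable and no
validation drug is ever seen during fitting. Desk-scale defaults are 50
iterations × 10 hold-outs; larger budgets are configuration only.

## Evaluation

- AUROC from average ranks (Mann–Whitney; ties count 1/2).
- AUPR as step-based average precision over distinct score thresholds
  (no linear PR interpolation).
- Curves averaged across hold-out runs on a fixed 1,001-point grid:
  linear interpolation for ROC, previous-point steps for PR.
- Two-sided permutation test on the difference of sample means:
  exhaustive enumeration with exact tie handling when C(n,k) ≤ n_perm,
  otherwise Monte Carlo with the add-one estimator (1+hits)/(1+N), which
  is never exactly zero and is exactly valid at test level α when
  α(N+1) is an integer.
- The novel-prediction cutoff maximizes the across-run mean F1 on a
  0.01-spaced probability grid, ties resolved toward the larger
  (more conservative) cutoff.

## Synthetic cohort generator

The generator is the package's study instrument, not a convenience mock;
its defaults are the study conditions. Drugs belong to latent clusters
(8 by default). The planted signal works through the clusters so that
every modality carries correlated evidence:

- interaction odds are multiplied (×12) for within-cluster pairs, with
  the between-cluster rate calibrated so overall prevalence matches the
  requested value (0.1);
- each cluster has a term pool from which member drugs draw part of
  their indication/side-effect sets, and each positive pair additionally
  receives identical shared risk terms;
- each cluster is associated with a paralog family of target variants;
  member drugs usually carry a family variant, and positive pairs are
  boosted toward carrying family members;
- yeast homolog pairs within a family receive shifted GI scores
  ~ N(δ = −0.4, σ = 0.2) with mostly passing p-values.

Realistic nuisance structure is included: multi-parent MedDRA
placements, 0–2 yeast homologs per gene (some genes have none, making
their drugs' pairs incomplete), failing allele measurements, and an
exclusion list. The `null()` variant sets the cluster odds to 1 and all
effect sizes to zero, changing nothing else.

Measured behavior (seeds 1–10, desk scale; see
`tests/test_acceptance.py` and `scripts/acceptance.py`): planted-cohort
test AUROC typically 0.70–0.80, null-cohort AUROC within 0.40–0.60.

## Determinism

All randomness flows through `numpy.random.default_rng` with explicitly
derived seed sequences (`[seed, subkey]`), so every stage — generation,
splitting, selection CV, TPE, evaluation — reproduces exactly from its
seed. XGBoost runs single-threaded with a fixed `random_state`.

## Limitations

- Desk-scale tuning (50 × 10) explores far less of the hyperparameter
  space than large-budget settings; reported numbers are not tuned to
  saturation.
- The synthetic generator demonstrates mechanism recovery, not clinical
  performance; absolute metric values on synthetic cohorts say nothing
  about real-world accuracy, and no claims are made about real drug
  data, which require licensed sources.
- The GI homology mapping uses a provided human→yeast table as-is; no
  orthology inference is performed.
- The permutation test targets mean differences only; heavy-tailed
  feature distributions may warrant rank-based contrasts instead.
- Group-MCP is solved by proximal gradient, which for nonconvex
  penalties guarantees stationary points, not global optima; warm starts
  along the λ path mitigate but do not remove this.
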