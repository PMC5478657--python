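# Methods

This note describes the model implemented by `omniga`, the choices made where
the design was genuinely open, and what the test suite does and does not
demonstrate.

## The model

An **omnivariate decision tree (ODT)** is a binary tree of fixed maximum
depth 5 (at most 2⁵ − 1 = 31 nodes, indexed breadth-first with the root at 1)
whose internal nodes each host their own two-class classifier:

- **MLR** — ridge-penalized logistic regression (penalty λ on a grid
  {1e−8, 1e−4, 1e−2, 1, 10}),
- **C45** — an entropy decision tree with a minimum-instances-per-split
  constraint ({2, 5, 10}) and bottom-up error-based pruning: a subtree is
  collapsed when the Clopper–Pearson upper confidence bound (confidence
  factor ∈ {0.1, 0.25, 0.5}) on its training error is no better than that of
  the collapsed leaf,
- **ANN** — a single-hidden-layer perceptron (hidden nodes ∈ {2, 5, 10,
  ⌈(d+2)/2⌉}, learning rate ∈ {0.3, 0.1, 0.01}),
- **RF** — a random forest (trees ∈ {10, 50, 100, 200}; candidate features
  per split ∈ {⌈√d⌉, ⌈log₂d⌉+1, d/4}).

Every node model obeys one contract: `predict_proba` returns a pair
(P(class 1), P(class 2)) summing to 1. Internal nodes route each sample to
one of two children by comparing the dominant-class score with a per-node
threshold in [−0.65, 0.65]; leaves carry the add-one (Laplace) smoothed class
distribution of their training samples, and the predicted label is its
argmax (ties to class 1).

### Routing semantics and a known pathology

The default `route_sample` implements the data-splitting pseudocode exactly
as specified, including its second branch:

- class-1 dominant (P₁ ≥ P₂): branch 1 iff P₁ ≥ t, else branch 2;
- class-2 dominant: branch 2 iff P₂ ≤ t, else branch 1.

Read literally, branch 2 receives exactly the scores P₁ ∈ [1 − t, t) — an
uncertainty band symmetric around ½, which is empty for t ≤ ½. High-
confidence class-2 samples therefore travel with high-confidence class-1
samples, and no threshold value can separate the two classes into different
subtrees. Under this rule an evolved tree's test F1 on separable rule data
plateaus near the all-one-class level (we measure ≈ 0.65), whereas the
symmetric variant — class-2 dominant: branch 2 iff P₂ ≥ t — routes by
predicted class and recovers the rules almost perfectly (≈ 0.99). We keep
the literal rule as the default because it is the stated contract, verify it
against an exhaustive truth-table oracle, and expose the discriminative
variant behind `symmetric_routing=True`. The rule-recovery acceptance run
and any real use of the package for classification should set this flag.

### Stopping criteria (defaults)

A node becomes a leaf when any of: depth 5 reached; the node is pure;
minority:majority ratio ≤ 1/500; or the node holds fewer than the minimum
number of instances — 100 when the training set exceeds 2,000 samples, else
⌈5% of the training set⌉ (the two rules coincide exactly at 2,000).

### Add-ons (2³ = 8 induction configurations)

- **SMOTE** — when a node's imbalance strictly exceeds 1:5, the minority
  class is grown by nearest-neighbour interpolation (k = 5, reduced when the
  minority is tiny) by a percentage (majority/minority − 1) × 50, bringing
  the minority to round((minority + majority)/2). Synthetic rows exist only
  for that node's model fit; children always partition the original samples.
- **ES** — a 2-bit genome field selects a training-effort fraction
  {0.25, 0.5, 0.75, 1.0}. Effort scales the ANN epoch budget (120 epochs at
  full effort), the RF tree count, the MLR optimizer iteration budget (200),
  and caps the C45 depth at ⌈fraction × unrestricted depth⌉. The epoch and
  iteration budgets are this package's choices; the four-level fraction
  grid likewise.
- **DL** — each child receives two extra feature columns: the parent's
  per-sample prediction score P(class 1) and the parent's split threshold.
  Augmentation is cumulative along the path (a depth-k node sees
  d + 2(k − 1) columns); at prediction time the columns are recomputed on
  the fly along each sample's own path.

## The genetic algorithm

A genome is 31 breadth-first node genes: model type ∈ [−1, 3] (−1 = pruned;
a pruned gene turns the slot into a leaf and its subtree is ignored),
threshold ∈ [−0.65, 0.65], a 4-bit parameter block indexing the model kind's
grids (out-of-range indices wrap modulo the grid size, so every bitstring
decodes), and the 2-bit ES field. Fitness is validation-set F1 (metric
configurable), scaled by subtracting the population's worst fitness;
parents come from a roulette wheel on the scaled values (uniform fallback
when all are zero). Crossover draws two distinct cut points on node
boundaries only — never inside a gene's bits — and exchanges the middle
splice; mutation is typed per position (model type redrawn uniformly in
[−1, 3], threshold in [−0.65, 0.65], bits flipped), each position mutating
independently with probability p_m. Elitism re-inserts the previous
generation's fittest genome over the new generation's worst, so the running
best validation fitness never decreases.

Defaults (open in the design, fixed here): population 20, 50 generations,
early halt after 10 non-improving generations, and an additional halt when a
genome reaches perfect validation fitness — continuing to evolve past a
perfect score cannot improve the selected model. Fitness evaluations are
seeded per (run seed, generation, genome index) and are independent, so
parallel evaluation through joblib is bit-identical to sequential.

## Prediction schemes and the framework

Each GA run yields three predictors: (1) the fittest genome's tree; (2) the
best of population−3 majority-voting committees (sizes 3 … population−1,
each the fittest tree plus randomly drawn distinct others; vote ties go to
the fittest member); (3) a random-forest meta-learner over a
3-features-per-tree stacked representation (signed score P₁ − P₂, the
threshold at the last internal node on the sample's path — 0 for a
single-leaf tree — and the predicted label as ±1), fitted on the validation
set with the tree count chosen by out-of-bag score. The validation set
trains the stacker because it is the only labelled data not consumed by
node-model training. The scheme with the best validation score becomes the
model's predictor; ties prefer the simpler scheme.

The framework crosses the 8 add-on configurations with a grid over
(p_c, p_m) ∈ {0.6, 0.8, 0.95} × {0.01, 0.05, 0.10} (stand-in defaults, all
configurable), runs one GA per cell, and keeps the best validated model.
Failed runs are logged and excluded, never silently replaced. Data handling:
2/3 train (of which 15% is reserved for validation), 1/3 test, stratified
and seed-reproducible; features min-max normalized to [−1, 1] on the
training partition (test values clipped, constant features mapped to 0);
for data with more than 300 features, gain-ratio ranking (10 equal-frequency
bins on the training partition; zero split-information features score 0;
ties by column order) keeps the top 300. The positive class for F1 defaults
to the training minority class.

## Synthetic data

`generate_rule_dataset` draws features uniformly on [−1, 1]^d and labels
them with a mutually exclusive, exhaustive set of conjunctive threshold
rules (an axis-aligned partition built by recursively splitting the
largest box), then meets the requested class ratio exactly by bounded
rejection sampling and optionally flips labels with a given noise rate. The
benchmark-scale preset is 2,000 samples × 65 features, balanced, noise-free,
8 rules — rule count and noise are this package's choices, since only the
size, dimension and balance of the reference benchmark are known.
`generate_imbalanced_gaussians` provides the 1:5+ imbalance regimes that
trigger SMOTE. What these fixtures do not emulate: correlated features,
covariance structure of real biomedical data, label noise that depends on
the features, or heavy-tailed marginals — passing tests show the machinery
is correct on rule-structured data, not that real-data performance matches
any published figure.

## Numerical choices and edge cases

- Thresholds are compared directly with probabilities; a negative threshold
  makes the dominant-class test always pass (branch 1).
- SMOTE synthetic counts use integer half-up arithmetic,
  n_new = (majority − minority + 1) // 2, so the count identity holds
  exactly regardless of parity.
- An empty routing branch becomes a leaf inheriting the parent's class
  distribution; a failed node-model fit likewise degrades the node to a
  leaf with a logged warning; a failed genome evaluation scores fitness 0.
- Partition sizes: validation = ⌊0.15 · pool⌋, remainder to train.
- Equal-frequency binning deduplicates identical quantile edges, so
  low-cardinality features get fewer bins.

## Problem sizes used in the checks

The structural full-expansion check uses coin-flip labels with
label-independent logistic routing hyperplanes (4,000 × 100), which keeps
every node impure and well-populated so all 31 slots fill; the rule-recovery
check runs a reduced search (one add-on configuration, population 10,
10 generations, symmetric routing) on the 2,000 × 65 noise-free preset; GA
property checks use a 400-sample fixture over 30 generations. These sizes
are the package's own test design.

## Known limitations

- Two-class problems only; the genome layout and routing are binary.
- The literal routing default is faithful to its stated contract but is not
  useful for classification (see above); users must opt into
  `symmetric_routing` for discriminative trees.
- The C45 node is a C4.5-style contract (entropy splits, error-based
  pruning, minimum instances), not a bit-for-bit reimplementation of any
  particular toolkit.
- Parameter grids, GA defaults and the (p_c, p_m) grid are declared
  stand-ins where the original configuration is not public.
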