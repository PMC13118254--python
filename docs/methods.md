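# Methods

## Scope

`ghcnse` scores candidate metabolic reactions for a given GEM from
topology alone. The package covers: reading GEMs and candidate pools
(BiGG JSON, SBML Level 3), building the co-participation graph and the
reaction hypergraph, substitution-negative sampling and stratified
cross-validation, the two-branch convolutional scorer with
squeeze-and-excitation (SE) enhancement, training, the five prediction
metrics plus recovery rates, pool scoring/selection for gap-filling, and
a synthetic-GEM generator that makes every stage testable without
downloads.

## Network reduction

Reactions are reduced to member *sets*: stoichiometric coefficients,
substrate/product roles, and reversibility are discarded at parse time,
because both topological constructions are binary and undirected — an
edge (or hyperedge incidence) records only that two metabolites
co-participate. Compartmentalized metabolites are distinct nodes.
Exchange and boundary pseudo-metabolites are kept as ordinary nodes; no
reaction classes are filtered. A metabolite appearing on both sides of a
reaction contributes one member.

Both topologies are built **from positive training reactions only**.
Held-out reactions and pool candidates are scored against that fixed
topology and never contribute edges; pool-only metabolites receive
learnable embeddings but are isolated nodes.

## Degree conventions

The graph propagation matrix is `A₁ = D⁻¹(A + I)` with `D` the degree
matrix of `A` alone, exactly as the architecture defines it (the row sum
is therefore `(dᵢ+1)/dᵢ`, not 1). Isolated nodes have degree 0, so every
inverse and inverse square root substitutes degree 1 element-wise; an
isolated node's propagation row becomes a unit self-pass-through and no
NaNs enter the pipeline.

## The SE block is per-reaction

The squeeze index set is the candidate reaction's member set: squeeze
averages the fused features over that reaction's members, excitation
produces one channel-weight vector per reaction, and only that
reaction's member embeddings are rescaled before the head pools them.
This is the reading consistent with the output head, which pools the
same member set; the alternative (one global squeeze over all nodes)
would make the block reaction-independent and the excitation output a
constant per batch.

## Hyperparameters

| symbol | meaning | default |
| --- | --- | --- |
| N₀ | embedding width | 256 |
| N₁ | adaptation width | 128 |
| N₂ | GCN output width | 128 |
| N₃ | HGCN / fusion width | 128 |
| N₄ | SE bottleneck (≤ N₃) | 16 |
| N₅ | head width | 64 |
| learning rate | Adam, constant | 5×10⁻⁴ |
| epochs | cap, with early stopping | 100 |
| batch size | reactions per step (full batch when fewer) | 256 |
| threshold | score binarization for recall/F1/accuracy/precision | 0.5 |

Widths were confirmed by the method's own calibration protocol: a grid
of proportionally scaled ladders evaluated by 5-fold CV AUPRC on a
held-aside tuning GEM generated with the same synthetic conditions
(generator seed 1729); the full-width ladder won and is the default.
Early stopping watches the epoch-mean training loss (patience 10,
min-delta 10⁻⁴). Adam uses β = (0.9, 0.999), ε = 10⁻⁸, no weight decay,
no dropout, no learning-rate schedule (a step decay is available as a
config option). `W₅` is a dense learnable m×m matrix initialized to the
identity, which makes the untrained hypergraph branch a plain
degree-normalized hypergraph convolution; a diagonal-only
parameterization is the natural memory fallback for large models.
Remaining weights use fan-in-scaled uniform (Kaiming-style)
initialization; embeddings are standard normal.

## Numerical choices

* Everything runs in float64 on a small reverse-mode autodiff engine
  (`ghcnse.autodiff`); for a fixed seed, training, scoring and
  checkpoints are bit-reproducible on one platform.
* LayerNorm has no learned affine terms and uses ε = 10⁻⁶: in float64
  this keeps standardized rows within 10⁻⁴ of unit variance for any
  realistic feature scale (an ε of 10⁻⁵ measurably distorts rows whose
  raw variance is below ~0.1).
* Batch normalization in the hypergraph input MLP normalizes each
  channel over all n nodes (biased variance), tracks running statistics
  with momentum 0.1, and uses them at evaluation, so a reaction's score
  does not depend on what else is in its batch.
* Scores are clamped to [10⁻⁷, 1−10⁻⁷] inside the cross-entropy only.
* AUPRC is computed as average precision (step-wise integral with tied
  scores grouped), not trapezoidal interpolation.
* Empty metric denominators (no predicted positives, no true positives)
  return 0 with a log note rather than raising.
* Recovery ties at rank k break by stable reaction-id order.
* Negative sampling retries a corruption colliding with a real reaction
  up to 100 times, then accepts it with a logged warning.

## Synthetic benchmark: what it emulates and what it does not

The generator partitions `n_metabolites` into `n_modules` communities
and draws each reaction's members from a single community with
probability `within_module_prob` (default 0.9), otherwise uniformly.
This plants exactly the kind of signal a topology-only scorer can use —
community-localized metabolite reuse, loosely mimicking pathway
structure — while `n_modules=1` gives a module-free null generator for
negative controls. Defaults (40 metabolites, 60 reactions of size 2–4,
4 communities, p = 0.9) define the desk-scale benchmark used by the
tests and the acceptance script; real GEMs are 2–3 orders of magnitude
larger, and the benchmark does not attempt realistic degree
distributions, hub metabolites (ATP, H₂O), stoichiometry, or multiple
compartments (a single `_c` suffix is kept for format realism).

Two properties of the benchmark bound what any scorer can achieve on
it. First, 10% of planted reactions carry no community signal by
construction and are indistinguishable from corrupted sets. Second, a
substitution negative replaces one member uniformly at random, so with
4 equal communities of 10 in a 40-metabolite universe roughly 9/39 ≈
23% of swaps land in the source community and leave the negative
coherent. Perfect separation of held-out positives from substitution
negatives is therefore impossible by design; the meaningful comparisons
are against the 0.5 balanced-chance baseline and the null-generator
control, and those margins — not absolute AUPRC — are what passing
tests demonstrate. Passing on this benchmark shows the pipeline learns
planted co-participation structure end-to-end; it does not certify
performance on real GEMs.

At this scale the free embedding table (n×N₀ parameters against ~100
training samples) lets the model drive training loss near zero while
held-out performance peaks earlier; the early-stopping default rarely
triggers before the epoch cap. This is a known small-data regime
limitation, accepted rather than patched with regularizers that the
architecture does not specify. One visible consequence is that removing
the hypergraph branch — whose dense W₅ contributes most of the excess
capacity — can match or slightly exceed the full model on the smallest
benchmarks, while with more training reactions (and in the regime the
architecture targets) the full model is expected to dominate.

## Evaluation protocol

The dataset is the GEM's reactions plus one substitution negative per
positive, generated once per experiment. Stratified 5-fold splitting
yields 4:1 train:test with balanced classes on both sides; each fold
retrains from scratch on its own topology. Recovery evaluation replaces
the fold's negative test samples with every pool reaction whose member
set is absent from the GEM and reports the fraction of true held-out
reactions among the top 25/50/100/N scores (N = the fold's positive
count). Gap-filling ranks the pool by confidence and selects by top-k
or threshold; combining confidence with auxiliary similarity evidence
is left as a pluggable hook (`secondary_score`) rather than inventing a
formula.

## Problem sizes

Tests and the acceptance script use the 40-metabolite benchmark
(5-fold CV ≈ 6 s per dataset on one CPU), a 200-reaction candidate pool
for recovery, and 5 experiment seeds × 4 variants (one 80/20 split
each) for the ablation comparison; the full acceptance run completes in
under a minute. These sizes are the package's chosen desk-scale study
conditions; the implementation itself is dense-matrix and handles
10³–10⁴ nodes, where the dense n×n propagation and m×m W₅ become memory
bound.

## Known limitations

* Purely topological: no biochemical features, no thermodynamics, no
  flux consistency check of gap-filled models.
* Dense matrices throughout; very large GEMs need the diagonal W₅
  option and a sparse propagation path that is not implemented.
* The score threshold 0.5 is a convention; calibrated thresholds per
  GEM are not attempted.
* Single-platform bit-reproducibility only; BLAS differences across
  platforms can change low-order bits.
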