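# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not establish.

## Synthetic cohorts: what is emulated and what is not

The generators define the conditions under which everything downstream is
tested.

**Tabular cohort** (`gen_tabular`).  An OASIS-style cross-sectional schema:
age (years, Gaussian, baseline 72 ± 9), sex (Bernoulli, p = 0.55), an
MMSE-like mental-state score (27 ± 2, clipped to [0, 30]), a CDR-like
ordinal in {0, 0.5, 1, 2} drawn from a class-conditional categorical,
normalized whole-brain volume (0.74 ± 0.04), and estimated intracranial
volume (1490 ± 160 cm³).  Class effects are additive mean shifts
(demented − non-demented); the CDR effect is an exponential tilt
exp(e·level) on the base probabilities so that e = 0 gives identical
distributions — this keeps "all effects zero" a genuine null across every
feature, including the ordinal one.  Default shifts (age +4 y, MMSE −5,
nWBV −0.04, CDR tilt 3) are in the range a clinician would call typical for
a mild-to-moderate dementia contrast.  Label counts follow
round(balance · n) exactly.  Not emulated: longitudinal visits, missing
data, site effects, correlated features.

**Phantom images** (`gen_images`).  Single-channel floats in [0, 1],
written as 8-bit PNG (v → round(255·v)) so fixtures are bit-exact.  Lesions
are isotropic Gaussian blobs truncated at 3σ; the ground-truth box is the
tight 3σ bound (0-based, half-open, row-major — the convention used
everywhere in the package).  Severity is encoded as blob count per class
(non-dementia 0, very mild 1–2, mild 3–4, moderate 5–6; disjoint ranges so
the label is a deterministic function of the image).  An optional
`min_separation` keeps blob centers apart when a test needs the count to be
visually unambiguous; infeasible geometry is a configuration error, not a
silent retry.  Not emulated: MRI physics, anatomy, partial-volume effects —
so image-side results demonstrate that the detector/classifier/LRP
machinery is correct, not that it would quantify real atrophy.

**Expression** (`gen_expression`).  Genes are linear-Gaussian
(baseline μ_g ~ N(8, 2), noise sd 1); the binary label is Bernoulli with
log-odds `edge_strength · Σ_d z_d` over the standardized driver values.
The class is the *only* collider, so the Markov blanket of the class node
is exactly the driver set — this is what makes "blanket recovery" a
well-posed benchmark.  Default drivers are named CTAGE6, F8A2, SAMD7.
Defaults: 200 genes × 104 samples, 3 drivers, strength 2 (log-odds sd
2√3 ≈ 3.5, a strong but not deterministic signal).  Not emulated:
gene–gene co-expression modules, batch effects, count noise.

## Tabular graph builder

The adjacency formula is stated with W_l, W_r ∈ R^{m×m} while the embedding
is E ∈ R^{m×d}; for d ≠ m the only dimensionally consistent placement of
square-in-m factors is on the left, so the package computes
A = row-softmax(σ(W_l E) σ(W_r E)ᵀ) with σ = sigmoid.  Inside the
convolution layers σ is ReLU (the conventional GNN default; the sigmoid is
specified only for the adjacency normalization).  The superscripted "E_k^0"
in the layer recurrence is read as the initial embedding, i.e. a residual
connection to E_0 at every layer — hence the invariant that zero layer
weights make the network the identity.

No training objective is prescribed for the builder, so it is trained as a
classifier with minimal invention: the per-sample feature matrix
E_0^i = diag(x^i)·B (column embeddings scaled by the standardized feature
values) runs through the K layers, is mean-pooled, and feeds a linear
cross-entropy head; B, W_l, W_r, W_k and the head are trained jointly.
Optimization is full-batch gradient descent with a backtracking step
(halve until the loss does not increase), which makes the recorded loss
history non-increasing by construction and keeps training deterministic.
Gradients are derived analytically and verified against finite differences
in the test suite.  Defaults: d = 8, K = 2, 150 epochs, initial step 0.5,
embeddings initialized N(0, 1)/√d.

`RowSample`'s distribution is the multinomial over the (normalized)
adjacency row; duplicate draws are merged so a graph has at most s·m
triples.  Because A is row-stochastic, every node's *outgoing* mass is 1 by
construction; the informative quantity is the attention a column *receives*
(its column mass), and that is what the learned-signal sanity check
measures.

## Image graph builder

The region detector is a deliberately simple, fully transparent stand-in
for a learned region-proposal network, behind a pluggable interface
(`DetectorConfig.classifier`, or replace `detect_rois` wholesale):
Gaussian smoothing (σ = 1), median background subtraction, thresholding at
max(0.08, 5·MAD-noise), connected components, and box estimation from
intensity-weighted second moments.  For a Gaussian blob the
intensity-weighted variance equals σ² (0.9733 σ² under 3σ truncation; the
estimator divides by that factor), so the reported box ±3σ̂ matches the
generator's ground-truth convention by *analysis*, not calibration.  When
several components are present, each component's moment window is masked to
the pixels nearer its own peak than any other peak, so a neighbor's halo
cannot inflate the estimate.  Greedy non-maximum suppression at IoU 0.3.

Relation probabilities use a fixed logistic score on pairwise geometry —
1.5·(1 − 2·dist/diag) + 2·IoU + corr of 8×8-resized crops — chosen to be
proximity-dominant and documented rather than trained, since no relation
training data exists in this setting.  The joint assignment score is the
product of per-ROI class factors and all ordered pairwise factors (all in
[0, 1], order-invariant).  Triples below weight 1e-6 are dropped; the
complementary clause weight 1 − α and the ROI's product probability P_x are
stored as entity metadata (JSON in the description field), not evaluated as
logic — no inference procedure over the weighted clauses is defined here.

The built-in classifier is a small explicit CNN (conv 5×5×6 → ReLU →
max-pool 2 → conv 3×3×8 → ReLU → global average pool → dense), trained with
Adam (lr 3e-3 default; the phantom benchmarks use 1e-2) on a stratified
75/25 split.  The global average pool is the right inductive bias for a
count-coded severity label: the conv stack detects lesions, the pool sums
their evidence.  Every layer implements explicit forward and backward
passes in numpy — the point is not speed but that the relevance rules below
can address each layer's exact linear structure.

## Relevance propagation

The ε-rule redistributes the **pre-softmax** class score (propagating the
probability would break conservation).  For linear/conv layers with
contributions z_ij = a_i w_ij and preactivation z_j:

R_i = Σ_j z_ij / (z_j + ε·sign(z_j)) · R_j.

Max-pooling is winner-take-all (relevance follows the argmax recorded in
the forward pass), average-pooling splits proportionally to window
activations, ReLU and reshapes pass relevance through.  At ε = 0 with zero
biases, conservation across every adjacent layer pair is an algebraic
identity and the tests assert it to 1e-6 relative; with ε > 0 the leakage
per layer is bounded by ε·Σ|R|/min|z| (asserted at 5% on the fixtures at
ε = 1e-3).  The default ε = 1e-6 trades a negligible leak for protection
against near-zero denominators; an exactly zero denominator can only carry
zero relevance and is guarded explicitly.  Relevance is linear in the
output-layer initialization (doubling the head doubles every relevance
value exactly — a test).  Unsupported layer types raise; nothing is
silently skipped.  Heatmaps normalize |R| by its maximum into [0, 1]
(an all-zero map stays zero); histograms use 256 fixed bins on [0, 1] so
counts always sum to the pixel count.

## Graphical gene tree

Design choices where the procedure was underspecified:

* **Permutation step = stability selection.**  The jittered replicates
  (uniform on [F_i − ε, F_i + ε], ε ∈ [0, 1]) are used to measure how
  stably a gene re-enters the class blanket; genes at frequency ≥ 0.5 are
  reported.  The alternative reading (sensitivity of a single classifier)
  gives no aggregation rule at all.
* **Screening.**  Structure search over tens of thousands of genes is not
  tractable for hill climbing; genes are pre-screened to the top 50 by
  mutual information with the class.  At the default signal strength the
  planted drivers clear screening with a wide margin.
* **Discretization.**  Per-gene tertiles — scale-free, and three levels keep
  CPTs well-populated at n in the hundreds.
* **Structure search.**  Greedy hill climbing with add/delete/reverse moves
  on the BIC score, max 3 parents per node, 3 restarts (restart 0 from the
  empty graph, others from seeded sparse random DAGs).  Acyclicity is
  checked before every move application via a reachability closure.  Family
  scores are cached, which is what makes 20-seed recovery runs over
  50 genes + class take seconds rather than hours.
* **Parameters.**  CPTs from counts with Laplace pseudocount 1; unseen
  parent configurations fall back to the uniform prior (never an error),
  and zero factors can therefore not poison the chain-rule joint.
* **Blanket search.**  BFS from the class: level 1 parents + children,
  level 2 the children's other parents; returned sorted.  An equivalent
  edge-algebra oracle (membership iff u→t, t→u, or a shared child) checks
  it on random DAGs.

A note on orientation: with the class as a pure collider the learned edges
may orient either way within the score-equivalence class, but the Markov
blanket is invariant to those re-orientations, which is why blanket
recovery (not edge recovery) is the benchmark.

## LIME and the submodular pick

Perturbations are Gaussian with per-feature sd equal to the training-set sd
(categorical columns are one-hot expanded upstream); similarity is
λ_x = exp(−d²/kw²) with d measured in sd units.  The surrogate is weighted
least squares; the complexity penalty Ω is realized as a hard cap: fit all
features, keep the `max_features` largest standardized slopes, refit on the
subset.  Fidelity is the λ-weighted R².  The black box for cohort tables is
an SVC with probability calibration inside a standardizing pipeline (the
probability estimates, not the margins, are what LIME locally regresses).

Global importance is I_j = sqrt(Σ_i |W_ij|) — the square-root column mass
of the explanation matrix, the original SP-LIME convention.  Coverage
counts a feature as covered when any picked instance has |W_ij| > 1e-12;
it is monotone and submodular (property-tested), so greedy selection with
lowest-index tie-breaking carries the (1 − 1/e) guarantee, which the tests
verify against exhaustive enumeration at small n.  Instances with zero
marginal gain are not picked, so |V| may be smaller than the budget.

For the class-level factor ranking, each instance's feature contribution is
its local slope times its standardized displacement from the cohort mean;
a class ranks features by the mean contribution toward it over its own
instances.  This is what makes "below-average brain volume" count *for*
the demented class even though its slope against p(demented) is negative.

## Evaluation and pipeline

AUC is computed by a threshold sweep with tied scores grouped, so the
trapezoid equals the Mann–Whitney statistic with ties counted ½ (asserted
to 1e-9 against scipy on random draws).  The pipeline derives every stage
seed from the global seed with fixed offsets, hashes the canonical config
and every artifact (SHA-256) into a manifest, and writes PNGs with fixed
metadata so reruns are byte-identical — determinism is asserted at the
manifest and dashboard level, not assumed.  A failed stage aborts with the
stage name and leaves the manifest flagging it; omitted stages render as
"absent" sections in the dashboard rather than errors.  The dashboard is a
single HTML file with all images inlined as data URIs, so it opens with no
network access.

## Problem sizes

The benchmarks run at deliberate desk scale: cohorts of 200–416 patients,
400 phantoms of 40×40 px for classifier training, 200 genes × 500 samples
with 50 screened genes for blanket recovery (20 seeds), and a demo pipeline
of 200 patients / 64 images / 120 genes.  These sizes are where the planted
effects are comfortably identifiable yet every experiment remains a
single-CPU job of seconds to a few minutes; the algorithms themselves are
size-agnostic, with the stated exception of hill-climbing structure search,
which is why screening exists.

## Known limitations

* The detector is tuned to blob-like bright lesions on dark backgrounds; it
  is a contract-satisfying baseline, not a clinical detector.
* Relation probabilities are heuristic; on real scene-graph data they
  should be replaced by a trained pairwise model via the pluggable
  interface.
* The GGT explainer reports association structure (a Markov blanket), not
  causal effects; tertile discretization discards within-tertile dose
  information.
* SP-LIME explanations inherit the black box's calibration; a poorly
  calibrated classifier yields faithful explanations of a wrong model.
* Passing recovery benchmarks on the synthetic cohorts shows the machinery
  is correct under the stated generative assumptions (independent features,
  single collider, isotropic lesions); it does not certify performance on
  real OASIS/GEO-style data, which violate all three.
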