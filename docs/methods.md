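# Methods

## The problem

Non-small-cell lung cancer brain metastases carry actionable EGFR variants —
exon-19 deletions (19Del), the exon-21 L858R point mutation (21L858R), or
wild-type EGFR (WT) — and biopsy of intracranial lesions is often infeasible.
`radiogcn` implements a noninvasive classifier of per-lesion EGFR status from
four co-registered MRI sequences (T1-CE, T2W, T2-FLAIR, DWI): radiomics
feature extraction, dual feature standardization in place of feature
selection, learned attention fusion of the per-sequence feature vectors, a
GraphSAGE classifier on a lesion-similarity graph, and average aggregation of
lesion probabilities to patient-level calls — plus the evaluation and
ablation protocol around it, and a synthetic-data module that makes the whole
pipeline testable without clinical data.

## Pipeline stages

### Preprocessing and feature extraction

Volumes and masks are resampled to 3 × 0.25 × 0.25 mm (linear interpolation
for images, nearest-neighbour for masks; per-axis size
`round(n · spacing_in / spacing_out)` so physical extent is preserved within
a voxel), lesions smaller than 5 mm in diameter are excluded (diameter =
maximum per-axis bounding-box extent, an inexpensive monotone surrogate for
the true maximal 3-D diameter; the 5.0 mm boundary is inclusive), each lesion
is cropped to its mask bounding box, and the patch is MinMax-rescaled to
[0, 255] (a constant patch maps to zeros).

Features follow the standard IBSI-aligned definitions, computed in
numpy/scipy: 18 first-order, 14 shape (mesh volume and surface area via
marching cubes; axis lengths from the voxel-coordinate covariance), and the
five texture families — GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5),
GLDM (14) — at a fixed discretization of 32 gray-level bins, 13 unique 3-D
directions for GLCM/GLRLM (feature values averaged over directions) and
26-connectivity elsewhere. The shipped registry enumerates 107
original-image features, 93 non-shape features per stationary-wavelet
sub-band (coif1, 8 sub-bands) and per Laplacian-of-Gaussian response
(σ = 1…5 mm) — 1,316 canonical names truncated to the first 1,290. The
truncation point matches the feature count the model was designed around;
since no standard filter bank yields that number exactly, the registry
itself (length, order, hash) is the contract, checked wherever a scaler or
model bundle is reapplied. First-order and shape values are verified in the
test suite against closed forms and analytic phantoms (ellipsoid masks,
two-level lines with hand-enumerated co-occurrence and run counts).

### Standardization

Two affine steps per sequence, replacing feature selection: each row
(lesion) is scaled to unit L2 norm, then each column is MinMax-mapped so the
*training* values span [0, 1]. The order (L2 first) is chosen so the final
training range guarantee holds. MinMax statistics are fitted on training
rows only and reused on test rows, which may fall outside [0, 1] and are not
clipped; zero-range columns map to 0.

### Attention fusion

For per-sequence vectors {f₁…f_K} (K = 4, d = 1,290):

    u_k = tanh(W f_k + b),   w_k = softmax_k(u_kᵀ u),   f = Σ_k w_k f_k

with W (a × d), b, u shared across lesions and learned jointly with the
classifier. The attention width defaults to a = 64 — small, since the head
only needs a scalar relevance score per modality. Weights are per-lesion, so
the model can downweight an artifact-corrupted sequence for one lesion while
trusting it elsewhere. K = 1 (single-sequence ablation) flows through the
same code path and degenerates to the identity.

### Lesion graph and GraphSAGE

The "similar score" between lesions is cosine similarity (the natural choice
for nonnegative standardized radiomics vectors). The training adjacency is
initialized once — from the cosine similarity of the standardized
concatenation of the K sequence blocks, a representation that does not change
during optimization — as a kNN graph (k = 10, ties toward the lower index,
symmetrized by union, edge weight = similarity, no self-loops), and held
fixed; gradients do not flow through edge weights. Each GraphSAGE layer
computes

    h' = ReLU(W_self h + W_neigh · mean_w(neighbours) + b)

where mean_w is the edge-weight-weighted mean (normalized by total absolute
edge weight; the zero vector for isolated nodes), with 2 layers, hidden width
64, dropout 0.2, and a linear softmax head over the M = 3 classes. Node
features — the fused vectors — are centered by their initial training column
means before entering the network; this constant shift removes the
common-mode activation a nonnegative input range induces and materially
stabilizes optimization.

Training minimizes inverse-frequency-weighted cross-entropy on lesion labels
with Adam (lr 1e-3), full batch, at most 300 epochs, early-stopped with
patience 30 on validation macro one-vs-rest AUC; the best-epoch parameters
are restored. The validation split is patient-stratified (default 20% of
patients per class) so no patient straddles the split. Prediction is
inductive: a test lesion attaches to its k most similar training lesions in
the same concatenation basis the adjacency was initialized from (never to
other test lesions), and its probabilities come from a forward pass against
the stored training hidden states. All randomness (init, dropout, splits) is
seed-derived; identical configuration reproduces artifacts bit-identically.

### Aggregation and evaluation

Patient probabilities are the plain average of the patient's lesion
probability vectors, renormalized to unit L1 norm. Reported metrics:
per-class one-vs-rest AUC (Mann–Whitney with half credit for ties) with a
95% percentile bootstrap CI halfwidth from 2,000 resamples — resampling
patients with replacement and carrying their lesions, which preserves
within-patient correlation; degenerate resamples missing a class are
redrawn — sensitivity/specificity/accuracy per class from the 3 × 3
confusion matrix (argmax with ties toward the lower class index), overall
accuracy, and Cohen's κ (defined as 1 when both margins are the same single
class). Paired models are compared with the classic DeLong test for
correlated ROC curves (structural-component covariance, two-sided normal p;
identical scores give p = 1); a bootstrap-difference variant is available
behind a flag since the evaluation protocol can be read either way. The
DeLong implementation is validated against a 20,000-rep sign-flip
permutation oracle and a 1,000-simulation type-I-error check in the test
suite.

### Ablation grid

`run_ablation` trains and evaluates {raw GCN, standardization + GCN,
standardization + fusion + GCN} × {T1-CE only, the other three sequences,
all four}, lesion- and patient-wise. Variants without fusion feed the
concatenation of the per-sequence vectors to the graph — the
information-preserving default for combining unfused sequences.

## The synthetic cohort generator

The generator emulates the study conditions: three classes, patients
carrying 1–4 lesions (uniform), four sequences of 1,290 features. Class
signal is a Gaussian mean shift of `effect_size` (default 2) noise-SDs on
per-sequence informative index sets (default: disjoint blocks of 64 indices,
~5% of features per sequence). Within sequence k only class k mod 3 gets its
own random ±1 signature; the other two classes share one — so any single
sequence separates just one class from the rest, and only combining
sequences resolves all three. This is what makes the multisequence ablation
direction hold by construction.

Two realism features drive the other ablation directions:

* **Scale heterogeneity.** Feature columns get log-normal scales (σ = 1) and
  each sequence a global scale (1, 30, 0.2, 8 — mimicking the very different
  units/dynamic ranges of T1-CE, T2W, FLAIR, DWI features). Without
  standardization the largest-scale sequence dominates any concatenation or
  cosine similarity, which is exactly the failure the standardization stage
  corrects.
* **Per-lesion artifacts.** With probability 0.25 a lesion has one random
  sequence corrupted: its class signature is replaced by another class's and
  its noise amplified ×4 (think motion or susceptibility artifact mimicking
  a different contrast). A per-lesion attention can learn to downweight the
  corrupted sequence; any weighting fixed across lesions cannot.

Signature patterns and column scales derive from a `pattern_seed` separate
from the sampling seed, so train and test cohorts share class structure
without sharing samples. Fold assignment is patient-disjoint and
class-stratified (per-class fold sizes differ by ≤ 1); patient-level splits
were chosen over lesion-level ones to preclude within-patient leakage.

What the generator does *not* emulate: feature correlations (real radiomics
features are massively redundant), patient-level random effects (lesions are
conditionally independent given the class), non-Gaussian tails, and any
imaging physics — image phantoms for the extraction stage are separate,
simple ellipsoids with Gaussian texture. Passing tests therefore demonstrate
that the pipeline recovers the designed class structure under realistic
scale and artifact nuisances, not clinical performance.

Under these conditions (30 patients/class training, 10/class held out,
effect size 2, seed 0) the full model reaches ≥ 0.95 one-vs-rest lesion AUC
per class and patient-level accuracy at or above lesion-level. The
standardized-concatenation variant performs essentially identically to the
fusion variant at these sample sizes — concatenation preserves all
information, and the shared graph smooths both — so the component ordering
holds with equality or margins at the third decimal; the clear, seed-robust
effects are standardization over raw features and four sequences over
T1-CE alone. Fusion's specific contribution shows up in the attention
weights themselves (the trainability test: with signal confined to one
sequence, that sequence's mean learned weight ends highest), not in a large
AUC gap.

## Numerical choices and edge cases

* Zero-range MinMax columns and zero-norm rows pass through as zeros; empty
  masks, empty manifests, single-node graphs, k ≥ node count (clamped with a
  warning), isolated nodes (zero aggregate), and single-class inputs (AUC
  and DeLong errors) are all defined explicitly.
* Cosine of a zero vector is 0; argmax ties break toward the lower class
  index; kNN ties toward the lower node index.
* Gray-level discretization uses fixed bin count 32 — a common default for
  [0, 255]-rescaled patches; constant regions collapse to a single level.
* Problem sizes in the test suite (cohort sizes, feature dimensions of
  150–400 for model-level unit tests, bootstrap B of 100–200 outside the
  headline run) are scaled so the full suite exercises every stage at
  realistic ratios while staying quick; the headline synthetic experiment
  always runs at the full 1,290-feature, 30-patients-per-class scale.

## Known limitations

* The feature extractor is validated against closed forms and analytic
  phantoms, not against an external radiomics implementation; texture
  features beyond the tested oracles may deviate from other packages in
  convention-level details (direction weighting, tie handling).
* The exact filter bank behind the 1,290-feature count is reverse-engineered
  (truncated canonical enumeration), not canonical.
* The graph is static after initialization; co-evolving the adjacency with
  the attention was tried and discarded (less stable, no accuracy gain).
* Where the protocol admits two readings — MinMax fitted on train only vs
  train+test jointly, inductive vs transductive graphs, resampling patients
  vs lesions in the lesion-wise bootstrap — this implementation always takes
  the leakage-free one.
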