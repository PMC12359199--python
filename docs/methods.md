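# Methods

## Scope and model

`plddtkit` implements the self-assessment loop for predicted protein
structures: computing the Local Distance Difference Test (LDDT) of a model
against a reference, and predicting it per residue (pLDDT) from the kinds of
features a structure-prediction network produces, using an E(n)-equivariant
graph neural network (EGNN) head. The package operates on single monomeric
chains whose residues are numbered by 1-based FASTA position.

## LDDT scoring

For residue *i*, the scorer collects partner atoms within an inclusion
radius *R* = 15 Å of residue *i*'s atoms **in the reference structure**, and
counts, over tolerance thresholds {0.5, 1, 2, 4} Å, the fraction of
(pair, threshold) combinations with |d_ref − d_model| ≤ t. Scores are scaled
to 0–100. Two modes:

* `calpha` — partners and probes are CA atoms only;
* `all_atom` — every heavy atom of residue *i* is scored against heavy atoms
  of other residues; the residue score is the mean over residue *i*'s atoms.
  This is empirically the more stringent score.

Pinned numerical conventions (the definition leaves them open):

* Threshold and inclusion-radius comparisons are inclusive (≤). Boundary
  cases are measure-zero; pinning them makes the brute-force and KD-tree
  paths bit-identical.
* Minimum sequence separation defaults to 0: only intra-residue pairs are
  excluded. Exposed in `LDDTConfig`.
* Atoms present in the reference but missing from the model are dropped from
  numerator and denominator alike — coverage is not penalized as accuracy.
* No stereochemistry penalty and no symmetry-aware atom swapping (Phe/Tyr
  ring flips); the latter is a known limitation against reference
  implementations on real side chains, but the synthetic side-chain stubs
  used here have no symmetric atoms.
* The score is deliberately asymmetric in (reference, model): inclusion sets
  are built from reference geometry only.

Residue scores with an empty inclusion set are undefined and excluded from
the model-level mean. Per-residue error is |pred − true|; model-level error
is its mean over residues defined in both profiles.

## Ensemble RMSF

Fluctuation is computed from ≥2 models sharing residue numbering: every
member is superposed onto member 0 (single-pass Kabsch on shared CA atoms;
no iterative mean-structure refinement), and RMSF_i is the root mean squared
deviation of residue *i*'s CA about its member-mean position. Collinear CA
sets are rejected as degenerate. The anchor choice is exposed; fluctuation
about the member mean (not the anchor) is the standard definition and is
what makes two identical members give exactly zero.

## Graph features

Nodes are residues; directed edges connect pairs with CA distance ≤ 16 Å
(both directions always present). Raw node input concatenates the single
representation (L×384), layer-averaged language-model embedding (L×33) and
RMSF (L×1); raw edge input concatenates the pair representation slice
pair[i,j,:] (not symmetrized — both directed edges exist anyway) and the
averaged attention slice (33). Ablation flags reproduce the feature-analysis
variants: `use_rmsf`, `use_esm`, `use_edges` (drops edge *features* but
keeps connectivity — message passing needs edges), and `use_extra` (single
representation only). Assembly is a pure rearrangement; all learned
transformations live in the head.

## Confidence head

Architecture: node transition (D_node→384, ReLU) and edge transition
(D_edge→128, ReLU) applied once; input projection 384→128; four equivariant
graph convolutions at hidden width 128; output projection 128→50; row
softmax. Each convolution computes, per directed edge i→j,

    m_ij = φ_e(h_i, h_j, ‖x_i − x_j‖², e_ij)
    x_i ← x_i + (1/deg i) Σ_j (x_i − x_j) φ_x(m_ij)
    h_i ← φ_h(h_i, Σ_j m_ij)

with φ_e, φ_x, φ_h two-layer maps (SiLU activations; φ_h without residual).
Messages depend on geometry only through squared distances, so per-residue
outputs are exactly invariant to rotations/translations and equivariant to
node permutations; coordinate updates are equivariant and the final
coordinates are discarded. Isolated nodes receive a zero message sum.

The 50 output bins cover LDDT [2b, 2b+2) (top bin closed at 100); the scalar
pLDDT is the expected bin center Σ_b p_b (2b+1) ∈ [1, 99] — the standard
readout for binned confidence heads (argmax would discard calibration).

Numerical choices:

* Squared distances entering φ_e are divided by the squared 16 Å cutoff;
  without this the raw values (up to 256) saturate the activations at
  initialization.
* Glorot initialization, except the second layers of φ_e and φ_x, which are
  scaled by 0.25: sum aggregation over ~16 neighbors otherwise grows node
  activations ~5× per layer at initialization.
* Log-probabilities are clamped at −30 in the loss.
* Coordinate updates are degree-normalized to avoid blow-up on dense graphs.

## Training loss

Residue *i* with true LDDT in bin b(i) contributes −w_{b(i)} log p_i[b(i)];
the loss is normalized by Σ w rather than by N, which keeps its scale stable
across proteins of different quality composition (the normalization choice
is open in the head's description; with uniform weights the loss reduces
exactly to cross-entropy either way). Bin weights are w_b = 1 − f_b with f_b
the training-set fraction of residue LDDT values in bin b, countering the
skew of training data toward high LDDT. LDDT = 100 maps to the top bin.

Optimization: Adam (β = 0.9/0.999), learning rate 1e-4 (the head-phase
fine-tuning rate), one protein per step, shuffled each epoch, fully seeded.
Decoupled weight decay 10 (effective shrink lr·wd = 10⁻³ per step) is
pinned as a default after development calibration at desk scale (579 raw
feature dimensions against ~10³ training residues): without it the head
memorizes noise columns and held-out rank correlation drops by ~0.04, with
a larger model-level error. Optional input-feature dropout is available
(`input_dropout`, default 0 — it slowed convergence without improving
generalization here). Default epochs: 40. A multilayer-perceptron head
(same transitions and widths, no message passing) trained identically
serves as the architecture baseline.

## Evaluation protocol

Per-target errors feed win/tie/loss counts with a 0.5-LDDT tie margin,
optionally restricted to targets where either method errs above 5.0
(strictly). Confusion matrices are row-normalized over the four standard
confidence categories (>90, 70–90, 50–70, <50; upper bounds inclusive,
category tests strict at the top: 90 falls in 70–90). Correct-category
counts are compared with a Pearson chi-squared test on the 2×2 table, 1 df,
no continuity correction. Ablation deltas are variant − full (positive =
variant worse) with quartile summaries. Undefined confusion rows are
reported absent, not zero-filled.

## Synthetic data

The generator makes every component testable with known ground truth; its
defaults define the study conditions used throughout the tests.

* **Backbones** — parametric α-helix (rise 1.5 Å/residue, radius 2.3 Å,
  100°/residue → consecutive CA–CA ≈ 3.83 Å), broken every 8–20 residues by
  a random hinge rotation of the remaining chain about the boundary CA
  (±60°), which preserves bonded geometry. Non-glycine residues get a CB
  stub 1.5 Å from the CA so all-atom scoring is exercised. Sequences are
  uniform over the 20 amino acids.
* **Decoys** — i.i.d. Gaussian coordinate noise per atom, segment-wise
  sigmas drawn from {0, 0.5, 1.5, 3, 6} Å with probabilities
  {.30, .25, .20, .15, .10}; this populates all four confidence categories.
  Side-chain atoms receive 1.5× the backbone sigma
  (`sidechain_noise_factor`): side-chain placement errors exceed backbone
  errors in real predicted models, and this asymmetry is what gives the
  all-atom score its extra stringency — with equal per-atom noise the two
  modes score within ~0.2 LDDT of each other, in no fixed order.
  Torsion-space perturbation would be more physical still; the Gaussian
  choice gives a direct, monotone sigma→LDDT link.
* **Ensembles** — 5 jittered copies with per-residue sigma
  `ensemble_jitter_scale × (100 − LDDT)/100` (default scale 2 Å), emulating
  dropout replicates whose spread tracks local error.
* **Features** — the quality signal is the absolute true LDDT on the 0–1
  scale embedded against unit Gaussian noise in column 0 of the single and
  embedding tensors (independent noise each) and as the endpoint mean in
  pair[:, :, 0]; the amplitude makes the variance ratio equal `feature_snr`
  for a typical within-protein LDDT spread (0.25 on the 0–1 scale). All
  other entries are i.i.d. N(0, 1); the attention tensor is pure noise. The
  RMSF channel is computed from a generated ensemble. Default
  `feature_snr` = 4 — a per-channel Pearson correlation of ≈ 0.89 with
  truth, reflecting that real trunk/language-model representations are
  strongly (but not perfectly) predictive of local error. At
  `feature_snr` = 0 every channel is made signal-free, including RMSF
  (quality-blind constant jitter), so no-signal negative controls are exact.
* **Training graphs** use the *reference* backbone coordinates, so quality
  information reaches the head only through the feature channels. This
  deliberately departs from the inference-time situation (where the
  assessed model's own coordinates are used): with i.i.d. Gaussian decoys
  the perturbed geometry itself would be a strong quality signal, and the
  no-signal negative control would stop being a control of the feature
  pathway.

What passing tests on this generator do **not** show: performance on real
decoys (correlated, physically plausible errors), real feature tensors
(signal distributed over many dimensions, non-Gaussian), side-chain
symmetry handling, or multi-chain context. The generator's job is to verify
the machinery — exact scoring, invariances, loss algebra, and that training
recovers a known planted signal and fails when the signal is absent.

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen as
desk-scale study conditions: 20 training + 10 held-out proteins of length
40–80 for recovery runs; 100 decoys for the stringency comparison; 50
proteins for the RMSF anticorrelation; 10 repeats at 10 training / 6
held-out proteins, 12 epochs, for the no-signal control; 60–200 random
structures for scorer-equivalence checks.

## Known limitations

* The scorer has no symmetry-aware side-chain swapping; against reference
  implementations on real structures, residues with symmetric side chains
  can score lower here.
* Training at desk scale is CPU-bound float64 numpy; the implementation is
  deliberately simple (no batching across proteins, no GPU path).
* The head's input transition assumes the ablation-dependent raw dimensions
  it was initialized with; parameters are not transferable across ablation
  settings.
* Renumbering uses exact subsequence embedding (constant-offset preferred);
  it does not handle point mutations between model and sequence.
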