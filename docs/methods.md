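# Methods

This note documents the model, the synthetic data it is exercised on, the
parameter defaults and the numerical choices, in the package's own words.

## 1. Setting and model

Ten clients hold vertically partitioned views of one aligned patient
cohort: clients 1–3 clinical notes, 4–6 fundus images, 7–9 IOP series;
client 10 is the integration node.  The trainable state splits into

- **private encoders**, one per modality client, never transmitted:
  - text: dense 300→128 + ReLU over the document embedding (TF-IDF-weighted
    mean of skip-gram Word2Vec vectors, z-scored per feature);
  - image: a convolutional backbone → global average pooling → linear head
    to 128 (a `tiny-cnn` preset with three conv blocks for CPU work, and a
    `resnet18-style` stack of four stages of residual basic blocks);
  - signal: Conv1D(kernel 3, 64 filters) → ReLU → MaxPool(2) → global
    average over time → 64 (cross-correlation, 'same' padding);
- the **shared head θ**: per-modality linear projections to a common
  dimension d_f, the FAM scoring vectors, one linear logit head per
  modality, and the classifier (BatchNorm, momentum 0.9, eps 1e-5 →
  Dropout 0.3 → Dense 64 + ReLU, extra L2 1e-4 → Dense C → softmax).

**Attention.**  For available modalities, z_i = w_i·[h_i ; var(h_i) ;
ent(h_i)] / τ with τ = 0.5, α = softmax over available modalities (max
subtraction for stability), H_fused = Σ α_i h_i.  The quality indicators
are the unbiased variance and the 16-equal-width-bin Shannon entropy
(natural log) of the latent's entries; they enter the score by
concatenation and are treated as stop-gradient constants — they describe
reliability rather than carry learning signal, and bin entropy is
piecewise constant in h anyway.  All other gradient paths (softmax,
weighted sum, KL, classifier) are exact; the test suite checks them
against numerical differentiation.  An optional 4-head variant partitions
d_f into four blocks, each with its own scoring vector and softmax.

**Objective.**  L = L_CE + λ_fuse·L_fuse + λ_att·L_sparsity with
L_fuse = (1/M)·Σ_i KL(p_i ‖ p_fused) over the per-modality logit heads and
L_sparsity = Σ_i |z_i| on the pre-softmax scores (an L1 on the weights
α themselves would be identically 1 and could not promote sparsity).  The
KL direction (modality ‖ fused) and the per-modality averaging are design
choices.  λ are selected from the grid {0.1, 0.01, 0.001}; the defaults
are (λ_fuse, λ_att) = (0.01, 0.001) — larger λ_att flattens the attention
toward uniform, which measurably degrades the fused classifier, because
feature-space mixing is not a logit ensemble.

**Federation.**  Each round every client copies θ, runs E local epochs of
minibatch Adam (β = (0.9, 0.999), weight decay 1e-5, cosine-annealed
learning rate over the T global rounds, floor 1e-6), and transmits the
clipped, noised, optionally encrypted parameter delta
Δθ = θ_before − θ_after.  Single-modality clients minimize cross-entropy of
the shared head on their own projected modality (attention degenerate at
weight 1) and update only the blocks their role trains (their projection +
classifier); the integration node trains the full objective, including the
attention scores and per-modality heads, on the encoded features it
receives — per modality, the *mean* latent over the three clients holding
it, which acts as an encoder ensemble and is legitimate because all three
encoders are trained against the same shared projection.

The server update is θ ← θ − η·G with G the ring-aggregated sum.
Aggregation modes: `sum` (as the update rule is usually written; default
η = 1/K realizes secure averaging), `mean` (sum/K), and `role` — each
parameter block's summed delta is divided by the number of clients whose
role trains that block (classifier: 10, each projection: 4, attention
scores and per-modality heads: 1).  The desk profile uses `role` with
η = 1: under plain averaging the attention parameters, which only the
integration node touches, receive 1/K of its learning signal per round and
never sharpen within a short training budget.

**Privacy.**  σ = C·sqrt(2 ln(1.25/δ))/ε (the classical Gaussian-mechanism
bound, valid for ε ≤ 1; defaults ε = 0.5, δ = 1e-5, C = 1).  Noise is
added to the real-valued update before fixed-point encoding (scale 2^16).
Paillier encryption uses g = n+1; 2048-bit keys by default, 512-bit in
tests.  The ring passes a running homomorphic sum client-to-client; only
the server role holds the private key, so no intermediate decryption is
possible.  The codec guarantees per-coordinate round-trip error ≤ 2^-17
and aggregate error ≤ K·2^-17.  No accountant composes ε across rounds; a
single per-round budget is reported, as is conventional when a single ε is
quoted.

## 2. Synthetic cohort

One latent severity s ∈ [0, 1] per patient drives all three modalities.
Labels are assigned first (exactly round(n·pos_fraction) positives;
default n = 2850 with 1380 positives, mirroring the combined source
collections), then severity is drawn from class-conditional truncated
normals — positives: mean 0.7 on [0.5, 1]; negatives: mean 0.3 on
[0, 0.5); both sd 0.12 — so `label = 1 iff severity ≥ 0.5` holds exactly
while the *features* of the two classes overlap through their noise.

- **Images**: a parametric optic-disc/optic-cup renderer.  The realized
  CDR is cdr_low + s·(cdr_high − cdr_low) (default range 0.3–0.8), exact
  by construction; the renderer returns the geometric masks on request so
  the realized ratio can be re-measured.  ONH-centered framing (disc
  radius 0.22 of the image side with ±8% jitter), vessel-like Bézier arcs,
  exposure gain U(0.8, 1.2), defocus blur, and pixel noise provide the
  nuisance variation; none of it touches the masks.
- **Notes**: a fixed ten-slot template grammar; each slot draws a
  glaucomatous filler with probability equal to s (healthy otherwise), so
  severity 1 is fully glaucomatous, severity 0 fully healthy, and the
  binomial middle overlaps.  The vocabulary is closed.
- **IOP**: series = patient baseline + s·gain + diurnal sinusoid + AR(1)
  noise, clipped at 0.  Defaults: population baseline 14 mmHg with
  between-patient sd 2.5 (healthy IOP spans roughly 10–21 mmHg), gain
  8 mmHg per unit severity, amplitude 2 mmHg, 2 cycles over the 96-step
  series (48 h at 30-min sampling), AR coefficient 0.7.

These defaults put the three modality severity proxies (CDR,
glaucomatous-term count, mean IOP) at separabilities of roughly AUC
0.95/0.9/0.8 — *informative but partial*, the regime in which per-client
performances cluster and fusion is modestly ahead, which is the operating
regime this package targets.  What the
generator does **not** emulate: photorealistic fundus texture, free-text
linguistic variety, inter-modality missingness at generation time,
site/batch effects, or label noise.  Passing tests therefore demonstrate
that the pipeline recovers structure it is known to contain, not clinical
performance on real data.

## 3. Preprocessing

- Tokenization: lowercase, alphabetic tokens, English stop words removed.
- TF-IDF: tf·ln(N/(df+1)), natural log.  Document vectors are the
  TF-IDF-weighted mean of in-vocabulary token embeddings, truncated at 200
  tokens; zero-weight or out-of-vocabulary degenerate cases fall back to
  the unweighted mean / the zero vector.
- Word2Vec: skip-gram with 5 negatives, window 5, min_count 2, 25 epochs,
  linear lr decay from 0.025; deterministic single-threaded minibatch
  updates.  On the small templated corpora this needs the full 25 epochs —
  a handful of epochs leaves embeddings near their random initialization.
- Images: CLAHE (clip limit 0.01, 8×8 tile grid) on the HSV value channel
  at the *native* render resolution, then resize to the encoder's input
  side.  Equalizing after downsampling to a very small raster would erase
  the regional disc/cup brightness cues that carry the CDR signal.
- Signals: Savitzky–Golay smoothing.  A window of k = p+1 (e.g. k=3, p=2)
  interpolates every window exactly and is the identity; the package
  default is therefore k=7, p=2, with the identity configuration still
  selectable.  Edges are handled by polynomial extrapolation of the
  terminal windows.
- Rebalancing: SMOTE (interpolation toward one of k=5 nearest minority
  neighbors at a Uniform(0,1) fraction, until counts are equal) followed
  by Tomek-link removal of the majority member of every opposite-label
  mutual-nearest-neighbor pair.  Applied per modality client in its own
  model-input space, on the training split only; the integration node
  trains on the aligned, unresampled training split because its latent
  inputs are recomputed every round.

## 4. Splits, profiles and problem sizes

Stratified splitting takes floor(fraction·n_class) per class into the
training set (fraction 0.8), which gives exactly 2280/570 for the
(1380, 1470) cohort.

Two profiles bundle the configuration:

- `study_profile`: n = 2850, 224 px renders, resnet18-style backbone,
  d = 300 text embeddings, d_f = 256, K = 10, T = 50, E = 5, batch 32,
  local lr 1e-4, DP noise at ε = 0.5, 2048-bit Paillier ring.  This is the
  full-scale configuration and is not exercised end-to-end by the tests.
- `desk_profile` (the tested study conditions): n = 600, 64 px renders
  encoded at 32 px by the tiny CNN, 50-dim text embeddings, d_f = 64,
  T = 10, local lr 3e-3 (encoders trained from scratch for only ten rounds
  need a larger step), role-aware aggregation with η = 1, σ = 0, plaintext
  aggregation.  One fit takes about two minutes on one CPU.

The encrypted and plaintext aggregation paths are verified equivalent
(within fixed-point quantization) on a one-round micro federation; the
full ring protocol is verified on K = 10 × 50-dim updates with 512-bit
keys.

## 5. Numerical and reporting choices

- Convergence is reported two ways: the mean local loss during adaptation,
  and the loss of the broadcast θ_t before adaptation ("global loss"),
  evaluated with full-batch BN statistics, dropout off, on a fixed
  ≤256-record training subset per client.  The global loss is the curve to
  read for convergence; the local-adaptation loss drifts up slightly in
  the last rounds as cosine annealing freezes local fitting — a
  measurement artifact, not divergence.
- Softmax/log computations use max-subtraction and probability clipping at
  1e-12; z-score divisors are floored at 1e-8 so constant features map to
  zero.
- Batch-norm runs with batch statistics in training and running statistics
  (momentum 0.9) at inference; each client keeps its own running
  statistics, which act as a small free personalization.
- Max-pool backward splits gradient equally among ties, keeping training
  deterministic.
- Rankings use competition ("1224") ranking, ties sharing the better rank;
  confidence spread is the population sd; AUC is the rank statistic with
  ties counted 1/2 (identical to trapezoidal ROC for score data).
- Determinism: every stochastic component (cohort, SMOTE, shuffling,
  dropout, DP noise, encryption blinding, Word2Vec) derives from explicit
  seeds; two runs with identical configuration produce bitwise-identical
  parameters.

## 6. Known limitations

- The federation is simulated in-process and sequential; "parallel" and
  "ring" are logical.  No network transport, stragglers, or dropout-
  tolerant participation.
- The server both aggregates and decrypts; the threat model is
  honest-but-curious, and the decrypted aggregate of noised updates is
  visible to it.
- No formal privacy accounting across rounds (single-ε reporting only).
- Labels are replicated to all clients as part of entity alignment; strict
  label-confinement VFL (labels at one party only) is a different protocol
  with split-learning-style activations, not implemented here.
- The tiny-CNN desk profile is a scaled stand-in: its absolute accuracies
  characterize the synthetic cohort, not any real screening population.
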