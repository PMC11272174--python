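# Methods

## Model

`stdgcc` assigns spatial-transcriptomics spots to spatial domains by
embedding each spot with a variational graph-convolutional encoder and
clustering the embedding. The model assumes that (i) spots within a
distance δ of each other are likely to share a domain, so their expression
should be smoothed together, and (ii) a good embedding must both
reconstruct the preprocessed expression matrix and carry enough global
information to let a discriminator tell real spots from feature-shuffled
ones (a Deep-Graph-Infomax-style mutual-information criterion).

### Preprocessing

Genes expressed in fewer than `min_spots = 5` spots are removed. Each
spot's counts are scaled to the **median library size** (a common
single-cell convention; the normalization target is otherwise arbitrary and
cancels in the subsequent standardization), then `log1p`, then each gene is
centered and divided by its population standard deviation. Genes that are
constant at this stage would give 0/0 and are mapped to all-zero columns;
an optional ±10 clip of standardized values is off by default. Highly
variable genes are ranked by the **variance of the log-normalized matrix**
(computed before standardization — afterwards every column has unit
variance by construction), descending, with ties broken by gene name so the
selection is deterministic and independent of input column order. The full
chain is: filter → normalize → log1p → scale → HVG-select.

### Spatial graph

`A0_ij = 1` iff `d_ij < δ` with a strict inequality — relevant in practice
because lattice platforms produce exactly repeating distances. Applied
literally to `i = j` this gives a unit diagonal (`d_ii = 0 < δ`), which we
keep; a zero-diagonal variant is available for ablation. The hybrid
adjacency `A = (1−λ)A0 + λI` (default λ = 0.8) balances self- versus
neighbor-expression; its diagonal is exactly 1 for any λ. Symmetric
normalization divides entry `(i,j)` by the single product
`√(D̃_i)·√(D̃_j)` computed once per entry, so the result is symmetric to
the last bit. Default δ = 250 platform units matches Visium-scale exports;
on the synthetic lattice (spacing 100) we use δ = 150 = 1.5 spacings, which
connects exactly the 4-neighborhood.

### Encoder, decoder, discriminator

Encoder widths default to F → 1024 → 512 → 256 with a 128-wide variational
head. The graph-convolution layer is `Â E W + b` with no internal
activation; a **shared learnable PReLU** (slope initialized at 0.25) is
applied between hidden layers, after hidden decoder layers, and to the
latent sample (`H = PReLU(Z)`); final layers are linear. The σ-head
produces `log σ` and exponentiates, guaranteeing positivity. The decoder is
a row-wise fully-connected mirror (128 → 256 → 512 → 1024 → F): the listed
widths are layer input widths, the last layer projecting back to F. The
readout is the plain column mean (no squashing; a sigmoid variant exists as
an option), and the discriminator passes the bilinear form `hᵀ W_D s`
through a logistic so the contrastive log-losses are defined. Weights are
Glorot-uniform, biases zero, seeded.

### Losses and training

The three loss terms and their weighted total are given in the README. Two
numerical guards: the cosine in the separation term is clamped to
`≤ 1 − 1e−7` before `log(1 − cos)` (the term diverges at cos = 1;
zero-norm vectors define cos = 0), and the discriminator log-terms are
evaluated from the logits via `log σ(x) = −softplus(−x)`, which is exact
and cannot underflow. Cosine similarity is the standard normalized form.
The separation term is minimized as cos → −1, pushing each corrupted
embedding away from its clean counterpart.

Training is full-graph: each epoch draws a fresh corruption permutation
(uniform over all N! permutations, fixed points allowed) and a fresh
reparameterization draw ε, evaluates the objective, and takes one Adam step
(defaults β₁ = 0.9, β₂ = 0.999, lr = 1e−5, 2500 epochs; no weight decay,
optional gradient clipping). **The corrupted view reuses the epoch's ε**
rather than drawing its own: the two views then differ only by the feature
shuffling, so the contrastive gradient contrasts exactly the corruption.
(With independent per-view draws the contrastive terms act on largely
noise-dominated embedding differences; we observed this destabilizes
training on small latent widths, collapsing the embedding.) The final
embedding for clustering is the noise-free pass (ε = 0, i.e. `PReLU(μ)`),
making everything downstream deterministic.

Ablation modes mirror the component analysis: `no_vgcn` (σ-head bypassed,
Z = μ, KL dropped), `no_decoder` (reconstruction dropped), and
`no_contrastive` (discriminator/corruption dropped). Masked branches are
skipped in the forward pass, so their parameters provably receive zero
updates and remain at initialization; all parameters are constructed in
every mode so that a given seed yields the same initialization across
modes, which makes mode comparisons share their starting point.

### Clustering and metrics

PCA (mean-centered, full SVD, components by decreasing explained variance)
reduces the embedding to 30 components — capped by the latent width and by
the achievable rank, with a warning. Component signs are fixed so each
component's largest-magnitude loading is positive; k-means is insensitive
to the signs, this only stabilizes the stored scores. k-means uses
k-means++ with 10 restarts, 300 iterations, tol 1e−4, and relabels clusters
contiguously from 1. NMI and ARI are computed directly from the contingency
table (`0·log 0 = 0`); for annotated data, k is the number of annotated
regions. In the degenerate cases where the adjustment denominators vanish
(both partitions single-cluster, or both all singletons) the partitions
coincide and both metrics return 1.

## Synthetic data generator

The generator emulates a sectioned tissue: a regular lattice of spots
(default 30 × 30, spacing 100 units), K spatially contiguous domains
(horizontal strips mimicking cortical layers; concentric rings and Voronoi
tessellations as alternatives), and negative-binomial counts
(`var = μ + μ²/θ`, default θ = 2) with independent dropout (default 20%).
Each domain owns `markers_per_domain = 10` genes whose mean is
`base_mean × fold_change` inside the domain (defaults 2.0 and 4×) and
`base_mean` elsewhere; the remaining genes are flat background. These
defaults give a clearly recoverable but noisy signal: an expression-only
k-means baseline reaches ARI ≈ 0.86, leaving measurable headroom for the
spatial model (≈ 0.95).

What the generator does **not** emulate: smoothly varying expression
gradients within a domain, spatial autocorrelation of technical noise,
platform artifacts (lateral diffusion, bead mixing), segmentation errors,
or histology. Passing the recovery tests therefore shows the pipeline
extracts spatially organized programs under overdispersion and sparsity —
not that it handles every failure mode of real sections.

## Scaled-down training profile

The reference configuration (widths 1024/512/256, latent 128, 2500 epochs)
is sized for real sections with thousands of HVGs. For the 150-gene
synthetic study and CI we use a `fast_profile`: widths 64/32, latent 16,
300 epochs. Its learning rate, 5e−4, was calibrated on the synthetic strips
fixture by a small grid (1e−4 … 1e−2), selecting for stable convergence of
the joint objective: at ≥ 1e−3 the cosine-separation term drives an
embedding collapse within 300 epochs, while at ≤ 1e−4 the narrow
randomly-initialized encoder — which at initialization scrambles the domain
signal — is left undertrained. These are not the reference settings and are
labeled as such wherever they appear.

A note on regimes: the reconstruction term scales with the number of
features F, so with the default weights the contrastive term is relatively
much stronger at F = 150 than at F = 3000. On easy fixtures where the
reconstruction pathway alone already saturates recovery, the contrastive
term buys robustness on harder data rather than additional accuracy, and
can cost a few hundredths of ARI; this is inherent to the fixed weighting,
not a defect of the optimization (the gradient check validates all terms).

## Numerical and design choices

- All computation is float64 numpy; gradients come from a minimal in-repo
  reverse-mode tape (`_autograd.py`) validated against central finite
  differences to 1e−4 relative on a toy model.
- Determinism: a single `numpy` Generator seeded from the config drives
  initialization, corruption permutations and ε; identical (data, config,
  seed) reproduce the loss history and labels bit-for-bit on a given
  platform.
- Adjacency is held sparse (CSR) end to end; the dense path is only used in
  tests.
- Degenerate inputs are rejected early with typed errors: negative counts,
  unalignable barcodes, zero-library spots, zero-degree graph rows,
  non-finite activations (reported with the offending layer/epoch).

## Known limitations

- Full-graph training holds the N × N adjacency and all activations in
  memory; very large sections (≫ 10⁵ spots) would need mini-batching,
  which is out of scope.
- The numpy implementation is single-threaded matrix algebra; it is sized
  for desk-scale experiments, not GPU-scale benchmarks.
- No batch integration across sections, no histology features, no label
  smoothing post-processing.
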