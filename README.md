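# stdgcc

Spatial-domain identification for spatial transcriptomics by deep graph
contrastive clustering.

Spatial transcriptomics platforms (10x Visium, Slide-seq, Stereo-seq, ...)
measure gene expression at known positions ("spots") across a tissue
section. A central analysis step is to partition the spots into **spatial
domains** — spatially coherent regions sharing an expression program, such
as cortical layers. Clustering expression alone fragments these regions;
this package fuses expression with the spatial neighbor structure.

## Method

Given a spot × gene count matrix and spot coordinates:

1. **Preprocessing** — drop genes expressed in fewer than 5 spots,
   library-size normalize each spot to the median library, `log1p`,
   standardize each gene, and keep the top *t* highly variable genes,
   yielding `X ∈ R^{N×F}`.
2. **Spatial graph** — connect spots with Euclidean distance `d_ij < δ`
   (strict), giving a binary proximity matrix `A0` (unit diagonal, since
   `d_ii = 0 < δ`); blend with the identity,
   `A = (1−λ)·A0 + λ·I`, and symmetrically normalize,
   `Â = D̃^{-1/2} A D̃^{-1/2}` with `D̃_ii = Σ_j A_ij`.
3. **Variational graph encoder** — a stack of graph convolutions
   `E_{k+1} = Â E_k W_k + b_k` (shared learnable PReLU between layers)
   feeds two parallel heads producing `μ` and `log σ`; the latent code is
   sampled by reparameterization, `Z = μ + σ ⊙ ε`, `ε ~ N(0, I)`, and the
   embedding is `H = PReLU(Z)`. A KL term
   `L_KL = (1/N)·(1/2)·Σ_ij (−log σ_ij² + μ_ij² + σ_ij² − 1)`
   regularizes the posterior toward `N(0, I)`.
4. **Decoder** — fully connected layers symmetric to the encoder
   reconstruct `X̃` row-wise; `L_r = (1/N)·‖X − X̃‖_F²`.
5. **Contrastive refinement** — a corrupted view shuffles spot features
   while keeping the graph; with global summary `s = mean_i(h_i)` and a
   bilinear discriminator `D(h, s) = σ(hᵀ W_D s)`, the loss
   `L_c = −mean_i log D(h_i, s) − mean_i log(1 − D(h̄_i, s))
          − mean_i log(1 − cos(h_i, h̄_i))`
   pulls real node/summary pairs together and pushes corrupted ones away.
6. **Joint objective** — `L = α·L_c + β·L_r + γ·L_KL`, defaults
   `(α, β, γ) = (2.0, 0.05, 0.005)`, optimized full-graph with Adam.
7. **Domain assignment** — PCA to 30 components of the noise-free final
   embedding, then k-means; agreement with annotations is scored by ARI and
   NMI (implemented from the contingency table).

The whole model (including reverse-mode gradients) runs on numpy; the
standard surrounding steps (PCA, k-means, file formats) use scikit-learn,
scipy and scanpy. See `docs/methods.md` for modeling details, parameter
defaults, and the synthetic data generator.

## Worked example

Simulate a five-layer tissue (30×30 lattice, 150 genes, negative-binomial
counts with 4× marker fold change and 20% dropout), then run the full
pipeline with the scaled-down training profile:

```sh
stdgcc simulate --layout strips --k 5 --grid 30x30 --genes 150 --seed 7 --out demo/data
# wrote 900 spots x 150 genes to demo/data
echo "delta: 150.0" > demo/cfg.yaml
stdgcc run --input demo/data --k 5 --fast --seed 7 --config demo/cfg.yaml --out demo/out
# {"k": 5, "ari": 0.9214706423935123, "nmi": 0.9218846555918114, "final_loss": 7.790893513167903}
```

The reported ARI/NMI compare the five recovered domains against the
generator's ground-truth layers: 0.92 means the spatial domains are
recovered almost exactly (1.0 would be a perfect partition match). `demo/out/`
holds the per-spot labels, the final embedding, and a training summary.
`delta: 150.0` sets the neighbor radius to 1.5 lattice spacings so each
interior spot connects to its 4-neighborhood.

Other entry points: `stdgcc train` (embedding + loss history only),
`stdgcc cluster` (k-means on a saved embedding), `stdgcc evaluate`
(ARI/NMI between two label files).

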