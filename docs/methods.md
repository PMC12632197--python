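# Methods

## Data model and preprocessing

A study consists of tissue *sections*, each pairing a whole-slide image
with barcoded spots (pixel centre coordinates) and a spot × gene count
matrix. Patches are cut as half-open windows `[c − 112, c + 112)` in both
axes ((row, col) = (y, x), origin top-left), which yields exactly 224×224
pixels with no off-by-one ambiguity; windows that overhang the slide are
reflect-padded with a logged warning, and a centre outside the slide is an
error. Sections with fewer than 180 non-background spots are dropped (the
comparison is strict, so 180 is retained); background status comes from the
spot table or from absence in the expression matrix — the package does no
tissue detection.

The gene panel is the `top_k` (default 785) genes with the highest variance
of log1p(library-size-normalised) expression pooled over all spots of all
training sections, restricted to genes also present in the single-cell
reference; ties break lexicographically so the panel is deterministic.
Labels are the spot's panel-gene counts scaled so the panel-gene sum equals
a frozen target (the median panel-gene library size of the training split,
stored with the model) and then mapped through `ln(1 + x)`. All-zero spots
map to all-zero labels. The same target-sum rule normalises the single-cell
reference, so the IE prior and the regression labels share one scale —
a deliberate design choice: a conditioning prior on a different scale from
the target would force the network to learn an arbitrary affine correction.

## Reference vectors and the IE prior

For each non-dead PanNuke class present in the reference, the most populous
minor subtype is selected (lexicographic tie-break; if the atlas has no
minor labels the whole major group is used and flagged in provenance).
Mapping an atlas's own ontology onto the five coarse classes is inherently
dataset-specific, so it is supplied by the user as a metadata column rather
than inferred. The class's canonical vector is the per-cell
library-normalised mean over those cells, log1p-transformed. Dead cells are
excluded from every computation.

The IE prior for a patch with per-class counts `N_cᵢ` is the exact weighted
sum `Σ πᵢ Ref_cᵢ` with `πᵢ = N_cᵢ / Σⱼ N_cⱼ` over non-dead classes; the
mixture of already-logged vectors is not re-normalised or exponentiated.
Patches with zero non-dead nuclei get uniform weights and a `degenerate`
flag rather than being dropped, so spot counts stay consistent with the
section filter; they remain countable and excludable downstream. Scaling
all counts by a positive factor leaves the prior unchanged, and each gene of
a non-degenerate prior lies within the min/max envelope of the reference
vectors.

## Architecture

The image encoder is a 34-layer residual CNN truncated before global
pooling and classification, so a 224×224×3 patch produces a 7×7×512 grid =
49 tokens of width `d_att` = 512. Because the package must run fully
offline, the backbone initialises from the model seed; externally trained
weights can be loaded through the checkpoint mechanism. Two single-block
self-attention stages refine the grid: channel self-attention (sequence =
the 512 channels, features = the 49 positions, one head since 49 is not
divisible by 8) and spatial self-attention (sequence = 49 positions, 8
heads), each with residual connection and layer normalisation. The
expression encoder is `Linear(N_G → d_att) → GELU → Linear(d_att → d_att)`
producing one token.

The decoder iterates, on the query stream: self-attention → `expr2img`
cross-attention (query = expression token + self-attention output,
key = value = image tokens) → MLP → `img2expr` cross-attention (query =
image tokens, key = expression token + MLP output, value = MLP output),
for two rounds, followed by a terminal `expr2img` attention that makes the
expression embedding the dominant signal in the output token. The round-1
query is the expression token itself; the round-2 query re-injects the
round-1 MLP output (the expression token re-enters additively inside
`expr2img`). Self-attention, the in-loop `expr2img` and `img2expr` share
weights across rounds while each round owns its MLP; together with the
terminal attention this realises exactly one self-attention, two
`expr2img`, one `img2expr` and two MLP modules. Layer norms are
post-residual; `n_heads` = 8 and `mlp_hidden` = 2·`d_att` follow common
light-decoder conventions since no values are fixed by the design. The
prediction head is a single affine map from the output token — the minimal
head consistent with removing mask/upsampling heads from the template
architecture. All randomness (initialisation, noise variants, scramble
permutations) flows from the one seed in `ModelConfig`.

Ablations: `random_ie` replaces each spot's prior with standard-normal
noise keyed by (seed, spot id), so the noise is stable across epochs;
`cellratio_noise` mixes the weights with a seeded flat-Dirichlet draw
(fraction 0.3 by default) before composing; `plain_resnet34` drops CSA/SSA;
`concat` replaces the decoder with `MLP(concat(mean image token, expression
token))`; `deep3` runs three rounds; `cross_gate_zero` multiplies every
cross-attention output by zero before its residual add, leaving only
residual paths (the output is then provably independent of the image, and
its gradient w.r.t. the image is exactly zero); `scramble_kv` permutes the
key/value tokens of the cross-attention sites with a seeded permutation
redrawn per batch — the identity permutation reproduces the default model
bit for bit.

## Training and evaluation

Training minimises mean-squared error with Adam, batch 32, 81 epochs and
learning rate 1e-4 by default; all compared variants share the same
configuration. Evaluation is leave-one-section-out: one fold per section,
each held out exactly once. Per-gene Pearson correlation is computed across
the held-out section's spots; genes with zero variance in either argument
are flagged undefined and excluded from means/medians (with the count
reported) rather than silently set to zero, which would bias the summary.
Model pairs are compared with the Wilcoxon signed-rank test on per-section
metrics (zeros dropped; for n ≤ 12 the null is enumerated exactly over all
2ⁿ sign patterns with midranks, so ties remain exact; larger n uses the
normal approximation). Well-predicted genes are ranked by a one-sided test
of ρ > 0 via `t = r·√((n−2)/(1−r²))` with n−2 degrees of freedom and
Benjamini–Hochberg adjustment across genes. The per-section dispersion
score is the mean excess over the section median PCC among the
top-decile genes (⌈n/10⌉ genes), non-negative by construction and requiring
at least 10 defined correlations — a documented stand-in, as is the pair of
robustness injections: *spot noise* displaces the patch window of
`round(level·n)` seeded spots by a nonzero offset up to one spot radius
(implemented as a content shift with reflect fill, since per-spot datasets
do not retain the whole slide), and *stain noise* applies a seeded
hue/saturation/value perturbation of configurable magnitude; labels are
never touched. Gene-set maps are per-spot means over a gene set;
pseudo-bulk is the column mean over all spots of a slide.

## The synthetic generator

`scist.simulate` creates studies that exercise every pipeline input. The
reference draws negative-binomial counts (dispersion 2.0, emulating
single-cell overdispersion) around type-specific exponentiated centroids —
each type up-regulates its own gene block by 2.0 on the log scale — with a
planted 60/40 minor-subtype split per type and optional dead cells.
Patches render each nucleus as an ellipse in a type-specific colour in a
disjoint grid slot on a noisy pink background, so connected-component
counting (or the bundled colour counter) recovers the planted counts
exactly. Spot compositions follow a section-level Dirichlet prior with
per-spot Dirichlet-multinomial sampling (about 12 nuclei per patch), and
labels are `IE + α·m + ε` where `m` is the per-type count vector through a
fixed seeded linear map and `ε` is i.i.d. Gaussian gene noise. Defaults —
α = 0.4 and σ = 0.3 on the log1p scale, 3 sections × 200 spots, 60 genes —
put the prior, the morphology signal and the noise on comparable footing at
desk scale. The generator composes IE with its own double-loop weighted
sum, deliberately independent of the pipeline's implementation, so the two
can be checked against each other exactly. With α = σ = 0 the labels equal
the prior; with α = 0 and σ > 0 the squared correlation of the prior with
the labels is `var/(var + σ²)` per gene, an analytic self-consistency
check.

What the generator does not emulate: real H&E texture, stain variation,
segmentation error, boundary mixing between spots, or — crucially — the
weak, noisy relationship between morphology and composition in real
tissue. Rendered patches encode the type counts losslessly in colour, so
image-only models are far stronger here than on real slides; passing
synthetic benchmarks demonstrates that the pipeline is wired correctly and
that the prior carries signal, not that relative model orderings transfer
to tissue. In particular the concatenation ablation, which collapses on
real data, can match the cross-attention decoder on these studies because
the mean image token already carries the full composition.

## Desk-scale configuration and numerics

The full-size model (49×512 tokens) is exercised for architecture
contracts; training experiments use a small configuration — a stride-4 5×5
stem plus two stride-2 3×3 stages to `d_att` = 32, 16 tokens from 64×64
patches, 4 heads — trained for 30 epochs at learning rate 3e-3 (the
noiseless sanity study trains 60 epochs, as it checks capacity rather than
a comparison). Desk-scale training runs in float32; oracle comparisons and
default construction use float64. The autodiff engine is a compact
reverse-mode implementation over numpy with fused
batch/layer-normalisation and im2col convolution; gradients of every
primitive are tested against central finite differences. Adam uses
standard bias correction (β = 0.9/0.999, ε = 1e-8). Training aborts with
diagnostics on non-finite loss. TSV interchange uses `%.17g` formatting and
round-trip float parsing, so written matrices reload bit-exactly.

## Known limitations

- No pretrained backbone weights are bundled; real-data performance would
  benefit from standard image-classification pretraining, loadable via
  checkpoints.
- The dispersion score and both noise injections are documented stand-ins
  for procedures whose exact definitions were not available.
- The IE prior ignores cell size and per-cell mRNA abundance; weighting is
  by nucleus count only.
- Ontology mapping from a reference atlas to the five coarse classes is the
  user's responsibility (a metadata column), not automated.
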