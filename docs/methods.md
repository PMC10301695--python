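# Methods

## The model

`pathvae` implements a variational autoencoder whose latent space and decoder
mirror a biological ontology. An ontology restricted to its "is a"
relationships is a directed acyclic graph (DAG) of terms; each term may carry
direct gene annotations. After trimming (below), every surviving term is
assigned a *depth* — the length of the longest directed path from any parentless
term — and the network is laid out so that:

- the latent space holds the depth-0 terms (the most generic surviving terms),
- decoder layer *d* holds the terms of depth *d*,
- the final reconstruction layer holds the genes.

Each term is represented by *k* neurons (default *k* = 3; one neuron per term
makes siblings sharing the same parents receive identical input, and three
neurons reduce sibling correlation). The decoder is **linear** (no activation
functions), **sparse** (a binary mask zeroes every weight that does not
correspond to a parent→child edge or a direct term→gene annotation), and
**non-negative** (weights are clamped to ≥ 0 after every optimizer step, so an
increase in a parent's activity can never decrease a descendant's — this is
what gives activities a direction). Because a term may have children several
depths below it, and genes are annotated to terms at every depth, the decoder
uses skip concatenation: the input of layer *d* is the concatenation of the
latent vector and all previous layer outputs, and the reconstruction layer
reads the concatenation of everything. A layer-*d* mask therefore has shape
`(k·|terms at depth d|) × (k·|terms at depth < d|)` with a `k×k` block of ones
per edge; the reconstruction mask has a `1×k` block per direct annotation.

The encoder is a standard one-hidden-layer network (ReLU, width 512 by
default, dropout 0.2) producing the mean μ(x) and log-variance of a diagonal
Gaussian posterior over the latent space. Training maximizes the evidence
lower bound with a Gaussian reconstruction likelihood, i.e. minimizes

    L = mean_samples ||x − x̂||² + β · KL(q(z|x) ‖ N(0, I)),

with the KL in closed form, the reparameterization trick (z = μ + σ·ε),
dropout 0.5 on the sampled z during training, and β = 1e-4. The optimizer is
AdamW (learning rate 1e-4, decoupled weight decay 0.01 on weight matrices),
batch size 128, an 80/20 seeded train/validation split, and the parameter
snapshot with the lowest validation loss is returned (earliest epoch on ties).

The whole network is implemented directly in NumPy with hand-written exact
gradients (`pathvae/_nn.py`). The architecture is small and fixed, so explicit
backpropagation is straightforward, fast on one CPU, and — together with
seeded `numpy.random.Generator` streams for initialization, batching, dropout
and reparameterization noise — makes every training run bit-reproducible.
The gradient implementation is verified against central finite differences in
the test suite.

## Ontology trimming

A raw ontology has a single root, which would give a one-dimensional latent
space. Trimming removes every term whose *descendant-gene count* (genes
annotated to the term or any term reachable below it) falls outside
`[bottom, top]` — generic terms with too many genes, specific terms with too
few. Defaults are bottom = 30, top = 1000. Counts are computed once on the
untrimmed graph (single pass, no iterative re-trimming). Children of removed
terms are rewired to the removed term's parents (edge contraction), so
reachability among kept terms is exactly preserved; depths are then recomputed
on the contracted graph.

A structural note: descendant-gene sets are monotone along edges (an
ancestor's set contains each descendant's), so a term removed by the top
threshold cannot have a kept ancestor, and a term removed by the bottom
threshold cannot have a kept descendant. A removed term therefore never sits
strictly between two kept terms, and under single-pass descendant-count
trimming contraction gives the same result as deletion. Contraction is kept
as the mechanism because it is what guarantees the reachability property
independent of the trimming rule.

Other ontology conventions: only `is_a` edges are used; obsolete terms are
dropped; GAF rows with a `NOT` qualifier are excluded; terms of equal depth
are ordered lexicographically (this fixes the neuron layout, making mask
construction a pure function of the trimmed ontology); gene identifiers are
matched exactly and case-sensitively; reconstruction connections use direct
annotations only, since descendant information already flows through the
term–term edges.

## Activities and perturbations

The *activity* of a term for a sample is the mean of its k neuron activations
when the sample is run through the model. Inference is deterministic: the
posterior mean μ is used instead of a sampled z and all dropout is off, so
repeated calls are bit-identical and screens are reproducible. Depth-0 terms
report averaged μ components.

An in-silico *knockout* sets one gene's input column to 0; a *stimulation*
sets it to a constant above the observed range (default: the data maximum
rounded up to the next integer, generalizing "set to 8 when the maximum is
6.8"). Node activities pre vs post perturbation are compared with a one-tailed
paired Wilcoxon signed-rank test; for stimulations, samples with zero baseline
expression of the gene can be excluded. Screens perturb genes one at a time
(single-gene semantics throughout), reuse the pre-perturbation activities, and
rank genes by p-value with ties broken by statistic magnitude and then gene ID;
untestable genes (all differences zero, or fewer than two usable pairs) rank
last with p = NaN rather than raising.

`term_and_gene_level_analysis` runs the paired test at every term node
(term-level) and at every reconstruction gene (gene-level), then performs
hypergeometric over-representation analysis of each term's descendant gene set
within the top-k (default 100) most affected genes, with Benjamini–Hochberg
correction; the background is the set of all model genes.

## Statistics

Rank-sum (Wilcoxon–Mann–Whitney) and signed-rank tests are delegated to scipy
with its automatic method choice: exact null distributions for small tie-free
samples, tie-corrected normal approximation with continuity correction
otherwise. Reported statistics are centered (U − n₁n₂/2 and W⁺ − m(m+1)/4), so
0 is the null expectation and the sign gives the direction. Zero differences
are dropped before the signed-rank test; identical constant samples give
p = 1. BH-FDR uses `statsmodels.stats.multitest.fdrcorrection`. Both tests are
validated against exhaustive enumeration oracles (all rank assignments / all
sign flips) for n ≤ 8 and against simulated type-I error at the 0.05 cutoff.

The pairwise-hit ranking (`rank_terms_for_groups`) runs, for every term and
every ordered pair of sample groups, a one-sided rank-sum test of "more active
in A than B"; a win at p ≤ 0.05 (uncorrected, configurable) is a hit. Groups
are ranked per term by hit count, and a group's top terms are sorted by
(rank, hits, median statistic). Jaccard similarity of two terms is
intersection-over-union of their descendant gene sets, with the empty-union
case defined as 0, and bands low ≤ 0.25 < medium ≤ 0.75 < high.

## Synthetic data

The generator emulates the model's own generative assumption. A random DAG is
grown from a single root with 1–2 parents per term and bounded depth; genes
are drawn for each term from a shared pool, so genes can annotate several
terms. Per sample, each root term receives a half-normal(1) latent activity —
non-negative, matching the decoder's positivity semantics; a child term's
activity is the parent-weight average with fixed weights ~ U(0.5, 1); a gene's
value is the sum of `w·activity` over the terms annotating it
(w ~ U(0.5, 1.5)) plus Gaussian noise (sd 0.5 by default), truncated at zero.
Truncation rather than exponentiation keeps the generative map piecewise
linear and analyzable. Optional group structure adds an `effect_size` shift
(default 2) to one root's activity for each non-reference group.

What this emulates: non-negative pathway activities driving genes through a
sparse positive linear map with additive noise — exactly the structure the
decoder can represent. What it does not emulate: count noise, dropout and
overdispersion of real scRNA-seq, batch effects, gene–gene regulation outside
the ontology, or annotation errors. Tests passing on this generator show the
machinery recovers known structure under the model's own assumptions; they do
not certify performance on real data.

`branch_driver_scenario` is a hand-constructed special case for perturbation
benchmarking: three branches under a root, where one branch's activity reaches
the expression matrix exclusively through a single driver gene (weight 2; the
branch's other annotated genes are pure noise). A trained model can then read
that branch only from the driver, so its knockout must depress the branch —
a ground truth for screening.

## Problem sizes and training length at desk scale

All analyses in the tests and the reproducibility script run on synthetic data
sized for a single CPU: ontologies of ~10–60 terms, 100–300 genes, 80–500
samples. The published protocol (300 epochs, batch 128) was designed for
datasets with tens of thousands of samples, where one epoch is hundreds of
optimizer steps. At 500 samples an epoch is ~4 steps, so the scaled-down runs
train longer by epoch count to reach an equivalent optimization budget: 1500
epochs for the 500-sample reproducibility analysis and 3000 for the 150-sample
branch-driver fixture, always keeping best-validation-epoch selection. The
`ModelSpec` default remains 300 epochs.

Training to convergence matters qualitatively for the screens: an
under-trained encoder leaves small but directionally consistent spurious
dependencies of every latent on every gene, and a paired signed-rank test
saturates for any consistent effect regardless of magnitude, which makes weak
spurious genes tie with true drivers. At convergence the spurious effects
become mixed-sign across samples and the true driver separates cleanly.

## Numerical and design choices

- Reconstruction likelihood: Gaussian with identity covariance (MSE), summed
  over genes and averaged over samples; inputs are continuous log-scale
  expression.
- Latent dropout acts on the sampled z (not on μ), training only.
- Decoder biases exist and are unconstrained; positivity applies to weights.
- Non-negative decoder initialization: |N(0, 1/√fan-in)| restricted to the
  mask, avoiding dead-at-zero starts.
- Validation loss is computed with z = μ and dropout off, making best-epoch
  selection deterministic.
- Untrained models produce activities with a warning, not an error.
- Checkpoints are a single zip archive (JSON metadata + raw arrays) embedding
  the trimmed ontology and its content hash; loading verifies both the format
  version and, when an ontology is supplied, the hash.

## Known limitations

- Only `is_a` relationships are modeled; other edge types are discarded.
- The decoder's prior structure is hard-coded; annotation errors propagate.
- Perturbations are single-gene; combinatorial effects are out of scope.
- Rank-based perturbation tests order genes by consistency, not effect size;
  p-values saturate in large sample sets (see above).
- The NumPy implementation targets CPU-scale problems; very large ontologies
  (thousands of terms) will train slowly compared to a GPU implementation.
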