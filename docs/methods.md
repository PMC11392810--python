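# Methods

This note documents the models, algorithms and numerical choices behind
`shmseq`, what the synthetic-data generators do and do not emulate, and the
problem sizes used by the test suite and `scripts/acceptance.py`.

## Synthetic references and reads

**Taxonomy and sequences** (`fixtures`). Taxonomies are balanced
root → family → genus → species trees; the default shape is 65 species
spread unevenly over 39 genera (the composition of a specific-pathogen-free
mouse gut community). Each species' 1,500-nt reference derives from one
ancestral template mutated along tree branches with a Jukes–Cantor-style
uniform substitution process (default 2% per branch; species branches use a
quarter of that rate). Two structural features are imposed:

- a substitution-free capture site — a fixed expansion of the degenerate
  surface-probe recognition segment `GGATTAGATACCCBDGTAGTCGAGATNB` —
  embedded at a configurable position (default 900), emulating the
  conserved flank the capture probe hybridizes to;
- a 250-nt variable region immediately upstream of the site that receives
  boosted (4×) substitutions on genus branches, so genera are discriminable
  from short fragments, as the 16S V4 hypervariable region is.

The generator does **not** emulate rRNA secondary structure, chimeras,
horizontal transfer, copy-number variation between species, or real 16S
conservation profiles. Classifier results on these fixtures therefore show
that the pipeline machinery works and that the architecture can learn
genus-discriminative sequence features; they do not certify accuracy on
real gut communities, where inter-genus divergence is far less uniform.

**Read simulation** (`sim16s`). The capture site on each reference is
located by Smith–Waterman local alignment (match +1, mismatch −1, gap −2)
of every concrete expansion of the degenerate probe (108 expansions; the
20-nt poly(A) attachment tail is excluded as it is the capture handle, not
a recognition site). Ties in score break to the leftmost interval. Species
whose best score falls under 80% of the maximum attainable are excluded
from simulation, mirroring the exclusion of species without a usable 16S
sequence. Fragments are the L bases immediately upstream of the site with
L ~ Normal(mean, sd) rounded, clamped to ≥1 and to the available upstream
span, then trimmed to the sequencer read length keeping the site-adjacent
end. Two length models matter: 400 ± 44 bp trimmed to 150 bp
(array-characteristic capture fragments) and 143 ± 13 bp truncated at
150 bp (classifier-training distribution). Biological mutations (default
0.1%) and sequencing errors (default 1% where used) are independent uniform
substitutions; quality strings are uniform Q40 (the original workflow
templates qualities from a real run — accepted here as an optional input
but not synthesized).

## Two-stage classification

**k-mer LCA stage** (`kmer_lca`). An exact index of canonical 31-mers maps
each k-mer to the LCA of all species whose reference contains it (no
minimizers and no low-complexity masking — at desk scale neither is
needed; masking is a documented difference from the tool that inspired
this stage). A read's k-mer hits are tallied per taxon; each root-to-leaf
path is scored by the summed hits inside the clade; the deepest maximal
taxon wins, with sibling ties resolved conservatively to their LCA. The
confidence of a call is the fraction of the read's valid (ACGT-only)
k-mers inside the chosen clade; while it is below the threshold (default
0.01) the call climbs toward the root. Calls that end at or above family
rank are reported unclassified.

**Deep stage** (`deep_taxa`). Reads are one-hot encoded over (A, C, G, T,
N), right-padded to 150 nt and masked. The network is: masking → four
parallel same-padding 1-D convolutions with kernel sizes 15, 17, 19, 23
(ReLU) → concatenation → dropout 0.5 → two bidirectional LSTM layers →
dropout 0.2 → dense (ReLU) → dropout 0.1 → dense (ReLU) → softmax over
genera. Hidden sizes are package defaults — 32 filters per branch, 48
recurrent units per direction, dense widths 96 and 48 (≈150k trainable
parameters); the published description fixes the kernel sizes and dropout
rates but not the filter/unit counts, so these are calibration choices.
Masking is carry-through: at padded steps the LSTM state passes unchanged,
so a read's output is identical whether it is padded to 150 or batched
with longer reads; convolution outputs at padded positions are zeroed.
Training uses Adam on categorical cross-entropy, per-epoch shuffling, an
80/20 split, at most 15 epochs, and early stopping when the training loss
has not decreased in 5 consecutive epochs. Mini-batches (default 128) are
used rather than single-example updates, a standard efficiency choice.
Dropout is inactive at prediction time; argmax ties break to the lowest
class index. The whole network is implemented in numpy (float32) with
explicit layer-by-layer backpropagation, validated against finite
differences in the test suite.

**Pipeline** (`pipeline`). Stage order: adapter trimming (3′
suffix–prefix match, ≥8 nt overlap, ≤1 mismatch) → mean-quality filter
(Q ≥ 20; the upstream protocol's exact filter is not restated anywhere, so
this explicit rule stands in and is config-exposed) → strict length filter
(>100 nt) → demultiplexing (candidates by shared 6-mers, unique assignment
at Hamming ≤2, ties unassigned, observed barcodes with >2 N unassigned) →
optional host screen (a read is host if ≥50% of its 31-mers occur in a
supplied host k-mer set; a precomputed flag file is also accepted — this
replaces alignment against the mouse genome while keeping the stage's
contract) → two-stage classification → UMI collapsing (within each
barcode × genus group, molecules are the connected components of the
Hamming ≤1 graph over UMIs) → taxa-by-barcode matrix. Every stage reports
exact kept/removed counts, so reads are conserved through the QC report.

## The spatial model

For one taxon (or gene) at a time, counts y at spot k of section j follow

    y ~ ZIP(s·λ, θ),  log λ = B + ψ + ε

with s the spot size factor (spot UMI total over the median spot total;
all-zero spots are excluded), θ the taxon's dropout probability, and:

- **B**: the characteristic expression of the spot's MROI. With several
  animals per condition a two-level hierarchy is used: β_l1 ~ N(0, 2²) per
  (condition, MROI) and β_l2 ~ N(β_l1, σ_l2²) per (animal, MROI) with
  σ_l2 ~ halfN(0,1); with one group per condition the model collapses to
  one level. MROIs absent from a section simply contribute no spots.
- **ψ**: a CAR Gaussian Markov random field per section on the rook
  (4-nearest-neighbor) adjacency of annotated spots, precision
  τ(K − αW), α ~ U(0,1), τ ~ InvGamma(1,1). Isolated spots (no neighbors)
  get unit diagonal weight in the precision so the prior stays proper and
  their field value shrinks to zero.
- **ε**: iid N(0, σ²) spot noise, σ ~ halfN(0, 0.3²).
- θ ~ Beta(1,2), gating a per-observation zero.

**Inference.** Hamiltonian Monte Carlo on the unconstrained parameter
vector (log/logit transforms with Jacobians; β_l2 and ε non-centered to
avoid funnel geometry). Gradients of the joint log posterior are analytic;
the CAR log-determinant uses precomputed generalized eigenvalues
(log det(K−αW) = Σ log K̃ᵢ + Σ log(1−αλ_m)). Each chain runs dual-averaging
step-size adaptation (target acceptance 0.8) with a diagonal mass matrix
estimated from the middle of warmup; trajectories use 16–32 leapfrog steps
with jitter. Defaults are 4 chains × 200 iterations (100 warmup + 100
kept, 400 total draws), matching the study's sampling schedule. Chains are
initialized at stratified empirical log rates with small jitter.
Diagnostics report split-R̂ per β cell and scalar, acceptance rates, and
divergent transitions (non-finite or exploding Hamiltonian error); more
than 10% divergences is flagged, not fatal. Fits are bitwise reproducible
for a fixed seed on a single thread.

**Differential calls.** For a contrast Δβ between two level-1 cells, the
prior is the closed-form difference of independent N(0, 2²) normals,
N(0, 8); the posterior density at zero is a normal approximation from the
400 draws (a Gaussian KDE option exists, but 400 draws make KDE tails
unstable, hence the normal default). BF = prior/posterior density at zero;
zero posterior sd reports BF = ∞ with a flag. The log threshold is read in
base 10 (log10 BF > 0.5, strict) together with Δβ > 0 — the figure-axis
convention; contrasts default to level-1 (condition-level) draws, both
config-exposed. Bacteria detection: a (taxon, region) pair is detected
when the region's weighted mean rate under SPF — the posterior-mean λ
averaged over the region's spots, which weights sections by their spot
count in the region (the weighting is not specified upstream; this choice
is config-exposed) — exceeds the maximum weighted mean over all germ-free
regions for that taxon, and the region carries more than 2% of the taxon's
total raw counts.

**Spatial count generator.** `fixtures.make_spatial_dataset` samples from
exactly this generative model (ψ by Cholesky solve of the CAR precision,
per-observation dropout) and stores every latent, so recovery tests can
recompute λ from the stored B, ψ, ε bit-exactly. It emulates region
structure via contiguous horizontal bands of the array — connected
regions, like real tissue-layer annotations — but not irregular region
shapes, varying section sizes, or segmentation noise.

## Niche analysis and benchmarking

Standardization is z-scoring with sample (n−1) standard deviation (the
convention is not stated upstream; fixed and documented here); constant
vectors are dropped. Cell-to-spot similarity is the Pearson correlation of
standardized expression vectors over common genes (≥3 required). Gene
modules are average-linkage hierarchical clusters under Manhattan distance
of genes' standardized spot-expression vectors, cut to a target count (28
at full scale); what is clustered is genes, with the cell × spot
similarity used only for cell-type mapping — the two readings of the
upstream description are both implemented behind a switch, as are
target-count vs distance-threshold cuts. Submodules re-cluster a module's
genes by cosine distance on max-scaled per-cell-type means, cut at 0.4×
the maximum linkage height; genes whose pre-scaling mean across cell types
is below 1 are removed (the literal post-scaling reading is selectable but
max-scaling makes it nearly vacuous). Cell-type enrichment is a two-sided
Wilcoxon signed-rank test of a submodule's genes in one type against their
mean in the rest, BH-corrected across types, with submodules under 5 genes
reported untested. Gene-set enrichment is the hypergeometric upper tail
(one-tailed Fisher) with BH correction and an FDR < 0.05 report threshold.

snRNA-seq utilities: TP10K normalization; variable-gene selection by LOESS
residuals of log CV on log mean within 20 equal-frequency mean bins,
taking the largest residuals equally across bins (consensus across samples
by recovery rate); nucleus filters (>800 genes strictly, genes in ≥10
cells, flagged mitochondrial/rRNA fraction <30%).

Benchmarking: pooled ("bulk-like") accuracy; macro F1; a false-positive
rate defined as misassigned classified reads over total classified reads
(the multiclass FPR convention is not defined upstream, so it is fixed
explicitly here — unclassified reads hurt accuracy but not FPR);
composition agreement at a chosen spot-group resolution (random partition
of spots, relative abundances per group compared by Pearson or
Bray–Curtis, mean over groups); and region-matched resampling correlation
(at most 3 coordinates per region per sample, min–max scaled within
sample, Spearman ρ, averaged over 1,000 repetitions by default).

## Problem sizes

Full-scale defaults (500,000 training reads, 2M simulated reads, 28
modules, 1,500 variable genes) are exposed as parameters. The test suite
and acceptance script run scaled-down versions chosen to exercise the same
code paths in minutes on one CPU:

- classifier: 3 genera × 2 species, 5,000 reads of ~90 ± 10 nt (≤100 nt),
  80/20 split, 3 epochs of the default architecture, 3 seeds;
- two-stage benchmark: 20,000 unseen reads at 0.1% mutations + 1%
  sequencing error;
- spatial model: 300 spots (4 sections × 75), 2 conditions × 2 animals, 3
  MROIs, 20 genes with known coefficients (generator: α = 0.8, τ = 10,
  σ = 0.25, θ = 0.1, animal effects sd 0.3 — a field whose standard
  deviation is comparable to the spot noise);
- end-to-end recovery: 8,000 noise-free reads over 6 species.

## Known limitations

- The HMC sampler is simple by design (no tree doubling); on the default
  4×200 schedule some fits show split-R̂ well above 1.1. The diagnostics
  report this honestly; longer chains fix it at proportional cost.
- The k-mer stage skips low-complexity masking, so on real references
  homopolymer-rich k-mers can inflate clade support.
- The deep classifier is genus-level only, as designed.
- β and ψ are only weakly identified when the CAR field is strong and
  regions are few: some of a smooth field realization can be absorbed
  into region means. The recovery experiment's coverage reflects this
  trade-off.
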