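# shmseq

Analysis toolkit for **spatial host–microbiome sequencing (SHM-seq)**: an
assay that captures bacterial 16S rRNA V4 fragments alongside host
polyadenylated transcripts on a spatially barcoded glass array, so the
microbial composition of a tissue section (here, mouse gut cross-sections)
can be mapped to its histology.

The package implements the computational core of the assay end to end, all
testable on synthetic data with no downloads:

- **`fixtures`** — deterministic generators for taxonomies, 16S-like
  reference sequences with an embedded capture-probe site, and
  region-structured spatial count data with known model parameters.
- **`sim16s`** — probe-anchored read simulation: Smith–Waterman location of
  the degenerate 16S surface probe (`GGATTAGATACCCBDGTAGTCGAGATNB`),
  fragment sampling immediately upstream of the capture site (normal length
  model, trimmed to the read length), uniform substitution models for
  biological mutations and sequencing error, and assembly into spatially
  barcoded FASTQ pairs with a truth table.
- **`kmer_lca`** — first-pass taxonomic classifier: exact canonical 31-mer
  index mapping each k-mer to the lowest common ancestor (LCA) of the
  species carrying it; reads scored by clade support with a confidence
  threshold (default 0.01) and reported at genus rank.
- **`deep_taxa`** — the deep fallback classifier: one-hot encoded reads
  (≤150 nt, channels A/C/G/T/N, masked padding) through four parallel 1-D
  convolutions (kernels 15/17/19/23), two bidirectional LSTM layers and a
  dropout/dense/softmax stack; trained with Adam on categorical
  cross-entropy. Implemented in numpy with explicit backpropagation.
- **`pipeline`** — read processing: adapter trimming, mean-quality and
  length (>100 nt) filters, spatial barcode demultiplexing (6-mer candidate
  retrieval, ≤2 mismatches, ties unassigned), optional host k-mer screen,
  two-stage classification (k-mer LCA first, deep model for unclassified
  reads), UMI collapsing (Hamming ≤1 connected components per barcode ×
  genus), and emission of the taxa-by-barcode matrix.
- **`splotch`** — hierarchical Bayesian spatial model. Counts per spot
  follow a zero-inflated Poisson, `y ~ ZIP(s·λ, θ)` with
  `log λ = B + ψ + ε`: `B` is the characteristic expression of the spot's
  morphological region (MROI) under a two-level hierarchy (condition →
  animal, `β_l1 ~ N(0, 2²)`, `β_l2 ~ N(β_l1, σ_l2²)`), `ψ` a conditional
  autoregressive (CAR) field on the 4-neighbor spot grid with precision
  `τ(K − αW)`, and `ε` iid spot noise. Inference is a hand-written
  Hamiltonian Monte Carlo sampler with analytic gradients (4 chains × 200
  iterations, 100 warmup). Differential expression uses the Savage–Dickey
  density ratio `BF = p(Δβ=0)/p(Δβ=0|D)` with calls at `log10 BF > 0.5` and
  `Δβ > 0`; bacteria are called detected per region when the SPF weighted
  mean rate beats every germ-free region and the region holds >2% of the
  taxon's counts.
- **`niche_eval`** — downstream analysis and benchmarking: standardized
  cell-to-spot Pearson similarity, hierarchical gene modules (average
  linkage, Manhattan distance, 28 clusters at full scale) and submodules
  (cosine distance, cut at 0.4× the maximum linkage height), Wilcoxon
  cell-type enrichment and one-tailed Fisher gene-set enrichment with
  Benjamini–Hochberg correction, TP10K normalization, CV-residual variable
  gene selection, nucleus QC filters, Bray–Curtis dissimilarity,
  classification reports and region-matched resampling correlations.

## Worked example

```python
import numpy as np
from shmseq import core_io, fixtures, sim16s, kmer_lca, pipeline

# 3 genera x 2 species, diverged references with an embedded probe site
cfg = fixtures.FixtureConfig(seed=7, n_genera=3, species_per_genus=2,
                             n_species=None, ref_length=1200,
                             probe_site_position=800,
                             branch_substitution_rate=0.05)
tree = fixtures.make_taxonomy(cfg)
refs = fixtures.make_references(tree, cfg)

layout = core_io.default_layout()            # 1,007 barcoded spots
ab = {s: 1/6 for s in tree.species_ids}
rs = sim16s.simulate_readset(refs, ab, 8000,
                             sim16s.LengthModel(mean=130, sd=15, trim_to=150),
                             layout=layout, seed=3)
paths = rs.write("scratch_sim")

index = kmer_lca.build_index(refs, k=31)
res = pipeline.run_pipeline(paths["r1"], paths["r2"], layout, index)
print(res.qc["stages"]["classify"])
rec = res.matrix.counts.sum(axis=1) / res.matrix.counts.sum()
```

Output:

```
{'kept': 7847, 'removed': 0, 'stage1_fraction': 1.0, 'classified_fraction': 1.0}
```

7,847 of 8,000 reads survive the strict >100 nt length filter, all
demultiplex to a layout barcode and classify at genus rank in the k-mer
stage (the reads are noise-free), and `rec` reproduces the input genus
abundances with Pearson r ≈ 1.00 and Bray–Curtis ≈ 0.006 after UMI
collapsing (7,831 molecules; a handful of reads shared a random barcode and
near-identical UMI).

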