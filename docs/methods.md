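# Methods

## The statistic

For a DNA sequence *s*, let O(z_i|s) be the observed frequency of tetramer
z_i among all overlapping 4-mer windows on the given strand, and let
E(z_i|s) be the frequency expected under a zero-order Markov model — every
base independent, with probabilities equal to the sequence-wide
mononucleotide frequencies, so that E(w1w2w3w4) is the product of the four
base frequencies. The relative entropy of the sequence is the
Kullback–Leibler divergence

    D_KL(s) = Σ_{i=1..256} O(z_i|s) · ln( O(z_i|s) / E(z_i|s) ),

with 0·ln 0 := 0. D_KL ≥ 0 by Gibbs' inequality, with equality exactly
when tetramer usage is fully explained by mononucleotide composition.
High D_KL indicates strong dependence between neighbouring bases — a
pronounced genome signature, interpreted as high information capacity;
low D_KL indicates a sequence that resembles an independent shuffle of
itself, as expected after heavy mutational randomisation. The companion
oligonucleotide-usage statistic is the mean observed/expected ratio,
D_OUV(s) = (1/256) Σ O(z_i|s)/E(z_i|s), implemented exactly as that mean:
cells with zero observed frequency contribute 0, so a homopolymer scores
1/256. (Note this printed form is a mean of ratios, not the variance-type
usage statistic that appears elsewhere in the literature under a similar
name; the package implements the formula as stated.)

Conventions, each chosen once and switchable where noted:

* **Log base** — natural log (nats) throughout; `log_base=` rescales.
* **Strand** — only the given strand is counted; no reverse-complement
  pooling.
* **Topology** — linear; no wrap-around windows across a circular origin.
* **Ambiguity codes** — tetramer windows containing any non-ACGT symbol
  are skipped; mononucleotide frequencies use unambiguous bases only.
  This avoids inventing frequencies for IUPAC codes.
* **No pseudocounts** — frequencies are raw maximum-likelihood estimates.
  The 10 kb ingestion filter keeps empty cells rare in practice.
* **Indexing** — tetramers are ordered lexicographically over A<C<G<T, so
  spectra are comparable across runs and files.

### Finite-sample behaviour

On a truly zero-order sequence of length L the expected D_KL is not zero
but approximately (number of free cells)/(2L) ≈ 252/(2L) nats — about
0.0126 at 10 kb and 0.0012 at 100 kb. This is why short sequences are
excluded (strictly greater than 10,000 bp, configurable) and why window
estimates sit slightly above the whole-sequence value: the inflation term
is ~25× larger at 5 kb than at 125 kb. Comparisons are therefore made at
matched or filtered lengths, and the window profiler compares windows
against each other, not against the whole-sequence value.

## Window profiles and low-entropy flagging

Chromosome profiles use consecutive non-overlapping windows (default
5,000 bp; at least 1,000 bp, below which 256-cell spectra are too sparse).
Each window is analysed independently against its own local zero-order
null. The trailing partial window is dropped — it would carry a different
variance. Coordinates are 0-based half-open; BED output uses the same
convention. All-ambiguous windows carry NaN and are excluded from summary
statistics. Output tables include both the raw window D_KL and its
difference from the profile mean.

`flag_low_entropy` flags maximal runs of windows whose D_KL falls below
`center − k·scale` (default k=2). Two numerical choices matter here and
are deliberate:

* **Robust center/scale (median and 1.4826·MAD) by default.** With the
  plain mean/SD rule, a compositionally distinct region spanning a
  sizeable fraction of the chromosome inflates the SD and drags the mean
  down until the threshold lands inside the anomaly itself — the region
  fragments or escapes detection entirely (masking). The median/MAD pair
  stays anchored to the bulk of the chromosome for contamination up to
  50%. `robust=False` restores the classical mean/SD rule.
* **Minimum run length (default 3 windows).** Under a homogeneous
  chromosome roughly 2% of windows fall below a 2-SD threshold by chance;
  on a 1,000-window profile that is ~20 isolated dips per genome. Real
  compositionally distinct regions extend over many consecutive windows,
  so runs shorter than `min_run` are discarded; with min_run=3 the
  expected number of false intervals per 1,000-window profile is ≪ 1.

## Cohort statistics

All cohort analyses operate on a per-sequence table (id, D_KL, D_OUV, AT,
GC, length + class/phylum/domain/species metadata).

* **Class comparisons** — two-sided Mann–Whitney rank-sum test per class
  pair (distributions are skewed but similar in shape). Raw p-values are
  reported, matching common practice for a handful of planned contrasts;
  `holm=True` applies a Holm adjustment. Classes with fewer than 5
  members are excluded with a warning.
* **D_KL vs AT** — OLS of ln(D_KL) on AT content per class. Natural log,
  consistent with the unit choice. Rows with D_KL = 0 are dropped (log
  undefined) rather than offset-shifted, and the drop is logged.
* **Size vs AT** — OLS with a fixed class-specific response transform
  that normalises each class's size distribution: sqrt for chromosomes,
  log for phages and plasmids, reciprocal (1/Y) for islands. The
  registry is total over the four classes and the transform is recorded
  in every report.
* **Combined model** — AT = a + b·D_KL + c·size + d·size², untransformed
  response. Size is centered before squaring to tame collinearity;
  coefficients are reported on the centered scale. The report carries the
  R² of the size block alone and the incremental R² of adding D_KL.
* **Nested-model LRT** — models are ordinary Gaussian linear models;
  2·(ℓ_full − ℓ_reduced) is referred to χ² with df equal to the parameter
  difference. Nesting is checked on the term sets.
* **Phylum models** — D_KL ~ phylum (factor), ~ GC, and ~ phylum + GC,
  with an F-test of the phylum × GC interaction on top of the additive
  model. Expects one row per species; `cohort_table(dedupe_species=True)`
  keeps the first occurrence per species (the dedup rule is explicit
  rather than inferred from strain names).
* **Domain contrast** — Welch unequal-variance t-test.
* **Conserved-gene contrast** — per-gene, paired Wilcoxon signed-rank on
  matched gene sets (the pairing must be a bijection; ortholog assignment
  is an input, not a function of this package). Pairing per gene, rather
  than pooling or concatenating the sets, is the stricter choice and
  keeps gene-level variance visible.

Every test exposed here has a simulation harness (used by the test suite
and the acceptance script) asserting type-I error within (0.01, 0.12) at
nominal 0.05 under its null.

## The synthetic-data generators

The generators produce the statistical regimes the analysis assumes, so
every stage can be exercised end to end without any external data.

* **Zero-order sequences** — i.i.d. bases with P(A)=P(T)=AT/2,
  P(C)=P(G)=(1−AT)/2; the null of the statistic and the "random genome"
  control in the profile analysis.
* **Biased sequences** — a first-order Markov chain with kernel
  T = (1−β)·P0 + β·B, where P0 is the zero-order kernel and B follows
  each base with its Watson–Crick complement with weight 0.8 and with a
  fresh draw from the base distribution with weight 0.2. The complement
  permutation (A↔T, C↔G) preserves any strand-symmetric base
  distribution, so the stationary AT content is exact for every β, and
  the 0.2 relaxation keeps the chain ergodic even at β=1. β=0 reduces
  exactly to the zero-order generator. First-order dependence is the
  simplest mechanism that produces nonzero tetranucleotide D_KL against a
  zero-order null; at 200 kb the mean D_KL rises smoothly from ~0.0006
  (β=0) through ~0.61 (β=0.5) to ~2.40 nats (β=1). Sampling exploits the
  mixture's renewal structure (complement-copy with probability 0.8β,
  fresh draw otherwise) and is fully vectorised.
* **Mutation** — per-site substitution with probability `rate`; the
  substitute is uniform over the three alternatives except that with
  probability `at_bias` it is drawn from {A,T} minus the current base,
  emulating the AT-ward mutational pressure of decaying genomes.
* **Four-class ensemble** — 40 sequences per class with ordered mean
  bias: chromosome-like β≈0.80 (1–5 Mb), island-like β≈0.70 (10–100 kb),
  phage-like β≈0.55 (20–100 kb), plasmid-like β≈0.45 (10–200 kb); AT
  drawn uniformly on (0.3, 0.7) per sequence; all lengths above the 10 kb
  filter. These class parameters are calibration choices — set once so
  that the class ordering and the AT association emerge robustly — not
  estimates of any real inventory. The optional coupling λ makes the
  effective bias β′ = β·(1 − λ·(AT − 0.5)) (clipped to [0,1]), so AT-rich
  sequences are less biased and ln(D_KL) regresses negatively on AT; at
  λ=0 D_KL is nearly flat in AT (and symmetric about 0.5), giving the
  decoupled control.
* **Embedded genome** — a β=0.8 chromosome (default 5 Mb) with a
  zero-order segment spliced at given coordinates (default the middle
  1 Mb), its AT elevated by +0.05; the anomalous mid-chromosome regime.
* **Ortholog pairs** — ancestral genes (default 100 × 1 kb, β=0.8,
  AT=0.4); set A mutated at 1% (a conserved reference), set B at
  `decay_rate` (default 15%) with `at_bias`=0.7 (a decayed relative).

All generators are fully determined by their seed; FASTA output is
byte-identical across runs.

### What the generators do and do not emulate

They reproduce the *statistical* structure the analyses rely on —
ordered class bias, an AT–bias coupling, mutational decay of paired
genes, a compositionally distinct chromosome region — but not codon or
gene structure, phylogenetic correlation between sequences, repeat
content, or the sampling biases of public sequence inventories. Passing
tests therefore demonstrate that the pipeline detects these effects when
present and stays calibrated when absent; they do not certify effect
sizes on real genome collections, and the R²/p values printed by the
analysis scripts characterise the synthetic cohorts only.

## Problem sizes

The analysis drivers and checks use: 160-sequence ensembles (40 per
class, chromosomes 1–5 Mb), 5 Mb chromosomes with 1,000 windows for the
profile analyses, 100-gene ortholog sets, 30 replicates per condition for
null/monotonicity curves, and 100 null simulations per test-calibration
harness. A full pass of the analysis scripts runs in a few minutes on one
CPU.

## Known limitations

* The zero-order null is the weakest dependence model; D_KL values are
  therefore upper bounds relative to first- or second-order nulls and not
  comparable across null orders.
* D_KL depends on sequence length through the finite-sample inflation
  term; cross-length comparisons should filter or match lengths (the
  10 kb filter is the default mitigation, not a cure).
* The bias mechanism is first-order; real genome signatures include
  higher-order and strand-asymmetric structure the generator does not
  model.
* `flag_low_entropy` assumes the anomalous fraction of a chromosome is
  well under half; above that, even the robust threshold loses its
  anchor.
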