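# Methods

`phagetf` re-implements, as a tested library, a computational survey of
transcription-factor genes (WhiB-like and Lsr2-like regulators) across
actinobacteriophage genomes: post-processing of conserved-domain
screens, an alignment-free whole-genome phylogeny, a translated
homolog-detection pipeline, identity clustering and gene trees,
genomic-context/GC analysis, and lifestyle/GC/genome-size group
statistics.  This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Synthetic genome collections

Every stage is exercised end to end on simulated data
(`phagetf.simulate`), because the real survey inputs are thousands of
downloaded genomes.  The generator emulates exactly the statistical
structure the analysis relies on:

- **Cluster structure.** Each cluster draws an independent random
  ancestor at its configured background GC; members descend from the
  ancestor by i.i.d. per-site substitution (uniform over the three
  alternative bases, no transition bias, no indels).  Descent is
  star-shaped: every member sits at one branch length from the
  ancestor, so the expected pairwise within-cluster divergence is
  `2p(1-p) + (2/3)p^2` for substitution probability `p`.  Between-cluster
  structure comes from ancestor independence, not a simulated deep tree:
  the analyses only require cluster-level separability.
- **Implanted regulator genes.** Seed proteins are mutated to a
  requested amino-acid divergence by substituting an exact count of
  positions (so realized divergence equals the target up to rounding,
  well within the ±5-point check applied by the tests), then
  back-translated with codon choice weighted by the background GC, an
  appended stop codon, uniform strand, and uniform placement subject to
  non-overlap and a 6 kb margin from the genome ends so 5 kb context
  windows are always complete.  0–2 copies per genome per plan entry.
- **AT-rich dips.** Upstream of every Lsr2-like implant (strand-aware),
  a window of configurable width (default 300 bp) is resampled at
  background GC minus the dip depth (default 0.15) — the signature of a
  xenogeneic-silencing target region.
- **Direct terminal repeats.** With `dtr_length_bp > 0` the first
  `dtr` bases are copied over the genome tail; one implant copy is
  placed inside the repeat (with a margin larger than the 500 bp gene
  pad, so both copies present identical extended loci), and the truth
  records the mirrored copy.  This reproduces the observation that
  gene copies inside terminal repeats are 100% identical.
- **Lifestyle labels.** Temperate/virulent is Bernoulli with base odds
  1:1; implant carriers have their odds multiplied by `lifestyle_odds`,
  producing the carrier-enrichment signal the group statistics measure.

What the generator does **not** emulate: real gene content and operon
structure, recombination/mosaicism, indels, codon-usage selection, and
sequencing artifacts.  Passing recovery tests therefore demonstrates
correctness of the pipeline's logic under its stated assumptions, not
performance on real phage assemblies.

## Whole-genome phylogeny

Genomes are summarized as `k`-mer frequency profiles (default `k = 6`,
4096 features; windows containing N are skipped; single-strand by
default with a `canonical` flag folding in reverse complements).
Profiles are compared with the Jensen-Shannon divergence in bits,
`JSD(P,Q) = H(M) − (H(P)+H(Q))/2`, `M = (P+Q)/2`, which is symmetric
and bounded by [0, 1] in base 2.

**Distance choice.** The distance fed to neighbor joining is
`sqrt(JSD)`, the form that satisfies the metric axioms.  This was
originally an option and raw JSD the default, but raw JSD grows
approximately quadratically in small composition differences, which
badly violates additivity: on simulated collections whose cluster GCs
lie along a gradient, both this package's NJ and an independent NJ
implementation ladder the intermediate clusters when given raw JSD
(concordance 0.5), while sqrt-JSD recovers every cluster across all
seeds tried.  Raw JSD remains available (`sqrt=False` /
`--raw-jsd`).

Neighbor joining is the Saitou–Nei algorithm with the Studier–Keppler
Q-criterion.  Ties in the Q-minimization break on the lowest index
pair, making the tree deterministic.  Negative branch lengths (possible
on non-additive inputs) are clamped to zero with the deficit moved to
the sibling branch.  On additive matrices the implementation recovers
the generating topology (Robinson–Foulds 0) and branch lengths to
1e-9; this is checked against 200 random trees of 5–12 taxa and
cross-checked against dendropy's NJ.

Cluster concordance reports, for every cluster with at least two
leaves, whether its leaf set is one side of some edge of the unrooted
tree (the unrooted notion of monophyly), plus the concordant fraction.

## Homolog detection pipeline

The detection pipeline composes five stages, mirroring a
TBLASTN → merge → extend → translate → BLASTP-filter workflow with an
in-repo alignment engine:

1. **Translated search.** Each protein query is Smith–Waterman-aligned
   (BLOSUM62; affine gaps costing `11 + L` for a gap of length `L`)
   against all six reading frames (translation table 11; codons with N
   give X; stop codons stay in frame as `*`, which BLOSUM62 penalizes).
   Significance uses Karlin–Altschul statistics with the gapped
   BLOSUM62 constants λ = 0.267, K = 0.041:
   `S' = (λS − ln K)/ln 2`, `E = m·n·2^(−S')` with `m` the query length
   and `n` the genome length.  Hits require `E ≤ 1e-5`.  Because
   Smith–Waterman yields one optimal alignment, each significant hit's
   footprint is masked with X and the frame re-searched (up to 8
   rounds), so multiple gene copies sharing a frame are all found.
   On random 50 kb genomes the expected maximum score sits far below
   the ~89 raw-score significance threshold, giving the near-zero
   empirical false-positive rate the tests measure.
2. **Merge.** Hit intervals are merged strand-ignorantly; overlapping
   *or bookended* intervals fuse (the samtools-merge convention).
   Verified against a covered-position oracle.
3. **Extend.** Merged loci get 500 bp padding per side to complete the
   gene for translation, clamped to the genome (no wraparound); a
   separate 5 kb pad defines the context locus for the synteny module.
4. **Translate.** All complete ORFs (start ATG/GTG/TTG, to a stop,
   ≥ 30 aa — Lsr2-like proteins are ~110 aa, WhiB ~80–120 aa, and 30
   avoids spurious micro-ORFs) on both strands within the extended
   locus; alternative starts translate as M; within a frame an ORF
   opens at the first start after the previous stop.
5. **Reciprocal filter.** Every candidate ORF protein is aligned back
   against the query library (E-value search space: candidate length ×
   total library residues).  The locus keeps exactly one protein — the
   candidate with the lowest best-hit E-value (ties: higher raw score,
   then lower coordinate) — and passes iff that E-value is ≤ 1e-5.

The pipeline is deterministic: identical inputs give byte-identical
locus tables.  An adapter (`domain_screen.read_hit_table` with a column
map) ingests external tabular hit files for full-scale runs.

## Domain screen post-processing

Conserved-domain hits are filtered to a TF catalog at the screen's
E ≤ 0.001, then collapsed per genome by single-linkage grouping of
intervals overlapping by ≥ 50% of the shorter hit (the standard
domain-deduplication rule; in real screens most raw domain IDs are
cross-database aliases reported at the same coordinates).  Each locus takes the family of its lowest-E-value
member.  The genomes × families count matrix drops families present in
fewer than 10 genomes (the floor is ≥ 10 and configurable, since
"at least 10" and "more than 10" both appear in published descriptions
of this style of screen).  Co-occurrence is Pearson correlation on
count columns; zero-variance columns yield NA, never 0.

## Identity clustering and gene trees

Pairwise protein identity is Needleman–Wunsch global alignment
(BLOSUM62, gaps 11/1) with the denominator equal to the full alignment
length including gap columns — terminal gaps count, the convention of
sequence-demarcation (SDT-style) identity scores.  Greedy clustering
follows the UCLUST scheme: length-descending order, first centroid at
≥ 90% identity wins, otherwise a new cluster; the representative is the
longest member.  This is centroid-anchored, not single linkage: a chain
A–B–C at 92% steps with A–C at 80% yields clusters {A, B} and {C}.

Gene trees are NJ on identity-derived distances: p-distance
`1 − identity` or Poisson-corrected `−ln(identity)` (default; identity
0 capped at distance 5).  This replaces ML inference deliberately — the
quantities consumed downstream (group monophyly and scatter) are
topology-level, where NJ is consistent, and the package stays
self-contained.  The "paraphyly index" of a source group
(phage/bacteria/plasmid) is the number of maximal group-pure edge sides
of the unrooted tree: 1 means monophyletic; phage sequences acquired
from k distant bacterial donor families score ≥ k.

## Genomic context and GC analysis

Extended-locus ORFs are annotated by best hit against a protein library
(global identity ≥ 0.3 and local E ≤ 1e-5, else "hypothetical");
overlapping calls resolve toward annotated, then higher score, then
longer ORF.  The bundled annotation library is a synthetic stand-in —
deterministic random proteins with family-realistic lengths under
common phage-neighborhood labels (integrase, excisionase, ParA/B, Ku,
RNase_T, SSB, ...) — usable for pipeline validation only; real runs
should supply curated FASTA libraries.  Per-cluster domain abundance is
the fraction of loci containing each domain, flagged at ≥ 50%
("more than half", boundary counted, configurable).

GC profiles use 100 bp windows (step 100), N excluded from numerator
and denominator, all-N windows NaN.  The upstream GC-dip test compares
the locus-wide median against the minimum GC over runs of 2–3
consecutive windows fully inside the 1 kb upstream span; a dip is
called at depth ≥ 0.10.  Averaging adjacent windows is essential: a
single 100 bp window has binomial noise of sd ≈ 0.05, so a
min-of-single-windows statistic would flag ~20% of flat loci at the
0.10 threshold, while the 2–3-window statistic keeps the false-positive
rate ≤ 5% and still detects planted 300 bp × 0.15 dips with ≥ 95%
power (both measured over 100 fixed seeds in the acceptance suite).
The dip criterion formalizes what is a visual judgement in published
GC plots; threshold and span are configurable.

## Group statistics

The Wilcoxon rank-sum test is implemented from first principles.  Exact
mode enumerates all C(n_x+n_y, n_x) assignments of pooled mid-ranks
(valid under ties) and reports the two-sided p as twice the smaller
tail, capped at 1; it is used automatically for n_x+n_y ≤ 12 and
verified against full enumeration and (tie-free) against
`scipy.stats.mannwhitneyu(method="exact")`.  Normal mode uses mid-ranks
with tie-corrected variance and a 0.5 continuity correction, matching
R's `wilcox.test` defaults; its type-I error at α = 0.05 is calibrated
to [0.03, 0.07] over 2000 null simulations.  Significance codes follow
the figure-legend ladder (**** < 1e-4 ≤ *** < 1e-3 ≤ ** < 0.01 ≤ * <
0.05 ≤ ns); `*` is included for completeness.  No multiple-testing
correction is applied by default (per-panel stars); a
Benjamini–Hochberg helper exists.

Lifestyle enrichment normalizes carrier counts by lifestyle group size
and excludes unknown-lifestyle genomes from numerator and denominator.
GC and genome-size comparisons are carrier vs non-carrier within
temperate and within virulent phages; cells with fewer than two genomes
on either side are skipped.

## Problem sizes and determinism

The test and acceptance workloads use 20–30 genomes of 50 kb, 200
random additive matrices of 5–12 taxa, 1000 short alignment pairs, 500
interval-merge instances, 2000 null Wilcoxon simulations, and 100 GC
profiles per condition — sizes chosen so each property is measured with
useful resolution while a full run stays within a couple of minutes on
one CPU.  Every stochastic component consumes an explicit seed;
`scripts/acceptance.py` derives all sub-seeds from its `--seed`
argument, and identical seeds give byte-identical outputs throughout.

## Known limitations

- The alignment engine is exact Smith–Waterman/Needleman–Wunsch; it
  does not reproduce BLAST's heuristic seeding or composition-adjusted
  statistics, so E-values agree with BLAST in spirit, not digit by
  digit.
- Bundled query/annotation libraries are synthetic stand-ins, not
  curated WhiB/Lsr2 sequences.
- NJ on identity distances replaces ML gene trees; branch lengths of
  gene trees should not be interpreted as substitution rates.
- The simulator's substitution-only model cannot probe robustness to
  indels or genome rearrangement.
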