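# Methods

This note documents the models and procedures implemented in `ph4h3`, the
parameters that matter, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Promoter definition and extraction

A Ph4h3 promoter is the intergenic region between the translational start
sites of a divergently transcribed *h4.1*/*h3* gene pair. Operationally the
anchor is the annotated CDS start in translation order (not the mRNA
start), so the extracted gap excludes both ATG codons by construction.
Coordinates are GFF3-style 1-based inclusive in all public records and
converted to 0-based half-open only at slicing boundaries, which removes a
whole class of off-by-one errors.

Canonical orientation: the stored promoter string is the h3 coding strand
of the gap. Position 1 therefore abuts the h4 ATG (the Ph4′ end) and the
last position abuts the h3 ATG (Ph3′). When h3 is the left-hand gene the
genomic slice is reverse-complemented; re-extracting a planted promoter is
an exact fixed point of this convention, and reverse-complementing the
genome while flipping all strand annotations leaves the result unchanged.

Homologs are found by Smith–Waterman local alignment (via Biopython's
`PairwiseAligner`) with BLOSUM62, gap open 11 / extend 1 (a gap of length g
costs 11 + g), and `X` made score-neutral. A gene qualifies as the
*h4.1*/*h3* homolog when its score reaches `min_score_fraction` (default
0.5) of the query's self-score. Histones are extremely conserved, so this
deterministic scheme replaces E-value-based search without loss for this
task; score ties and extra copies above threshold are reported to the
caller and the pipeline refuses to pick silently unless `--take-best` is
set.

## Alignment and distances

The initial multiple alignment is progressive in the Clustal-W fashion:

- **Guide distances**: k-tuple word counts (k = 4),
  `1 − shared words / min word count`. These only seed the guide tree; the
  reproducible object downstream is the refined HMM consensus, which
  re-aligns everything, so an O(n²·L) word count is preferred over full
  pairwise DP.
- **Guide tree**: neighbor joining on the k-tuple matrix.
- **Merging**: profile–profile global alignment with affine gaps (Gotoh,
  three matrices), column score = frequency-weighted sum of pairs with
  match +2 / mismatch −1, gap open 10 / extend 0.2 (a gap of length g costs
  10 + 0.2 g; terminal gaps are charged). Ties prefer diagonal, then the
  gap consuming the first profile — determinism over cosmetics. With two
  sequences this is exactly pairwise global DP, which the tests verify
  against an independent aligner.

Pairwise promoter distance is the conventional percent-identity distance:
`1 − identities / mutually ungapped columns`, 1.0 when no column is
comparable. It is computed over the *refined* match-state alignment when
the HMM stage has run, since that alignment is the stable one.

Neighbor joining follows the standard agglomeration with two fixed
conventions: at equal Q-criterion the lowest (row, col) pair is joined, and
negative branch lengths are clamped to zero with the deficit moved to the
sibling branch so the pair's summed length is preserved. NJ is exact on
additive matrices (tested on 4- and 5-taxon trees) and cross-checked
against an independent implementation.

## Profile HMM and iterative consensus refinement

The model is a DNA profile HMM with per-node match/insert/delete states,
full 3×3 transition bundles per node, Laplace pseudocounts (1.0 per
emission cell, 0.1 per legal transition), and a uniform background.
A column of the source alignment is a match column iff its gap fraction is
strictly below 0.5.

Alignment is **glocal**: a path must traverse the entire match chain (via
matches or deletions) but may absorb arbitrary 5′/3′ sequence in N-/C-flank
states. Flank residues are scored as exactly zero (background emission, no
transition cost). This is a deliberate design choice: it makes "appending
junk flanks never lowers the optimal score" an exact invariant, and it
means trimming is driven purely by what the core model gains, not by a
tunable flank penalty. Scores are log₂-odds against the background,
computed in log space throughout; state ties break M > D > I, and at equal
exit score the path keeping more residues inside the core wins.

Refinement loop: estimate the model from the current alignment → emit the
consensus → Viterbi-align every *original* sequence → drop flank residues
and insert-state residues → rebuild an M-column alignment from the match
states → re-derive the match-column mask → repeat. Convergence is declared
when the consensus string, including case, is byte-identical between
iterations (the strictest reading of "until the consensus converged");
`max_iter` (default 50) guards against oscillation and returns the last
model with a warning. The match length can only change through the mask
rule, which is how poorly conserved end columns are progressively shed —
the same behaviour as the published 835 → 790-position trajectory, whose
initial value depends on the seed alignment and is therefore logged but not
asserted.

Consensus emission: per match state take the argmax residue (ties
alphabetical) with probability p; uppercase if p ≥ 0.5, lowercase if
0.25 ≤ p < 0.5, `n` below 0.25 (both comparisons use ≥). Information
content per match state is IC = 2 + Σ p log₂ p bits, clamped to [0, 2], and
exported as a TSV a logo renderer can consume; no images are produced.

Both DP kernels (profile–profile Gotoh and glocal Viterbi) are numba-JIT
compiled; the 85 × ~800 bp study scale runs in seconds on one CPU.

## Motif scanning

PFMs are read in the JASPAR dialect (via Bio.motifs) or as plain 4-column
count tables. The log-odds transform uses background-proportional
pseudocounts:

    w[r,j] = log2( (c[r,j] + 0.8·bg[r]) / (colsum_j + 0.8) / bg[r] )

with uniform background by default. Scanning scores every window on the
canonical strand and, for the reverse strand, the reverse-complemented
weight matrix at the same window, so hits on both strands are reported in
canonical-strand coordinates (1-based inclusive). A hit requires score
strictly above the threshold; the pipeline default of 9 bits reflects the
"score above 9" working threshold of the source analysis, but because that
score function was never published the threshold, base and background are
all configurable, and absolute hit counts are not treated as reproducible
quantities. `N` contributes 0 bits and never disqualifies a window.

## Architecture analysis

Hits are assigned to their nearer promoter end by midpoint (ties to Ph4′);
the distance to the end is measured from the hit's outer edge, and a hit is
"toward" its end when its 5′→3′ direction points at that end ('−' points
left/Ph4′, '+' points right/Ph3′). Same-motif hits are paired into mirror
pairs (opposite strands, opposite halves — midpoints on opposite sides of
L/2) and tandem pairs within an end (opposite strands, same end); when more
than two candidates exist, matching is greedy outermost-first, which
reproduces the canonical 2 + 2 site layout deterministically. Pair
separation is the exclusive inner-edge gap (start_downstream − end_upstream
− 1); overlapping members report separation 0 with an overlap flag, and all
pairwise hit overlaps are tabulated separately. Conserved regions are
maximal unions of sliding windows (default 25 nt) whose mean IC reaches a
cutoff; the pipeline default cutoff is 1.25 bits, chosen to sit above the
background IC of a moderately diverged family while below fully conserved
blocks. Regions are reported both in model coordinates and as negative
offsets from each ATG (−1 = nucleotide abutting the start codon).

## Synthetic data generator

The generator emulates the observed structure of the promoter family at
study scale; its defaults are the study conditions used by the tests and
the acceptance script:

- 85 species, 800 bp ancestral promoter, Yule tree (birth rate 1.0) scaled
  to a maximum root-to-leaf path of 0.15 expected substitutions/site —
  producing pairwise identity distances up to ~0.2–0.25, the diverged-but-
  alignable regime of a congeneric family.
- Jukes–Cantor substitutions (p = ¾(1 − e^(−4d/3))); indels are Poisson
  events (0.005 per site per unit branch length) with geometric lengths
  (mean 3).
- Two conserved blocks per end at offsets 100–200 nt with a 0.1
  substitution-rate multiplier, matching where the real family concentrates
  its conservation.
- A planted mirror quartet of Spt10-style sites: outermost sites 51 and
  58 nt from the Ph4′/Ph3′ ends, pair gaps 63 and 59 nt, opposite
  orientations within each end, mirrored across ends. Site content is
  re-sampled from the motif's PFM at each leaf (the bundled synthetic
  look-alike matrices carry 95% consensus per column, i.e. ≤5% per-site
  divergence at motif positions), and indels are redrawn if they would
  intersect a motif or conserved block, so truth coordinates stay exact
  under tracked shifts.
- Each promoter is embedded between a leftward histone-H4-like and a
  rightward histone-H3-like gene model (synthetic look-alike proteins with
  two per-species substitutions) plus a decoy gene, emitted as genome
  FASTA + GFF3 + proteome with a machine-readable truth table. All
  randomness flows through one seeded generator; outputs are byte-identical
  under a fixed seed.

What it does **not** emulate: real base composition or codon usage, rate
heterogeneity beyond the two-block pattern, gene conversion/duplication,
annotation errors, or genome-scale gene counts. Passing the pipeline on
synthetic data therefore demonstrates correctness of the machinery and
recoverability of planted signal under the stated evolutionary model — not
performance on arbitrary real genomes.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on small fixtures (4–12 species, 300–400 bp;
exhaustive oracles at M ≤ 4, sequences ≤ 6 nt). The acceptance script and
parameter-recovery tests use the full study conditions: 85 species × 800 bp
for the pipeline run, tree height 0.02 for the exact-architecture check
(the low-divergence regime in which spacing recovery is exact), and 85
sequences from a known 200-state generator (match emission 0.9, ~2 indel
events per sequence) for match-length and consensus recovery. These sizes
are the package's reference workload and complete in seconds.

## Known limitations

- The profile HMM has no local alignment mode and no posterior decoding;
  Viterbi only.
- The initial progressive MSA is deliberately simple (no iterative MSA
  refinement, no sequence weighting); the HMM stage is the refined object.
- PWM scores carry no p-value calibration; thresholds are in bits and the
  mapping to any external scoring scheme is approximate.
- `hmmalign --trim`-style behaviour is reproduced by the free-flank
  convention above; corner-case agreement with other profile-HMM software
  is not guaranteed, and this package's contract is the one documented
  here.
- Distance values depend on the final alignment; with very short or highly
  diverged inputs the percent-identity distance saturates and the NJ tree
  should be read as descriptive, not phylogenetic inference.
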