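# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Family identification by consensus pattern

The VQ core is matched with the explicit residue-class pattern
`F x x x V Q x [LFIV] T [GA]` (strict) — the five conserved positions of
the motif plus the observed variation at positions 8 and 10 — or with H
accepted at the Q position (relaxed), covering the VQ→VH variant reported
in several grasses. A consensus pattern was chosen over a profile HMM
because every conserved position of the core is known and a deterministic
pattern needs no external profile database; the cost is that weakly
diverged cores outside the residue classes are missed, which is the
documented trade-off of the strict/relaxed pair. `X` never matches a
conserved position. Matches are reported non-overlapping, left to right,
for determinism. The residue class `{L,F,I,V}` at position 8 covers the
types observed in wheat (L/F/I) plus V seen elsewhere; both classes are
editable on the `MotifPattern` config object.

Protein MW is the sum of average (not monoisotopic) residue masses plus one
water (18.0153 Da), mirroring the convention of the standard web
calculators, reported to 2 decimals. pI uses the Bjellqvist pKa set
(shipped as editable JSON: C-terminus 3.55, residue-specific N-terminal
pKas, side chains D 4.05 / E 4.45 / C 9.0 / Y 10.0 / H 5.98 / K 10.0 /
R 12.0) and bisection of the Henderson–Hasselbalch net charge on [0, 14]
to 10⁻³ pH units. Uncharged/unknown residues contribute no charge.

## Neighbor-joining phylogeny

Distances are protein p-distances over gap-free columns, Poisson-corrected
(−ln(1−p)) by default with plain p selectable; the correction is clamped
just inside its domain (1−p floored at 10⁻⁶) so saturated rows yield a
large finite distance rather than an error. NJ follows Saitou–Nei: join
the pair minimizing Q = (n−2)d(i,j) − r(i) − r(j), branch lengths from the
standard closed forms with negative estimates clamped to 0, ties broken by
the lowest (row, column) index pair so runs are platform-reproducible. The
final edge is attached wholly to the non-internal side, which preserves
path-length additivity; on exactly additive matrices the generating
topology is recovered (verified by exhaustive topology enumeration up to
six taxa).

Bootstrap resamples alignment columns with replacement, rebuilds the tree
per replicate, and counts recovery of each internal bipartition of the
full-alignment tree. Supports are stored as raw replicate counts
(0…replicates); percentage rescaling is an output option. Rows are
canonically ordered (by label) before distance computation so supports are
invariant to input row order despite index-based tie-breaking.

Subfamily labels (e.g. VQI–VQVII) propagate from anchor leaves: each
unlabeled leaf takes the label of the smallest clade containing it and at
least one anchor, provided all anchors in that clade agree; disagreement
gives `UNASSIGNED`. Clades are taken with respect to the NJ rooting.

A small progressive aligner (pairwise Gotoh profile alignment on BLOSUM62,
gap open 10 / extend 0.5, average-linkage guide tree) is bundled only so
the pipeline runs end to end without external MSA software; for production
alignments supply an aligned FASTA.

## Nei–Gojobori Ka/Ks and clock dating

Synonymous sites per codon are counted fractionally: at each of the three
positions, the share of the three possible nucleotide changes that
preserve the amino acid (changes creating a stop count as nonsynonymous),
summed and averaged between the two sequences. Codon pairs with a gap,
ambiguity character or stop on either side are excluded pairwise. For
codons differing at more than one position, differences are averaged with
equal weights over all minimal substitution pathways, excluding pathways
through stop codons (all pathways are kept if every one crosses a stop, so
counts stay defined). Proportions pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction K = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is outside the
correction's domain and yields a missing value (`None`), which propagates
to the ratio and the selection class. Ka/Ks with Ks = 0 is likewise
missing, never infinite. The implementation agrees with an independent
NG86 implementation (Biopython's `calculate_dn_ds`) to ~10⁻¹⁵ on evolved
pairs, which the test suite checks.

Sliding windows apply the same estimator to windows of 30 codons every 3
codons by default; the window count is ⌊(L−w)/s⌋+1. These defaults are a
design choice for family-scale CDS lengths and are CLI-configurable.

Divergence dates use the synonymous clock T = Ks/(2λ)·10⁻⁶ MYA. The
default λ = 6.5×10⁻⁹ synonymous substitutions per site per year is the
grass nuclear-gene rate consistent with the bundled pair table's printed
Ks↔date pairs (e.g. Ks 0.0163 ↔ 1.2538 MYA), and is exposed as
`ClockConfig`.

## Homolog pairs

Pairs are detected by exact Smith–Waterman with affine gaps (match +2,
mismatch −3, gap of length k costs 5 + 2k by default) — affordable at
family scale and free of heuristic seeding artifacts. Traceback prefers
diagonal, then a gap in the second sequence, then the first, so alignments
are deterministic. Identity is percent matched columns over aligned
columns; coverage is the aligned span on the shorter sequence over its
length. Both thresholds default to 75% and are configurable; the defaults
are the common family-survey criteria, and a curated pair table can be
supplied directly so downstream Ka/Ks does not depend on this choice.
Species come from `species|gene` id tags.

## Clusters and promoter elements

A gene cluster is a maximal greedy run of consecutive genes (per
chromosome, sorted by start) whose span — first member's start to last
member's end — stays below 200 kb, with at least 2 members. Greedy maximal
extension was chosen over all-subsets enumeration for determinism and
because published cluster counts use the same informal rule.

The cis-element dictionary ships as editable TSV (element, IUPAC
consensus, category ∈ {phytohormone, abiotic}) with PlantCARE-style names;
the exact proprietary matrices of the online services are not reproduced,
so genome-scale element percentages are not comparable to service output.
Scanning reports every (possibly overlapping) exact occurrence on both
strands; minus-strand hits carry the plus-strand coordinate of their
leftmost base. Summaries report per-element and per-category percentages
of total hits.

## Germination, ΔΔCt and candidate calling

GI = (3n₁ + 2n₂ + 1n₃)/(3N) over a 3-day assay (weights favor early
germination; GI ∈ [0,1]) and GR = (n₁+n₂+n₃)/N·100. Relative expression is
2^−ΔΔCt against a reference gene and calibrator sample; replicate fold
changes reduce to mean ± standard error.

Heatmap preparation is log₂(x+1), per-gene z-score (constant rows map to
zero), and average-linkage Euclidean clustering of rows and columns with
label-sorted input for deterministic leaf order. These transforms are a
design choice, exposed as the function's contract.

The candidate classifier operationalizes "consistently higher in one
dormancy class" as a strict min-over-max rule on replicate means: called
for the low-dormancy class iff at every shared timepoint the lowest
low-class variety mean strictly exceeds the highest high-class mean
(symmetric for the other direction), else `none`. A relaxed
`mean_difference` rule is available. With three varieties per class the
strict rule has a small per-gene false-positive probability
(≈2·(1/20)³ per flat gene under exchangeable noise, ~1% per 44-gene null
set), so exact recovery of planted direction counts holds for almost all,
but not every, seed.

## Synthetic data

Generators are deterministic given (parameters, seed) and record planted
truth sufficient to score their downstream stage:

- **Proteomes** — i.i.d. residue decoys rejection-sampled to be motif-free
  (under the relaxed pattern, so recovery is exact in both modes); motif
  proteins carry exactly one planted core of a requested domain type at a
  recorded position. Default lengths 127–723 aa, the span observed in the
  wheat family.
- **Codon pairs** — a random stop-free ancestor; Poisson(pS·S) synonymous
  and Poisson(pN·N) nonsynonymous one-step substitutions at distinct
  codons, with pS/pN the JC-inverted target Ks/Ka. Restricting to one-step
  changes per codon keeps the NG86 counting assumptions exact at low
  divergence; the generator is not a realistic model of high divergence.
- **Promoters** — uniform-nucleotide backgrounds iteratively re-randomized
  until dictionary-clean, then elements planted at non-overlapping recorded
  positions on random strands and re-verified by scanning.
- **Germination** — multinomial day counts (default 50 seeds, 3 replicates)
  with class day-probabilities chosen to match the contrast between
  low-dormancy (GI ≈ 0.9, GR ≈ 98%) and high-dormancy (GI ≈ 0.07,
  GR ≈ 10%) phenotypes.
- **Expression** — log-normal gene baselines over a six-variety
  (three per class), three-timepoint, three-replicate design; direction
  genes multiplied by a fold effect (default 4) in their class at every
  timepoint, with multiplicative log-normal noise (default σ = 0.1).

None of the generators simulates real genome composition, codon-usage
bias, or the homoeologous subgenome structure of hexaploid wheat — passing
recovery tests demonstrates correctness of the estimators under their own
assumptions, not performance on real data.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 500-codon
pairs × 50 replicates for parameter recovery, 200 random pairs ≤50 nt for
the alignment oracle, exhaustive topology enumeration to six taxa (123
trees), a 65-gene × 54-sample expression matrix, and a 20-replicate
bootstrap in the demo pipeline. Defaults for real use (e.g. 1000 bootstrap
replicates) are higher and configurable.
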