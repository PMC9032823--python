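# Methods

## Scope and model

panbbh reimplements the standard desk pipeline for genus-level bacterial
comparative genomics: ortholog assignment by bidirectional best hits
(BBH), partition of gene families into core / accessory / singleton
classes, pan- and core-genome development curves over genome subsets with
Heaps'-law and exponential-decay fits, and pairwise AAI/ANI identity
matrices with genus/species rank calls. The pipeline operates on
per-genome nucleotide FASTA (contigs) plus protein FASTA (predicted CDS
translations); a GFF3 file may supply the gene→contig map.

## Genome summaries

Scaffolds strictly shorter than 1500 nt are discarded before any other
stage (the bound is inclusive: a 1500-nt scaffold is kept). GC content is
100·(G+C)/(A+C+G+T): ambiguous N bases are excluded from both numerator
and denominator — the convention of assembly-QC tools, which avoids
deflating GC — while total base counts include N. Set-wide GC is reported
as the arithmetic mean ± sample standard deviation (n−1 denominator; with
n−1 the nine-genome worked example reproduces the published 64.2 ± 4.5%,
which a population SD does not). Values are kept unrounded internally and
rounded to one decimal only at reporting time.

## Protein alignment and bit scores

Ortholog detection uses exact Smith–Waterman local alignment (BLOSUM62,
affine gaps: open 11, extend 1 — a gap of length g costs 11 + g) rather
than a seeded heuristic. Exactness costs speed but removes heuristic
nondeterminism and lets the implementation be verified against a naive
O(nm) Gotoh oracle, which the test suite does on hundreds of random
pairs. Raw scores are converted to bits with the standard gapped
Karlin–Altschul constants for this scoring system (λ = 0.267, K = 0.041):
S′ = (λ·S − ln K)/ln 2. Percent identity is counted over aligned columns
(gap columns included, BLAST-style); query coverage is the aligned span
over the query length. E-values and composition-based statistics are out
of scope.

A best hit is retained when its bit score is ≥ 60 (inclusive), the
default threshold of the BBH ortholog criterion; the cutoff is exposed as
a parameter everywhere. Ties on bit score are broken toward the
lexicographically smallest partner id and logged, so results are
deterministic.

## Ortholog table construction

`build_table` is reference-anchored: families are seeded by the reference
genome's genes, and each other genome contributes its BBH partner of the
reference gene (BBH is a partial matching per genome pair, so anchoring
cannot conflict). Genes without a reference partner are clustered by
single-linkage over the remaining pairwise BBH graph; unmatched genes
become singleton families. When single linkage pulls two genes of one
genome into a component, the gene with the larger summed BBH bit score
stays and the other is split off (logged) — families hold at most one
gene per genome, keeping the presence/absence matrix binary as pan/core
counting requires. The partition property (every gene in exactly one
family) is asserted after every build, and family composition is
invariant to the genome input order. Paralog-aware orthology
(tree reconciliation, synteny) is a non-goal.

## Development curves and fits

For every subset size N in 1..G, pan size (families present in ≥ 1 subset
genome) and core size (families present in all subset genomes) are
recorded per subset. All C(G, N) subsets are enumerated when that count
is ≤ `max_samples_per_N` (default 500 — with ≤ 10 genomes every size is
exhaustive, which guarantees agreement with the enumeration oracle);
otherwise that many distinct subsets are drawn uniformly with a seeded
generator. The median of an even number of samples is the mean of the two
central values; quartiles are the 25th/75th percentiles.

Both laws are fitted to the per-N medians by nonlinear least squares on
the original scale (not log space — fitting the power law in log space
changes the estimator; log–log OLS supplies only the starting point for
Heaps). The decay fit n = k·e^(−N/τ) + tgθ is initialized at
tgθ₀ = min median, k₀ = max − min, τ₀ = G/3 and bounded to k ≥ 0, τ > 0,
tgθ ≥ 0; tolerances are tightened so noiseless inputs are recovered to
≈ 1e−6 relative, which the test grid checks for γ ∈ {0.1, 0.5, 0.9} and
for a known decay triple. On degenerate flat input the power law
collapses to γ = 0 and the decay to k = 0 with an unidentifiable τ (the
fitted curve still reproduces the data). α = 1 − γ classifies openness;
the boundary α = 1 is assigned to "closed" since only α < 1 is defined as
open. A genome set too small for a law (Heaps needs ≥ 3 subset sizes, the
decay ≥ 4) is recorded as a skipped fit by the pipeline rather than a
run-aborting error.

## AAI and ANI

AAI is the unweighted mean percent identity over BBH ortholog pairs (a
length-weighted variant is available by flag; weighting is a convention
choice, not a finding). Because exact SW scoring is symmetric, the two
directions give identical pair sets, so no separate reverse pass is
computed. ANI follows the classic fragment recipe: query contigs are cut
into consecutive 1020-nt windows (a trailing remainder ≥ 200 nt is kept
as a shorter fragment so small genomes still yield a value); each
fragment is placed at its best subject location by edit-distance infix
search (edlib) and re-aligned locally on the located window with match
+1, mismatch −1, gap open −5, extend −2; fragments with ≥ 30% identity
over ≥ 70% of their length are retained, and the one-way ANI is their
mean identity. The reported ANI is the mean of the two directions.
Fragments of unrelated sequence produce short local alignments that fail
the coverage filter, so unrelated genome pairs correctly yield NA rather
than a spurious low identity. The infix pre-location step exists because
a full local alignment of every fragment against a whole genome is
quadratic in genome size; the scoring of the final alignment is the local
DP above, applied to the located window.

Rank calls use the conventional windows: ANI above 95% (the conservative
lower end of the >95–96% species criterion, configurable) ⇒ same
species; otherwise AAI within 65–95%, and 16S identity within 95–98.6%
when a 16S value is supplied, ⇒ same genus; otherwise different genus.
Species takes precedence, so increasing ANI can never demote a call. 16S
identities are user-supplied; rRNA prediction is out of scope. Identity
matrices are ordered by average-linkage hierarchical clustering on
distance 100 − identity; genomes with NA cells are removed greedily
(fewest removals) before clustering, and an all-tied matrix preserves the
input order.

## Synthetic genome sets

The generator emulates a genus-level collection under a star phylogeny.
Every family gets a root protein (residues uniform over the 20 standard
amino acids) and a root CDS (back-translated with uniform synonymous
codon choice). Each genome carrying the family receives a copy with
i.i.d. per-site substitutions that never restore the original symbol.
Divergence parameters are calibrated **pairwise**: a configured
divergence d means two genomes' copies differ at ≈ d of their sites, so
recovered AAI/ANI ≈ 100·(1 − d); internally each copy substitutes at the
compensating per-copy rate 1 − √(1 − d) relative to the root. Genomes are
emitted as contigs of concatenated CDS separated by random spacers
(120 nt by default; one contig per genome unless split). Accessory
occupancy sets are drawn uniformly without replacement. The design is
recorded in a truth table so downstream recovery is checkable exactly.

Defaults: protein length 300 aa (a typical bacterial CDS), divergence
0.02 (comfortably within BBH's unambiguous regime — the recovery
guarantee is exercised at ≤ 0.05), spacer 120 nt. The generator has no
indels, rearrangements, gene-length variation, horizontal transfer, or
phylogenetically correlated divergence; passing tests therefore
demonstrate correctness of the pipeline's bookkeeping and estimators
under the designed truth, not robustness to assembly artifacts or
realistic evolutionary structure.

The shipped `"guyparkeria-like"` preset encodes a published genus-scale
partition design — eight genomes, 1458 core, 909 accessory, and 837
singleton families (pan 3204) — at protein length 30 so genus-scale
tables stay cheap to build. Since 909 accessory families do not divide
evenly over occupancies 2..7, the preset uses (152, 152, 152, 151, 151,
151), and the 837 singletons are spread as 105×5 + 104×3; the per-genome
singleton count accordingly accepts a per-genome sequence as well as a
single integer.

## Pipeline and reproducibility

`run_all` chains filter → summaries → orthologs → partition →
development → fits → identity and writes fixed-name artifacts plus a
manifest (version, seed, config hash, per-stage counts). Every random
choice flows from the single configured seed, so a rerun reproduces all
numeric outputs byte-identically. Ortholog construction offers two
modes: `bbh` (the default, alignment-based) and `truth` (families taken
from the simulator's recorded design; valid only for simulated input).
Truth mode exists because all-vs-all exact SW over eight ~2300-protein
genomes is far beyond a desk budget; it exercises the genus-scale
partition, curve, and fit machinery end to end, while BBH mode is
validated end to end on smaller sets where exact alignment is affordable.
In truth mode the identity stage computes AAI over the table's member
pairs instead of re-running BBH — the same quantity, since at low
divergence the table's pairs are the BBH pairs.

CLI precedence is: values in a config file override command-line flags,
which override built-in defaults (documented contract; keep run
parameters in the config file when both are used).

## Problem sizes used in the shipped checks

Test and acceptance workloads are sized for a single CPU: ortholog
recovery on 4 genomes × ~25 proteins of 100 aa; identity recovery on
2–3 genomes × 25–30 proteins of 300 aa (~30 kb of nucleotide per
genome); development/fit machinery at the full 3204-family, 8-genome
preset (cheap, since curves operate on the presence matrix); growth-law
refits on noiseless 8–10 point grids. The law fitters are
scale-independent, and the estimators' convergence is checked by the
divergence-recovery grid rather than by genome size.

## Known limitations

- BBH with a fixed bit-score floor is one of several ortholog criteria;
  score-ratio cutoffs or graph-community clustering can split/lump
  differently on real data near the threshold.
- AAI/ANI of distantly related pairs is sensitive to the fragment filter
  floors; values below ~75% ANI are essentially reported as NA by
  construction.
- The exact aligner is O(nm) per pair; all-vs-all BBH is practical for
  small sets or short proteins, and a faster engine would be needed for
  dozens of real genomes.
- The synthetic generator's star phylogeny makes all pairs exchangeable;
  clade structure in real identity matrices is only reproduced if
  divergence is programmed per pair (not currently supported).
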