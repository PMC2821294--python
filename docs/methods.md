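# Methods

## The analysis in one paragraph

The pipeline assembles three independent lines of comparative evidence
that the *yjeA* and *yjeK* gene products modify EF-P Lys34: (i) the two
genes physically cluster with *efp* across phylogenetically distant
genomes; (ii) their phyletic profile co-occurs — genomes either carry
both or neither; (iii) the Lys34 column of EF-P is nearly invariant
exactly in the genomes that carry the pair, and degenerate (Arg, Met,
Asn, Gln) where the pair is absent.  A fourth stage separates the
*yjeK* subfamily from the canonical lysine-catabolism aminomutase (LAM,
*ablA*) — which it resembles too closely for sequence similarity alone —
by combining a JTT/neighbor-joining tree with gene-neighborhood labels
(*yjeK* clusters with *efp*, *ablA* with *ablB*).

## Family assignment

Each protein is aligned locally (Smith–Waterman, affine gaps) against
every reference sequence of the five tracked families.  Defaults:
BLOSUM62, gap open 11, gap extend 1 (the standard protein-search
parameterization); identity ≥ 0.30 over aligned columns and query
coverage ≥ 0.70.  The identity floor reflects the ~31–33% identities
observed between genuine homologs in this system (YjeA vs LysRS2, YjeK
vs LAM); the coverage floor is the pipeline's proxy for the truncation
criterion (YjeA lacks the anticodon-binding domain, YjeK the C-terminal
multimerization domain), since a full-length match to a truncated
reference implies the query is not carrying the extra domain at the
aligned region's scale.  `X` scores 0 against everything.  Ties are
broken by score, then family name ascending, and flagged — a
reproducibility choice, not a biological one.  A score screen
(`min_score`, default 40) skips the traceback alignment for hopeless
candidates; it is far below any alignment that could pass the
identity/coverage thresholds on family-sized proteins and can be set to
0.

The shipped reference families are **synthetic**: seeded draws from the
JTT stationary distribution with the EF-P PGKG motif planted at
positions 32–35 and the yjeK/ablA pair derived from a common ancestor at
a divergence leaving them ~30% identical.  They reproduce the
*structure* of the real discrimination problem (cross-matching LAM
superfamily, truncation-scale length differences) without shipping
third-party sequence data; real curated references can be supplied as
per-family FASTA files.

## Clustering classification

Two genes are "physically clustered" when at most `max_intervening = 5`
genes lie between them on the same replicon (wrapping across the origin
on circular replicons).  An operon additionally requires strict
consecutiveness, one strand, and intergenic gaps ≤ `operon_max_gap =
100` bp — deliberately a geometry test, not a transcription-unit model.
The clustering threshold is configurable and echoed in every output
because the original SEED-based criterion is not published.  Categories
are mutually exclusive with precedence operon > pairwise > none, so the
three percentages over genomes carrying both *yjeA* and *yjeK* sum to
100.  With paralogs, the best-clustering combination of copies counts;
genomes where two distinct pairs cluster separately are flagged
`multi-pair` and reported by their best single pair.

## Conservation at the anchor

Instead of a full multiple alignment, each EF-P sequence is anchored
directly on the PGKG motif (the motif itself defines the focal column;
its third position is Lys34).  When the exact motif is absent, the
focal position is freed and the three flanking positions are scored
with BLOSUM62 against the motif; a window passes at flank score ≥ 12
(three conserved flanks at near-identity score 19).  The leftmost best
window wins.  This fallback is what lets Arg/Met/Asn/Gln replacement
alleles be counted rather than dropped.  Known limitation: a spurious
`PGxG` occurring upstream of the true motif misanchors that sequence;
at the study scale this contributes ≲0.5% noise to the residue
distributions (visible as rare unexpected residues), well inside
binomial sampling error.

Residue percentages are per sequence by default (each paralog is one
observation); a per-genome mode (genome counts as Lys if any copy has
it) exists because real exceptions are concentrated in paralog-carrying
genomes.  Logo columns use R = log₂20 − (H + eₙ), eₙ = 19/(2·ln2·n),
clamped at 0 — the WebLogo convention, so a pure column at n = 200
carries 4.2534 bits.

## Phylogenetics

The JTT replacement process is encoded as a reversible CTMC: rate matrix
Q built from the published 190 exchangeabilities and 20 stationary
frequencies, normalized to one expected substitution per site per unit
branch length; P(t) = exp(Qt) via a symmetric eigendecomposition
computed once.  Pairwise distances maximize
Σ_sites log(π(a)·P_t(a→b)) over pairwise-complete columns (gap and X
columns deleted per pair, matching Protdist's spirit; the direction of
comparison is irrelevant by reversibility) with bounded scalar
optimization on [1e−6, 10] to xatol 1e−6; an optimum pinned at the upper
bound is logged as saturated.  The all-pairs and bootstrap paths first
bracket the optimum on a shared 160-point geometric grid, then refine —
identical objective, much cheaper than independent cold starts.

Neighbor-joining follows Saitou–Nei with the Studier–Keppler Q
criterion; ties take the lowest index pair (determinism over fidelity to
Phylip's internal ordering); negative branch lengths are clamped to 0
with the original value logged.  Bootstrap resamples columns with
replacement to the original width, n_reps = 1000 by default, fully
seeded.  Supports are counts of replicates containing each internal
bipartition of the point-estimate tree (counts, not percentages).  The
conserved-region restriction (e.g. a 118-column active-site block) is an
input column slice, not inferred.

Subfamily splitting walks the tree from a midpoint rooting (clades of an
unrooted tree are rooting-dependent; the midpoint puts the deepest split
at the root, which is exactly the split of interest).  Maximal subtrees
whose non-empty context labels agree become subfamilies; a mixed subtree
containing exactly one odd taxon out absorbs it as a "conflicting
placement" rather than fragmenting the clade; same-context partitions
separated only by the root trifurcation are merged.  Taxa with no
context ride along with their clade, or form a single unassigned pool.

## Synthetic data: what it does and does not emulate

The generator's defaults are the study conditions: 725 genomes; P(both
*yjeA* and *yjeK*) = 200/725, plus 2/725 *yjeA*-only genomes (the two
known symbiont exceptions) and no *yjeK*-only genomes; arrangement mix
(0.31, 0.60, 0.09) among with-pair genomes; anchor residue K with
probability 0.97 (else Ala/His, the observed paralog-case replacements)
in the with-pair stratum and the 70/24.1/3.4/2.2/0.3 K/R/M/N/Q mix
without; 20–60 decoy genes per genome (shuffled reference residues, so
they carry family-like composition but no homology); planted family
members evolved 0.3 substitutions/site from the references with the
EF-P anchor window held intact apart from the planted residue; an
ablA/ablB cluster planted in 25% of genomes so the context-disambiguation
path is exercised (the real frequency of the lysine-catabolism cluster
is not published; 0.25 keeps both branches of the logic active at desk
scale).  Category geometry is constructed to satisfy the classifier's
definitions exactly — operon triples consecutive/co-oriented with 20–80
bp gaps, pairwise members with ≤ 2 intervening decoys, "none" families
separated by ≥ 6 decoys — and every genome draws its RNG stream from
(seed, genome index), so subsets reproduce byte-identically.

What it does not emulate: real gene-content heterogeneity, intergenic
sequence, codon structure, horizontal transfer, annotation error, or
taxonomic correlation between genomes (each genome is independent).
Passing tests therefore demonstrate that the pipeline recovers planted
signal through the full file-format round trip under realistic noise
levels — not that it is robust to SEED-era annotation artifacts.

Alignments evolve along an explicit tree (root from stationary
frequencies, per-branch JTT transitions); the two-clade helper (12 + 12
taxa, terminal branches 0.15, deep split 1.0, 118 columns) mirrors the
scale of the real LAM/YjeK analysis (24 homologs, 118 active-site
columns).

## Verification strategy and problem sizes

Every numerical kernel is checked against an oracle built by a different
route: local alignment against a memoized top-down affine recursion
(itself validated by exhaustive enumeration of all alignments at tiny
sizes); ML distances against a 1e−4 likelihood grid (agreement within
2e−4, 100 pairs); NJ against 100 random additive matrices built and
measured without any phylogenetics library (patristic error < 1e−9);
P(t) against Chapman–Kolmogorov (< 1e−8); NJ topology against
scikit-bio's independent implementation; JTT distances were additionally
validated against phangorn's `dist.ml` during development (4-decimal
agreement).  Statistical recovery uses binomial 99% CI half-widths at
the realized sample sizes as tolerances, fixed in advance of the planted
probabilities.  Desk-scale sizes: the tally stages run at the full 725
(they cost seconds through the table route); the closed-loop
alignment-based run uses 120 genomes and the recovery run 1000 genomes
with truth-based labels, keeping the whole suite inside a few minutes on
one CPU while leaving every code path exercised at full scale at least
once.
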