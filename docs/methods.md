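# Methods

This note records the models, conventions and parameter choices behind
`hsfkit`, and what the synthetic-data tests do and do not demonstrate.

## Protein statistics

Molecular weight is the sum of average (isotope-abundance-weighted)
residue masses plus one water (18.0153 Da), reported in kDa to one
decimal — the convention of curated family tables. The isoelectric point
is the unique root of the Henderson–Hasselbalch net charge over the
ionizable groups (N/C termini, D, E, C, Y, H, K, R), found by bisection to
1e-4 pH units. The pKa set is the EMBOSS convention (N-term 8.6, C-term
3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). Published pI
values rarely state their pKa set, so agreement with a table is checked to
±0.2 units, not exactly; the net-charge function is strictly decreasing in
pH (both termini are always present), so the bisection root is unique.

The packaged file `data/tahsfa2b_synthetic_standin.faa` is a **synthetic**
413-residue sequence whose amino-acid composition was solved, against an
independent brute-force charge-grid oracle, to match the published
TaHsfA2b summary statistics (413 aa, 45.6 kDa, pI 4.99). It exists so the
statistics pipeline can be checked against published numbers without
redistributing the real sequence; it is not that sequence.

## EST assembly

Reads are linked when their best local alignment covers ≥ `min_overlap`
(default 100 nt) at identity strictly greater than `identity_threshold`
(default 0.995). The identity denominator is the number of aligned overlap
columns, counting internal gap columns as mismatches — a conservative,
reproducible choice. The strict inequality is deliberate: a homeolog pair
at exactly 99.5% must not merge. Clusters are single linkage; the
consensus is a column-wise majority vote on the longest member (ties
become IUPAC ambiguity codes), and reads are compared in both
orientations, with the strand recorded.

For speed, pairs are gated by shared 16-mers and then scored by an
anchored ungapped identity (exact whenever the reads differ only by
substitutions); full Smith–Waterman runs only for pairs within
`full_alignment_band` (default 0.004) below the threshold, where an indel
could change the verdict. The gate and fast path never alter decisions on
substitution-only data; widen the band for indel-rich input.

Singletons with no scaffold match above `min_genome_identity` (0.95 over
≥ 100 nt) are discarded as presumed low-quality reads; multi-read contigs
are kept but flagged. Validated contigs are extended with up to
`extension_limit` (500 nt) of flanking scaffold sequence per side,
truncated and noted at scaffold ends.

## Domain annotation

DBD search is Smith–Waterman (BLOSUM62, gap open 11 / extend 1) against
labelled reference domains; a hit requires score ≥ 75 and identity ≥ 0.30.
These thresholds were calibrated on residue-shuffle nulls: across 1000
shuffles of a family-length protein the false-positive rate is ≤ 1%
(enforced by a test). Completeness calls use the coverage of the
*reference* (not the query, whose anchors may be mutated): FullDBD at
≥ 90% reference coverage or both anchors covered; N_half / C_half when
only the LNTY / GFRK side is covered. The two anchors flank the position
of a very large intron in wheat Hsf genes, which is why half-domain cDNA
fragments are common.

The HR-A/B scanner tests all seven heptad phases downstream of the DBD
and reports the window maximizing hydrophobic occupancy at the a/d
positions, requiring ≥ 60% over ≥ 3 heptads; the hydrophobic set is
{L, I, V, M, F} — F is included as a coiled-coil scanner convention,
beyond the AHA hydrophobic set. A second qualifying window after a linker
(≤ 60 residues) makes the hit bipartite, with the linker length recorded.

The AHA score is a pure composition measure: (aromatic + hydrophobic +
acidic) / window length over a sliding window (default 25, shrunk to short
peptides), qualifying only with ≥ 1 aromatic and ≥ 1 acidic residue. It
supports the directional claim that mutating aromatic/acidic residues
lowers the score; it does not model transactivation activity.

## Phylogenetic classification

Distances are Poisson-corrected proportions with pairwise deletion:
p = differing / comparable sites (sites where neither row is gapped),
d = −ln(1−p). Pairs with no comparable sites or p ≥ 1 are flagged and
refuse tree building with an explicit pair list. Neighbor–Joining follows
Saitou–Nei; Q-criterion ties break at the lowest (row, col) index pair and
negative branch lengths are clamped to zero with the event logged — both
conventions are needed because the method itself leaves them open.
Bootstrap supports are the percentage of column-resampled replicates
containing each internal bipartition of the full-data tree; replicates
whose resampled distances are undefined are skipped (counting against
support, the conservative direction).

The joint alignment for classification is a center-star progressive
alignment (center chosen by k-mer distance, BLOSUM62 global pairwise
alignments merged by gap projection). This is adequate for the closely
related within-family regions being classified; tests that need exact
distances supply fixed alignments instead. Queries carrying the full
DBD→HR-A/B region are placed on a joint tree with the references and take
the majority label of the smallest clade containing them and ≥ 1
reference; vote ties resolve to the nearest reference by patristic
distance (confidence then reflects that proximity, 1/(1+d)). Queries
without the region are labelled by highest full-length global identity to
a reference (homology fallback), and flagged as such.

## HSE grammar

Elements are chains of alternating GAA / TTC core triplets. Chain
construction is layered and deterministic: (1) exact cores linked at
spacer exactly 2; (2) one degenerate core may bridge two exact chains at
spacers 2/2; (3) direct links with lengthened spacers (3 to
2 + `max_gap_extension`, default +3); (4) degenerate bridges with
lengthened spacers. Degeneracy (Hamming distance 1 from the core) is
recognized only *interior* to a chain and at most once per element:
terminal single-mismatch triplets are statistically indistinguishable from
background, and admitting them makes the reported element set depend on
scan direction. All tie-breaks (smallest total gap, then smallest maximal
gap, then highest position weight, then the lexicographically smaller of
the triplet and its reverse complement) are strand-invariant; scanning a
sequence and its reverse complement yields mirrored elements with
identical categories and scores (verified over 1000 random sequences).

Categories follow the binding-activity hierarchy: `perfect_triple`
(3 exact cores, spacers 2) scores 1.0; `degenerate_triple` scores the
weight of its mismatched position; `double` (2 exact cores) 0.1 — an
order of magnitude below the perfect element; `gapped` 0.0 — a lengthened
spacer abolishes detectable binding; `extended` (> 3 cores) 1.0. Position
weights are keyed in the GAA frame, which is strand-invariant (a TTC-core
mismatch at read position p is the same physical site as a GAA-frame
mismatch at 4−p): position 1 (TTT for a TTC core, AAA for GAA) is
permissive (0.5) because that element is functional in vivo; positions 2–3
are restrictive (0.1), matching the weakly bound synthetic variants. All
weights are conventions encoding qualitative outcomes — never measured
affinities — and are fully configurable. Flanking context (±1 nt) is
recorded but unscored: flanking sequence is known to modulate binding but
no quantitative rule is available. TCC-like cores, which appear in some
printed element formulas but in none of the concrete elements, are treated
as typographical variants of TTC and can be enabled as extra degenerate
cores in config.

On iid uniform sequence the expected number of perfect-triple windows is
2·(L−12)·4⁻⁹ per sequence of length L (9 fixed bases, two orientations);
the scanner's Monte-Carlo null is checked against this within three
standard errors. For GC-skewed backgrounds the expectation must be
recomputed from the stated composition.

## Expression quantification

The relative level is Er^Ct(ref) / Et^Ct(target) × F, with Er raised to
the reference gene's Ct and Et to the target's — the only reading of the
formula under which more target mRNA yields a higher level. Efficiencies
(valid range (1, 2.2]) come from dilution series as E = 10^(−1/slope) of
the least-squares Ct-vs-log10(amount) fit. Group comparisons use a
two-sided Welch t-test — a documented choice, since published asterisk
annotations rarely name a test — with no multiple-testing correction by
default (matching per-gene presentation) and Benjamini–Hochberg available.
Array re-analysis consumes already-normalized non-log matrices; probe sets
with both group means below 20 are "not detectable", and relative levels
set the control group to 1 by construction.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (parameters, seed) via a local
`numpy` Generator; every output has a truth table.

**Families.** A root protein = DBD template (96 aa, containing LNTY and
GFRK) + HR-A/B heptad template + random tail (120–220 aa). Subfamily
founders diverge at 0.25 substitutions/site, members at 0.04, by uniform
Poisson replacement (matching the Poisson-correction assumption) with
anchor and heptad a/d positions held fixed so domain detection remains
solvable. Coding sequences are reverse-translated with random synonymous
codons.

**Homeologs.** The three subgenome copies differ at evenly spaced
diagnostic sites (spacing = 1/divergence, default 0.010), each copy
carrying a distinct allele. Regular spacing guarantees that no ≥ 100-nt
window is identical between copies, so the >99.5% merge rule behaves
uniformly across read overlaps. Real inter-subgenome polymorphism is
unevenly distributed and sometimes locally identical; assembly separation
of real homeologs is therefore harder than these tests show.

**ESTs.** Reads of 400–700 nt tile the (possibly 5'/3'-truncated) exposed
region with stratified starts at coverage 5, random strand, and
substitution errors at 0.0005/base — the quality of end-trimmed ESTs, the
relevant regime since raw chromatogram ends are assumed removed upstream.
At this error rate, adjacent-read links fail with probability ≈ 1e-3 and
the 20-seed gene-count recovery criterion is met (19/20); higher error
rates make the strict identity rule drop links, which is a property of the
published procedure, not of this implementation.

**Promoters.** iid background (default uniform; GC-skew options provided)
of 1500 nt with planted elements of each category at recorded coordinates
and strands. An 8-nt C/G-only buffer flanks each plant — no {C,G} triplet
is within one mismatch of GAA or TTC — so background bases cannot chain
onto a planted element and change its category. Planted degenerate
elements carry the mismatch in the middle core, as in the published
atypical element.

**Expression.** Ct tables invert the efficiency model with lognormal
noise at the design CV (default 10%, 3 replicates — the usual qPCR
design); arrays are lognormal around group means (15 replicates where the
larger design is emulated). No real codon usage, probe cross-hybridization
or chromatogram error profiles are modelled; conclusions about those
require real data.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: 20 seeds for each recovery
property; 2 genes × 3 homeologs for assembly recovery; 8 subfamilies × 2
members for subclass recovery; 10⁵ (tests) / 2×10⁴ (acceptance script)
random 1-kb sequences for the scanner null; 10⁴ null data sets for the
type-I error; 50 random 5–8-taxon trees for the NJ oracle. These sizes
make each property estimable with comfortable margins while keeping a
full run in minutes on one core. Bisection tolerance 1e-4 pH; NJ additive
recovery asserted to 1e-9; identity comparisons at the exact threshold use
strict inequality everywhere.
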