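# Methods

## Scope and data model

The package analyses a plant transcription-factor gene family along six
axes: member census, within/between-species homology, selection and
duplication dating, phylogeny with subfamily assignment, promoter
cis-element content, and expression quantification. All internal
coordinates are 0-based half-open; on-disk exon tables are 1-based
inclusive and converted only at the I/O boundary. Sequences are
upper-cased on read and U→T for nucleotide sets. Gene models are a
GFF-lite exon table (gene, chrom, strand, exon start/end) rather than full
GFF3 — the analyses only need exon/intron structure and the CDS.

The published inputs for the Moso bamboo trihelix family — the 35-row
per-gene census, the 12 duplicate-pair Ka/Ks estimates, and the
paralog/ortholog pair lists — are packaged as TSVs under `famevol/data/`
and loaded through `famevol.datasets`. One printed value (PeTTF17's
molecular weight, 6250.04 Da for a 229-aa protein) is physically
implausible but is kept verbatim, because the family-level summary it
enters is defined over the printed values.

## Census

Translation uses the standard code; the terminal stop is dropped and an
internal stop is an error carrying the codon index. Molecular weight is
the sum of average (isotope-abundance-weighted) residue masses plus one
water (18.0153 Da) — the convention of the common protein-parameter web
tools. The isoelectric point solves net charge = 0 by bisection on
pH ∈ [0, 14] to |charge| < 1e-4, with charge from the termini and the
D, E, C, Y, H, K, R side chains under a stated, overridable pKa table
(N-term 9.69, C-term 2.34, D 3.65, E 4.25, C 8.3, Y 10.07, H 6.0,
K 10.53, R 12.48). Both quantities are composition-only, which the tests
exploit (permutation invariance; MW additivity up to one water).

Family membership is called with an ungapped log-odds PSSM built from a
seed alignment of the DNA-binding domain (pseudocount 0.5, uniform
background). Full profile-HMM machinery is deliberately out of scope; the
census logic downstream of the membership call is the analysis surface.
The hit threshold is calibrated empirically: the maximum window score over
1000 random sequences of background composition, plus a 5-bit margin.
The margin makes the false-positive rate effectively zero at the cost of
missing weak true domains — the right trade for a membership filter.
Mean ORF and protein lengths in reports are truncated (not rounded) to
integers, matching how the published family summaries were derived; mean
MW is reported to 2 decimals.

## Homology

The published analysis used a heuristic nucleotide search; this package
substitutes exact Smith–Waterman local alignment (match +2, mismatch −3,
gap open −5, extend −2) via Biopython's PairwiseAligner, which is
deterministic and cannot miss a qualifying pair, so on real data it may
legitimately find a superset of a seeded heuristic's pairs. Paralogy:
aligned length strictly greater than 300 bp (columns where both sequences
have a residue) AND identity ≥ 0.40 over those columns (gap columns
excluded from the denominator, the usual convention). Orthology:
reciprocal best hit by alignment score with the same aligned-length rule;
score ties break to the lexicographically smallest id, making the RBH set
a deterministic partial matching. Paralogy is pairwise — one gene may
join several pairs.

## Selection and dating

Codon alignment is protein-guided: global Needleman–Wunsch on the
translations (BLOSUM62, gap open −10, extend −1) back-threaded onto the
source codons, so gaps occur only as whole codons and frame is preserved.

Ka/Ks is the classical Nei–Gojobori counting estimator, matching the
default of the desktop tools used for the published values:

- Sites: each codon position contributes the fraction of its three
  possible changes that are synonymous; changes creating a stop count as
  nonsynonymous, so S + N = 3 × (ungapped codon columns) exactly. Site
  totals are averaged over the two sequences.
- Differences: averaged with equal weight over all minimal mutational
  pathways between each codon pair; pathways through stop codons are
  excluded (if every pathway is blocked — essentially unreachable at
  ordinary divergence — all pathways are used as a fallback).
- Correction: Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is
  flagged saturated and the corresponding rate is undefined.

Duplication age is T = Ks/(2λ) with λ = 6.5 × 10⁻⁹ synonymous
substitutions per site per year (configurable). Ka/Ks > 1 is positive
selection, < 1 purifying, = 1 (within 1e-9) neutral. Reports give the
ratio to 4 decimals and T to 2 decimals, the precision of the published
tables.

Sliding-window Ka/Ks uses 150-bp windows stepped 9 bp over the ungapped
alignment columns; both parameters are codon-divisible so windows are
codon-snapped (50 codons, step 3). Windows with saturated or undefined
ratios are reported as undefined; alignments shorter than one window fall
back to a single whole-alignment window with a warning.

Ks-band grouping is 1-D single-linkage clustering cut at the k−1 largest
gaps (default k = 3, ties leftmost), with bands numbered oldest-first by
mean Ks. A fixed absolute gap threshold was considered and rejected: on
the published 12-pair Ks set the relevant inter-band gap is 0.2225 while
the largest within-band gap is 0.2051, so no round threshold separates
them robustly; cutting the largest gaps reproduces the published three
bands and generalizes. The per-family report also counts pairs with
Ka/Ks > 1 and pairs dated younger than a species-divergence reference
(default 12 My), using unrounded ages.

## Phylogeny

Protein distances are Poisson-corrected, d = −ln(1 − p), with pairwise
deletion of gapped columns; p at or beyond 1 − e⁻²⁰ is capped at 20
substitutions/site with a flag. MSA construction itself is out of scope —
the module accepts an aligned FASTA (or the synthetic generator's
gap-free alignments); alignment heuristics are not part of the analysis
being tested.

Neighbor joining is the Saitou–Nei algorithm with the standard
Q-criterion. Determinism: Q ties resolve to the lexicographically
smallest pair of cluster representatives (a cluster is represented by its
smallest member label); negative branch lengths are clamped to zero; the
final two clusters are joined with the remaining distance split evenly
(path lengths are unaffected by that split). On additive matrices the
algorithm recovers the generating topology and all leaf-to-leaf path
lengths exactly; a test cross-checks topology against dendropy's
independent NJ implementation.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree, and reports for each internal bipartition of the
point-estimate tree the percentage of replicates containing it. Default
1000 replicates for analyses; tests use 20–100 for runtime.

Subfamily assignment reads clades in the unrooted sense: every edge
bipartition defines two candidate clades, and a query takes the subfamily
of the smallest side containing it and at least one anchor, provided
those anchors agree; conflicts leave the query unassigned with a
diagnostic. Working with edge bipartitions (rather than the rooted node
hierarchy) makes the result independent of NJ's arbitrary root placement.
Every required subfamily must have at least one anchor.

## Promoters

Promoters are the 2000 bp immediately upstream of the translation start
on the coding strand (reverse-complemented for minus-strand genes),
truncated with a warning at contig edges. The element dictionary is a
packaged, editable TSV of IUPAC consensus strings curated from the plant
promoter literature, each categorized (phytohormone / stress /
development / light) and subcategorized (MeJA, SA, ABA, GA, IAA, ...).
Scanning is exact IUPAC matching on both strands; a self-reverse-
complementary consensus matching both strands at the same coordinates is
counted once. Because proprietary scoring matrices of the original web
service are not reproduced, absolute counts on real genomes will differ
from published figures; the analysis surface is the counting and
category-share arithmetic, which is exact. Shares are percentages within
each category block, reported to 2 decimals.

## Expression

2⁻ΔΔCt quantification averages technical replicates first, forms
ΔCt = Ct(target) − Ct(reference) within each biological replicate,
ΔΔCt against the calibrator condition within the same biological
replicate, and reports the mean and standard error of 2⁻ΔΔCt across
biological replicates only (amplification efficiency fixed at 2). The
calibrator fold is exactly 1 for every gene by construction. The
quantification is invariant to any constant added to all Ct values, and
rescales as a ratio when the calibrator changes.

Tissue specificity uses tau = Σ(1 − xᵢ/x_max)/(n − 1) on
log₂(x + 1)-transformed values (0 = uniform, 1 = single-tissue); the
published analysis reported specificity only qualitatively, so the
statistic choice is this package's. Heatmap gene ordering is
average-linkage hierarchical clustering on Euclidean distances of
row-z-scored log values with optimal leaf ordering (deterministic);
constant rows z-score to zeros rather than NaN.

## Synthetic data

The generator is first-class, tested code; its defaults define the test
conditions.

- **Codon evolution**: ancestors are random stop-free CDS (ATG first).
  A duplicate copy evolves by iterated single-nucleotide proposals:
  stop-creating changes are rejected; synonymous changes are accepted and
  nonsynonymous ones with relative probability ω (inverted for ω > 1);
  evolution stops when accepted synonymous changes per synonymous site
  reach the target Ks. The realized counts — not the targets — are the
  recorded truth. This accept/reject single-hit process was chosen over a
  full codon-model CTMC because its truth is exact by construction.
  Targets beyond Ks = 5 are refused as saturated. Default 500 codons.
- **Two species**: each ortholog pair descends from its own ancestor,
  with each species' copy evolved Ks/2 independently. Decoy genes are
  unrelated randoms.
- **Promoters**: uniform background with planted consensus instances at
  recorded non-overlapping positions and strands; chance background
  matches of the planted elements are scrubbed by point mutations outside
  the planted intervals until a scan finds exactly the planted set, so
  the truth list is exhaustive.
- **Ct tables**: Ct = base − log₂(true fold) + N(0, sd), default
  sd = 0.15 cycles, constant-Ct reference gene, six timepoints
  (0, 1, 3, 6, 12, 24 h), 3 biological × 3 technical replicates.
- **Tissue matrices**: lognormal baseline with one planted dominant
  tissue per gene (default 8-fold).
- **Protein clades**: a root sequence, per-clade ancestors at a mutated
  fraction `between_p`, members at a further `within_p` — gap-free MSAs
  for NJ/bootstrap/assignment tests.

What the generator does **not** emulate: indels (beyond whole-codon
alignment gaps), among-site rate heterogeneity, codon-usage and
composition bias, correlated replicate noise, and domain-level
conservation heterogeneity within genes. Recovery tests therefore show
the estimators are correct under their own model assumptions, not that
real-genome results would be identical. In particular, simulated
families use purifying ω (0.2–0.5) across the published Ks range
(0.1–1.3): under uniform-rate simulation a pair at Ks ≈ 1.3 with ω > 1
would fall below any aligner's detection limit, whereas real gene pairs
at that depth remain detectable through conserved domains that the
uniform-rate model does not have.

## Problem sizes and numerical choices

Recovery analyses use 300-codon genes for all-pairs alignment (paralog
and RBH recoveries: 12 pairs + 4 singletons, 15 pairs + 2 decoys per
species) and 500 codons for Ka/Ks parameter recovery (20 replicates at
Ks 0.3, ω 0.2) — sizes at which the estimates are stable and the whole
analysis set runs in well under a minute. NJ recovery uses 50 random
additive matrices of 4–12 taxa. Bootstrap examples use 100 replicates.
All randomness flows from explicit integer seeds through one numpy
Generator per entry point; reruns are byte-identical.

## Known limitations

- NG86 with Jukes–Cantor underestimates rates under strong
  transition/transversion bias; maximum-likelihood dN/dS and
  branch/site models are out of scope.
- The PSSM membership scan is ungapped and will miss domains split by
  insertions.
- IUPAC consensus scanning has no score gradation; weak matrix matches
  that a weighted scan would report are invisible.
- The divergence-time clock inherits all caveats of a single fixed λ.
- Heatmap leaf ordering is deterministic but linkage-method dependent;
  a different linkage gives a different (equally valid) ordering.
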