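# Methods

## The analysis model

The pipeline treats a CAZyme annotation run as a chain of pure functions
from per-organism HMMER domain tables to comparative statistics. Its core
assumptions are:

* each protein's CAZyme content is fully described by the domain hits that
  survive quality filtering and overlap resolution — non-CAZyme domains
  (e.g. Pfam families outside the CAZy scheme) are invisible, so an
  "accessory domain" always means another CAZyme family;
* counting is protein-level: an organism's GH count is the number of
  proteins carrying ≥ 1 GH domain, not the number of GH domain instances
  (instance-level tallies are exported alongside, since family-abundance
  heat maps are sometimes drawn at domain level);
* a genome's CAZyme investment is summarised by
  `%CAZyme CDS = 100 · cazyme_cds / total_cds`, where `total_cds` comes
  from the genome annotation (metadata or GFF3), never from the domain
  table itself.

## Hit filtering

The quality and overlap rules follow the conventions of the dbCAN parser
family, with every threshold exposed in `FilterConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 0.35 | minimum covered fraction of the HMM profile |
| `max_ievalue` | 1e−15 | i-Evalue ceiling, alignments ≥ 80 aa |
| `relaxed_ievalue_for_short` | 1e−3 | i-Evalue ceiling, alignments < 80 aa |
| `short_alignment_cutoff` | 80 aa | boundary between the two ceilings |
| `overlap_fraction` | 0.5 | max shared fraction of the shorter alignment |
| `same_family_only` | off | restrict overlap resolution to same-family hits |

Coverage is measured on HMM-profile coordinates (`hmm_from/hmm_to` against
the profile length), because the covered fraction of the *profile* is what
distinguishes a genuine domain from a fragment. Overlap is measured on
alignment (`ali`) coordinates — the region actually displayed in an
architecture — not the wider envelope.

Overlap resolution is greedy: hits are visited by ascending i-Evalue (ties
broken by higher coverage, then family string, then position, then the
remaining numeric fields, making the order total so the outcome is
independent of input order); a hit is kept iff it overlaps every
previously kept hit by at most `overlap_fraction` of the shorter of the
two intervals. Greedy best-e-value-first matches standard annotation
practice; it is not an optimal weighted interval scheduling, and the test
suite pins its exact behaviour against subset enumeration on small
proteins. Note that a chain A–B–C in which B overlaps each flank by less
than half the shorter interval keeps all three hits — only overlaps
*beyond* the fraction create a conflict. Cross-family overlaps are
resolved by default (configurable), since redundant hits from related
profiles usually carry different family names.

## Architectures and patterns

Retained domains are ordered by alignment start (ties: alignment end, then
family string). Patterns partition proteins: `alone` (one domain),
`multi_copy` (≥ 2 copies of one label, nothing else), `with_accessory`
(≥ 2 distinct labels). Tallies run at subfamily granularity by default so
subfamily-specific associations (GH13_11 with CBM48) are countable as
such; `granularity="family"` collapses subfamilies onto parents, which is
the right view when asking whether *any* GH13 co-occurs with CBM48. Both
views are exposed because family-level aggregates and subfamily-specific
counts answer different questions; the default favours the finer one since
coarsening is lossless in that direction.

## Substrate map

The built-in map encodes the family → substrate assignments for the eight
tracked polysaccharides, including the bifunctional cases (GH13 and GH15:
starch + dextran; GH48: cellulose + chitin; the ten GH families shared
between cellulase and xylanase activity). Subfamily labels inherit their
parent's substrates. EC numbers ride along as opaque annotation strings.
The shipped `data/substrate_map.tsv` mirrors the built-in map; a larger
curated table can be loaded (or appended) from any 4-column TSV, which is
the intended extension point — the default map deliberately contains only
assignments that are individually well attested, not an exhaustive CAZy
dump.

## Statistics conventions

Medians are midpoints of central order statistics; quartiles use type-7
linear interpolation; standard deviations use the n−1 denominator — the
defaults of the R tooling this kind of analysis is usually reported with,
so tables produced elsewhere under those defaults reproduce identically.
Welch's t-test uses Welch–Satterthwaite degrees of freedom with two-sided
p-values; degenerate zero-variance inputs return t=0, p=1 (equal means) or
p=0 without division failures. Pairwise tests are uncorrected by default
(Bonferroni/BH available) because raw pairwise p-values are the
convention in the source analyses. PCA is covariance PCA of the
mean-centred organisms × 6 category matrix (matching `prcomp` defaults;
unit-variance scaling behind a flag), computed by SVD, with each
component's sign fixed so its largest-magnitude loading is positive.
R² is the squared Pearson correlation of an OLS fit; constant predictors
are rejected, constant responses give R² = 0 by convention.

The statistics layer accepts any profile-shaped TSV, so externally
produced per-organism tables can be fed straight into group summaries,
Welch tests and PCA without rerunning annotation.

## Synthetic data

`generate_dataset` emulates the study design the statistics assume: 61
organisms over 3 suborders and 9 families (42/6/13 per suborder, i.e. a
~70/10/20% split), genome sizes drawn from family-specific 2–16 Mb ranges
with CDS counts at ~1 CDS/1.15 kb plus 5% lognormal noise (giving the
tight CDS ~ genome-size regression real annotations show), family-specific
%CAZyme targets between 2.16% (marine Nannocystaceae) and 4.44%
(Archangiaceae) with 0.2–0.5 point SDs, and marine habitat for the
Nannocystineae. Architectures are drawn from a weighted template pool
covering all six categories and the characteristic multi-domain patterns
(GH23 ± CBM50 copies, GH13 subfamilies + CBM48, GH6+CBM4, CE8 triplicate,
GH32 with paired CBM66). True hits sample coverage from U(0.70, 1.0) and
log10 i-Evalue from U(−60, −20).

Decoys exercise both filter branches: overlap decoys copy a true hit's
interval shifted by under half its length with an e-value 10³–10⁶× worse;
noise hits draw coverage from U(0.05, 0.30), below the quality threshold.
Planted domains are spaced by more than 60% of the longer flanking domain,
which guarantees a decoy can conflict only with its own source hit; a
short induction argument (source accepted ⇒ decoy rejected) then gives
exact recovery of the planted truth even with decoys enabled, which the
suite asserts as precision = recall = 1.

`generate_count_matrix` draws category counts as
`round(median · exp(s_i + e_ij))` with an organism-level shared factor
`s_i ~ N(0, 0.35)` and per-category noise `e_ij ~ N(0, 0.20)`; the
multiplier's median is 1, so sample medians track the configured category
medians (defaults GH 84, GT 77, CE 63, CBM 62, AA 19, PL 14), and the
shared factor produces the dominant first principal component that real
category tables exhibit. Zero dispersion reproduces the medians exactly.

What the generator does *not* emulate: real HMMER score/bias
distributions beyond the fields the filter inspects, nucleotide or protein
sequences, non-CAZyme domains, fragmented draft assemblies, and
phylogenetic autocorrelation between related organisms. Passing tests
therefore demonstrate the correctness of the bookkeeping and statistics on
data with the assumed structure, not robustness to annotation artefacts in
real proteomes.

## Numerical and interface choices

* Coordinates are 1-based inclusive end to end (the HMMER convention).
* The domtblout writer emits full-precision floats so write∘read is the
  identity — round-trip fidelity is favoured over column prettiness.
* The default column orientation puts the protein in the target columns
  and the HMM in the query columns; files with the HMM as target are read
  with `orientation="target-hmm"`.
* GC% excludes ambiguity codes from numerator and denominator; GFF3 CDS
  counting is by distinct `ID` attribute so multi-line CDS features count
  once.
* All tables are tab-delimited UTF-8 with a header row and '.' decimals;
  the run manifest records SHA-256 checksums of inputs and outputs.
* Problem sizes in the test suite and acceptance script (8–61 synthetic
  organisms, count matrices up to n=1000) are chosen to exercise every
  code path at desk scale while keeping the full suite in the
  tens-of-seconds range.

## Known limitations

* The filter thresholds are conventions, not values fitted to any gold
  standard; users matching a specific published parser should set them
  explicitly.
* Architectures see only CAZyme domains, so a protein whose catalytic
  domain is separated from its CBM by a non-CAZyme domain still reads as a
  contiguous two-domain architecture.
* The substrate map is intentionally minimal; family→substrate biology
  beyond the shipped assignments must be supplied via TSV.
* Greedy overlap resolution can discard a pair of compatible hits in
  favour of one better-scoring conflicting hit; on real multi-domain
  proteins this is rare but possible.
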