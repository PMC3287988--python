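# Methods

This note records how the pipeline's operations are defined, what the
synthetic data emulate (and deliberately do not), the numerical choices,
and the places where the design was genuinely open.

## Coordinates and containers

All internal coordinates are 0-based half-open on a named chromosome with a
strand; conversion to GFF3/SAM (1-based inclusive) and BED (0-based
half-open) happens only in the format readers/writers. Count matrices are
pandas DataFrames (species × libraries, non-negative integers); alignments
are per-placement records carrying the read's total genome-wide hit count.

## Adapter trimming

A cut position is the 0-based index of the first adapter base in the read.
The trimmer scans suffix/prefix overlaps from longest to shortest and
returns the first overlap with at most `max_mismatches` mismatching
positions (default 0); `N` on either side never matches. Overlaps longer
than the adapter are not suffix/prefix overlaps and are never considered,
and overlap lengths are distinct by construction, so "longest qualifying
overlap" has no ties. Defaults — `min_overlap = 6`, exact matching — are
design choices, not field constants; both are exposed as configuration.
Reads without a detectable adapter are *retained* untrimmed and flagged:
trimming describes, it does not discard; the downstream length filters
(19–26 nt for miRNA and repeat counting) decide what is used.

## Alignment

The reference aligner is an exhaustive, ungapped (Hamming) scan of every
offset on both strands, vectorised per read base over the genome array.
For each read it reports the complete best stratum: all placements at the
minimal achieved distance d\*, provided d\* ≤ `max_mismatches` (default 2).
Reverse-strand placements match the read's reverse complement against the
forward genome. There is no seeding heuristic and no sub-sampling of ties,
so best-stratum completeness is exact by construction and is tested against
independent oracles (a pure-Python triple loop at 2 kb, a matrix
sliding-window comparison at 50 kb). This is practical because the package
targets desk-scale genomes (tens of kb); real-scale alignments enter via
SAM/BAM or BED import, with hit counts taken from `NH` tags or derived by
counting records per read. The hit-count cap used before repeat profiling
(`max_hits = 5000`) is inclusive.

## Annotation and counting

Category assignment: among features covering at least 70% of the READ's
aligned length (read-relative, strand-agnostic), the highest-priority class
wins, in the fixed order microRNA > other ncRNA > pseudogene > exon > gene >
LINE > other repeat; pre-miRNA hairpin intervals are the microRNA-category
features. A multi-mapping read contributes one category — the best across
its placements — so category tallies plus "unannotated" sum exactly to the
number of aligned reads.

miRNA counting applies three rules per (read, species) pair: length within
19–26 nt; some placement within ±2 bp of an annotated copy of the species;
and total genomic hits ≤ the species' genomic copy number. The position
tolerance is interpreted as BOTH endpoints within ±2 bp on the same strand
(`tolerance_mode = "both"`); a 5'-end-only mode is available, since the
endpoint convention was an open choice. A read satisfying the rules for
several species increments each of them (the rules define a per-species
predicate, not an arbitration) but never increments one species twice.
Copy numbers equal the number of annotated genomic copies, which the
synthetic reference guarantees equals the number of exact sequence
occurrences in the genome (it verifies this and refuses to emit a reference
where planting collisions break the bookkeeping).

## Normalisation and differential expression

Size factors are median-of-ratios: for species with positive counts in all
libraries, the ratio of each count to the species' across-library geometric
mean; the per-library factor is the median ratio. Species containing any
zero are excluded from the median. Note a consequence of the geometric-mean
reference: multiplying one of m libraries by k multiplies factor *ratios*
by k while all factors shift by k^(1/m), so normalised counts change by one
matrix-wide constant, not zero.

The variance-stabilising transform is the closed-form generalised log
`glog(x) = log2(x + sqrt(x² + 1)) − 1` of size-factor-normalised counts —
finite at zero, strictly increasing, asymptotically `log2(x)`. A fitted
VST would add coefficients without changing any property the package's
analyses rely on.

The two-group test is an explicit negative-binomial Wald test, not a
wrapper around an external DE package:

- normalised counts `y = k/s`; group means `q_A`, `q_B`; pooled mean `q₀`;
- per-species moment dispersion from the within-group variances,
  `α = (v − q·mean(1/s)) / q²`, pooled across the two groups;
- moderation: `α` is shrunk toward the across-species median with
  `prior_df = 10` pseudo-observations. Raw moment dispersions from 2–3
  replicates are far too noisy to use directly: unmoderated, the test loses
  most of its power against even 8-fold changes, and clipping negative
  moment estimates to zero makes it measurably conservative (null rate
  ≈ 0.035–0.045 instead of 0.05). The moderated value, floored at 1e-8, is
  reported; the *unfloored* moderated value enters the Wald variance;
- Wald statistic `(q_A − q_B) / se` with
  `se² = q₀·Σ(1/s)/n² (each group) + α·q₀²·(1/n_A + 1/n_B)`, floored at 1%
  of its Poisson part; reference distribution t with
  `n_A + n_B − 2 + prior_df` degrees of freedom (residual plus prior
  information); BH adjustment across species.

Calibration was verified by simulation (NB null, 2000 species, 3 vs 3,
unequal size factors) across true dispersions 0.01–0.2: the empirical
fraction of raw p < 0.05 stays within a few per mille of nominal, and
planted 8-fold changes at dispersion 0.05 are recovered essentially
completely at 5% FDR. Log2 fold-changes are reported with pseudocount 0.5
on normalised counts, so one-sided zeros stay finite.

## Comparison

Spearman correlation (mean ranks for ties) is computed on RAW counts —
rank correlation is invariant to monotone per-library transforms, so size
factors are irrelevant there — after dropping species with all-zero rows
(rank-degenerate). Clustering uses complete-linkage agglomeration over
Euclidean distances between glog-normalised library columns, implemented
directly (O(n³), n = libraries) with a deterministic tie-break: among
minimal-distance pairs, merge the lexicographically smallest pair of sorted
leaf-label tuples. Merge heights are non-decreasing (complete linkage is
monotone); the dendrogram exports Newick (ultrametric, leaf depth = half
the merge height), cophenetic distances and the top split. The star-ratio
report flags, per library, every miR/miR\* pair whose star count strictly
exceeds the mature count.

## Repeat profiling

Repeat analysis uses reads of 19–26 nt with ≤ 5000 hits whose placements
never touch a pre-miRNA (a single pre-miRNA-overlapping placement removes
the read entirely). A read is assigned to a repeat class when its interval
lies inside an instance interval expanded by 2 bp per side
("containment-with-slack"): repeat instances are orders of magnitude longer
than reads, so the endpoint-to-endpoint reading of a ±2 bp rule would be
vacuous here; the slack parameter is configurable. Multi-mapping reads
count once per distinct class, never per instance. Mean coverage is class
read count divided by the class's genomic instance count; proportions are
reported for all classes and with the dominant housekeeping classes
{RNA, rRNA, tRNA} removed, each view summing to 1.

Consensus coverage aligns reads to a repeat consensus with the same
best-stratum engine and accumulates per-position depth separately by
strand, per *placement* (coverage semantics), so total depth equals the
summed length of aligned placements as an exact integer identity.

## The synthetic data: what it emulates, and what it does not

The generator plants, on a random genome (default 50 kb): pre-miRNA
hairpins with mature and star arms of 19–24 nt (one species duplicated to
two exact genomic copies), protein-coding genes with exons, small ncRNAs,
pseudogenes, and repeat instances copied from per-class consensus
templates — including truncated copies of a 3 kb L1-like consensus whose
first 600 bp are designated the promoter. Identical template copies make
repeat-derived reads genuinely multi-mapping. Feature-free windows are
recorded for background sampling.

A protocol profile sets: the modal insert length (22 or 23 nt) and spread
of a truncated discrete Gaussian on 19–30 nt; the 3' adapter sequence and
read-through probability; a multiplicative miR\* sampling weight
(`star_enrichment ≥ 1`); and the fractions of reads drawn from feature-free
background ("unannotated") and from inside repeat instances. With
enrichment 1 the emitted per-species counts equal the truth table exactly
(the property the exact-recovery tests rely on); with enrichment e > 1 the
per-library total is redrawn multinomially with star species up-weighted by
e. miRNA reads are exact annotated sequences; the profile's length mode is
expressed through the background and repeat components, while miRNA insert
lengths follow the annotation. Quality strings are constant (`I`): the
pipeline never uses qualities.

Deliberately not modelled: sequencing errors beyond adapter read-through,
colour-space chemistry, barcodes/indexes, 5' adapters, and positional
isomiR jitter. Consequently, passing tests demonstrate the *logic* of the
pipeline — rule correctness, conservation laws, statistical calibration,
and the direction of planted biases — not robustness to base-call noise or
annotation error in real libraries.

## Study-condition simulations

`srnaproto.studies` freezes the simulation designs used by the test suite
and the reproduction script:

- **Clustering study**: 2 protocols × 2 cell types × 2 replicates per
  replicate run; 15 miRNA loci; 1200 annotated reads per library; one
  lognormal biological baseline per cell type with a 1.5× effect on 20% of
  mature species and replicate-level lognormal jitter (σ = 0.2); protocol
  bias is the IDT-like 5× star enrichment alone. 100 seeded replicates run
  the full trim/align/count/normalise/cluster chain; the recorded outcome
  is whether the dendrogram's top split separates the protocols. Background
  fractions are zero here because background reads cannot enter the miRNA
  count matrix and would only add runtime.
- **Star localisation study**: four libraries (2 IDT-like, 2 standard) from
  one truth table with baseline star/mature ratio 0.3, so enrichment lifts
  the IDT ratio to ≈ 1.5 while the standard libraries stay near 0.3.
- **DE null/power studies**: 2000 species, lognormal means around 100,
  size factors 0.7–1.3, NB dispersion 0.05, 3 vs 3; the power study plants
  8-fold changes in 50 species.
- **Size-factor recovery**: planted factors {0.5, 1, 2, 4} under Poisson
  noise over 200 species; error is the maximum relative deviation of
  factor ratios.

Problem sizes (50 kb genome, 10–15 miRNA loci, 1–2 × 10³ reads per library,
100 clustering replicates) were chosen so the whole suite and the
reproduction script each complete in well under a minute to a few minutes
on one CPU while keeping every planted effect comfortably identifiable.

## Degenerate inputs and edge behaviour

Size factors are undefined (and refused, with guidance) when no species is
positive in every library. Spearman returns NA for rank-degenerate vectors.
The DE test refuses groups with fewer than two libraries. `class_profile`
refuses classes that have reads but no recorded instances (a bookkeeping
bug by definition). The reference generator refuses seeds of `None`,
genomes under 10 kb, fewer than two miRNA loci, plantings that do not fit,
and any reference whose realised copy numbers contradict the annotation.

## Known limitations

The exhaustive aligner is quadratic in genome size and intended only for
toy genomes; the NB test assumes a common dispersion scale across species
(its moderation target is a single median, not a mean-dependent trend); the
star-ratio report treats naming (`name` / `name*`) as the pairing
authority; and the pipeline's category tally resolves multi-mapped reads by
best category rather than fractional weighting — all documented choices
where the underlying convention is genuinely unsettled.
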