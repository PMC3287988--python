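# srnaproto

Small-RNA sequencing libraries made from the *same* biological sample but
with different 3' adapters, library-preparation protocols or sequencing
platforms can look strikingly different: the modal insert length shifts
between 22 and 23 nt, passenger-strand miR* species can be captured more
efficiently than their mature partners, and large fractions of reads fall
outside any annotation. `srnaproto` is a desk-scale, fully testable
implementation of the classic analysis workflow used to characterise these
protocol biases — together with a synthetic-data generator that *plants*
them, so every stage of the pipeline can be checked against known truth.

It is aimed at people building or teaching small-RNA-seq quantification
pipelines who want every rule (trimming, alignment strata, annotation
priorities, counting constraints, normalisation) to be explicit, seeded and
verifiable, rather than hidden inside a large aligner or DE framework.

## The pipeline

1. **Trim** — 3'-adapter read-through is removed by the maximal
   suffix/prefix overlap between the read end and the adapter start, cutting
   immediately in front of the first adapter base (`min_overlap` 6 nt,
   exact matching by default).
2. **Align** — reads are placed on the genome by an exhaustive scan that
   reports the complete *best stratum*: every placement on either strand
   achieving the read's minimal Hamming distance d\* ≤ 2. SAM/BED import is
   available for externally aligned data; reads with more than 5000
   placements are excluded from repeat profiling (inclusive bound).
3. **Annotate** — a read is assigned to a feature category when ≥ 70% of
   its aligned length overlaps the feature, with priority
   microRNA > other ncRNA > pseudogene > exon > gene > LINE > other repeat.
   A read of 19–26 nt counts toward a mature miRNA or miR\* species only if
   its placement is within ±2 bp of an annotated copy (both ends, same
   strand) and its genomic hit count does not exceed the species' genomic
   copy number.
4. **Quantify** — median-of-ratios size factors
   `s_j = median_i (k_ij / (prod_j k_ij)^(1/m))`, a generalised-log
   transform `glog(x) = log2(x + sqrt(x² + 1)) − 1`, and a two-group
   negative-binomial Wald test with moment-based, moderated dispersions and
   Benjamini–Hochberg correction.
5. **Compare** — pairwise Spearman rank correlation on raw counts,
   complete-linkage hierarchical clustering on Euclidean distances between
   glog profiles, and a miR/miR\* report flagging libraries where the star
   form out-counts the mature form.
6. **Repeats** — after removing reads touching pre-miRNAs, repeat-class
   read counts are normalised by the class's number of genomic instances
   (mean coverage), and reads are aligned to repeat consensus sequences for
   strand-resolved per-position depth (the LINE-1 promoter sense/antisense
   pattern).

The synthetic generator (`srnaproto.synthio`) builds a toy genome with
pre-miRNA hairpins (including a two-copy species), genes/exons, ncRNAs,
pseudogenes and repeat instances copied from per-class consensus templates
(an L1-like element with a designated promoter region among them), then
samples protocol-biased FASTQ libraries with per-read provenance.

## Worked example

```
srnaproto simulate --config examples/demo.yaml --seed 1 --outdir demo
srnaproto run --config demo/run.yaml --outdir demo/results
```

The demo simulates 8 libraries — two protocol families (`illumina_like`,
22 nt mode, no star bias; `idt_like`, 23 nt mode, 5× miR\* over-capture,
larger unannotated background) × two cell types × two replicates — from a
shared biological baseline, and runs the full pipeline. With seed 1 the
dendrogram (`demo/results/dendrogram.nwk`) comes out as

```
(((ES_XX_idt_1,ES_XX_idt_2),(ES_XY_idt_1,ES_XY_idt_2)),
 ((ES_XX_std_1,ES_XX_std_2),(ES_XY_std_1,ES_XY_std_2)));
```

(branch lengths elided): the **top split separates the two protocols, not
the two cell types** — the protocol bias dominates the planted biology.
The star-ratio report shows 11 star>mature inversions, all in the four
`idt` libraries and none elsewhere; within-protocol Spearman correlations
(0.89–0.98) exceed cross-protocol ones (0.72–0.86). The DE table ranks the
three planted cell-type species first (raw p = 0.027, 0.072, 0.121) but
none clears the 5% FDR at this depth, because pooling both protocols into
each cell-type group inflates the within-group dispersion — the same
technical-variation effect the clustering exposes.

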