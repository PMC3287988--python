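# Demo simulation: two protocol families x two cell types x two replicates.
# Generate data and a run config, then run the pipeline:
#
#   srnaproto simulate --config examples/demo.yaml --seed 1 --outdir demo
#   srnaproto run --config demo/run.yaml --outdir demo/results
#
# The XY libraries carry a modest planted cell-type effect on three mature
# miRNAs; the idt_like profile carries a 5x miR* over-capture, a 23 nt
# length mode and a larger unannotated background.
reference:
  genome_length: 50000
  n_mirnas: 10
  n_repeat_instances: 40
# All libraries share one biological baseline per cell type
# (truth_seed_offset) plus replicate-level lognormal jitter.
libraries:
  - {id: ES_XX_std_1, profile: illumina_like, group: XX, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2}
  - {id: ES_XX_std_2, profile: illumina_like, group: XX, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2}
  - {id: ES_XY_std_1, profile: illumina_like, group: XY, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2,
     effect: {syn-miR-1: 2.0, syn-miR-2: 0.5, syn-miR-3: 2.0}}
  - {id: ES_XY_std_2, profile: illumina_like, group: XY, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2,
     effect: {syn-miR-1: 2.0, syn-miR-2: 0.5, syn-miR-3: 2.0}}
  - {id: ES_XX_idt_1, profile: idt_like, group: XX, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2}
  - {id: ES_XX_idt_2, profile: idt_like, group: XX, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2}
  - {id: ES_XY_idt_1, profile: idt_like, group: XY, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2,
     effect: {syn-miR-1: 2.0, syn-miR-2: 0.5, syn-miR-3: 2.0}}
  - {id: ES_XY_idt_2, profile: idt_like, group: XY, n_reads: 2000,
     truth_seed_offset: 0, replicate_sigma: 0.2,
     effect: {syn-miR-1: 2.0, syn-miR-2: 0.5, syn-miR-3: 2.0}}
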