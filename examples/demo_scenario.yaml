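# Demo synthetic study: 16 genes on two 100-kb chromosomes, one operon,
# six planted read-through regions, 2x2 design (HS vs WT, IP vs input)
# with two replicates per cell and Poisson-resampled coverage.
#
# The first two DoGs are transcribed in both conditions but 8x deeper in
# the HS IP fraction (a planted IP-vs-input interaction); the remaining
# regions are heat-shock-specific transcription with no IP enrichment.
seed: 20
n_chroms: 2
chrom_length: 100000
n_genes: 16
operon_prob: 0.25
n_replicates: 2
condition: HS
reference: WT
gene_depth: 10.0
noise: true
planted:
  - {gene_index: 0, category: DoG, length: 800, depth: 12.0, condition_specific: false, ip_log2fc: 3.0}
  - {gene_index: 3, category: DoG, length: 600, depth: 12.0, condition_specific: false, ip_log2fc: 3.0}
  - {gene_index: 5, category: ADoG, length: 700, depth: 12.0, condition_specific: true, ip_log2fc: 0.0}
  - {gene_index: 8, category: PoG, length: 500, depth: 12.0, condition_specific: true, ip_log2fc: 0.0}
  - {gene_index: 11, category: APoG, length: 400, depth: 12.0, condition_specific: false, ip_log2fc: 2.0}
  - {gene_index: 13, category: DoG, length: 900, depth: 12.0, condition_specific: true, ip_log2fc: 0.0}
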