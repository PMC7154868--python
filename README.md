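# rbpkit

Analysis toolkit for characterizing the sequence specificity and target
association of an RNA-binding protein, built around four experiment types:

- **RBNS-style selection** (`rbpkit.synthetic`, `rbpkit.kmers`): simulate
  random RNA 40-mer pools and concentration-dependent pulldown libraries
  under an explicit saturating (Langmuir) binding model; count all k-mers
  (k = 6–9) and compute per-k-mer enrichment R values (sample frequency /
  input frequency) with z-scores across the 4^k k-mer space.
- **Consensus motif assembly** (`rbpkit.motif`): align significant k-mers
  (z ≥ 3) against the top-enrichment seed and build a position frequency
  matrix; MEME-minimal output.
- **Genome motif scanning** (`rbpkit.genome`): exact k-mer (with optional
  mismatch derivatives) and PFM log-odds scanning of FASTA genomes on both
  strands, circular-genome aware, with per-GFF-feature sense/antisense hit
  counts and BED6 output.
- **RIP-chip and blot quantification** (`rbpkit.ripchip`, `rbpkit.quant`):
  two-channel array enrichment (replicate F635/F532 ratios, median of
  ratios, rRNA-sum normalization, wt/control differentials, bedGraph
  tracks) and paired-signal metrics (fold enrichment, fraction bound,
  stroma/membrane partition, control-adjusted specificity calls).

Everything the pipeline consumes can be generated by the seeded synthetic
data module, so the full analysis is exercisable offline.

## CLI

All functionality is exposed through one entry point:

```sh
rbpkit simulate --config sim.yaml --outdir pools/        # FASTQ pools per concentration
rbpkit count   --reads pools/input.fastq --k 8 --out counts
rbpkit enrich  --sample pools/100nM.fastq --input pools/input.fastq \
               --k 6 --k 7 --k 8 --k 9 --out enr         # per-k TSV, R + z
rbpkit motif   --enrichment enr_k8.tsv --zmin 3 --out motif.meme --aligned aligned.tsv
rbpkit scan    --genome plastome.fa --queries top_kmers.txt --mismatch 1 \
               --gff annotation.gff3 --sense-only --circular --out hits.bed
rbpkit ripchip --wt wt_array.tsv --control mutant_array.tsv --out enrichment.tsv \
               --track enrichment.bedgraph
rbpkit quant   --table blot.tsv --out metrics.tsv
```

A simulation config looks like:

```yaml
binding_model:
  motif_affinities: {UGGUUGGU: 100.0}
  background_affinity: 1.0
  combine_rule: max
selection:
  protein_concentrations: [0, 100, 1000]   # nM; 0 is the required control
  rna_concentration: 0.5                   # µM
  read_length: 40
  n_input_reads: 100000
  n_pulldown_reads: 100000
  seed: 1
```

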