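# rhizovir

A pipeline for soil virome detection and activity analysis: it calls viral
population (vOTU) presence from read-mapping breadth of coverage, normalizes
abundances, classifies transcriptionally active vOTUs from metatranscriptome
gene counts, runs community-ecology statistics (Shannon, Bray-Curtis, NMDS,
PERMANOVA, Mantel, two-way ANOVA + Tukey, random-intercept mixed models),
tests genes for differential activity between rhizosphere and bulk soil with
a simplified negative-binomial Wald test, applies rule-based vOTU
characterization (temperate/lytic lifestyle, host-prediction filtering,
ssRNA phage completeness, RdRp identity clustering), and identifies
rhizosphere "priming" vOTUs — populations active in the seedling rhizosphere
under continuous cropping but absent from it under virgin rotation.

A bundled synthetic-data generator produces the complete input bundle with
planted ground truth (active matrix, priming set, enriched genes,
compartment/rotation effects, virus-host abundance coupling) so every stage
has a recoverable answer.

## CLI

The pipeline runs through a fixed stage order
(detect → quantify → activity → ecology → differential → classify →
priming → report); each stage command runs the pipeline through that stage:

```sh
rhizovir simulate --config config.yaml --seed 1   # write synthetic inputs
rhizovir report   --config config.yaml --seed 1   # run all eight stages
```

A minimal `config.yaml`:

```yaml
input_dir: data/
output_dir: run/
n_permutations: 9999
thresholds:
  breadth: 0.75        # presence: fraction of genome covered >= 1x
  min_group_reads: 4   # gene-count filter, summed over group replicates
  activity_window_bp: 10000   # one transcribed gene per this many bp
  host_p: 0.05         # strict host-prediction filter
simulation:            # consumed by `rhizovir simulate`
  n_votus: 120
  priming_set_size: 15
```

All thresholds default to the values above; every run writes a
`manifest.json` recording the parameters used and per-stage input/output
counts. Fixed seeds give byte-identical outputs.

## Inputs

Tab-separated tables under `input_dir` (exactly what `rhizovir simulate`
writes): `design.tsv` (sample × compartment/rotation/growth-stage/replicate),
`catalog.tsv` (vOTU lengths, nucleic type, source library, provirus flags),
`genes.gff3` + `gene_functions.tsv` (gene models with COG letters and Pfam
hits), `counts_<library>.tsv` and `breadth_<library>.tsv` per DNA library,
`rna_gene_counts.tsv`, `library_sizes.tsv`, and optional
`host_predictions.tsv` / `host_otu_table.tsv`.

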