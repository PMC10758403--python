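# cpcub

Codon-usage-bias (CUB) analysis pipeline for chloroplast protein-coding
genes: nucleotide composition (GC, GC1/GC2/GC3, GC3s), relative
synonymous codon usage (RSCU), Wright's effective number of codons (ENc)
with its expected-value curve, the codon adaptation index (CAI), the
three mutation-vs-selection diagnostics (ENc-plot, PR2-plot, neutrality
regression), optimal-codon calling from high/low-expression gene
extremes (delta-RSCU rule), FPKM expression comparison across taxa, and
C-to-U RNA-editing effect classification — plus synthetic-data
generators that plant known ground truth for every stage.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks closed-form
ENc limits, brute-force oracle equivalence (RSCU/ENc/CAI/FPKM),
parameter recovery on mutation-driven and selection-driven synthetic
pools, and exact edit-effect round trips.

## CLI

All analyses are exposed as `cpcub` subcommands. Quick tour on
synthetic data:

```sh
cpcub simulate --regime selection --n-genes 80 --seed 1 --out-prefix demo
cpcub filter demo.fasta --taxon demo
cpcub rscu demo.fasta
cpcub enc demo.fasta
cpcub encplot demo.fasta
cpcub pr2 demo.fasta
cpcub neutrality demo.fasta
cpcub optimal demo.fasta --fraction 0.05
```

The full multi-taxon pipeline runs from one flat YAML config:

```sh
cpcub run-all config.yaml
```

with a config like

```yaml
taxa:
  Roscoea: roscoea_cds.fasta        # FASTA or GenBank (.gb) per taxon
  Cautleya: cautleya.gb
out_dir: out
extreme_fraction: 0.05              # high/low-expression gene fraction
delta_rscu: 0.08                    # optimal-codon threshold
overrep_threshold: 1.6
habitat_groups: {Roscoea: open, Cautleya: shade}
pools: {RosCau: [Roscoea, Cautleya]}
counts: {Roscoea: roscoea_counts.tsv}   # optional FPKM stage
gene_lengths: lengths.tsv
edit_sites: {Roscoea: roscoea_edits.tsv}  # optional editing stage
seed: 1
```

Outputs are TSV tables (per-gene statistics, RSCU matrix, neutrality
fits, ENc-plot data, optimal-codon calls, shared-optimal sets, FPKM,
edit-effect summaries) plus a run log; reruns are byte-identical.

## Layout

- `src/cpcub/sequence_io.py` — FASTA/GenBank CDS reading, validation and
  filtering, functional gene categories
- `src/cpcub/codon_stats.py` — composition, RSCU, ENc, CAI, PR2
- `src/cpcub/selection_analysis.py` — ENc-plot, neutrality regression,
  diagnostic interpretation
- `src/cpcub/optimal_codons.py` — extreme-gene selection, delta-RSCU
  optimal-codon calls, cross-taxon sharing
- `src/cpcub/expression_fpkm.py` — FPKM and cross-taxon comparison
- `src/cpcub/rna_editing.py` — edit-effect classification, summaries,
  editing/RSCU association
- `src/cpcub/synthetic_data.py` — ground-truth generators and writers
- `src/cpcub/cli_reports.py` — config validation, pipeline driver, CLI
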