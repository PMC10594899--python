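# mirlocus

From a small-RNA count matrix to a locus co-localization claim: a tested,
reusable pipeline that (1) calls differentially expressed miRNAs between two
groups with a negative-binomial Wald test and Benjamini–Hochberg correction,
(2) quantifies how strongly one DE direction clusters inside a named genomic
locus (hypergeometric and permutation nulls, effect-size comparison),
(3) predicts miRNA targets in 3'UTRs by seed matching plus duplex
re-alignment with score/energy screens, (4) ranks pathways per miRNA by
hypergeometric enrichment and pools them into a cross-miRNA recurrence
table, and (5) analyses RT-qPCR validation data with the 2^-ddCt method.
A synthetic-data module generates every input with planted ground truth, so
the whole chain is testable offline.

## Layout

| module | role |
| --- | --- |
| `mirlocus.synthdata` | simulators for annotation, NB counts, sequences, gene sets, reads, qPCR — all seeded, with truth tables |
| `mirlocus.smallrna` | read-level QC: length filter/histogram, priority-rule category annotation, first-base composition, per-chromosome abundance |
| `mirlocus.de` | size factors, NB Wald test, BH adjustment, up/down calls, PCA, sample correlation, pattern clustering |
| `mirlocus.locus` | locus membership, fraction reports, hypergeometric + permutation tests, Mann–Whitney effect-size comparison |
| `mirlocus.targets` | seed-site scanner (8mer/7mer-m8/7mer-A1/6mer), Gotoh duplex aligner, stacking-energy proxy, score/energy filtering, prediction intersection |
| `mirlocus.enrich` | per-miRNA hypergeometric enrichment, top-k ranking, recurrence table |
| `mirlocus.qpcr` | 2^-ddCt relative expression, Shapiro-screened Welch t / rank-sum comparison |
| `mirlocus.io`, `mirlocus.config`, `mirlocus.pipeline`, `mirlocus.cli` | BED/GFF3/FASTA/GMT/TSV IO, YAML config, end-to-end driver, CLI |

## CLI

```sh
# full synthetic run: simulate -> profile -> de -> locus -> targets -> enrich -> qpcr
mirlocus run --outdir out --seed 0

# individual stages, optionally from a YAML config
mirlocus de --config pipeline.yaml
mirlocus locus --config pipeline.yaml
```

Every stage writes TSV tables into the output directory plus a single
deterministic `report.json` (same config + seed ⇒ byte-identical outputs).
A config file mirrors `mirlocus.config.PipelineConfig`; any field can be
omitted to use defaults, e.g.

```yaml
outdir: out
seed: 0
simulation:
  n_mirnas_total: 150
  n_locus_mirnas: 101
  n_up_planted: 32
  n_down_planted: 48
thresholds:
  alpha: 0.05
  lfc_min: 1.0
  score_min: 150.0
  energy_max: -20.0
```

To analyse real data instead of simulating, disable the simulate stage and
point `inputs.*` at a BED/GFF3 annotation, a count matrix + samples TSV,
miRNA/UTR FASTA, a GMT file and a qPCR table; the locus is supplied as
`locus_chrom`/`locus_start`/`locus_end`.

## Conventions

* Coordinates are 0-based half-open internally; BED is read verbatim, GFF3
  converted on read/write.  Locus membership is ≥1 bp overlap, strand
  ignored.
* log2 fold changes are group A over group B.
* T and U are interchangeable on input; sequences are canonicalized to U.
* Alignment scores are reported as raw aligner units × a calibration
  constant (1.5) that anchors a perfect 22-mer duplex near the conventional
  "Max Score" scale; thresholds and the calibration are configurable.
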