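# clonevo

Clonal-evolution analysis of matched diagnosis/relapse leukemia pairs.

Given per-patient variant tables at three timepoints (initial diagnosis INI,
remission REM, relapse REL), CNA/CN-LOH segment profiles and blast-content
fractions, `clonevo`:

- partitions variants into somatic vs constitutional using the remission
  sample, with purity correction for low-blast samples;
- classifies each relapse as **TYPE1** (all clonal diagnosis mutations, allele
  frequency ≥ 0.30, preserved at relapse) or **TYPE2** (a subset of clonal
  diagnosis mutations confidently lost), with preserved / lost / gained
  bookkeeping, coverage guards and hypermutator flagging (> 85 coding
  mutations at relapse);
- compares CNA/CN-LOH profiles between timepoints (state-matched reciprocal
  overlap ≥ 0.5) as independent confirmation of TYPE2 calls;
- builds 96-channel trinucleotide mutation spectra and refits non-negative
  signature exposures (NNLS) to identify dominant mutational processes;
- screens remission variants for constitutional loss-of-function hits in a
  cancer-predisposition gene list and tests carrier enrichment between types;
- deconvolves bulk chromatin-accessibility profiles into T-cell precursor
  stage mixtures (fold-change region signature + NNLS) and compares
  dominant fractions between types (exact Mann–Whitney);
- computes the cohort statistics: two-sided Fisher exact tests, Welch t from
  summary statistics, log-rank, and printed-percent reproductions;
- ships a fully labeled synthetic-cohort simulator (clone trees, binomial
  read sampling, CNA gain/loss, germline variants, signature-biased
  hypermutation bursts, stage-mixture accessibility profiles) so every stage
  is exercisable without controlled-access data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (one test per
criterion). One assertion is intentionally red: the published p-value for the
diagnosis-clonality Fisher table is inconsistent with its own printed counts
(exact p rounds to 0.0382, not 0.0387); the test states the published value
and the comment explains the discrepancy.

## CLI

```sh
# generate a fully labeled synthetic cohort (default: 18 TYPE1 + 20 TYPE2)
clonevo fixtures generate --out cohort/ --seed 7

# classify one patient case directory
clonevo classify --case-dir cohort/cases/P01 --out reports/

# full cohort run: classification, CNA confirmation, Fisher / t / log-rank,
# CPG carrier enrichment, stage deconvolution
clonevo cohort --dir cohort/ --out reports/

# individual stages
clonevo cpg --variants rem.tsv --genes cpg_genes.txt --out cpg.tsv
clonevo signatures --variants variants.tsv --genome genome.fa \
    --signatures signatures.tsv --out exposures.json
clonevo deconv --atlas atlas.tsv --profiles profiles.tsv --out mixtures.tsv
```

All thresholds (clonality cutoff, absence rules, reciprocal-overlap fraction,
...) can be overridden with `--config config.yaml`; the effective values are
logged and embedded in every JSON report. Exit codes: 0 ok, 1 validation
error, 2 configuration error.

### File formats

- Variant TSV: header `chrom pos ref alt alt_count depth effect gene coding
  timepoint patient_id`; rows with `alt_count == 0` encode reference pileups
  used for absence calls. A minimal VCF 4.2 subset (FORMAT/AD, INFO
  EFFECT/GENE/TIMEPOINT/PATIENT) is also read.
- CNA segments: BED4+ `chrom start end state [logratio]` with state one of
  `gain`, `loss`, `cnloh` (0-based half-open).
- Signature matrix: TSV with one row per signature and 96 context columns
  (`A[C>A]A` … `T[T>G]T`).
- Atlas / profiles: TSV matrices keyed by a `region_id` column.
- Gene list: one symbol per line, `#` comments allowed.

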