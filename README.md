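# strlink

Short-tandem-repeat (STR) repeat-number estimation from paired-end insert
sizes for multiple individuals at once, coupling each individual's
insert-size likelihood through sampled coalescent genealogies with a
multiple-tree belief-propagation decoder.

A read pair spanning an STR locus reports an insert size shifted by
`-u * (n - n_ref)` relative to the true fragment length, so insert sizes
carry repeat-number information even for repeat tracts longer than the
read length. `strlink` implements:

- **basic model** (`strlink.insert_model`): per-individual insert-size
  likelihood `P(l | n)` with an O(states x K) normalization-table
  recurrence and exhaustive diploid grid search;
- **mutation model** (`strlink.mutation`): exact per-generation stepwise
  repeat evolution and its clipped-normal (Brownian) approximation used as
  belief-propagation edge potentials;
- **genealogies** (`strlink.genealogy`): Kingman coalescent simulation,
  biallelic flanking-site and repeat evolution on trees, Newick I/O, and a
  Metropolis–Hastings sampler of ultrametric genealogies conditioned on
  phased flanking genotypes (Felsenstein pruning, two-state model);
- **multi-tree BP** (`strlink.bp`): the factor graph joining diploid
  insert-size factors with a tree ensemble, loopy (sum-product) plus
  mixed-product message passing (10 + 10 cycles), decoding with max-product
  backtracking, and an exact brute-force marginal-MAP oracle for tiny
  instances;
- **rate selection** (`strlink.rate_selection`): the message-agreement
  score over a candidate STR mutation-rate grid;
- **simulation pipeline** (`strlink.pipeline`): the end-to-end benchmark
  (coalescent truth, direct insert-size simulation, estimation, RMSE with
  haplotype-pairing minimization) plus SAM/VCF ingestion utilities.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` reproduces the published simulation benchmarks
(10 replicates at up to 100 individuals); the full suite takes roughly
15–20 minutes on one CPU, the non-acceptance part a few seconds.

Known limitation (covered by one deliberately failing benchmark
assertion): the message-agreement score used for mutation-rate selection
rewards sharply peaked genealogy-side messages and therefore tends to pick
the smallest candidate rate; on shuffled-panel runs at the higher mutation
rate this over-couples individuals and inflates RMSE relative to running
with the true rate (pass `rate_grid_multipliers=None` to
`SimulationConfig` to fix the rate instead).

## CLI

```sh
strlink simulate -I 10 --coverage 20 --mu-s 2.73e-4 --seed 1 --out-dir rep0
strlink sample-trees --vcf rep0/panel.vcf --out rep0/trees.newick \
    --burn-in 5000 --seed 1
strlink estimate-basic --obs rep0/observations.tsv --region rep0/region.tsv \
    --out rep0/basic_calls.tsv
strlink estimate-coalescent --obs rep0/observations.tsv \
    --region rep0/region.tsv --trees rep0/trees.newick --out rep0/calls.tsv
strlink select-rate --obs rep0/observations.tsv --region rep0/region.tsv \
    --trees rep0/trees.newick --out rep0/scores.tsv
strlink evaluate --truth rep0/truth.tsv --calls rep0/calls.tsv
```

Observations are TSV (`sample_id`, `s`, `e`; 1-based coordinates) or
SAM/BAM; regions are a BED-like TSV (`chrom`, `start`, `end`, `unit`,
`ref_repeat`, `id`; 1-based inclusive); tree ensembles are Newick, one
tree per line, with leaf labels `<sample>_1` / `<sample>_2`; panels are
phased VCF.

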