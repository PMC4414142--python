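# methdrift

Analysis toolkit for age-related gene-body DNA methylation change and
its association with gene expression.

Given paired young/old methylome data — bisulfite read-window loci
(RRBS-style) and methylation-capture enrichment peaks — plus a
differential-expression table, `methdrift` computes:

* **Methylation drift by baseline level** — per-methylation-bin
  increase/decrease ratios showing that highly methylated loci
  preferentially gain and lowly methylated loci preferentially lose
  methylation with age;
* **Cross-platform concordance** — the increase/decrease balance of
  bisulfite loci inside capture peaks that gained enrichment;
* **Subdomain localisation** — Fisher tests of down- vs up-regulated
  gene counts by where methylation enrichment sits in the gene
  (5′ end, mid-gene, TES-proximal 3′ end, and the −1300…−500 bp
  subregion upstream of the TES), against peak-free control genes;
* **bsDens quintiles** — the down/up gene ratio as a function of
  intragenic bisulfite-locus density
  (`bsDens = 100 · n_loci · 36 / gene length`);
* **A density-matched resampling null** — is a gene subset (e.g.
  genes whose loci all sit in the TES-proximal quarter) down-biased
  *beyond what its bsDens predicts*? Null samples are drawn from
  low/high-density pools with a mixing weight solved so the null
  median bsDens matches the subset's.

A self-contained synthetic data generator with planted, recorded
effects makes the whole pipeline testable without sequencing data.
See `docs/methods.md` for the full model and conventions.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (exact rational-arithmetic
Fisher enumeration, exhaustive overlap scans) and acceptance tests
that verify calibration and recovery of planted effects across many
independent synthetic datasets (~2 minutes total).

## Worked example

Generate a synthetic study (both planted effects switched on), then
run individual analyses:

```sh
$ methdrift simulate --preset full --seed 5 --n-genes 1000 --out demo
{
  ...
  "n_genes": 1000,
  "n_loci": 8399,
  "n_peaks": 2058,
  "seed": 5
}

$ methdrift concordance --rrbs demo/rrbs_loci.tsv --peaks demo/mecap_peaks.tsv
subset I/D = 2.250 (18/8), reference I/D = 1.037 (871/840), Fisher p = 0.0754

$ methdrift drift --rrbs demo/rrbs_loci.tsv --out drift.tsv
reference I/D = 1.037; 15 bins written to drift.tsv

$ head -4 drift.tsv
bin_lo  bin_hi  n_increase  n_decrease  id_ratio      fisher_p        i_fraction
0       0.05    56          34          1.647058824   0.03975046662   0.6222222222
0.05    0.1     76          120         0.6333333333  0.001491903344  0.387755102
0.1     0.15    51          115         0.4434782609  5.739881588e-07 0.3072289157

$ methdrift quintiles --genes demo/genes.bed --rrbs demo/rrbs_loci.tsv \
    --expression demo/expression.tsv --out quintiles.tsv
 quintile  n_genes  median_metric  n_down  n_up  di_ratio  fisher_p
        1      181       1.345593      35    19  1.842105  0.874999
        2      181       2.669303      37    22  1.681818  0.649820
        3      181       4.112719      36    25  1.440000  0.298577
        4      180       5.768844      38    13  2.923077  0.327649
        5      180       8.758181      35    12  2.916667  0.315071

$ methdrift resample --genes demo/genes.bed --rrbs demo/rrbs_loci.tsv \
    --expression demo/expression.tsv --n-iter 2000 --out resample.tsv
 quartile  n_genes  di_ratio        p  null_median_ratio
        1        3  2.000000 0.579210           1.000000
        2        7  5.000000 0.432784           2.000000
        3       35  0.833333 0.237381           2.000000
        4      170  3.230769 0.045977           1.882353
```

The quartile-4 row is the genes whose loci all lie in the TES-proximal
quarter of the gene body: their down/up ratio (3.23) exceeds the
density-matched null's centre (1.88) with resampling p = 0.046 even in
this small 1,000-gene example; at the default 3,000-gene study size the
effect is recovered with p < 0.01 in nearly every seed.

The bundled reference contingency tables can be re-checked at any
time:

```sh
$ methdrift report
Reference contingency checks (two-sided Fisher's exact test vs control (723, 665))
consistent-change locus I/D ratio: 1.11 (17661/15842)

  five_prime             (  76 vs   61)  p = 0.474  expected p > 0.05   [PASS]
  mid                    ( 375 vs  329)  p = 0.643  expected p > 0.05   [PASS]
  three_prime            ( 178 vs   89)  p = 1.2e-05  expected 1.3e-05    [PASS]
  three_prime_subregion  (  85 vs   28)  p = 1.78e-06  expected 9.7e-07    [PASS]
```

## End-to-end pipeline

```sh
cat > config.yaml <<'YAML'
simulate: {preset: full, seed: 3}
params: {n_iter: 1000}
YAML
methdrift run-all --config config.yaml --out results/
```

writes provenance-stamped TSV tables (`drift_table.tsv`,
`quintiles_bsdens.tsv`, `resampling_quartiles.tsv`, …) plus
`summary.json`. Real data are supplied with an `inputs:` section
(`genes` BED6/GTF, `rrbs` locus TSV or Bismark coverage files,
`mecap_peaks`/`mecap_track`, `expression`) instead of `simulate:`.

## Library use

```python
from methdrift import (
    generate_dataset, preset_config, compute_gene_density,
    classify_expression_table, quintile_di_table, matched_null_test,
)

ds = generate_dataset(preset_config("tes_effect", seed=0))
classes = classify_expression_table(ds.expression)
classes.index = ds.expression["gene_id"]
dens = compute_gene_density(ds.genes, ds.loci).assign(
    expr_class=classes)
ref = dens[dens.n_loci > 0]
res = matched_null_test(ref[ref.pos_min >= 0.75], ref, seed=0)
print(res.observed_ratio, res.p)
```
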