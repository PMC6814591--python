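# agesig

Cross-species, cross-tissue analysis of transcriptomic aging signatures.

Bulk RNA-seq studies of aging sample several species (e.g. human, mouse
and short- and average-lived fish) and tissues (brain, liver, skin,
blood) at three ages — mature (M), aged (A) and old-aged (OA) — and ask
which senescence- and inflammation-related genes change consistently with
age across species and tissues.  `agesig` implements that analysis as a
tested Python pipeline for anyone who wants to run the same screen on
their own count matrices or study its statistical behaviour:

* **TPM normalization** and the expressed-gene filter (TPM > 1 in at
  least one sample);
* **differential expression** between the three age pairs — early aging
  (M vs A), late aging (M vs OA) and longevity (A vs OA) — with a
  self-contained negative-binomial Wald test (median-of-ratios size
  factors, method-of-moments dispersion, t reference) and
  Benjamini–Hochberg FDR per (species, tissue, comparison);
* **conserved-signature filtering**: a gene qualifies in a (species,
  tissue) cell when it is a DEG (FDR < 0.05) in one comparison and moves
  the same way by ≥ 10% (|log2FC| ≥ log2 1.1) in the others; it is a
  conserved aging signature when its qualifying cells span ≥ 3 species
  and ≥ 3 tissues;
* **tissue-exclusive markers** at a stricter 25% fold, per species group;
* **expression-variability analysis**: per-gene coefficient of variation
  (sd/mean of TPM) within each age group, compared between ages with a
  two-sided Welch t-test — lower CV at old age indicates tighter control
  of expression in long-lived individuals;
* **functional profiling** by majority vote over DEG process annotations;
* **embedding separation scores** quantifying that samples cluster by
  species and tissue, not by age (silhouette coefficients on log2(TPM+1),
  optional seeded t-SNE).

Because the original multi-species data sets are external, the package
ships a first-class **synthetic study generator** that plants conserved
signatures, tissue markers and old-age variability shifts in negative-
binomial counts with known ground truth; every statistical claim the
package makes is tested by recovery and calibration against it.  See
`docs/methods.md` for the model and all defaults.

## Worked example

```python
from agesig import RunConfig, run_pipeline, recovery_report

summary = run_pipeline(RunConfig(seed=1, out_dir="run1"))
print(summary.n_selected, summary.n_conserved_up, summary.n_conserved_down)
print(recovery_report(summary))
sep = summary.separation
print(round(sep.silhouette_by_species_tissue, 3),
      round(sep.silhouette_by_age_within_cluster, 3))
```

prints

```
114 30 26
{'conserved': {'sensitivity': 0.9333333333333333, 'false_calls': 0.0},
 'tissue_marker': {'sensitivity': 0.7, 'false_calls': 0.0}}
0.442 0.331
```

The simulated study (4 species × 3 tissues × 3 ages × 5 replicates, 2000
genes) planted 30 conserved-up, 30 conserved-down and 10 liver-exclusive
genes.  The pipeline preselected 114 genes (complete orthologs and DEG at
least once), called 30 up- and 26 down-conserved signatures — 56/60 of
the planted genes, with zero false calls — recovered 7/10 liver markers,
and the species × tissue clustering (silhouette 0.44) is far crisper than
any age separation within clusters (0.33), the expected pattern when
constitutive tissue identity dwarfs the aging signal.  All result tables
(DE, selection, conserved calls, markers, CV tests, profiles, separation,
ground truth, resolved configuration) are written under `run1/`.

The same stages are available from the shell:

```sh
aging-sig run --seed 1 --out-dir run1
aging-sig simulate --seed 1 --out-dir sim
aging-sig de --counts sim/counts_mouse.tsv --meta sim/meta_mouse.tsv \
             --lengths sim/gene_lengths.tsv --out-dir de_mouse
```

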