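# Methods

`agesig` re-implements, as a tested pipeline, a cross-species and
cross-tissue screen for transcriptomic aging signatures: bulk RNA-seq count
matrices from several species and tissues, each sampled at a mature (M), an
aged (A) and an old-aged (OA) time point, are normalized, tested for
differential expression between ages, and filtered for genes whose age
trend is conserved across species and tissues, for tissue-exclusive aging
markers, and for age-dependent changes in expression variability.  Because
the published multi-species data sets are not bundled, every statistical
guarantee is anchored on a seeded synthetic-data generator with planted
ground truth.

## The synthetic study generator

Counts are gamma-Poisson (negative binomial, NB) with
`Var(X) = mu + alpha * mu^2`; `alpha` (default 0.1) is one shared
dispersion per run, a typical magnitude for bulk RNA-seq biological
replicates.  Per-gene baseline means are drawn log-uniformly over
`10^1.3 .. 10^3` (roughly 20–1000 counts), the expressed range where the
downstream TPM > 1 filter and the Wald test operate with reasonable power
at n = 5 replicates.  Gene lengths are uniform over 500–5000 nt and
identical across orthologues; every simulated gene has a complete
one-to-one ortholog entry keyed by a reference (mouse-convention) id.

Planted structure:

* **Conserved signatures** — `n_conserved_up`/`n_conserved_down` genes
  (default 30 + 30 of 2000) whose mean is multiplied (divided) by
  `conserved_fold` (default 2) per age step in *every* species and tissue,
  so all three age comparisons see a consistent direction.  This is the
  simplest generative model satisfying the premises of the conservation
  filter, which assumes monotone change towards old age.
* **Tissue-exclusive markers** — `n_tissue_markers` genes (default 10, in
  liver) with the same monotone trend but only in their designated tissue.
* **Old-age variability shift** — the NB dispersion of every gene is
  multiplied by `oa_cv_scale` in the OA group only.  Scaling the dispersion
  rather than the mean changes the coefficient of variation while leaving
  the log2 fold change of unplanted genes centred at zero, cleanly
  separating the variability effect from the differential-expression
  effect.  The default is 0.5, emulating the headline observation that
  expression is more tightly controlled in long-lived individuals; 2.0
  plants the opposite (fish-skin-like) pattern, and 1.0 is the calibration
  null.

**Constitutive expression identity.**  Real bulk RNA-seq samples separate
by tissue and species far more strongly than by age.  The generator
therefore applies per-(species, gene), per-(tissue, gene) and
per-(species, tissue, gene) multiplicative log2-normal effects with
standard deviations 1.5, 1.0 and 0.5 — strong constitutive identity
(several-fold typical differences between tissues or species for most
genes) against a subtle aging signal confined to the planted genes.  These
magnitudes were fixed once, by pilot simulation, so that the generator
simultaneously exhibits (i) the cluster structure the embedding analysis
presumes and (ii) enough per-cell power that planted genes remain
recoverable; they are study conditions, not tuning knobs.  A mild
log-uniform per-sample library-size factor (±0.15 decades) exercises the
size-factor normalization; batch effects and GC/length bias are out of
scope.

What the generator does **not** emulate: real ortholog maps are incomplete
and many-to-many (the map here is complete and strictly 1:1 unless edited);
real dispersion varies per gene with a mean–dispersion trend; age effects
in real data are not perfectly monotone or shared across all cells.
Passing recovery tests therefore demonstrate that the filters implement
their stated rules and recover the planted model — not that the biological
findings of any particular study would replicate.

## Normalization and differential expression

TPM is the usual within-sample normalization:
`TPM_gs = 1e6 * (c_gs / l_g) / sum_j (c_js / l_j)`; an all-zero library
stays all-zero.  Genes with TPM ≤ 1 in every sample of a (species, tissue)
— taken across all three age groups jointly, since filtering precedes the
per-comparison tests — are discarded.

The DE stage is a self-contained NB Wald test rather than a wrapper around
an external package, because downstream filters consume only (log2FC, FDR)
and a small, calibrated test is easier to reason about than a replicated
tool:

* median-of-ratios size factors (genes with any zero count excluded from
  the reference; factors rescaled to geometric mean 1);
* per-group means `m0, m1` on the normalized scale;
  `log2FC = log2((m1 + 0.5) / (m0 + 0.5))` with a symmetric pseudocount of
  0.5 preventing infinite fold changes;
* gene-wise dispersion by method of moments pooled across the two groups
  (df-weighted), floored at 1e-8; no shrinkage of dispersions or fold
  changes;
* delta-method standard error of the log fold change,
  `Var(log m_k) ≈ (m_k + alpha m_k^2) / (n_k (m_k + 0.5)^2)`;
* the Wald statistic is referred two-sidedly to a **t distribution with
  n0 + n1 − 2 degrees of freedom**.  With the variance estimated from this
  few replicates the standard-normal reference is measurably
  anticonservative (type-I ≈ 0.09 at nominal 0.05 with n = 5 per group);
  the t reference restores calibration (≈ 0.053, inside the 0.035–0.065
  acceptance band) without touching the statistic itself.

P-values are Benjamini–Hochberg adjusted within each
(species, tissue, comparison) table — families are per DE run, never
global across tissues.  A DEG is `FDR < 0.05`.  The three comparisons are
early aging (M vs A), late aging (M vs OA) and longevity (A vs OA), with
the older group always the contrast, so positive log2FC means upregulation
with aging.

## Signature filters

**Preselection.**  A gene survives iff its ortholog entry is complete in
every species *and* it is a DEG in at least one table; exclusion reasons
(`missing_ortholog`, checked first, then `never_de`) are recorded per gene.

**Cell qualification.**  Within one (species, tissue), a gene qualifies
*up* when some comparison has `FDR < 0.05` with positive log2FC and every
other comparison has `log2FC ≥ log2(1.10) ≈ 0.1375` (a ≥ 10% change in the
same direction); *down* is symmetric.  The significant comparison itself
needs only the sign, matching the reading that significance substitutes
for the effect-size floor there.  The rule can never return both
directions for the same cell.

**Conserved signatures.**  A direction is conserved when its qualifying
cells span ≥ 3 distinct species *and* ≥ 3 distinct tissues (not merely
≥ 3 cells).  Both directions are evaluated independently; a gene split
between directions is conserved only if one direction alone meets the
span criterion.  All thresholds (10%, 25%, FDR 0.05, 3/3 spans) are
configuration keys with these canonical defaults.

**Tissue-specific markers.**  The same rule at a 25% fold floor, applied
within named species groups (e.g. all species, mammals, fishes): a marker
for tissue *t* in group *G* qualifies with one direction in *t* for every
species of *G* and in no other tissue for any species of *G*; exclusivity
is judged at the same 25% threshold, since the stricter screen applies the
same strategy with only the threshold raised.

## Variability (CV) analysis

For each (species, tissue, age group), the CV of every expressed gene is
`sd / mean` of TPM across replicates (n−1 denominator).  "Expressed" is
read as group-mean TPM > 1 — the per-group reading avoids CVs on
dropout-dominated rows and is an interpretive choice, recorded here.  Age
groups are compared with a two-sided Welch t-test on the per-gene CV
vectors (no equal-variance guarantee exists between the two CV
distributions), with directions labelled at the p ≤ 0.01 / 0.001 / 0.0001
tiers and percentile summaries (2.5%, median, 97.5%) mirroring the
box-plot bounds.

## Functional profiles

DEGs of each (species, tissue, comparison), mapped to reference ids, vote
once per annotation label they carry (one vote per label, not per gene —
the alternative reading is noted as unresolved); unannotated DEGs count
under `unannotated`.  The dominant process is the argmax label set — ties
are reported as sets, never broken.  Profiles with fewer than 5 DEGs are
flagged `low_support` but still emitted.

## Embedding and separation scores

The pooled samples × selected-genes matrix uses `log2(TPM + 1)` (the exact
input scale of the original clustering is unstated; this choice is
recorded in the output metadata).  The 2-D stochastic-neighbor embedding
is delegated to scikit-learn (seeded, default perplexity 10) and is not
part of the tested contract; the testable quantity is the trio of mean
silhouette coefficients — by tissue, by species × tissue, and by age group
evaluated within each species × tissue cluster and averaged.  A labeling
with a single class yields NaN rather than an error.

## Problem sizes and numerical choices

Recovery and separation guarantees are evaluated on 4 species × 3 tissues
× 3 ages × 5 replicates with 2000 genes (10 seeds for recovery averages,
20 for the separation win rate); DE calibration on 2000-gene null pairs
over 20 seeds; CV power on 1000-gene single-tissue studies (20 power
seeds per direction, 100 null seeds).  These sizes give stable Monte-Carlo
averages while keeping a full verification run in the order of a minute.
Degenerate inputs are handled explicitly: identical groups give
log2FC = 0, p = 1; all-zero libraries give all-zero TPM columns; constant
replicate vectors give CV 0 and t = 0, p = 1; single-class labelings give
NaN silhouettes.

## Known limitations

* The NB test uses gene-wise moment dispersions without shrinkage; at very
  low means or n < 4 it loses power relative to shrinkage-based tools.
* Strict 1:1 orthology is enforced; many-to-many rows are rejected with a
  warning rather than resolved, as no resolution rule is defined.
* The conservation criterion implements the joint reading (≥ 3 species and
  ≥ 3 tissues spanned by the same direction's cells); the span thresholds
  are configurable for the alternative readings.
* CV comparisons treat per-gene CVs as independent observations; the
  mild positive correlation between age groups sharing genes makes the
  Welch test conservative, which the null calibration confirms.
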