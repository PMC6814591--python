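"""TPM normalization, expression filtering and differential expression.

The differential-expression stage is a self-contained negative-binomial Wald
test: median-of-ratios size factors, per-group NB means on the normalized
scale, gene-wise method-of-moments dispersion pooled across the two groups,
and a Wald statistic on the log2 fold change referred to a small-sample t
distribution.  It is calibrated by simulation rather than by matching any
published tool's internals; downstream stages consume only (log2fc, FDR).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DE_COLUMNS,
    AgeGroup,
    Comparison,
    CountMatrix,
    DEResultTable,
    GeneLengths,
    StudyDesign,
    TPMMatrix,
    ValidationError,
)

__all__ = [
    "tpm_normalize",
    "expression_filter",
    "size_factors",
    "nb_wald_test",
    "bh_fdr",
    "run_de",
]

logger = logging.getLogger(__name__)

#: symmetric pseudocount on normalized group means, preventing infinite
#: log2 fold changes
PSEUDOCOUNT = 0.5

#: lower bound on the method-of-moments NB dispersion estimate
DISPERSION_FLOOR = 1e-8


def tpm_normalize(cm: CountMatrix, lengths: GeneLengths) -> TPMMatrix:
    """Transcripts-per-million normalization.

    ``TPM[g, s] = 1e6 * (c[g, s] / l[g]) / sum_j (c[j, s] / l[j])``; an
    all-zero sample stays all-zero (the one documented exception to the
    column-sum invariant).
    """
    lens = lengths.as_array(cm.gene_ids)
    rates = cm.counts / lens[:, None]
    col_sums = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(col_sums > 0, 1e6 * rates / col_sums, 0.0)
    return TPMMatrix(cm.gene_ids, cm.samples, tpm)


def expression_filter(tpm: TPMMatrix) -> set[str]:
    """Genes considered expressed: TPM strictly greater than 1 in at least
    one sample.  The complement is discarded from differential expression."""
    if tpm.n_samples == 0 or tpm.n_genes == 0:
        return set()
    keep = (tpm.tpm > 1.0).any(axis=1)
    return {g for g, k in zip(tpm.gene_ids, keep) if k}


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Genes with a zero geometric mean (any zero count) are excluded from the
    reference, as is conventional for the median-of-ratios estimator.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 1:
        raise ValidationError("size_factors expects a genes x samples matrix")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; cannot compute "
            "median-of-ratios size factors"
        )
    log_counts = np.log(counts[all_positive])
    log_ref = log_counts.mean(axis=1)
    log_sf = np.median(log_counts - log_ref[:, None], axis=0)
    log_sf -= log_sf.mean()  # geometric mean exactly 1
    return np.exp(log_sf)


def _pooled_mom_dispersion(
    x0: np.ndarray, x1: np.ndarray
) -> np.ndarray:
    """Gene-wise NB dispersion, method of moments pooled across two groups.

    Solves ``variance = mu + alpha * mu^2`` within each group and combines
    the two estimates weighted by degrees of freedom; floored at
    ``DISPERSION_FLOOR``.
    """
    n0, n1 = x0.shape[1], x1.shape[1]
    m0 = x0.mean(axis=1)
    m1 = x1.mean(axis=1)
    v0 = x0.var(axis=1, ddof=1)
    v1 = x1.var(axis=1, ddof=1)
    num = (n0 - 1) * (v0 - m0) + (n1 - 1) * (v1 - m1)
    den = (n0 - 1) * m0**2 + (n1 - 1) * m1**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    cm: CountMatrix,
    baseline: AgeGroup,
    contrast: AgeGroup,
    kept_genes: Iterable[str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> DEResultTable:
    """Negative-binomial Wald test of ``contrast`` against ``baseline``.

    Positive ``log2fc`` means higher expression in the contrast (older)
    group.  The Wald statistic ``log2fc / SE`` is referred two-sidedly to a
    t distribution with ``n_baseline + n_contrast - 2`` degrees of freedom,
    the natural reference for a variance estimated from this few replicates.
    Swapping the two groups negates every fold change and leaves every
    p-value unchanged.  The returned table has FDR unset (NaN).
    """
    baseline = AgeGroup(baseline)
    contrast = AgeGroup(contrast)
    mask0 = cm.sample_mask(age_group=baseline)
    mask1 = cm.sample_mask(age_group=contrast)
    species = cm.samples[0].species if cm.samples else "?"
    tissues = sorted({s.tissue for s in cm.samples})
    tissue = tissues[0] if len(tissues) == 1 else "/".join(tissues)
    for age, mask in ((baseline, mask0), (contrast, mask1)):
        if mask.sum() < 2:
            raise ValidationError(
                f"group ({species}, {tissue}, {age.value}) has "
                f"{int(mask.sum())} replicate(s); at least 2 are required"
            )

    if kept_genes is None:
        gene_idx = np.arange(cm.n_genes)
    else:
        kept = set(kept_genes)
        unknown = kept - set(cm.gene_ids)
        if unknown:
            raise ValidationError(
                f"kept_genes not in the count matrix: {sorted(unknown)[:5]}"
            )
        gene_idx = np.array(
            [i for i, g in enumerate(cm.gene_ids) if g in kept], dtype=int
        )
    genes = [cm.gene_ids[i] for i in gene_idx]

    sub = cm.counts[:, mask0 | mask1]
    sf = size_factors(sub)
    normed = sub / sf[None, :]
    # group column positions within the two-group submatrix
    order = np.flatnonzero(mask0 | mask1)
    in0 = np.isin(order, np.flatnonzero(mask0))
    x0 = normed[np.ix_(gene_idx, np.flatnonzero(in0))]
    x1 = normed[np.ix_(gene_idx, np.flatnonzero(~in0))]
    n0, n1 = x0.shape[1], x1.shape[1]

    m0 = x0.mean(axis=1)
    m1 = x1.mean(axis=1)
    alpha = _pooled_mom_dispersion(x0, x1)
    log2fc = np.log2((m1 + pseudocount) / (m0 + pseudocount))
    var_log = (m0 + alpha * m0**2) / (n0 * (m0 + pseudocount) ** 2) + (
        m1 + alpha * m1**2
    ) / (n1 * (m1 + pseudocount) ** 2)
    se_lfc = np.sqrt(var_log) / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se_lfc > 0, log2fc / np.where(se_lfc > 0, se_lfc, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=n0 + n1 - 2)
    p = np.clip(p, 0.0, 1.0)
    base_mean = normed[gene_idx].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": np.nan,
        },
        columns=DE_COLUMNS,
    )
    return DEResultTable(species, tissue, _comparison_for(baseline, contrast), table)


def _comparison_for(baseline: AgeGroup, contrast: AgeGroup) -> Comparison:
    for comp in Comparison:
        if comp.baseline is baseline and comp.contrast is contrast:
            return comp
    # reversed or ad-hoc pair: report the canonical comparison if one matches
    for comp in Comparison:
        if {comp.baseline, comp.contrast} == {baseline, contrast}:
            return comp
    return Comparison.EARLY


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_de(
    cm: CountMatrix,
    lengths: GeneLengths,
    design: StudyDesign | None = None,
    fdr_cut: float = 0.05,
) -> list[DEResultTable]:
    """The full DE stage for one species: per tissue, TPM-normalize over all
    three age groups jointly, drop never-expressed genes, run the NB Wald
    test for each of the three age comparisons and BH-adjust within each
    (species, tissue, comparison) table."""
    species = cm.samples[0].species if cm.samples else "?"
    if design is not None:
        tissues = [t for t in design.tissues.get(species, []) ]
    else:
        tissues = list(dict.fromkeys(s.tissue for s in cm.samples))
    results: list[DEResultTable] = []
    for tissue in tissues:
        t_mask = cm.sample_mask(tissue=tissue)
        if not t_mask.any():
            logger.warning("species %s: tissue %s absent, skipped", species, tissue)
            continue
        sub = cm.subset_samples(t_mask)
        missing = [a.value for a in AgeGroup if not sub.sample_mask(age_group=a).any()]
        if missing:
            raise ValidationError(
                f"({species}, {tissue}): age group(s) {missing} missing"
            )
        tpm = tpm_normalize(sub, lengths)
        kept = expression_filter(tpm)
        logger.info(
            "DE %s/%s: %d of %d genes pass the TPM > 1 filter",
            species, tissue, len(kept), sub.n_genes,
        )
        for comp in Comparison:
            de = nb_wald_test(sub, comp.baseline, comp.contrast, kept_genes=kept)
            de.table["fdr"] = bh_fdr(de.table["p_value"].to_numpy())
            results.append(de)
    return results
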