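"""Coefficient-of-variation analysis of expression across age groups.

For every expressed gene the CV (sample standard deviation over mean, n-1
denominator) is computed within each age group of one (species, tissue);
group-level differences are assessed with a two-sided Welch t-test on the
per-gene CV values.  A significantly lower CV in the old-aged group is the
"tighter control in long-lived individuals" pattern; a higher CV is the
fish-skin exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AgeGroup, TPMMatrix, ValidationError

__all__ = [
    "CVTable",
    "CVComparison",
    "compute_cv",
    "compare_cv",
    "cv_percentile_summary",
    "SIGNIFICANCE_TIERS",
]

#: the three significance tiers reported alongside each comparison
SIGNIFICANCE_TIERS = (0.01, 0.001, 0.0001)

#: group-mean TPM above which a gene counts as expressed within an age group
EXPRESSION_CUT = 1.0


@dataclass
class CVTable:
    """Per-gene CV within each age group of one (species, tissue)."""

    species: str
    tissue: str
    table: pd.DataFrame  # gene_id, age_group, cv, n_samples

    def cvs(self, age: AgeGroup) -> np.ndarray:
        mask = self.table["age_group"] == AgeGroup(age).value
        return self.table.loc[mask, "cv"].to_numpy(dtype=float)


@dataclass
class CVComparison:
    """Welch t-test of the per-gene CV distributions of two age groups."""

    species: str
    tissue: str
    age_pair: tuple[AgeGroup, AgeGroup]
    mean_cv_1: float
    mean_cv_2: float
    t_statistic: float
    p_value: float
    direction: str  # "decrease" | "increase" | "none"
    significance_tier: float | None  # tightest tier met, or None


def compute_cv(
    tpm: TPMMatrix,
    gene_subset: Iterable[str] | None = None,
    expression_cut: float = EXPRESSION_CUT,
) -> CVTable:
    """CV of TPM across replicates, per gene and age group.

    Restricted to ``gene_subset`` when given (the preselected-gene analysis)
    or to all genes otherwise (the all-expressed-genes verification).  A gene
    enters an age group only when that group's mean TPM exceeds
    ``expression_cut`` — zero-mean rows never yield a CV.
    """
    species = {s.species for s in tpm.samples}
    tissues = {s.tissue for s in tpm.samples}
    if len(species) != 1 or len(tissues) != 1:
        raise ValidationError(
            "compute_cv expects samples of a single (species, tissue); got "
            f"species={sorted(species)}, tissues={sorted(tissues)}"
        )
    if gene_subset is not None:
        keep = set(gene_subset)
        idx = [i for i, g in enumerate(tpm.gene_ids) if g in keep]
    else:
        idx = list(range(tpm.n_genes))
    genes = [tpm.gene_ids[i] for i in idx]
    rows: list[dict] = []
    for age in AgeGroup:
        mask = tpm.sample_mask(age_group=age)
        n = int(mask.sum())
        if n == 0:
            continue
        if n < 2:
            raise ValidationError(
                f"age group {age.value} has {n} replicate(s); at least 2 are "
                "required for a CV"
            )
        x = tpm.tpm[np.ix_(idx, np.flatnonzero(mask))]
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        expressed = mean > expression_cut
        for g, m, s, e in zip(genes, mean, sd, expressed):
            if e:
                rows.append(
                    {"gene_id": g, "age_group": age.value, "cv": s / m,
                     "n_samples": n}
                )
    table = pd.DataFrame(rows, columns=["gene_id", "age_group", "cv", "n_samples"])
    return CVTable(species.pop(), tissues.pop(), table)


def compare_cv(
    cv: CVTable, pair: tuple[AgeGroup, AgeGroup] = (AgeGroup.A, AgeGroup.OA)
) -> CVComparison:
    """Two-sided Welch t-test between the CV distributions of an age pair.

    The direction ("decrease" when the second group's mean CV is lower) is
    labelled only at the tiers of ``SIGNIFICANCE_TIERS``; otherwise "none".
    Swapping the pair negates the statistic and flips the direction.
    """
    a1, a2 = (AgeGroup(a) for a in pair)
    cv1, cv2 = cv.cvs(a1), cv.cvs(a2)
    if len(cv1) < 2 or len(cv2) < 2:
        raise ValidationError(
            f"age pair ({a1.value}, {a2.value}) needs >= 2 CVs per group, got "
            f"{len(cv1)} and {len(cv2)}"
        )
    if np.array_equal(cv1, cv2) and np.ptp(cv1) == 0:
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(cv2, cv1, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t_stat):  # both groups constant and equal
            t_stat, p = 0.0, 1.0
    mean1, mean2 = float(cv1.mean()), float(cv2.mean())
    tier = None
    for level in sorted(SIGNIFICANCE_TIERS, reverse=True):
        if p <= level:
            tier = level
    if tier is not None:
        direction = "decrease" if mean2 < mean1 else "increase"
    else:
        direction = "none"
    return CVComparison(
        species=cv.species,
        tissue=cv.tissue,
        age_pair=(a1, a2),
        mean_cv_1=mean1,
        mean_cv_2=mean2,
        t_statistic=t_stat,
        p_value=p,
        direction=direction,
        significance_tier=tier,
    )


def cv_percentile_summary(cv: CVTable) -> pd.DataFrame:
    """2.5%, median and 97.5% percentiles of the CV distribution per age
    group (linear interpolation), mirroring the box-plot bounds."""
    rows = []
    for age in AgeGroup:
        values = cv.cvs(age)
        if len(values) < 2:
            continue
        p_lo, med, p_hi = np.percentile(values, [2.5, 50.0, 97.5])
        rows.append(
            {"age_group": age.value, "p2_5": p_lo, "median": med, "p97_5": p_hi,
             "n_genes": len(values)}
        )
    return pd.DataFrame(rows, columns=["age_group", "p2_5", "median", "p97_5", "n_genes"])


def cv_comparisons_frame(comparisons: Iterable[CVComparison]) -> pd.DataFrame:
    rows = [
        {
            "species": c.species,
            "tissue": c.tissue,
            "group_1": c.age_pair[0].value,
            "group_2": c.age_pair[1].value,
            "mean_cv_1": c.mean_cv_1,
            "mean_cv_2": c.mean_cv_2,
            "t_statistic": c.t_statistic,
            "p_value": c.p_value,
            "direction": c.direction,
            "significance_tier": "" if c.significance_tier is None else c.significance_tier,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "tissue", "group_1", "group_2", "mean_cv_1",
                 "mean_cv_2", "t_statistic", "p_value", "direction",
                 "significance_tier"],
    )
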