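"""Synthetic multi-species aging-study generator with planted ground truth.

Counts are drawn from a gamma-Poisson (negative binomial) law with
``variance = mu + alpha * mu^2``.  The generator plants three kinds of
structure that the downstream pipeline is designed to recover:

* conserved signatures — genes whose mean expression changes by a constant
  fold per age step (mature -> aged -> old-aged) in every species and tissue,
  upward or downward;
* tissue-exclusive markers — genes with the same monotone age trend but only
  in one designated tissue;
* an old-age variability shift — the NB dispersion of every gene is scaled by
  ``oa_cv_scale`` in the old-aged group, planting lower (< 1) or higher (> 1)
  expression variability at old age without moving the mean.

Constitutive per-species, per-tissue and species × tissue baseline effects
give every sample the strong tissue/species expression identity that real
bulk RNA-seq shows, against which the subtle aging signal is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .datatypes import (
    PROCESS_VOCABULARY,
    AgeGroup,
    AnnotationTable,
    CountMatrix,
    GeneLengths,
    OrthologMap,
    SampleMeta,
    StudyDesign,
    ValidationError,
)

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate_study", "simulate_null_pair"]

DEFAULT_SPECIES = ("human", "mouse", "zebrafish", "killifish")
DEFAULT_TISSUES = ("brain", "liver", "skin")

ROLE_NULL = "null"
ROLE_UP = "conserved_up"
ROLE_DOWN = "conserved_down"
ROLE_MARKER = "tissue_marker"

# process labels planted per role so the majority-vote profiler has
# recoverable truth
ROLE_LABELS = {
    ROLE_UP: "immune/inflammatory response",
    ROLE_DOWN: "oxidative stress response",
    ROLE_MARKER: "senescence",
}


def _default_design() -> StudyDesign:
    return StudyDesign.balanced(DEFAULT_SPECIES, DEFAULT_TISSUES, n_replicates=5)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``baseline_mean_log_range`` is the log10 range of per-gene baseline count
    means; species/tissue effects are log2-normal multiplicative deviations
    around that baseline.  ``conserved_fold`` and ``marker_fold`` apply per
    age step, so the old-aged mean differs from the mature mean by the square
    of the fold.
    """

    n_genes: int = 2000
    design: StudyDesign = field(default_factory=_default_design)
    baseline_mean_log_range: tuple[float, float] = (1.3, 3.0)
    nb_dispersion: float = 0.1
    n_conserved_up: int = 30
    n_conserved_down: int = 30
    conserved_fold: float = 2.0
    n_tissue_markers: int = 10
    marker_tissue: str = "liver"
    marker_fold: float = 2.0
    oa_cv_scale: float = 0.5
    species_effect_sd: float = 1.5
    tissue_effect_sd: float = 1.0
    interaction_sd: float = 0.5
    library_scale_log_range: tuple[float, float] = (-0.15, 0.15)
    seed: int = 0

    def validate(self) -> None:
        n_planted = self.n_conserved_up + self.n_conserved_down + self.n_tissue_markers
        if n_planted >= self.n_genes:
            raise ValidationError(
                f"planted genes ({n_planted}) must number fewer than n_genes "
                f"({self.n_genes})"
            )
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.oa_cv_scale <= 0:
            raise ValidationError("oa_cv_scale must be positive")
        for name in ("conserved_fold", "marker_fold"):
            if getattr(self, name) <= 1:
                raise ValidationError(f"{name} must exceed 1")
        if self.baseline_mean_log_range[0] > self.baseline_mean_log_range[1]:
            raise ValidationError("baseline_mean_log_range must be (low, high)")
        self.design.validate()
        if self.n_tissue_markers > 0:
            has_marker_tissue = any(
                self.marker_tissue in self.design.tissues[sp]
                for sp in self.design.species
            )
            if not has_marker_tissue:
                raise ValidationError(
                    f"marker tissue {self.marker_tissue!r} absent from design"
                )
        for sp in self.design.species:
            for ti in self.design.tissues[sp]:
                for age in AgeGroup:
                    if self.design.n_replicates(sp, ti, age) < 1:
                        raise ValidationError(
                            f"design cell ({sp}, {ti}, {age.value}) has no replicates"
                        )


@dataclass
class SimTruth:
    """Planted ground truth: role and expected per-age mean for every gene."""

    table: pd.DataFrame  # ref_id, role, tissue, mean_m, mean_a, mean_oa

    def genes_with_role(self, role: str) -> list[str]:
        mask = self.table["role"] == role
        return list(self.table.loc[mask, "ref_id"])

    @property
    def conserved_up(self) -> list[str]:
        return self.genes_with_role(ROLE_UP)

    @property
    def conserved_down(self) -> list[str]:
        return self.genes_with_role(ROLE_DOWN)

    @property
    def markers(self) -> list[str]:
        return self.genes_with_role(ROLE_MARKER)

    def role_of(self, ref_id: str) -> str:
        row = self.table.loc[self.table["ref_id"] == ref_id, "role"]
        return row.iloc[0] if len(row) else ROLE_NULL


@dataclass
class SimResult:
    counts: dict[str, CountMatrix]
    lengths: GeneLengths
    orthologs: OrthologMap
    annotations: AnnotationTable
    truth: SimTruth


def _species_gene_id(species: str, ref_id: str) -> str:
    return f"{species}_{ref_id}"


def simulate_study(cfg: SimConfig) -> SimResult:
    """Draw one complete synthetic study.

    Identical configuration and seed give byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    ref_ids = [f"g{i:05d}" for i in range(1, n + 1)]

    lo, hi = cfg.baseline_mean_log_range
    base_mu = 10.0 ** rng.uniform(lo, hi, size=n)
    lengths_nt = rng.integers(500, 5001, size=n)

    # assign planted roles
    roles = np.full(n, ROLE_NULL, dtype=object)
    n_planted = cfg.n_conserved_up + cfg.n_conserved_down + cfg.n_tissue_markers
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    up_idx = planted_idx[: cfg.n_conserved_up]
    down_idx = planted_idx[cfg.n_conserved_up : cfg.n_conserved_up + cfg.n_conserved_down]
    marker_idx = planted_idx[cfg.n_conserved_up + cfg.n_conserved_down :]
    roles[up_idx] = ROLE_UP
    roles[down_idx] = ROLE_DOWN
    roles[marker_idx] = ROLE_MARKER

    # per-gene log2 fold per age step (conserved genes: everywhere)
    step_lfc = np.zeros(n)
    step_lfc[up_idx] = np.log2(cfg.conserved_fold)
    step_lfc[down_idx] = -np.log2(cfg.conserved_fold)
    marker_step_lfc = np.zeros(n)
    marker_step_lfc[marker_idx] = np.log2(cfg.marker_fold)

    # constitutive expression identity (log2 scale)
    all_tissues = sorted({ti for sp in cfg.design.species for ti in cfg.design.tissues[sp]})
    tissue_eff = {
        ti: rng.normal(0.0, cfg.tissue_effect_sd, size=n) for ti in all_tissues
    }
    species_eff = {
        sp: rng.normal(0.0, cfg.species_effect_sd, size=n) for sp in cfg.design.species
    }
    interaction_eff = {
        (sp, ti): rng.normal(0.0, cfg.interaction_sd, size=n)
        for sp in cfg.design.species
        for ti in cfg.design.tissues[sp]
    }

    age_steps = {AgeGroup.M: 0, AgeGroup.A: 1, AgeGroup.OA: 2}
    counts: dict[str, CountMatrix] = {}
    for sp in cfg.design.species:
        gene_ids = [_species_gene_id(sp, g) for g in ref_ids]
        samples: list[SampleMeta] = []
        cols: list[np.ndarray] = []
        for ti in cfg.design.tissues[sp]:
            log2_base = (
                np.log2(base_mu)
                + species_eff[sp]
                + tissue_eff[ti]
                + interaction_eff[(sp, ti)]
            )
            for age in AgeGroup:
                steps = age_steps[age]
                lfc = step_lfc.copy()
                if ti == cfg.marker_tissue:
                    lfc = lfc + marker_step_lfc
                mu_age = 2.0 ** (log2_base + steps * lfc)
                alpha = cfg.nb_dispersion * (
                    cfg.oa_cv_scale if age is AgeGroup.OA else 1.0
                )
                nb_n = 1.0 / alpha
                n_rep = cfg.design.n_replicates(sp, ti, age)
                for rep in range(1, n_rep + 1):
                    lib = 10.0 ** rng.uniform(*cfg.library_scale_log_range)
                    mu = mu_age * lib
                    p = nb_n / (nb_n + mu)
                    cols.append(rng.negative_binomial(nb_n, p))
                    samples.append(
                        SampleMeta(
                            sample_id=f"{sp}_{ti}_{age.value}_{rep}",
                            species=sp,
                            tissue=ti,
                            age_group=age,
                            replicate=rep,
                        )
                    )
        counts[sp] = CountMatrix(gene_ids, samples, np.column_stack(cols))

    # gene lengths identical across orthologues
    lengths = GeneLengths(
        {
            _species_gene_id(sp, g): int(l)
            for sp in cfg.design.species
            for g, l in zip(ref_ids, lengths_nt)
        }
    )

    ortho_table = pd.DataFrame(
        {sp: [_species_gene_id(sp, g) for g in ref_ids] for sp in cfg.design.species},
        index=pd.Index(ref_ids, name="ref_id"),
    )
    orthologs = OrthologMap(ortho_table)

    # annotations: planted roles get their diagnostic label; null genes get
    # one or two labels drawn from the shipped vocabulary
    annotations: dict[str, set[str]] = {}
    vocab = list(PROCESS_VOCABULARY)
    n_labels = rng.integers(1, 3, size=n)
    for i, g in enumerate(ref_ids):
        if roles[i] in ROLE_LABELS:
            annotations[g] = {ROLE_LABELS[roles[i]]}
        else:
            picks = rng.choice(len(vocab), size=n_labels[i], replace=False)
            annotations[g] = {vocab[j] for j in picks}
    annotation_table = AnnotationTable(annotations, vocabulary=PROCESS_VOCABULARY)

    fold = np.where(
        roles == ROLE_UP,
        cfg.conserved_fold,
        np.where(roles == ROLE_DOWN, 1.0 / cfg.conserved_fold, 1.0),
    )
    truth_frame = pd.DataFrame(
        {
            "ref_id": ref_ids,
            "role": roles,
            "tissue": np.where(roles == ROLE_MARKER, cfg.marker_tissue, ""),
            "mean_m": base_mu,
            "mean_a": base_mu * np.where(roles == ROLE_MARKER, cfg.marker_fold, fold),
            "mean_oa": base_mu
            * np.where(roles == ROLE_MARKER, cfg.marker_fold, fold) ** 2,
        }
    )
    return SimResult(counts, lengths, orthologs, annotation_table, SimTruth(truth_frame))


def simulate_null_pair(
    n_genes: int,
    n_per_group: int,
    mean: float,
    dispersion: float,
    seed: int,
) -> CountMatrix:
    """Two groups of NB replicates drawn from the identical law.

    Used to calibrate the type-I error of the differential-expression test;
    the groups are labelled as mature and aged samples of one tissue.
    """
    if n_genes < 1 or n_per_group < 1:
        raise ValidationError("n_genes and n_per_group must be positive")
    if mean <= 0:
        raise ValidationError("mean must be positive")
    if dispersion <= 0:
        raise ValidationError(
            "dispersion must be strictly positive (the Poisson limit is excluded)"
        )
    rng = np.random.default_rng(seed)
    nb_n = 1.0 / dispersion
    p = nb_n / (nb_n + mean)
    counts = rng.negative_binomial(nb_n, p, size=(n_genes, 2 * n_per_group))
    samples = [
        SampleMeta(
            sample_id=f"null_{age.value}_{rep}",
            species="sim",
            tissue="tissue",
            age_group=age,
            replicate=rep,
        )
        for age in (AgeGroup.M, AgeGroup.A)
        for rep in range(1, n_per_group + 1)
    ]
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    return CountMatrix(gene_ids, samples, counts)


def with_overrides(cfg: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **kwargs)
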