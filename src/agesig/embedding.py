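"""Cross-sample embedding input and cluster-separation scores.

All samples of all species are pooled into one log2(TPM + 1) matrix over the
preselected reference genes, each species contributing its own orthologue's
expression.  The quantitative form of the clustering claim — tissues and
species separate strongly while ages within a cluster barely do — is a trio
of mean silhouette coefficients; the 2-D stochastic-neighbor embedding
itself is delegated to scikit-learn and is not part of the tested contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .datatypes import OrthologMap, TPMMatrix, ValidationError

__all__ = [
    "EmbeddingInput",
    "SeparationReport",
    "build_embedding_input",
    "tsne_embed",
    "separation_scores",
]

logger = logging.getLogger(__name__)

DEFAULT_PERPLEXITY = 10.0


@dataclass
class EmbeddingInput:
    """Pooled samples × selected reference genes, log2(TPM + 1) scale."""

    sample_ids: list[str]
    species: list[str]
    tissue: list[str]
    age_group: list[str]
    gene_ids: list[str]
    matrix: np.ndarray  # samples x genes

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.gene_ids)
        df.insert(0, "age_group", self.age_group)
        df.insert(0, "tissue", self.tissue)
        df.insert(0, "species", self.species)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class SeparationReport:
    silhouette_by_tissue: float
    silhouette_by_species_tissue: float
    silhouette_by_age_within_cluster: float
    computed_on: str  # "embedding_2d" | "feature_space"


def build_embedding_input(
    tpm_by_species: Mapping[str, TPMMatrix],
    selected_genes: Sequence[str],
    orthologs: OrthologMap,
) -> EmbeddingInput:
    """Assemble the pooled expression matrix over the selected genes.

    Values are ``log2(TPM + 1)`` of each species' own orthologue; a sample of
    a species lacking some selected gene's orthologue gets a 0 fill there
    (logged once per species/gene).
    """
    genes = sorted(selected_genes)
    if not genes:
        raise ValidationError("empty gene selection; nothing to embed")
    sample_ids: list[str] = []
    species_l: list[str] = []
    tissue_l: list[str] = []
    age_l: list[str] = []
    blocks: list[np.ndarray] = []
    for sp in sorted(tpm_by_species):
        tpm = tpm_by_species[sp]
        to_sp = orthologs.reference_to_species(sp)
        gene_pos = {g: i for i, g in enumerate(tpm.gene_ids)}
        block = np.zeros((tpm.n_samples, len(genes)))
        for j, ref in enumerate(genes):
            sp_gene = to_sp.get(ref)
            if sp_gene is None or sp_gene not in gene_pos:
                logger.warning(
                    "species %s lacks orthologue of %s; filling with 0", sp, ref
                )
                continue
            block[:, j] = np.log2(tpm.tpm[gene_pos[sp_gene], :] + 1.0)
        blocks.append(block)
        sample_ids.extend(tpm.sample_ids)
        species_l.extend(s.species for s in tpm.samples)
        tissue_l.extend(s.tissue for s in tpm.samples)
        age_l.extend(s.age_group.value for s in tpm.samples)
    return EmbeddingInput(
        sample_ids, species_l, tissue_l, age_l, genes, np.vstack(blocks)
    )


def tsne_embed(
    inp: EmbeddingInput,
    seed: int = 0,
    perplexity: float = DEFAULT_PERPLEXITY,
) -> np.ndarray:
    """Seeded 2-D stochastic-neighbor embedding of the pooled matrix.

    Thin delegation to scikit-learn; the perplexity is capped below the
    sample count as the optimizer requires.
    """
    perplexity = min(perplexity, max(1.0, (inp.n_samples - 1) / 3.0))
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(inp.matrix)


def _safe_silhouette(coords: np.ndarray, labels: Sequence[str]) -> float:
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or len(classes) > len(labels) - 1 or (counts < 2).any():
        return float("nan")
    return float(silhouette_score(coords, labels, metric="euclidean"))


def separation_scores(
    inp: EmbeddingInput, embedded: np.ndarray | None = None
) -> SeparationReport:
    """Mean silhouette coefficients under three labelings.

    ``silhouette_by_tissue`` labels samples by tissue alone,
    ``silhouette_by_species_tissue`` by the species × tissue combination, and
    ``silhouette_by_age_within_cluster`` evaluates the age labeling inside
    each species × tissue cluster separately and averages the per-cluster
    scores.  Scores are computed on the 2-D embedding when provided, else on
    the feature space; an undefined labeling yields NaN, never an exception.
    """
    coords = embedded if embedded is not None else inp.matrix
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != inp.n_samples:
        raise ValidationError("coordinate rows do not match the sample count")
    tissue_labels = inp.tissue
    st_labels = [f"{sp}|{ti}" for sp, ti in zip(inp.species, inp.tissue)]
    s_tissue = _safe_silhouette(coords, tissue_labels)
    s_species_tissue = _safe_silhouette(coords, st_labels)
    per_cluster: list[float] = []
    for cluster in sorted(set(st_labels)):
        idx = [i for i, lab in enumerate(st_labels) if lab == cluster]
        score = _safe_silhouette(coords[idx], [inp.age_group[i] for i in idx])
        if not np.isnan(score):
            per_cluster.append(score)
    s_age = float(np.mean(per_cluster)) if per_cluster else float("nan")
    return SeparationReport(
        silhouette_by_tissue=s_tissue,
        silhouette_by_species_tissue=s_species_tissue,
        silhouette_by_age_within_cluster=s_age,
        computed_on="embedding_2d" if embedded is not None else "feature_space",
    )
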