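"""Core domain types for the cross-species aging-signature analysis.

Samples are bulk RNA-seq libraries annotated with species, tissue and one of
three age groups: mature (M), aged (A) and old-aged (OA).  All downstream
stages (differential expression, signature filtering, variability analysis)
operate on the validated containers defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "AgeGroup",
    "Comparison",
    "SampleMeta",
    "CountMatrix",
    "TPMMatrix",
    "GeneLengths",
    "OrthologMap",
    "AnnotationTable",
    "StudyDesign",
    "DEResultTable",
]


class ValidationError(ValueError):
    """A container invariant was violated."""


class FormatError(ValueError):
    """An input file does not conform to the expected tabular format."""


class AgeGroup(str, enum.Enum):
    """The three sampled ages: mature, aged and old-aged."""

    M = "M"
    A = "A"
    OA = "OA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Comparison(enum.Enum):
    """The three age contrasts, each an ordered (baseline, contrast) pair.

    EARLY compares mature against aged, LATE mature against old-aged and
    LONGEVITY aged against old-aged.  The contrast (older) group is always
    listed second, so a positive log2 fold change means upregulation with
    aging.
    """

    EARLY = (AgeGroup.M, AgeGroup.A)
    LATE = (AgeGroup.M, AgeGroup.OA)
    LONGEVITY = (AgeGroup.A, AgeGroup.OA)

    @property
    def baseline(self) -> AgeGroup:
        return self.value[0]

    @property
    def contrast(self) -> AgeGroup:
        return self.value[1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one RNA-seq library."""

    sample_id: str
    species: str
    tissue: str
    age_group: AgeGroup
    replicate: int

    def __post_init__(self) -> None:
        if not isinstance(self.age_group, AgeGroup):
            object.__setattr__(self, "age_group", AgeGroup(self.age_group))
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive "
                f"integer, got {self.replicate}"
            )


def _check_samples(samples: Sequence[SampleMeta]) -> None:
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            raise ValidationError(f"duplicate sample id {s.sample_id!r}")
        seen.add(s.sample_id)


def _check_gene_ids(gene_ids: Sequence[str]) -> None:
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Index(gene_ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids: {dupes[:5]}")


class _ExpressionMatrix:
    """Shared gene × sample bookkeeping for count and TPM matrices."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        values: np.ndarray,
    ) -> None:
        _check_gene_ids(gene_ids)
        _check_samples(samples)
        values = np.asarray(values)
        if values.shape != (len(gene_ids), len(samples)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        self.gene_ids: list[str] = list(gene_ids)
        self.samples: list[SampleMeta] = list(samples)
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from exc

    def sample_mask(
        self,
        tissue: str | None = None,
        age_group: AgeGroup | None = None,
    ) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if tissue is not None:
            mask &= np.array([s.tissue == tissue for s in self.samples])
        if age_group is not None:
            age_group = AgeGroup(age_group)
            mask &= np.array([s.age_group == age_group for s in self.samples])
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": [s.species for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "age_group": [s.age_group.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


class CountMatrix(_ExpressionMatrix):
    """Integer gene × sample read counts for one species."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integral; refusing to coerce")
        if counts.size and counts.min() < 0:
            g, s = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise ValidationError(
                f"negative count at gene {gene_ids[g]!r}, sample "
                f"{samples[s].sample_id!r}"
            )
        super().__init__(gene_ids, samples, counts.astype(np.int64))

    @property
    def counts(self) -> np.ndarray:
        return self.values

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            self.gene_ids, [self.samples[i] for i in idx], self.values[:, idx]
        )


class TPMMatrix(_ExpressionMatrix):
    """Transcripts-per-million matrix; every column with signal sums to 1e6."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        tpm: np.ndarray,
    ) -> None:
        tpm = np.asarray(tpm, dtype=float)
        if tpm.size and tpm.min() < 0:
            raise ValidationError("TPM values must be non-negative")
        super().__init__(gene_ids, samples, tpm)
        col_sums = tpm.sum(axis=0) if tpm.size else np.array([])
        nonzero = col_sums > 0
        if nonzero.any() and not np.allclose(
            col_sums[nonzero], 1e6, rtol=1e-9, atol=0
        ):
            raise ValidationError("non-empty TPM columns must sum to 1e6")

    @property
    def tpm(self) -> np.ndarray:
        return self.values

    def subset_samples(self, mask: np.ndarray) -> "TPMMatrix":
        idx = np.flatnonzero(mask)
        return TPMMatrix(
            self.gene_ids, [self.samples[i] for i in idx], self.values[:, idx]
        )


class GeneLengths(Mapping[str, int]):
    """Per-gene transcript length in nucleotides, used for TPM."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        self._lengths = {str(g): int(l) for g, l in lengths.items()}
        bad = [g for g, l in self._lengths.items() if l <= 0]
        if bad:
            raise ValidationError(f"non-positive gene length for {bad[:5]}")

    def __getitem__(self, gene: str) -> int:
        return self._lengths[gene]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def as_array(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._lengths]
        if missing:
            raise ValidationError(f"missing gene length for {missing[:5]}")
        return np.array([self._lengths[g] for g in gene_ids], dtype=float)


class OrthologMap:
    """One-to-one linkage of per-species gene ids to a reference id.

    The reference namespace follows the mouse-orthologue convention used for
    cross-species reporting.  Entries missing an orthologue in any species are
    retained but flagged incomplete.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        # table: index = reference gene id, one column per species, NaN = missing
        if table.index.has_duplicates:
            raise ValidationError("duplicate reference gene ids in ortholog map")
        for sp in table.columns:
            col = table[sp].dropna()
            if col.duplicated().any():
                dup = sorted(col[col.duplicated()].unique())
                raise ValidationError(
                    f"species {sp!r}: gene id(s) {dup[:3]} mapped to more than "
                    "one reference gene (one-to-one violation)"
                )
        self.table = table
        self.species: list[str] = list(table.columns)

    @property
    def reference_ids(self) -> list[str]:
        return list(self.table.index)

    def is_complete(self, ref_id: str) -> bool:
        return bool(self.table.loc[ref_id].notna().all())

    @property
    def complete_ids(self) -> list[str]:
        mask = self.table.notna().all(axis=1)
        return list(self.table.index[mask])

    def species_to_reference(self, species: str) -> dict[str, str]:
        """Map species gene id -> reference gene id."""
        col = self.table[species].dropna()
        return {v: k for k, v in col.items()}

    def reference_to_species(self, species: str) -> dict[str, str]:
        col = self.table[species].dropna()
        return dict(col.items())

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)


class AnnotationTable:
    """Reference gene -> set of biological-process labels.

    A gene may carry several labels (e.g. both senescence and apoptosis);
    labels must come from the declared controlled vocabulary.
    """

    def __init__(
        self,
        annotations: Mapping[str, Iterable[str]],
        vocabulary: Iterable[str] | None = None,
    ) -> None:
        self.annotations: dict[str, frozenset[str]] = {
            g: frozenset(labels) for g, labels in annotations.items()
        }
        used = set().union(*self.annotations.values()) if self.annotations else set()
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else used
        stray = used - self.vocabulary
        if stray:
            raise ValidationError(
                f"annotation labels outside the controlled vocabulary: "
                f"{sorted(stray)[:5]}"
            )

    def labels_for(self, ref_id: str) -> frozenset[str]:
        return self.annotations.get(ref_id, frozenset())

    def __len__(self) -> int:
        return len(self.annotations)


# canonical process vocabulary shipped with the simulator
PROCESS_VOCABULARY = (
    "immune/inflammatory response",
    "senescence",
    "apoptosis",
    "oxidative stress response",
    "cell cycle",
    "other",
)


@dataclass
class StudyDesign:
    """Which (species, tissue, age group) cells exist and their replicate counts.

    Not every species contributes every tissue; missing combinations are
    explicit and skipped downstream.
    """

    species: list[str]
    tissues: dict[str, list[str]]  # species -> available tissues
    replicates: dict[tuple[str, str, AgeGroup], int] = field(default_factory=dict)

    @classmethod
    def balanced(
        cls,
        species: Sequence[str],
        tissues: Sequence[str],
        n_replicates: int,
    ) -> "StudyDesign":
        reps = {
            (sp, ti, age): n_replicates
            for sp in species
            for ti in tissues
            for age in AgeGroup
        }
        return cls(list(species), {sp: list(tissues) for sp in species}, reps)

    def cells(self) -> list[tuple[str, str]]:
        """All available (species, tissue) combinations."""
        return [(sp, ti) for sp in self.species for ti in self.tissues[sp]]

    def n_replicates(self, species: str, tissue: str, age: AgeGroup) -> int:
        return self.replicates.get((species, tissue, AgeGroup(age)), 0)

    def validate(self) -> None:
        for sp in self.species:
            if sp not in self.tissues:
                raise ValidationError(f"species {sp!r} has no tissue list")
        for (sp, ti, age), n in self.replicates.items():
            if n < 0:
                raise ValidationError(f"negative replicate count for {(sp, ti, age)}")

    def variance_eligible(self, species: str, tissue: str) -> bool:
        """True when all three age groups carry >= 2 replicates."""
        return all(self.n_replicates(species, tissue, a) >= 2 for a in AgeGroup)


DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "p_value", "fdr"]


@dataclass
class DEResultTable:
    """Per-gene differential-expression results for one (species, tissue,
    comparison) cell: log2 fold change (contrast over baseline), Wald p-value
    and BH-adjusted FDR."""

    species: str
    tissue: str
    comparison: Comparison
    table: pd.DataFrame  # columns DE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"DE table missing columns {missing}")
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValidationError("DE table has duplicate gene rows")
        for col in ("p_value", "fdr"):
            vals = t[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValidationError(f"{col} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.tissue, self.comparison.name)

    def degs(self, fdr_cut: float = 0.05) -> list[str]:
        mask = self.table["fdr"].to_numpy(dtype=float) < fdr_cut
        return list(self.table.loc[mask, "gene_id"])
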