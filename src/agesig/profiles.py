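"""Dominant biological process per (species, tissue, comparison).

Each differentially expressed gene votes once for every process label it
carries; the dominant process is the label (or labels, when tied) with the
most votes.  Profiles built from very few DEGs are flagged rather than
suppressed, since they may poorly reflect the underlying age-related
processes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .datatypes import AnnotationTable, Comparison, DEResultTable, OrthologMap

__all__ = ["ProcessProfile", "profile_comparison", "profiles_frame"]

UNANNOTATED = "unannotated"

#: below this many DEGs a profile is flagged as low support
MIN_DEGS_DEFAULT = 5


@dataclass
class ProcessProfile:
    species: str
    tissue: str
    comparison: Comparison
    n_degs: int
    label_counts: Counter
    dominant: frozenset[str]
    low_support: bool


def profile_comparison(
    de_table: DEResultTable,
    annotations: AnnotationTable,
    orthologs: OrthologMap,
    fdr_cut: float = 0.05,
    min_degs: int = MIN_DEGS_DEFAULT,
) -> ProcessProfile:
    """Majority vote over the annotated functions of one table's DEGs.

    DEGs are mapped to the reference namespace before annotation lookup;
    genes without an annotation (or without a reference mapping) are counted
    under ``"unannotated"``.  All labels attaining the maximum count are
    dominant — ties are retained, never broken.
    """
    ref_of = orthologs.species_to_reference(de_table.species)
    degs = de_table.degs(fdr_cut)
    counts: Counter = Counter()
    for gene in degs:
        ref = ref_of.get(gene)
        labels = annotations.labels_for(ref) if ref is not None else frozenset()
        if labels:
            counts.update(labels)
        else:
            counts[UNANNOTATED] += 1
    if counts:
        top = max(counts.values())
        dominant = frozenset(lab for lab, c in counts.items() if c == top)
    else:
        dominant = frozenset()
    return ProcessProfile(
        species=de_table.species,
        tissue=de_table.tissue,
        comparison=de_table.comparison,
        n_degs=len(degs),
        label_counts=counts,
        dominant=dominant,
        low_support=len(degs) < min_degs,
    )


def profiles_frame(profiles: Iterable[ProcessProfile]) -> pd.DataFrame:
    rows = [
        {
            "species": p.species,
            "tissue": p.tissue,
            "comparison": p.comparison.name,
            "n_degs": p.n_degs,
            "dominant": ";".join(sorted(p.dominant)),
            "low_support": p.low_support,
            "label_counts": ";".join(
                f"{lab}={c}" for lab, c in sorted(p.label_counts.items())
            ),
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "tissue", "comparison", "n_degs", "dominant",
                 "low_support", "label_counts"],
    )
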