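"""Gene preselection and the conserved / tissue-specific signature filters.

A gene qualifies in one (species, tissue) cell when it is significantly
differentially expressed in at least one of the three age comparisons and
changes in the same direction by at least a minimum fold (10% by default) in
every other comparison.  A conserved signature is a gene whose qualifying
cells span at least three species and three tissues; tissue-specific markers
use the same rule at a stricter 25% fold in exactly one tissue of a species
group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import Comparison, DEResultTable, OrthologMap, ValidationError

__all__ = [
    "GeneSelection",
    "SignatureCall",
    "TissueMarkerCall",
    "OverlapResult",
    "preselect_genes",
    "qualifies_in_cell",
    "conserved_signatures",
    "tissue_specific_markers",
    "common_deg_overlap",
]

logger = logging.getLogger(__name__)

REASON_MISSING_ORTHOLOG = "missing_ortholog"
REASON_NEVER_DE = "never_de"


@dataclass
class GeneSelection:
    """Outcome of the ortholog + ever-DE preselection."""

    initial: set[str]
    selected: list[str]
    excluded: dict[str, str]  # reference gene -> exclusion reason

    def __post_init__(self) -> None:
        if set(self.selected) | set(self.excluded) != self.initial:
            raise ValidationError("selection does not partition the initial list")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref_id": g, "selected": g not in self.excluded,
             "reason": self.excluded.get(g, "")}
            for g in sorted(self.initial)
        ]
        return pd.DataFrame(rows, columns=["ref_id", "selected", "reason"])


@dataclass
class SignatureCall:
    """One reference gene, one direction, and its supporting cells."""

    ref_id: str
    direction: str  # "up" | "down"
    supporting_cells: frozenset[tuple[str, str]]
    conserved: bool = field(init=False)
    species_count: int = field(init=False)
    tissue_count: int = field(init=False)
    min_species: int = 3
    min_tissues: int = 3

    def __post_init__(self) -> None:
        self.species_count = len({sp for sp, _ in self.supporting_cells})
        self.tissue_count = len({ti for _, ti in self.supporting_cells})
        self.conserved = (
            self.species_count >= self.min_species
            and self.tissue_count >= self.min_tissues
        )


@dataclass
class TissueMarkerCall:
    """A gene qualifying in one tissue for every species of a group."""

    ref_id: str
    tissue: str
    direction: str
    group: str
    supporting_species: frozenset[str]
    exclusive: bool


@dataclass
class OverlapResult:
    """Per-species DEG sets (reference namespace) and their intersections."""

    tissue: str
    species_sets: dict[str, set[str]]
    intersection_counts: dict[tuple[str, ...], int]


def preselect_genes(
    initial: Iterable[str],
    orthologs: OrthologMap,
    de_tables: Sequence[DEResultTable],
    fdr_cut: float = 0.05,
) -> GeneSelection:
    """Keep genes with a complete orthologue set that were differentially
    expressed at least once anywhere; record the exclusion reason otherwise
    (missing orthologue checked first)."""
    initial = set(initial)
    # reference ids that were ever significant in any table
    ever_de: set[str] = set()
    by_species_ref: dict[str, dict[str, str]] = {}
    for de in de_tables:
        ref_of = by_species_ref.setdefault(
            de.species, orthologs.species_to_reference(de.species)
        )
        for g in de.degs(fdr_cut):
            ref = ref_of.get(g)
            if ref is not None:
                ever_de.add(ref)
    selected: list[str] = []
    excluded: dict[str, str] = {}
    for gene in sorted(initial):
        if gene not in orthologs or not orthologs.is_complete(gene):
            excluded[gene] = REASON_MISSING_ORTHOLOG
            if gene not in orthologs:
                logger.warning("gene %s absent from the ortholog map", gene)
        elif gene not in ever_de:
            excluded[gene] = REASON_NEVER_DE
        else:
            selected.append(gene)
    return GeneSelection(initial, selected, excluded)


def qualifies_in_cell(
    rows: Mapping[Comparison, tuple[float, float]],
    min_change: float = 0.10,
    fdr_cut: float = 0.05,
) -> str | None:
    """Evaluate the consistency rule for one gene in one (species, tissue).

    ``rows`` maps each comparison to ``(log2fc, fdr)``.  The gene qualifies
    *up* when some comparison is significant (fdr < cut) with a positive fold
    change and every other comparison changes upward by at least the minimum
    fold (``log2fc >= log2(1 + min_change)``); *down* is symmetric.  Returns
    ``"up"``, ``"down"`` or ``None``; never both.
    """
    if not 0 < min_change < 1:
        raise ValidationError("min_change must lie in (0, 1)")
    thr = np.log2(1.0 + min_change)
    comps = list(rows)
    for sign, name in ((1.0, "up"), (-1.0, "down")):
        for c in comps:
            lfc_c, fdr_c = rows[c]
            if fdr_c < fdr_cut and sign * lfc_c > 0:
                others_ok = all(
                    sign * rows[o][0] >= thr for o in comps if o is not c
                )
                if others_ok:
                    return name
    return None


def _cell_lookup(
    de_tables: Sequence[DEResultTable],
) -> dict[tuple[str, str], dict[Comparison, dict[str, tuple[float, float]]]]:
    """(species, tissue) -> comparison -> gene -> (log2fc, fdr)."""
    out: dict[tuple[str, str], dict[Comparison, dict[str, tuple[float, float]]]] = {}
    for de in de_tables:
        cell = out.setdefault((de.species, de.tissue), {})
        genes = de.table["gene_id"].to_numpy()
        lfc = de.table["log2fc"].to_numpy(dtype=float)
        fdr = de.table["fdr"].to_numpy(dtype=float)
        cell[de.comparison] = {g: (l, f) for g, l, f in zip(genes, lfc, fdr)}
    return out


def _gene_cell_rows(
    cells, orthologs: OrthologMap, ref_id: str
) -> dict[tuple[str, str], dict[Comparison, tuple[float, float]]]:
    """Collect the three comparison rows of one reference gene per cell."""
    out: dict[tuple[str, str], dict[Comparison, tuple[float, float]]] = {}
    for (sp, ti), comps in cells.items():
        sp_gene = orthologs.reference_to_species(sp).get(ref_id)
        if sp_gene is None:
            continue
        rows = {}
        complete = True
        for comp in Comparison:
            table = comps.get(comp)
            if table is None or sp_gene not in table:
                complete = False
                break
            rows[comp] = table[sp_gene]
        if complete:
            out[(sp, ti)] = rows
        else:
            logger.debug("cell (%s, %s): gene %s lacks a comparison row, skipped",
                         sp, ti, ref_id)
    return out


def conserved_signatures(
    de_tables: Sequence[DEResultTable],
    selection: GeneSelection,
    orthologs: OrthologMap,
    min_change: float = 0.10,
    fdr_cut: float = 0.05,
    min_species: int = 3,
    min_tissues: int = 3,
) -> list[SignatureCall]:
    """Evaluate the consistency rule in every cell for each selected gene and
    call a direction conserved when its supporting cells span at least
    ``min_species`` species and ``min_tissues`` tissues.  Directions are
    evaluated independently; a gene split between directions is conserved
    only if one direction alone meets the span criterion."""
    cells = _cell_lookup(de_tables)
    calls: list[SignatureCall] = []
    for ref_id in selection.selected:
        support: dict[str, set[tuple[str, str]]] = {"up": set(), "down": set()}
        for cell, rows in _gene_cell_rows(cells, orthologs, ref_id).items():
            direction = qualifies_in_cell(rows, min_change, fdr_cut)
            if direction is not None:
                support[direction].add(cell)
        for direction in ("up", "down"):
            if support[direction]:
                calls.append(
                    SignatureCall(
                        ref_id,
                        direction,
                        frozenset(support[direction]),
                        min_species=min_species,
                        min_tissues=min_tissues,
                    )
                )
    return calls


def tissue_specific_markers(
    de_tables: Sequence[DEResultTable],
    selection: GeneSelection,
    orthologs: OrthologMap,
    tissue_groups: Mapping[str, Sequence[str]] | None = None,
    min_change: float = 0.25,
    fdr_cut: float = 0.05,
) -> list[TissueMarkerCall]:
    """Tissue-exclusive markers within species groups.

    A gene is a marker for tissue ``t`` within group ``G`` when it qualifies
    (at the stricter marker fold) with one direction in ``t`` for *every*
    species of ``G`` and in no other tissue for *any* species of ``G``;
    exclusivity is judged at the same threshold.
    """
    cells = _cell_lookup(de_tables)
    all_species = sorted({sp for sp, _ in cells})
    if tissue_groups is None:
        tissue_groups = {"all": all_species}
    calls: list[TissueMarkerCall] = []
    for ref_id in selection.selected:
        gene_rows = _gene_cell_rows(cells, orthologs, ref_id)
        qualifications = {
            cell: qualifies_in_cell(rows, min_change, fdr_cut)
            for cell, rows in gene_rows.items()
        }
        for group_name, members in tissue_groups.items():
            members = list(members)
            tissues_by_species = {
                sp: {ti for (s, ti) in cells if s == sp} for sp in members
            }
            group_tissues = sorted(set().union(*tissues_by_species.values()))
            for tissue in group_tissues:
                lacking = [sp for sp in members if tissue not in tissues_by_species[sp]]
                if lacking:
                    logger.debug(
                        "group %s: species %s lack tissue %s; (%s, %s) skipped",
                        group_name, lacking, tissue, ref_id, tissue,
                    )
                    continue
                directions = {qualifications.get((sp, tissue)) for sp in members}
                if len(directions) != 1 or None in directions:
                    continue
                (direction,) = directions
                other_hits = [
                    (sp, ti)
                    for (sp, ti), d in qualifications.items()
                    if sp in members and ti != tissue and d is not None
                ]
                calls.append(
                    TissueMarkerCall(
                        ref_id=ref_id,
                        tissue=tissue,
                        direction=direction,
                        group=group_name,
                        supporting_species=frozenset(members),
                        exclusive=not other_hits,
                    )
                )
    return calls


def common_deg_overlap(
    de_tables: Sequence[DEResultTable],
    tissue: str,
    orthologs: OrthologMap,
    fdr_cut: float = 0.05,
) -> OverlapResult:
    """Per-species DEG sets of one tissue (union over the three comparisons,
    mapped to reference ids) and every intersection cardinality."""
    species_sets: dict[str, set[str]] = {}
    for de in de_tables:
        if de.tissue != tissue:
            continue
        ref_of = orthologs.species_to_reference(de.species)
        refs = {ref_of[g] for g in de.degs(fdr_cut) if g in ref_of}
        species_sets.setdefault(de.species, set()).update(refs)
    if len(species_sets) < 2:
        raise ValidationError(
            f"tissue {tissue!r}: at least 2 species are required, "
            f"found {sorted(species_sets)}"
        )
    counts: dict[tuple[str, ...], int] = {}
    names = sorted(species_sets)
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(species_sets[sp] for sp in combo))
            counts[combo] = len(inter)
    return OverlapResult(tissue, species_sets, counts)


def signature_calls_frame(calls: Sequence[SignatureCall]) -> pd.DataFrame:
    rows = [
        {
            "ref_id": c.ref_id,
            "direction": c.direction,
            "species_count": c.species_count,
            "tissue_count": c.tissue_count,
            "conserved": c.conserved,
            "supporting_cells": ";".join(
                f"{sp}:{ti}" for sp, ti in sorted(c.supporting_cells)
            ),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_id", "direction", "species_count", "tissue_count",
            "conserved", "supporting_cells",
        ],
    )


def marker_calls_frame(calls: Sequence[TissueMarkerCall]) -> pd.DataFrame:
    rows = [
        {
            "ref_id": c.ref_id,
            "tissue": c.tissue,
            "direction": c.direction,
            "group": c.group,
            "supporting_species": ";".join(sorted(c.supporting_species)),
            "exclusive": c.exclusive,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["ref_id", "tissue", "direction", "group",
                 "supporting_species", "exclusive"],
    )
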