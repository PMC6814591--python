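import itertools

import numpy as np
import pandas as pd
import pytest

from agesig.datatypes import Comparison, DEResultTable, OrthologMap, ValidationError
from agesig.signatures import (
    GeneSelection,
    common_deg_overlap,
    conserved_signatures,
    preselect_genes,
    qualifies_in_cell,
    tissue_specific_markers,
)

LOG2_1_1 = np.log2(1.1)


# ---------------------------------------------------------------------------
# independent brute-force oracles, coded directly from the textual rule
# ---------------------------------------------------------------------------

def oracle_qualifies(rows, min_change, fdr_cut):
    """A gene qualifies in a direction if some comparison is significant with
    that sign and every OTHER comparison moves the same way by >= the minimum
    fold."""
    comps = list(rows)
    thr = np.log2(1 + min_change)
    for direction, sgn in (("up", 1), ("down", -1)):
        for c in comps:
            lfc, fdr = rows[c]
            if not (fdr < fdr_cut and sgn * lfc > 0):
                continue
            if all(sgn * rows[o][0] >= thr for o in comps if o != c):
                return direction
    return None


def oracle_conserved(per_gene_cells, min_change, fdr_cut, min_species, min_tissues):
    """gene -> {direction: (cells, conserved)} by direct rule evaluation."""
    out = {}
    for gene, cells in per_gene_cells.items():
        for direction in ("up", "down"):
            cset = {
                cell
                for cell, rows in cells.items()
                if oracle_qualifies(rows, min_change, fdr_cut) == direction
            }
            if cset:
                n_sp = len({sp for sp, _ in cset})
                n_ti = len({ti for _, ti in cset})
                out[(gene, direction)] = (
                    cset, n_sp >= min_species and n_ti >= min_tissues
                )
    return out


def make_de_tables(per_gene_cells):
    """Build DEResultTable objects (species gene namespace = reference) from
    gene -> cell -> comparison -> (lfc, fdr)."""
    cells = sorted({c for g in per_gene_cells.values() for c in g})
    tables = []
    for sp, ti in cells:
        for comp in Comparison:
            rows = []
            for gene, gcells in per_gene_cells.items():
                if (sp, ti) in gcells and comp in gcells[(sp, ti)]:
                    lfc, fdr = gcells[(sp, ti)][comp]
                    rows.append(
                        {"gene_id": f"{sp}_{gene}", "base_mean": 10.0,
                         "log2fc": lfc, "p_value": fdr, "fdr": fdr}
                    )
            if rows:
                tables.append(DEResultTable(sp, ti, comp, pd.DataFrame(rows)))
    return tables


def identity_orthologs(genes, species):
    table = pd.DataFrame(
        {sp: [f"{sp}_{g}" for g in genes] for sp in species},
        index=pd.Index(genes, name="ref_id"),
    )
    return OrthologMap(table)


def full_selection(genes):
    return GeneSelection(set(genes), sorted(genes), {})


class TestQualifiesInCell:
    def rows(self, early, late, longevity):
        return {
            Comparison.EARLY: early,
            Comparison.LATE: late,
            Comparison.LONGEVITY: longevity,
        }

    def test_up_call_above_ten_percent_threshold(self):
        rows = self.rows((0.8, 0.01), (0.5, 0.5), (0.14, 0.5))
        assert qualifies_in_cell(rows) == "up"  # 0.14 >= log2(1.1) = 0.1375...

    def test_boundary_just_below_threshold_fails(self):
        rows = self.rows((0.8, 0.01), (0.5, 0.5), (0.10, 0.5))
        assert qualifies_in_cell(rows) is None  # 0.10 < 0.1375

    def test_down_is_symmetric(self):
        rows = self.rows((-0.8, 0.01), (-0.5, 0.5), (-0.14, 0.5))
        assert qualifies_in_cell(rows) == "down"

    def test_significant_comparison_needs_only_sign(self):
        # the significant comparison itself may move by less than the fold
        rows = self.rows((0.05, 0.01), (0.5, 0.5), (0.2, 0.5))
        assert qualifies_in_cell(rows) == "up"

    def test_no_significant_comparison_fails(self):
        rows = self.rows((0.8, 0.2), (0.5, 0.2), (0.5, 0.2))
        assert qualifies_in_cell(rows) is None

    def test_invalid_min_change_rejected(self):
        with pytest.raises(ValidationError):
            qualifies_in_cell(self.rows((1, 0.01), (1, 0.5), (1, 0.5)), min_change=0.0)

    def test_exhaustive_grid_matches_brute_force(self):
        lfc_grid = [-0.5, -0.2, -0.1, 0.0, 0.1, 0.2, 0.5]
        fdr_grid = [0.01, 0.2]
        n_checked = 0
        for lfcs in itertools.product(lfc_grid, repeat=3):
            for fdrs in itertools.product(fdr_grid, repeat=3):
                rows = {
                    comp: (lfc, fdr)
                    for comp, lfc, fdr in zip(Comparison, lfcs, fdrs)
                }
                assert qualifies_in_cell(rows) == oracle_qualifies(rows, 0.10, 0.05)
                n_checked += 1
        assert n_checked == 7**3 * 2**3

    def test_direction_exclusivity_on_random_instances(self, rng):
        # implementation never returns both; oracle agrees on 500 instances
        for _ in range(500):
            rows = {
                comp: (rng.normal(0, 0.5), rng.uniform(0, 0.3))
                for comp in Comparison
            }
            got = qualifies_in_cell(rows)
            assert got == oracle_qualifies(rows, 0.10, 0.05)


class TestPreselect:
    def _tables(self, fdrs_by_gene):
        rows = [
            {"gene_id": f"s1_{g}", "base_mean": 5.0, "log2fc": 1.0,
             "p_value": f, "fdr": f}
            for g, f in fdrs_by_gene.items()
        ]
        return [DEResultTable("s1", "liver", Comparison.EARLY, pd.DataFrame(rows))]

    def test_selected_and_exclusion_reasons(self):
        genes = ["g1", "g2", "g3"]
        om_table = pd.DataFrame(
            {"s1": ["s1_g1", "s1_g2", None]},
            index=pd.Index(genes, name="ref_id"),
        )
        om = OrthologMap(om_table)
        tables = self._tables({"g1": 0.04, "g2": 0.06, "g3": 0.01})
        sel = preselect_genes(set(genes) | {"g9"}, om, tables, fdr_cut=0.05)
        assert sel.selected == ["g1"]
        assert sel.excluded["g2"] == "never_de"
        assert sel.excluded["g3"] == "missing_ortholog"
        assert sel.excluded["g9"] == "missing_ortholog"  # absent entirely

    def test_selection_partitions_initial(self):
        with pytest.raises(ValidationError):
            GeneSelection({"a", "b"}, ["a"], {})


class TestConservedSignatures:
    SPECIES = ["s1", "s2", "s3"]

    def _run(self, per_gene_cells, **kw):
        genes = sorted(per_gene_cells)
        tables = make_de_tables(per_gene_cells)
        om = identity_orthologs(genes, self.SPECIES)
        return conserved_signatures(tables, full_selection(genes), om, **kw)

    def strong_up(self):
        return {c: (0.8, 0.01) for c in Comparison}

    def test_span_three_species_three_tissues_is_conserved(self):
        cells = {
            ("s1", "blood"): self.strong_up(),
            ("s2", "liver"): self.strong_up(),
            ("s3", "skin"): self.strong_up(),
            ("s1", "liver"): self.strong_up(),
        }
        calls = self._run({"g1": cells})
        assert len(calls) == 1
        c = calls[0]
        assert (c.species_count, c.tissue_count, c.conserved) == (3, 3, True)

    def test_one_tissue_is_not_conserved(self):
        cells = {
            ("s1", "blood"): self.strong_up(),
            ("s2", "blood"): self.strong_up(),
            ("s3", "blood"): self.strong_up(),
        }
        calls = self._run({"g1": cells})
        assert calls[0].tissue_count == 1
        assert not calls[0].conserved

    def test_split_directions_reported_separately_unconserved(self):
        up, down = self.strong_up(), {c: (-0.8, 0.01) for c in Comparison}
        cells = {
            ("s1", "blood"): up, ("s2", "liver"): up,
            ("s3", "skin"): down, ("s1", "liver"): down,
        }
        calls = self._run({"g1": cells})
        assert {c.direction for c in calls} == {"up", "down"}
        assert not any(c.conserved for c in calls)

    def test_threshold_monotonicity(self, rng):
        # calls at the stricter 25% fold are a subset of calls at 10%
        for _ in range(50):
            cells = {
                (sp, ti): {
                    comp: (rng.normal(0, 0.6), rng.uniform(0, 0.2))
                    for comp in Comparison
                }
                for sp in self.SPECIES
                for ti in ["blood", "liver", "skin"]
            }
            loose = self._run({"g1": cells}, min_change=0.10)
            strict = self._run({"g1": cells}, min_change=0.25)
            loose_cells = {
                (c.direction, cell) for c in loose for cell in c.supporting_cells
            }
            strict_cells = {
                (c.direction, cell) for c in strict for cell in c.supporting_cells
            }
            assert strict_cells <= loose_cells

    def test_matches_brute_force_on_500_random_instances(self, rng):
        tissues = ["blood", "liver", "skin"]
        for _ in range(500):
            n_genes = int(rng.integers(1, 21))
            genes = [f"g{i}" for i in range(n_genes)]
            per_gene = {}
            for g in genes:
                cells = {}
                for sp in self.SPECIES:
                    for ti in tissues:
                        if rng.random() < 0.8:
                            cells[(sp, ti)] = {
                                comp: (
                                    float(rng.normal(0, 0.6)),
                                    float(rng.uniform(0, 0.2)),
                                )
                                for comp in Comparison
                            }
                per_gene[g] = cells
            got = {
                (c.ref_id, c.direction): (set(c.supporting_cells), c.conserved)
                for c in self._run(per_gene)
            }
            expected = oracle_conserved(per_gene, 0.10, 0.05, 3, 3)
            assert got == expected


class TestTissueMarkers:
    SPECIES = ["s1", "s2", "s3"]

    def _run(self, per_gene_cells, groups=None, **kw):
        genes = sorted(per_gene_cells)
        tables = make_de_tables(per_gene_cells)
        om = identity_orthologs(genes, self.SPECIES)
        return tissue_specific_markers(
            tables, full_selection(genes), om, tissue_groups=groups, **kw
        )

    def strong(self, sign=1.0):
        return {c: (sign * 0.8, 0.01) for c in Comparison}

    def weak(self):
        return {c: (0.01, 0.9) for c in Comparison}

    def test_exclusive_liver_marker(self):
        cells = {(sp, "liver"): self.strong() for sp in self.SPECIES}
        cells.update({(sp, "skin"): self.weak() for sp in self.SPECIES})
        calls = self._run({"g1": cells})
        assert len(calls) == 1
        assert calls[0].tissue == "liver"
        assert calls[0].exclusive

    def test_extra_tissue_hit_breaks_exclusivity(self):
        cells = {(sp, "liver"): self.strong() for sp in self.SPECIES}
        cells[("s2", "skin")] = self.strong()
        for sp in ("s1", "s3"):
            cells[(sp, "skin")] = self.weak()
        calls = self._run({"g1": cells})
        liver = [c for c in calls if c.tissue == "liver"]
        assert liver and not liver[0].exclusive

    def test_one_species_missing_qualification_blocks_marker(self):
        cells = {(sp, "liver"): self.strong() for sp in ("s1", "s2")}
        cells[("s3", "liver")] = self.weak()
        assert self._run({"g1": cells}) == []

    def test_species_groups_evaluated_separately(self):
        # qualifies in the fishes group only
        cells = {
            ("s1", "skin"): self.weak(),
            ("s2", "skin"): self.strong(),
            ("s3", "skin"): self.strong(),
            ("s1", "liver"): self.weak(),
            ("s2", "liver"): self.weak(),
            ("s3", "liver"): self.weak(),
        }
        groups = {"mammals": ["s1"], "fishes": ["s2", "s3"]}
        calls = self._run({"g1": cells}, groups=groups)
        assert [(c.group, c.tissue, c.exclusive) for c in calls] == [
            ("fishes", "skin", True)
        ]

    def test_marker_threshold_is_stricter(self):
        # 20% change qualifies at the 10% rule but not at the 25% marker rule
        cells = {
            (sp, "liver"): {c: (np.log2(1.20), 0.01) for c in Comparison}
            for sp in self.SPECIES
        }
        assert self._run({"g1": cells}, min_change=0.25) == []
        assert self._run({"g1": cells}, min_change=0.10) != []


class TestCommonDEGOverlap:
    def _tables(self, degs_by_species, tissue="liver"):
        tables = []
        genes = sorted({g for s in degs_by_species.values() for g in s} | {"gX"})
        for sp, degs in degs_by_species.items():
            rows = [
                {"gene_id": f"{sp}_{g}", "base_mean": 5.0, "log2fc": 1.0,
                 "p_value": 0.01 if g in degs else 0.9,
                 "fdr": 0.01 if g in degs else 0.9}
                for g in genes
            ]
            tables.append(DEResultTable(sp, tissue, Comparison.EARLY, pd.DataFrame(rows)))
        om = identity_orthologs(genes, sorted(degs_by_species))
        return tables, om

    def test_pairwise_intersection(self):
        tables, om = self._tables({"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"}})
        res = common_deg_overlap(tables, "liver", om)
        assert res.species_sets["s1"] == {"a", "b", "c"}
        assert res.intersection_counts[("s1", "s2")] == 2

    def test_disjoint_sets(self):
        tables, om = self._tables({"s1": {"a"}, "s2": {"b"}})
        res = common_deg_overlap(tables, "liver", om)
        assert res.intersection_counts[("s1", "s2")] == 0

    def test_single_species_rejected(self):
        tables, om = self._tables({"s1": {"a"}})
        with pytest.raises(ValidationError, match="2 species"):
            common_deg_overlap(tables, "liver", om)

    def test_matches_set_algebra_on_three_species(self, rng):
        genes = [f"g{i}" for i in range(30)]
        degs = {
            sp: set(rng.choice(genes, size=rng.integers(0, 20), replace=False))
            for sp in ("s1", "s2", "s3")
        }
        tables, om = self._tables(degs)
        res = common_deg_overlap(tables, "liver", om)
        for combo, n in res.intersection_counts.items():
            assert n == len(set.intersection(*(degs[sp] for sp in combo)))
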