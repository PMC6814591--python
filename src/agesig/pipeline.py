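"""End-to-end orchestration: simulate → DE → signatures → CV → profiles →
embedding, as one reproducible, seeded run writing all results to a single
run directory."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from . import io as asio
from .datatypes import AgeGroup, DEResultTable, TPMMatrix, ValidationError
from .embedding import build_embedding_input, separation_scores, tsne_embed
from .expression import run_de, tpm_normalize
from .profiles import ProcessProfile, profile_comparison, profiles_frame
from .signatures import (
    GeneSelection,
    SignatureCall,
    TissueMarkerCall,
    conserved_signatures,
    marker_calls_frame,
    preselect_genes,
    signature_calls_frame,
    tissue_specific_markers,
)
from .simulate import SimConfig, SimResult, SimTruth, simulate_study
from .variability import CVComparison, compare_cv, compute_cv, cv_comparisons_frame

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "recovery_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, seed and stage toggles of one pipeline run.

    Defaults are the analysis' canonical values: FDR 0.05, a 10% minimum
    fold for conserved signatures, 25% for tissue markers, support spanning
    at least 3 species and 3 tissues, and a 5-DEG floor for process
    profiles.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    fdr_cut: float = 0.05
    min_change: float = 0.10
    marker_min_change: float = 0.25
    min_species: int = 3
    min_tissues: int = 3
    min_degs: int = 5
    seed: int = 0
    tissue_groups: dict[str, list[str]] | None = None
    run_embedding: bool = True
    run_tsne: bool = False
    tsne_perplexity: float = 10.0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if not 0 < self.fdr_cut < 1:
            raise ValidationError("fdr_cut must lie in (0, 1)")
        if not 0 < self.min_change < 1 or not 0 < self.marker_min_change < 1:
            raise ValidationError("fold thresholds must lie in (0, 1)")
        if self.min_change > self.marker_min_change:
            raise ValidationError(
                "min_change must not exceed marker_min_change: the marker "
                "filter is the stricter one"
            )
        if self.min_species < 1 or self.min_tissues < 1:
            raise ValidationError("span thresholds must be positive")

    def resolved(self) -> dict[str, object]:
        out: dict[str, object] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "sim":
                for sf in dataclasses.fields(SimConfig):
                    if sf.name == "design":
                        continue
                    out[f"sim.{sf.name}"] = getattr(v, sf.name)
            elif f.name not in ("out_dir", "tissue_groups"):
                out[f.name] = v
        return out


@dataclass
class RunSummary:
    """Counts and in-memory results of one run."""

    n_genes: int
    n_selected: int
    n_excluded_missing_ortholog: int
    n_excluded_never_de: int
    n_conserved_up: int
    n_conserved_down: int
    n_markers_by_tissue: dict[str, int]
    cv_directions: dict[tuple[str, str], str]
    elapsed: dict[str, float]
    # stage outputs
    de_tables: list[DEResultTable]
    selection: GeneSelection
    conserved_calls: list[SignatureCall]
    marker_calls: list[TissueMarkerCall]
    cv_comparisons: list[CVComparison]
    profiles: list[ProcessProfile]
    separation: object | None
    truth: SimTruth | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_genes", self.n_genes),
            ("n_selected", self.n_selected),
            ("n_excluded_missing_ortholog", self.n_excluded_missing_ortholog),
            ("n_excluded_never_de", self.n_excluded_never_de),
            ("n_conserved_up", self.n_conserved_up),
            ("n_conserved_down", self.n_conserved_down),
        ]
        rows += [
            (f"n_markers_{ti}", n) for ti, n in sorted(self.n_markers_by_tissue.items())
        ]
        rows += [
            (f"cv_direction_{sp}_{ti}", d)
            for (sp, ti), d in sorted(self.cv_directions.items())
        ]
        rows += [(f"elapsed_{st}", round(v, 3)) for st, v in self.elapsed.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


def run_pipeline(cfg: RunConfig, sim_result: SimResult | None = None) -> RunSummary:
    """Execute all enabled stages in dependency order.

    When ``sim_result`` is not supplied, the study is simulated from
    ``cfg.sim`` with ``cfg.seed`` overriding its seed.  Identical inputs,
    configuration and seed give identical summaries.  When ``cfg.out_dir``
    is set, every stage output plus the resolved configuration is written
    there.
    """
    cfg.validate()
    elapsed: dict[str, float] = {}
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if sim_result is None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        sim_result = simulate_study(sim_cfg)
    data = sim_result
    elapsed["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d genes, %d species", len(data.truth.table),
                len(data.counts))

    # differential expression per species
    t0 = time.perf_counter()
    de_tables: list[DEResultTable] = []
    for sp in sorted(data.counts):
        de_tables.extend(run_de(data.counts[sp], data.lengths, fdr_cut=cfg.fdr_cut))
    elapsed["de"] = time.perf_counter() - t0
    logger.info("de: %d result tables", len(de_tables))

    # preselection over the full reference gene universe
    t0 = time.perf_counter()
    initial = set(data.orthologs.reference_ids)
    selection = preselect_genes(initial, data.orthologs, de_tables, cfg.fdr_cut)
    logger.info("preselect: %d of %d genes kept", len(selection.selected),
                len(initial))

    conserved = conserved_signatures(
        de_tables,
        selection,
        data.orthologs,
        min_change=cfg.min_change,
        fdr_cut=cfg.fdr_cut,
        min_species=cfg.min_species,
        min_tissues=cfg.min_tissues,
    )
    markers = tissue_specific_markers(
        de_tables,
        selection,
        data.orthologs,
        tissue_groups=cfg.tissue_groups,
        min_change=cfg.marker_min_change,
        fdr_cut=cfg.fdr_cut,
    )
    elapsed["signatures"] = time.perf_counter() - t0

    # CV analysis per (species, tissue) on the selected genes
    t0 = time.perf_counter()
    cv_comparisons: list[CVComparison] = []
    tpm_by_species: dict[str, TPMMatrix] = {}
    for sp in sorted(data.counts):
        cm = data.counts[sp]
        tpm_by_species[sp] = tpm_normalize(cm, data.lengths)
        to_sp = data.orthologs.reference_to_species(sp)
        sp_selected = {to_sp[g] for g in selection.selected if g in to_sp}
        for tissue in dict.fromkeys(s.tissue for s in cm.samples):
            tpm_sub = tpm_by_species[sp].subset_samples(
                tpm_by_species[sp].sample_mask(tissue=tissue)
            )
            cv_table = compute_cv(tpm_sub, gene_subset=sp_selected)
            cv_comparisons.append(
                compare_cv(cv_table, (AgeGroup.A, AgeGroup.OA))
            )
    elapsed["cv"] = time.perf_counter() - t0

    # functional profiles per DE table
    t0 = time.perf_counter()
    profiles = [
        profile_comparison(
            de, data.annotations, data.orthologs,
            fdr_cut=cfg.fdr_cut, min_degs=cfg.min_degs,
        )
        for de in de_tables
    ]
    elapsed["profiles"] = time.perf_counter() - t0

    # embedding separation
    separation = None
    if cfg.run_embedding and selection.selected:
        t0 = time.perf_counter()
        emb_in = build_embedding_input(
            tpm_by_species, selection.selected, data.orthologs
        )
        coords = (
            tsne_embed(emb_in, seed=cfg.seed, perplexity=cfg.tsne_perplexity)
            if cfg.run_tsne
            else None
        )
        separation = separation_scores(emb_in, coords)
        elapsed["embedding"] = time.perf_counter() - t0

    n_up = sum(1 for c in conserved if c.conserved and c.direction == "up")
    n_down = sum(1 for c in conserved if c.conserved and c.direction == "down")
    markers_by_tissue: dict[str, int] = {}
    for m in markers:
        if m.exclusive:
            markers_by_tissue[m.tissue] = markers_by_tissue.get(m.tissue, 0) + 1
    summary = RunSummary(
        n_genes=len(data.truth.table),
        n_selected=len(selection.selected),
        n_excluded_missing_ortholog=sum(
            1 for r in selection.excluded.values() if r == "missing_ortholog"
        ),
        n_excluded_never_de=sum(
            1 for r in selection.excluded.values() if r == "never_de"
        ),
        n_conserved_up=n_up,
        n_conserved_down=n_down,
        n_markers_by_tissue=markers_by_tissue,
        cv_directions={(c.species, c.tissue): c.direction for c in cv_comparisons},
        elapsed=elapsed,
        de_tables=de_tables,
        selection=selection,
        conserved_calls=conserved,
        marker_calls=markers,
        cv_comparisons=cv_comparisons,
        profiles=profiles,
        separation=separation,
        truth=data.truth,
    )
    if out_dir is not None:
        _write_outputs(out_dir, cfg, data, summary)
    return summary


def _write_outputs(
    out_dir: Path, cfg: RunConfig, data: SimResult, summary: RunSummary
) -> None:
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    for de in summary.de_tables:
        name = f"{de.species}_{de.tissue}_{de.comparison.name}.tsv"
        asio.write_de_table(de, de_dir / name)
    asio.write_table(summary.selection.to_frame(), out_dir / "selection.tsv")
    asio.write_table(
        signature_calls_frame(summary.conserved_calls), out_dir / "conserved.tsv"
    )
    asio.write_table(marker_calls_frame(summary.marker_calls), out_dir / "markers.tsv")
    asio.write_table(
        cv_comparisons_frame(summary.cv_comparisons), out_dir / "cv_tests.tsv"
    )
    asio.write_table(profiles_frame(summary.profiles), out_dir / "profiles.tsv")
    if summary.separation is not None:
        sep = summary.separation
        asio.write_table(
            pd.DataFrame(
                [
                    {
                        "silhouette_by_tissue": sep.silhouette_by_tissue,
                        "silhouette_by_species_tissue": sep.silhouette_by_species_tissue,
                        "silhouette_by_age_within_cluster": sep.silhouette_by_age_within_cluster,
                        "computed_on": sep.computed_on,
                    }
                ]
            ),
            out_dir / "separation.tsv",
        )
    asio.write_table(data.truth.table, out_dir / "truth.tsv")
    asio.write_table(summary.to_frame(), out_dir / "summary.tsv")
    asio.write_config(cfg.resolved(), out_dir / "run_config.txt")


def recovery_report(
    summary: RunSummary, truth: SimTruth | None = None
) -> dict[str, dict[str, float]]:
    """Sensitivity and false-call counts per planted class.

    A conserved call counts as recovered only when its direction matches the
    planted role; an exclusive-marker call only when tissue and gene match.
    ``sensitivity`` is NaN when nothing of that class was planted.
    """
    truth = truth if truth is not None else summary.truth
    if truth is None:
        raise ValidationError("recovery_report requires simulated ground truth")
    truth_genes = set(truth.table["ref_id"])
    call_genes = {c.ref_id for c in summary.conserved_calls}
    stray = call_genes - truth_genes
    if stray:
        raise ValidationError(
            f"calls refer to genes outside the simulated universe: "
            f"{sorted(stray)[:5]}"
        )

    out: dict[str, dict[str, float]] = {}
    conserved_called = {
        (c.ref_id, c.direction) for c in summary.conserved_calls if c.conserved
    }
    planted = {
        **{g: "up" for g in truth.conserved_up},
        **{g: "down" for g in truth.conserved_down},
    }
    recovered = sum(1 for g, d in planted.items() if (g, d) in conserved_called)
    false_calls = sum(
        1 for g, d in conserved_called if planted.get(g) != d
    )
    out["conserved"] = {
        "sensitivity": recovered / len(planted) if planted else float("nan"),
        "false_calls": float(false_calls),
    }

    marker_called = {
        (m.ref_id, m.tissue) for m in summary.marker_calls if m.exclusive
    }
    planted_markers = {
        (g, t)
        for g, t in zip(truth.table["ref_id"], truth.table["tissue"])
        if t != ""
    }
    m_recovered = sum(1 for key in planted_markers if key in marker_called)
    m_false = sum(1 for key in marker_called if key not in planted_markers)
    out["tissue_marker"] = {
        "sensitivity": (
            m_recovered / len(planted_markers) if planted_markers else float("nan")
        ),
        "false_calls": float(m_false),
    }
    return out
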