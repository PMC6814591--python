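"""Tab-separated readers and writers for all pipeline inputs and outputs.

One tabular dialect throughout: UTF-8 TSV, a single header line, lines
starting with ``#`` ignored on input, floats written at six significant
digits.  Every writer round-trips through the matching reader.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DE_COLUMNS,
    AgeGroup,
    AnnotationTable,
    Comparison,
    CountMatrix,
    DEResultTable,
    FormatError,
    GeneLengths,
    OrthologMap,
    SampleMeta,
    ValidationError,
)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_annotations",
    "write_annotations",
    "read_de_table",
    "write_de_table",
    "read_config",
    "write_config",
    "write_table",
]

_META_COLUMNS = ["sample_id", "species", "tissue", "age_group", "replicate"]
FLOAT_FORMAT = "%.6g"


def _read_tsv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a gene × sample count TSV plus its sample-metadata TSV.

    Samples are returned in metadata order; a sample present in one file but
    not the other is an error.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id column plus sample columns")
    gene_col = raw.columns[0]
    gene_ids = raw[gene_col].tolist()
    meta = _read_tsv(meta_path)
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"{meta_path}: missing metadata columns {missing_cols}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            species=row.species,
            tissue=row.tissue,
            age_group=AgeGroup(row.age_group),
            replicate=int(row.replicate),
        )
        for row in meta.itertuples()
    ]
    matrix_ids = list(raw.columns[1:])
    meta_ids = [s.sample_id for s in samples]
    unknown = sorted(set(meta_ids) - set(matrix_ids))
    if unknown:
        raise ValidationError(
            f"metadata lists sample(s) absent from the count matrix: {unknown}"
        )
    extra = sorted(set(matrix_ids) - set(meta_ids))
    if extra:
        raise ValidationError(
            f"count matrix contains sample(s) absent from the metadata: {extra}"
        )
    counts = np.empty((len(gene_ids), len(samples)), dtype=np.int64)
    for j, sid in enumerate(meta_ids):
        col = raw[sid]
        for i, value in enumerate(col):
            try:
                iv = int(value)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {value!r} at gene "
                    f"{gene_ids[i]!r}, sample {sid!r}"
                ) from None
            if iv < 0:
                raise FormatError(
                    f"{path}: negative count {iv} at gene {gene_ids[i]!r}, "
                    f"sample {sid!r}"
                )
            counts[i, j] = iv
    return CountMatrix(gene_ids, samples, counts)


def write_count_matrix(
    cm: CountMatrix, path: str | Path, meta_path: str | Path
) -> None:
    df = cm.to_frame().reset_index()
    _write_tsv(df, path)
    _write_tsv(cm.meta_frame(), meta_path)


def read_gene_lengths(path: str | Path) -> GeneLengths:
    df = _read_tsv(path)
    if not {"gene_id", "length_nt"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_id, length_nt")
    try:
        lengths = {r.gene_id: int(r.length_nt) for r in df.itertuples()}
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer length ({exc})") from exc
    return GeneLengths(lengths)


def write_gene_lengths(lengths: GeneLengths, path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(lengths), "length_nt": [lengths[g] for g in lengths]}
    )
    _write_tsv(df, path)


def read_ortholog_map(
    path: str | Path, species: Sequence[str] | None = None
) -> OrthologMap:
    """Read a reference-id + one-column-per-species ortholog TSV.

    Empty cells mark a missing orthologue; the row is kept but incomplete.
    """
    df = _read_tsv(path)
    if df.columns[0] != "ref_id":
        raise FormatError(f"{path}: first column must be 'ref_id'")
    if species is not None:
        missing = [sp for sp in species if sp not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing species column(s) {missing}")
        df = df[["ref_id", *species]]
    table = df.set_index("ref_id")
    return OrthologMap(table)


def write_ortholog_map(om: OrthologMap, path: str | Path) -> None:
    _write_tsv(om.table.reset_index(), path)


def read_annotations(
    path: str | Path, vocabulary: Sequence[str] | None = None
) -> AnnotationTable:
    """Read a (ref_id, label) long-format annotation TSV."""
    df = _read_tsv(path)
    if not {"ref_id", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns ref_id, label")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples():
        mapping.setdefault(row.ref_id, set()).add(row.label)
    return AnnotationTable(mapping, vocabulary=vocabulary)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    rows = [
        {"ref_id": g, "label": lab}
        for g in sorted(ann.annotations)
        for lab in sorted(ann.annotations[g])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["ref_id", "label"]), path)


_DE_FILE_COLUMNS = ["species", "tissue", "comparison", *DE_COLUMNS]


def read_de_table(path: str | Path) -> DEResultTable:
    df = _read_tsv(path)
    missing = [c for c in _DE_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing DE columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty DE table")
    keys = df[["species", "tissue", "comparison"]].drop_duplicates()
    if len(keys) != 1:
        raise FormatError(f"{path}: DE table mixes several (species,tissue,comparison)")
    species, tissue, comparison = keys.iloc[0]
    table = df[DE_COLUMNS].copy()
    for col in ("base_mean", "log2fc", "p_value", "fdr"):
        table[col] = table[col].astype(float)
    return DEResultTable(species, tissue, Comparison[comparison], table)


def write_de_table(de: DEResultTable, path: str | Path) -> None:
    df = de.table.copy()
    df.insert(0, "comparison", de.comparison.name)
    df.insert(0, "tissue", de.tissue)
    df.insert(0, "species", de.species)
    _write_tsv(df, path)


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` run-configuration file."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in cfg:
            fh.write(f"{key} = {cfg[key]}\n")


def write_table(obj: Any, path: str | Path) -> None:
    """Write any declared tabular result with a stable column order.

    Dispatches on type; DataFrames are written as-is.  Lists of dataclass-like
    records with a ``to_record`` method are serialized one row per record, an
    empty list producing a header-only file is not possible without a schema,
    so callers with possibly-empty record lists should use the specific
    writers in their own modules.
    """
    if isinstance(obj, DEResultTable):
        write_de_table(obj, path)
    elif isinstance(obj, OrthologMap):
        write_ortholog_map(obj, path)
    elif isinstance(obj, AnnotationTable):
        write_annotations(obj, path)
    elif isinstance(obj, GeneLengths):
        write_gene_lengths(obj, path)
    elif isinstance(obj, pd.DataFrame):
        _write_tsv(obj, path)
    else:
        raise TypeError(f"no writer registered for {type(obj).__name__}")


def frame_to_tsv_bytes(df: pd.DataFrame) -> bytes:
    """Serialize a frame exactly as the writers do (for byte-identity checks)."""
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return buf.getvalue().encode("utf-8")
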