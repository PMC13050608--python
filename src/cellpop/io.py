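"""Readers and writers for all on-disk representations.

Supported formats:

* AnnData ``.h5ad`` files and AnnData zarr stores — only the per-cell
  observation table (``obs``) is read; the expression matrix is never
  touched, so backed/zarr stores load fast regardless of size.
* Delimited count matrices (CSV, or TSV auto-detected from a ``.tsv``
  extension): header row = cell types, first column = sample id.
* Delimited metadata tables: first column = entity id.
* Hierarchy edge lists: two columns ``child,parent``.
* JSON view configurations (see :mod:`cellpop.render` for the schema).

Every reader/writer pair is a lossless round trip on its own output.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CellTable,
    CellTypeHierarchy,
    Dataset,
    MetadataTable,
    PopulationMatrix,
    ValueKind,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


def _delimiter_for(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith(".tsv") else ","


@dataclass(frozen=True)
class LoadSpec:
    """How to pull per-cell annotations out of a source file.

    ``sample_field`` and ``celltype_field`` name columns of the per-cell
    observation table.  Columns listed in ``metadata_fields`` are lifted to
    per-sample metadata by taking the first value per sample; a lifted column
    that is not constant within some sample is dropped with a warning.
    """

    source_path: str
    source_kind: str  # anndata_h5 | anndata_zarr | counts_delimited
    sample_field: str = "sample"
    celltype_field: str = "cell_type"
    metadata_fields: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source_kind not in ("anndata_h5", "anndata_zarr", "counts_delimited"):
            raise ValidationError(f"unknown source kind {self.source_kind!r}")
        if self.sample_field == self.celltype_field:
            raise ValidationError("sample_field and celltype_field must differ")


def _read_obs(spec: LoadSpec) -> pd.DataFrame:
    import anndata as ad

    if not os.path.exists(spec.source_path):
        raise ParseError(f"no such file or store: {spec.source_path}")
    try:
        if spec.source_kind == "anndata_h5":
            adata = ad.read_h5ad(spec.source_path)
        else:
            adata = ad.read_zarr(spec.source_path)
    except ParseError:
        raise
    except Exception as exc:  # h5py/zarr raise many concrete types
        raise ParseError(f"could not read {spec.source_path}: {exc}") from exc
    return adata.obs


def read_cells(spec: LoadSpec) -> Tuple[CellTable, MetadataTable]:
    """Load per-cell records plus lifted per-sample metadata from AnnData."""
    if spec.source_kind == "counts_delimited":
        raise ValidationError(
            "counts_delimited sources hold no per-cell records; "
            "use read_counts_delimited"
        )
    obs = _read_obs(spec)
    needed = [spec.sample_field, spec.celltype_field, *spec.metadata_fields]
    missing = [c for c in needed if c not in obs.columns]
    if missing:
        raise ParseError(
            f"missing column(s) {missing} in {spec.source_path}; "
            f"available: {sorted(obs.columns)}"
        )
    df = pd.DataFrame(
        {
            "cell_id": obs.index.astype(str),
            "sample_id": obs[spec.sample_field].astype(str).to_numpy(),
            "celltype": obs[spec.celltype_field].astype(str).to_numpy(),
        }
    )
    cells = CellTable.from_frame(df)
    if cells.n_unknown:
        logger.warning(
            "%d cells had missing/empty cell-type labels; labelled 'unknown'",
            cells.n_unknown,
        )

    sample_order = list(pd.unique(df["sample_id"]))
    meta_cols: dict = {}
    for field in spec.metadata_fields:
        vals = obs[field]
        per_sample = {}
        constant = True
        for sid, group in vals.groupby(df["sample_id"].to_numpy(), sort=False):
            uniq = group.dropna().unique()
            if len(uniq) > 1:
                constant = False
                break
            per_sample[sid] = uniq[0] if len(uniq) else None
        if not constant:
            logger.warning(
                "obs column %r is not constant within every sample; dropped", field
            )
            continue
        meta_cols[field] = [per_sample.get(s) for s in sample_order]
    meta = MetadataTable(pd.DataFrame(meta_cols, index=pd.Index(sample_order)))
    return cells, meta


# ---------------------------------------------------------------------------
# delimited count matrices


def read_counts_delimited(path: str, delimiter: Optional[str] = None) -> PopulationMatrix:
    """Read a rectangular count table: header = cell types, first col = sample."""
    delim = _delimiter_for(path, delimiter)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    col_labels = header[1:]
    if len(set(col_labels)) != len(col_labels):
        raise ParseError(f"{path}: duplicate cell-type labels in header")
    width = len(header)
    samples: List[str] = []
    values: List[List[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: row {lineno} has {len(row)} fields, expected {width}"
            )
        label = row[0]
        if label in samples:
            raise ParseError(f"{path}: row {lineno}: duplicate sample label {label!r}")
        samples.append(label)
        parsed = []
        for cell in row[1:]:
            try:
                parsed.append(int(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: row {lineno}: non-integer count {cell!r}"
                ) from None
        values.append(parsed)
    return PopulationMatrix(
        row_labels=tuple(samples),
        col_labels=tuple(col_labels),
        values=np.array(values, dtype=float),
        value_kind=ValueKind.COUNT,
    )


def write_counts_delimited(
    matrix: PopulationMatrix, path: str, delimiter: Optional[str] = None
) -> None:
    if matrix.value_kind != ValueKind.COUNT:
        raise ValidationError("only count matrices are written as count tables")
    delim = _delimiter_for(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["sample", *matrix.col_labels])
        for lab, row in zip(matrix.row_labels, matrix.values):
            writer.writerow([lab, *(int(v) for v in row)])


# ---------------------------------------------------------------------------
# metadata tables


def read_metadata_delimited(path: str, delimiter: Optional[str] = None) -> MetadataTable:
    """Read an entity-metadata table; first column is the entity id."""
    delim = _delimiter_for(path, delimiter)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, delimiter=delim, index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate entity ids")
    return MetadataTable(df)


def write_metadata_delimited(
    meta: MetadataTable, path: str, delimiter: Optional[str] = None
) -> None:
    delim = _delimiter_for(path, delimiter)
    meta.df.to_csv(path, sep=delim, index_label="id")


# ---------------------------------------------------------------------------
# hierarchy edge lists


def read_hierarchy_edges(path: str, delimiter: Optional[str] = None) -> CellTypeHierarchy:
    """Read a two-column child,parent edge list into a forest.

    An empty file yields an empty hierarchy in which every label is a root.
    Cycles and conflicting parents are rejected.
    """
    delim = _delimiter_for(path, delimiter)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    edges = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.lower() for c in row[:2]] == ["child", "parent"]:
                continue  # optional header
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected child,parent")
            edges.append((row[0].strip(), row[1].strip()))
    try:
        return CellTypeHierarchy.from_edges(edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_hierarchy_edges(
    hierarchy: CellTypeHierarchy, path: str, delimiter: Optional[str] = None
) -> None:
    delim = _delimiter_for(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["child", "parent"])
        for child in sorted(hierarchy.parent):
            writer.writerow([child, hierarchy.parent[child]])


# ---------------------------------------------------------------------------
# JSON view configs (schema lives with ViewConfig in render)


def read_config(path: str):
    """Parse a JSON view configuration; unknown keys are rejected by name."""
    from .render import ViewConfig

    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    return ViewConfig.from_dict(payload)


def write_config(config, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# whole-dataset convenience round trips


def write_atlas_anndata(
    cells: CellTable,
    path: str,
    sample_meta: Optional[MetadataTable] = None,
    kind: str = "anndata_zarr",
    sample_field: str = "sample",
    celltype_field: str = "cell_type",
) -> None:
    """Serialize a cell table (plus optional sample metadata) to an AnnData store.

    Metadata fields are broadcast onto cells so :func:`read_cells` can lift
    them back per sample.
    """
    import anndata as ad
    import warnings

    obs = pd.DataFrame(
        {
            sample_field: cells.df["sample_id"].to_numpy(),
            celltype_field: cells.df["celltype"].to_numpy(),
        },
        index=pd.Index(cells.df["cell_id"].astype(str), name="cell_id"),
    )
    if sample_meta is not None:
        for field in sample_meta.fields:
            mapping = sample_meta.df[field].to_dict()
            obs[field] = [mapping.get(s) for s in cells.df["sample_id"]]
    adata = ad.AnnData(obs=obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "anndata_zarr":
            adata.write_zarr(path)
        elif kind == "anndata_h5":
            adata.write_h5ad(path)
        else:
            raise ValidationError(f"unknown store kind {kind!r}")


def load_dataset(
    spec: LoadSpec,
    hierarchy_path: Optional[str] = None,
    sample_meta_path: Optional[str] = None,
    celltype_meta_path: Optional[str] = None,
) -> Dataset:
    """One-stop loader: cells or counts, plus optional side tables."""
    from .core import build_population_matrix

    if spec.source_kind == "counts_delimited":
        matrix = read_counts_delimited(spec.source_path)
        lifted = MetadataTable.empty(matrix.sample_labels)
    else:
        cells, lifted = read_cells(spec)
        matrix = build_population_matrix(cells)

    sample_meta = lifted
    if sample_meta_path is not None:
        extra = read_metadata_delimited(sample_meta_path)
        merged = lifted.df.join(extra.df, how="left")
        missing = set(matrix.sample_labels) - set(merged.index)
        if missing:
            raise ParseError(f"sample metadata missing entries for {sorted(missing)}")
        sample_meta = MetadataTable(merged)
    celltype_meta = (
        read_metadata_delimited(celltype_meta_path)
        if celltype_meta_path is not None
        else MetadataTable.empty(matrix.celltype_labels)
    )
    hierarchy = (
        read_hierarchy_edges(hierarchy_path) if hierarchy_path is not None else None
    )
    if hierarchy is not None and len(hierarchy.nodes) > 0:
        # labels outside the forest are treated as roots: add them
        extra_nodes = set(matrix.celltype_labels) - set(hierarchy.nodes)
        if extra_nodes:
            hierarchy = CellTypeHierarchy(
                nodes=hierarchy.nodes | extra_nodes, parent=hierarchy.parent
            )
    return Dataset(matrix, sample_meta, celltype_meta, hierarchy)
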