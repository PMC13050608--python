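"""Core data model: per-cell tables, population matrices, metadata, hierarchies.

The central object is the :class:`PopulationMatrix`, a dense samples x
cell-types matrix of counts (or values derived from counts).  A sample is one
single-cell dataset (one biological specimen); a cell type is the categorical
annotation attached to each cell.  Matrices are small (hundreds of samples by
tens of cell types), so dense storage is always safe.

Label order on construction is first-appearance order in the input; display
order is view state and is controlled by the sort operations in
:mod:`cellpop.transforms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Reserved label assigned to cells whose cell-type annotation is missing or
#: empty.  Such cells are kept (they are real cells) rather than dropped.
UNKNOWN_CELLTYPE = "unknown"


class ValueKind(str, Enum):
    """What the matrix entries mean."""

    COUNT = "count"
    FRACTION_WITHIN_SAMPLE = "fraction_within_sample"
    FRACTION_WITHIN_CELLTYPE = "fraction_within_celltype"
    LOG_COUNT = "log_count"
    LOG_FRACTION = "log_fraction"


class Orientation(str, Enum):
    """Which semantic axis the matrix rows carry."""

    SAMPLES_AS_ROWS = "samples_as_rows"
    CELLTYPES_AS_ROWS = "celltypes_as_rows"


FRACTION_KINDS = frozenset(
    {ValueKind.FRACTION_WITHIN_SAMPLE, ValueKind.FRACTION_WITHIN_CELLTYPE}
)
LOG_KINDS = frozenset({ValueKind.LOG_COUNT, ValueKind.LOG_FRACTION})


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class CellTable:
    """One record per cell: (cell_id, sample_id, celltype, extras).

    Backed by a :class:`pandas.DataFrame` with columns ``cell_id``,
    ``sample_id``, ``celltype`` plus any extra per-cell fields.  Cells whose
    cell-type label is missing or empty are assigned the reserved label
    ``"unknown"``; ``n_unknown`` reports how many, so loaders can log it.
    """

    df: pd.DataFrame
    n_unknown: int = 0

    def __post_init__(self) -> None:
        required = {"cell_id", "sample_id", "celltype"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"cell table missing columns: {sorted(missing)}")
        if len(self.df) == 0:
            raise ValidationError("cell table is empty")
        dup = self.df["cell_id"][self.df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate cell_id: {dup.iloc[0]!r}")
        for col in ("sample_id", "celltype"):
            vals = self.df[col]
            if vals.isna().any() or (vals.astype(str) == "").any():
                raise ValidationError(f"empty or missing value in {col!r}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        extra_fields: Sequence[str] = (),
    ) -> "CellTable":
        """Build from ``(cell_id, sample_id, celltype[, extras])`` tuples.

        ``extras`` is an optional mapping; keys listed in ``extra_fields``
        become columns.
        """
        rows = []
        for rec in records:
            cell_id, sample_id, celltype = rec[0], rec[1], rec[2]
            extras = rec[3] if len(rec) > 3 else {}
            row = {"cell_id": cell_id, "sample_id": sample_id, "celltype": celltype}
            for f in extra_fields:
                row[f] = extras.get(f)
            rows.append(row)
        df = pd.DataFrame(rows)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTable":
        """Build from a data frame, mapping blank cell types to ``unknown``."""
        df = df.copy()
        for col in ("cell_id", "sample_id"):
            if col in df.columns:
                df[col] = df[col].astype(str)
        ct = df["celltype"]
        blank = ct.isna() | (ct.astype(str).str.strip() == "")
        n_unknown = int(blank.sum())
        df["celltype"] = ct.astype(str).where(~blank, UNKNOWN_CELLTYPE)
        return cls(df=df.reset_index(drop=True), n_unknown=n_unknown)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class PopulationMatrix:
    """Ordered labels x labels dense matrix of counts or derived values.

    ``orientation`` records which semantic axis the rows carry so that
    sample-wise operations stay correct after a transpose.
    """

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray
    value_kind: ValueKind = ValueKind.COUNT
    orientation: Orientation = Orientation.SAMPLES_AS_ROWS

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.row_labels, "row")
        _check_unique(self.col_labels, "column")
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"matrix shape {vals.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if np.any(vals < 0):
            raise ValidationError("matrix values must be non-negative")
        if self.value_kind == ValueKind.COUNT and not np.allclose(
            vals, np.round(vals)
        ):
            raise ValidationError("count matrix must hold integers")

    # -- semantic accessors -------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def sample_axis(self) -> int:
        return 0 if self.orientation == Orientation.SAMPLES_AS_ROWS else 1

    @property
    def celltype_axis(self) -> int:
        return 1 - self.sample_axis

    @property
    def sample_labels(self) -> tuple:
        return (
            self.row_labels
            if self.orientation == Orientation.SAMPLES_AS_ROWS
            else self.col_labels
        )

    @property
    def celltype_labels(self) -> tuple:
        return (
            self.col_labels
            if self.orientation == Orientation.SAMPLES_AS_ROWS
            else self.row_labels
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def grand_total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class MetadataTable:
    """Per-entity metadata: unique entity ids, homogeneously typed fields.

    A field is either numeric or categorical (strings); missing values are
    NaN/None.  Backed by a data frame indexed by entity id.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.df.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate entity id in metadata: {dup!r}")
        df = self.df.copy()
        df.index = df.index.astype(str)
        for col in df.columns:
            s = df[col]
            if pd.api.types.is_numeric_dtype(s):
                df[col] = s.astype(float)
            else:
                # categorical: everything non-missing becomes a string
                df[col] = s.where(s.isna(), s.astype(str)).astype(object)
        object.__setattr__(self, "df", df)

    @classmethod
    def empty(cls, entity_ids: Sequence[str]) -> "MetadataTable":
        return cls(pd.DataFrame(index=pd.Index([str(e) for e in entity_ids])))

    @property
    def entity_ids(self) -> tuple:
        return tuple(self.df.index)

    @property
    def fields(self) -> tuple:
        return tuple(self.df.columns)

    def has_field(self, name: str) -> bool:
        return name in self.df.columns

    def is_numeric(self, name: str) -> bool:
        self._require(name)
        return pd.api.types.is_numeric_dtype(self.df[name])

    def values_for(self, name: str, entity_ids: Sequence[str]) -> pd.Series:
        self._require(name)
        return self.df[name].reindex([str(e) for e in entity_ids])

    def subset(self, entity_ids: Sequence[str]) -> "MetadataTable":
        return MetadataTable(self.df.loc[[str(e) for e in entity_ids]])

    def _require(self, name: str) -> None:
        if name not in self.df.columns:
            raise ValidationError(
                f"metadata field {name!r} not found; available: {sorted(self.df.columns)}"
            )


@dataclass(frozen=True)
class CellTypeHierarchy:
    """A forest over cell-type labels: child -> parent; roots are absent keys.

    Models the cell ontology relation from fine-grained types to coarser
    ancestors (CD4+ T cell -> T cell -> lymphocyte), enabling aggregation to a
    coarser granularity.
    """

    nodes: frozenset
    parent: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        parent = dict(self.parent)
        object.__setattr__(self, "parent", parent)
        all_nodes = set(self.nodes) | set(parent) | set(parent.values())
        object.__setattr__(self, "nodes", frozenset(all_nodes))
        # cycle check by walking every chain
        for start in parent:
            seen = {start}
            cur = start
            while cur in parent:
                cur = parent[cur]
                if cur in seen:
                    cycle = self._trace_cycle(cur)
                    raise ValidationError(f"hierarchy contains a cycle: {cycle}")
                seen.add(cur)

    def _trace_cycle(self, node: str) -> list:
        cycle = [node]
        cur = self.parent[node]
        while cur != node:
            cycle.append(cur)
            cur = self.parent[cur]
        return cycle

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "CellTypeHierarchy":
        """Build from (child, parent) pairs; conflicting parents are rejected."""
        parent: dict = {}
        nodes: set = set()
        for child, par in edges:
            child, par = str(child), str(par)
            if child in parent and parent[child] != par:
                raise ValidationError(
                    f"node {child!r} has conflicting parents: "
                    f"{parent[child]!r} and {par!r}"
                )
            parent[child] = par
            nodes.update((child, par))
        return cls(nodes=frozenset(nodes), parent=parent)

    @classmethod
    def empty(cls) -> "CellTypeHierarchy":
        return cls(nodes=frozenset(), parent={})

    def depth(self, node: str) -> int:
        """Root depth is 0; unknown labels are treated as roots."""
        d = 0
        cur = node
        while cur in self.parent:
            cur = self.parent[cur]
            d += 1
        return d

    def ancestor_at_depth(self, node: str, depth: int) -> str:
        """The ancestor of ``node`` at the given depth (itself if shallower)."""
        chain = [node]
        cur = node
        while cur in self.parent:
            cur = self.parent[cur]
            chain.append(cur)
        chain.reverse()  # root first
        if depth >= len(chain) - 1:
            return node
        return chain[depth]

    def roots(self) -> list:
        return sorted(n for n in self.nodes if n not in self.parent)

    def children(self, node: str) -> list:
        return sorted(c for c, p in self.parent.items() if p == node)

    def dfs_order(self) -> list:
        """Depth-first traversal of the forest, siblings alphabetical."""
        order = []

        def visit(n: str) -> None:
            order.append(n)
            for c in self.children(n):
                visit(c)

        for r in self.roots():
            visit(r)
        return order

    def order_labels(self, labels: Sequence[str]) -> list:
        """Given labels, return them in hierarchy depth-first order.

        Labels not in the forest are treated as extra roots, appended
        alphabetically after the known ones.
        """
        pos = {n: i for i, n in enumerate(self.dfs_order())}
        known = sorted((lab for lab in labels if lab in pos), key=lambda l: pos[l])
        unknown = sorted(lab for lab in labels if lab not in pos)
        return known + unknown


@dataclass(frozen=True)
class Dataset:
    """A population matrix with sample/cell-type metadata and optional hierarchy."""

    matrix: PopulationMatrix
    sample_meta: MetadataTable
    celltype_meta: MetadataTable
    hierarchy: Optional[CellTypeHierarchy] = None

    def __post_init__(self) -> None:
        missing_s = set(self.matrix.sample_labels) - set(self.sample_meta.entity_ids)
        if missing_s:
            raise ValidationError(
                f"sample metadata missing entries for: {sorted(missing_s)}"
            )
        missing_t = set(self.matrix.celltype_labels) - set(
            self.celltype_meta.entity_ids
        )
        if missing_t:
            raise ValidationError(
                f"cell-type metadata missing entries for: {sorted(missing_t)}"
            )
        if self.hierarchy is not None and len(self.hierarchy.nodes) > 0:
            outside = set(self.matrix.celltype_labels) - set(self.hierarchy.nodes)
            if outside:
                raise ValidationError(
                    f"cell types absent from hierarchy: {sorted(outside)}"
                )

    @classmethod
    def from_matrix(
        cls,
        matrix: PopulationMatrix,
        sample_meta: Optional[MetadataTable] = None,
        celltype_meta: Optional[MetadataTable] = None,
        hierarchy: Optional[CellTypeHierarchy] = None,
    ) -> "Dataset":
        if sample_meta is None:
            sample_meta = MetadataTable.empty(matrix.sample_labels)
        if celltype_meta is None:
            celltype_meta = MetadataTable.empty(matrix.celltype_labels)
        return cls(matrix, sample_meta, celltype_meta, hierarchy)

    def row_meta(self) -> MetadataTable:
        """Metadata for the current matrix rows (respects orientation)."""
        return (
            self.sample_meta
            if self.matrix.orientation == Orientation.SAMPLES_AS_ROWS
            else self.celltype_meta
        )

    def col_meta(self) -> MetadataTable:
        return (
            self.celltype_meta
            if self.matrix.orientation == Orientation.SAMPLES_AS_ROWS
            else self.sample_meta
        )

    def replace(self, **kw) -> "Dataset":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Operations


def build_population_matrix(cells: CellTable) -> PopulationMatrix:
    """Tally cells into a samples x cell-types count matrix.

    Entry (s, t) is the number of cells with sample ``s`` and cell type ``t``.
    Row/column label order is first-appearance order in the table; the sum of
    all entries equals the number of cells.
    """
    df = cells.df
    samples = list(pd.unique(df["sample_id"]))
    types = list(pd.unique(df["celltype"]))
    tab = pd.crosstab(df["sample_id"], df["celltype"])
    tab = tab.reindex(index=samples, columns=types, fill_value=0)
    return PopulationMatrix(
        row_labels=tuple(samples),
        col_labels=tuple(types),
        values=tab.to_numpy(dtype=float),
        value_kind=ValueKind.COUNT,
        orientation=Orientation.SAMPLES_AS_ROWS,
    )


def total_counts(matrix: PopulationMatrix, axis: str) -> np.ndarray:
    """Per-row or per-column cell-count totals, in label order.

    Only defined on count matrices: totals of fractions are not cell counts.
    """
    if matrix.value_kind != ValueKind.COUNT:
        raise ValidationError(
            f"total_counts requires a count matrix, got {matrix.value_kind.value}"
        )
    if axis == "rows":
        return matrix.values.sum(axis=1)
    if axis == "cols":
        return matrix.values.sum(axis=0)
    raise ValidationError(f"axis must be 'rows' or 'cols', got {axis!r}")


def presence_stats(matrix: PopulationMatrix) -> pd.DataFrame:
    """Per-cell-type presence across samples.

    Returns a frame indexed by cell type with columns ``n_samples_present``
    (samples with count > 0), ``universally_present`` and
    ``absent_everywhere``.  This is the machinery behind making absent and
    universally present cell types visually explicit.
    """
    if matrix.value_kind != ValueKind.COUNT:
        raise ValidationError(
            f"presence_stats requires a count matrix, got {matrix.value_kind.value}"
        )
    n_samples = matrix.values.shape[matrix.sample_axis]
    present = (matrix.values > 0).sum(axis=matrix.sample_axis)
    return pd.DataFrame(
        {
            "n_samples_present": present.astype(int),
            "universally_present": present == n_samples,
            "absent_everywhere": present == 0,
        },
        index=list(matrix.celltype_labels),
    )
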