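"""View transforms over a :class:`~cellpop.core.Dataset`.

Normalization, log transform, sorting, metadata filtering, grouping,
hierarchy collapse and transposition.  Every function is pure: it returns a
new ``Dataset`` and never mutates its input.

The canonical pipeline order (enforced by ``render.apply_view``) is

    filter -> group/collapse -> normalize -> log -> sort -> transpose

because grouping already-normalized fractions would be statistically wrong,
and a fixed order makes any view reproducible from its configuration.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CellTypeHierarchy,
    Dataset,
    MetadataTable,
    Orientation,
    PopulationMatrix,
    ValueKind,
    FRACTION_KINDS,
    LOG_KINDS,
)
from .errors import ValidationError


class SortKind(str, Enum):
    TOTAL_COUNT = "total_count"
    ALPHABETICAL = "alphabetical"
    METADATA_FIELD = "metadata_field"
    HIERARCHY = "hierarchy"


@dataclass(frozen=True)
class SortKey:
    """One key of a lexicographic multi-key sort on matrix rows or columns."""

    axis: str  # "rows" | "cols"
    kind: SortKind
    field: Optional[str] = None
    direction: str = "ascending"

    def __post_init__(self) -> None:
        if self.axis not in ("rows", "cols"):
            raise ValidationError(f"sort axis must be rows/cols, got {self.axis!r}")
        if self.direction not in ("ascending", "descending"):
            raise ValidationError(f"bad sort direction {self.direction!r}")
        kind = SortKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind == SortKind.METADATA_FIELD and not self.field:
            raise ValidationError("metadata_field sort key requires a field name")


class FilterMode(str, Enum):
    KEEP_VALUES = "keep_values"
    DROP_VALUES = "drop_values"
    NUMERIC_RANGE = "numeric_range"


@dataclass(frozen=True)
class FilterSpec:
    """Keep/drop rows or columns by a metadata field.

    ``values`` is a set of categories for keep/drop modes, or an inclusive
    ``(lo, hi)`` pair for ``numeric_range``.
    """

    axis: str
    field: str
    mode: FilterMode
    values: object

    def __post_init__(self) -> None:
        if self.axis not in ("rows", "cols"):
            raise ValidationError(f"filter axis must be rows/cols, got {self.axis!r}")
        mode = FilterMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode == FilterMode.NUMERIC_RANGE:
            try:
                lo, hi = self.values
                float(lo), float(hi)
            except (TypeError, ValueError):
                raise ValidationError(
                    "numeric_range filter requires (lo, hi) numeric bounds"
                ) from None
        else:
            object.__setattr__(self, "values", frozenset(str(v) for v in self.values))


# ---------------------------------------------------------------------------
# helpers


def _permute(ds: Dataset, axis: str, order: Sequence[int]) -> Dataset:
    """Reorder one matrix axis (and nothing else) by integer positions."""
    m = ds.matrix
    if axis == "rows":
        labels = tuple(m.row_labels[i] for i in order)
        values = m.values[list(order), :]
        matrix = PopulationMatrix(labels, m.col_labels, values, m.value_kind, m.orientation)
    else:
        labels = tuple(m.col_labels[i] for i in order)
        values = m.values[:, list(order)]
        matrix = PopulationMatrix(m.row_labels, labels, values, m.value_kind, m.orientation)
    return ds.replace(matrix=matrix)


def _meta_for_axis(ds: Dataset, axis: str) -> MetadataTable:
    return ds.row_meta() if axis == "rows" else ds.col_meta()


def _axis_labels(ds: Dataset, axis: str) -> tuple:
    return ds.matrix.row_labels if axis == "rows" else ds.matrix.col_labels


def _samples_on(ds: Dataset, axis: str) -> bool:
    """True if the given matrix axis currently carries the samples."""
    rows_are_samples = ds.matrix.orientation == Orientation.SAMPLES_AS_ROWS
    return rows_are_samples == (axis == "rows")


# ---------------------------------------------------------------------------
# normalization / log


def normalize(ds: Dataset, mode: str = "within_sample") -> Dataset:
    """Turn counts into fractions.

    ``within_sample`` divides each sample's vector by that sample's total
    cell count (the classical population-plot quantity); samples with zero
    cells stay all-zero.  ``within_celltype`` divides each cell type's vector
    by that type's grand total across samples, answering what share of all
    cells of a type each sample contributes.  ``none`` is the identity.

    Transforms always start from counts: re-normalizing an already normalized
    matrix is rejected.
    """
    if mode == "none":
        return ds
    m = ds.matrix
    if m.value_kind != ValueKind.COUNT:
        raise ValidationError(
            f"normalize requires a count matrix, got {m.value_kind.value}"
        )
    if mode == "within_sample":
        axis = m.celltype_axis  # sum over cell types -> per-sample totals
        kind = ValueKind.FRACTION_WITHIN_SAMPLE
    elif mode == "within_celltype":
        axis = m.sample_axis
        kind = ValueKind.FRACTION_WITHIN_CELLTYPE
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    totals = m.values.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(totals > 0, m.values / np.where(totals == 0, 1, totals), 0.0)
    matrix = PopulationMatrix(m.row_labels, m.col_labels, vals, kind, m.orientation)
    return ds.replace(matrix=matrix)


def log_transform(ds: Dataset, base: float = 10.0, pseudocount: float = 1.0) -> Dataset:
    """Elementwise v -> log_base(v + pseudocount).

    With the default pseudocount of 1, zero maps to zero, so absent
    (zero-count) cells remain exactly zero after the transform.
    """
    m = ds.matrix
    if m.value_kind in LOG_KINDS:
        raise ValidationError("matrix is already log-transformed")
    if base <= 0 or base == 1:
        raise ValidationError(f"log base must be positive and != 1, got {base}")
    if pseudocount <= 0 and np.any(m.values == 0):
        raise ValidationError(
            "pseudocount must be > 0 when zero values are present"
        )
    vals = np.log(m.values + pseudocount) / math.log(base)
    kind = (
        ValueKind.LOG_FRACTION if m.value_kind in FRACTION_KINDS else ValueKind.LOG_COUNT
    )
    matrix = PopulationMatrix(m.row_labels, m.col_labels, vals, kind, m.orientation)
    return ds.replace(matrix=matrix)


# ---------------------------------------------------------------------------
# sorting


@functools.total_ordering
class _Rev:
    """Wrapper inverting comparison, for descending components of a sort key."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __eq__(self, other):
        return self.v == other.v

    def __lt__(self, other):
        return other.v < self.v


def _key_component(ds: Dataset, key: SortKey, labels: Sequence[str]):
    """Per-label component values for one sort key, missing always last."""
    desc = key.direction == "descending"
    if key.kind == SortKind.TOTAL_COUNT:
        m = ds.matrix
        sums = m.values.sum(axis=1) if key.axis == "rows" else m.values.sum(axis=0)
        comps = [(False, -s if desc else s) for s in sums]
    elif key.kind == SortKind.ALPHABETICAL:
        comps = [(False, _Rev(lab) if desc else lab) for lab in labels]
    elif key.kind == SortKind.METADATA_FIELD:
        meta = _meta_for_axis(ds, key.axis)
        series = meta.values_for(key.field, labels)
        numeric = meta.is_numeric(key.field)
        comps = []
        for v in series:
            if pd.isna(v):
                comps.append((True, 0))  # missing sorts last either direction
            elif numeric:
                comps.append((False, -float(v) if desc else float(v)))
            else:
                comps.append((False, _Rev(str(v)) if desc else str(v)))
    elif key.kind == SortKind.HIERARCHY:
        if ds.hierarchy is None:
            raise ValidationError("hierarchy sort key requires an attached hierarchy")
        if not _samples_on(ds, key.axis):
            ordered = ds.hierarchy.order_labels(labels)
        else:
            raise ValidationError("hierarchy sort applies to the cell-type axis")
        pos = {lab: i for i, lab in enumerate(ordered)}
        comps = [(False, -pos[lab] if desc else pos[lab]) for lab in labels]
    else:  # pragma: no cover
        raise ValidationError(f"unknown sort kind {key.kind}")
    return comps


def sort(ds: Dataset, keys: Sequence[SortKey]) -> Dataset:
    """Stable lexicographic multi-key sort; first key is primary.

    Ties after all keys keep the current order (stable sort with original
    position as the final tiebreaker).  Missing metadata sorts last whatever
    the direction.  Row and column keys may be mixed; each axis is permuted
    by its own keys.
    """
    for axis in ("rows", "cols"):
        axis_keys = [k for k in keys if k.axis == axis]
        if not axis_keys:
            continue
        labels = _axis_labels(ds, axis)
        comps = [_key_component(ds, k, labels) for k in axis_keys]
        decorated = sorted(
            range(len(labels)), key=lambda i: tuple(c[i] for c in comps)
        )
        ds = _permute(ds, axis, decorated)
    return ds


def hierarchy_order(ds: Dataset) -> Dataset:
    """Convenience: order the cell-type axis by hierarchy depth-first traversal."""
    axis = "rows" if ds.matrix.orientation == Orientation.CELLTYPES_AS_ROWS else "cols"
    return sort(ds, [SortKey(axis=axis, kind=SortKind.HIERARCHY)])


# ---------------------------------------------------------------------------
# filtering


def filter(ds: Dataset, spec: FilterSpec) -> Dataset:  # noqa: A001 - spec name
    """Keep only rows/cols whose metadata satisfies ``spec``.

    Entities with a missing value in the filtered field are dropped under
    ``keep_values`` and ``numeric_range`` (they cannot be shown to satisfy
    the predicate) but kept under ``drop_values``.
    Survivor order is preserved.
    """
    meta = _meta_for_axis(ds, spec.axis)
    labels = _axis_labels(ds, spec.axis)
    series = meta.values_for(spec.field, labels)
    if spec.mode == FilterMode.NUMERIC_RANGE:
        if not meta.is_numeric(spec.field):
            raise ValidationError(
                f"numeric_range filter on non-numeric field {spec.field!r}"
            )
        lo, hi = spec.values
        mask = series.notna() & (series >= float(lo)) & (series <= float(hi))
    elif spec.mode == FilterMode.KEEP_VALUES:
        mask = series.notna() & series.astype(str).isin(spec.values)
    else:  # drop_values: missing kept
        mask = series.isna() | ~series.astype(str).isin(spec.values)
    keep = [i for i, ok in enumerate(mask.to_numpy()) if ok]
    ds = _permute(ds, spec.axis, keep)
    # subset the matching metadata table
    kept_labels = _axis_labels(ds, spec.axis)
    if _samples_on(ds, spec.axis):
        ds = ds.replace(sample_meta=ds.sample_meta.subset(kept_labels))
    else:
        ds = ds.replace(celltype_meta=ds.celltype_meta.subset(kept_labels))
    return ds


# ---------------------------------------------------------------------------
# grouping / hierarchy collapse


def group_by(ds: Dataset, axis: str, field: str) -> Dataset:
    """Merge rows (or columns) sharing a metadata category, summing counts.

    Category order is first appearance along the current label order.  The
    new metadata table carries only the grouping field.  Grouping happens on
    counts, before normalization, so the grand total is conserved exactly.
    """
    m = ds.matrix
    if m.value_kind != ValueKind.COUNT:
        raise ValidationError("group_by requires a count matrix (group before normalizing)")
    meta = _meta_for_axis(ds, axis)
    if meta.is_numeric(field):
        raise ValidationError(
            f"cannot group on numeric field {field!r}; bin it into categories first"
        )
    labels = _axis_labels(ds, axis)
    series = meta.values_for(field, labels)
    cats: list = []
    members: dict = {}
    for lab, v in zip(labels, series):
        cat = "missing" if pd.isna(v) else str(v)
        if cat not in members:
            members[cat] = []
            cats.append(cat)
        members[cat].append(lab)
    idx_of = {lab: i for i, lab in enumerate(labels)}
    rowwise = axis == "rows"
    parts = []
    for cat in cats:
        pos = [idx_of[l] for l in members[cat]]
        block = m.values[pos, :] if rowwise else m.values[:, pos]
        parts.append(block.sum(axis=0 if rowwise else 1))
    summed = np.stack(parts, axis=0 if rowwise else 1)
    if rowwise:
        matrix = PopulationMatrix(tuple(cats), m.col_labels, summed, m.value_kind, m.orientation)
    else:
        matrix = PopulationMatrix(m.row_labels, tuple(cats), summed, m.value_kind, m.orientation)
    new_meta = MetadataTable(pd.DataFrame({field: cats}, index=pd.Index(cats)))
    if _samples_on(ds, axis):
        return ds.replace(matrix=matrix, sample_meta=new_meta)
    return ds.replace(matrix=matrix, celltype_meta=new_meta)


def collapse_to_depth(ds: Dataset, depth: int) -> Dataset:
    """Replace each cell type by its hierarchy ancestor at ``depth``.

    Types whose own depth is <= ``depth`` stay themselves.  Counts of merged
    types are summed (grand total conserved) and the resulting labels are
    ordered by depth-first traversal of the hierarchy.
    """
    if ds.hierarchy is None:
        raise ValidationError("collapse_to_depth requires an attached hierarchy")
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    m = ds.matrix
    if m.value_kind != ValueKind.COUNT:
        raise ValidationError("collapse_to_depth requires a count matrix")
    hier = ds.hierarchy
    ct_axis = "rows" if m.orientation == Orientation.CELLTYPES_AS_ROWS else "cols"
    labels = _axis_labels(ds, ct_axis)
    mapped = [hier.ancestor_at_depth(lab, depth) for lab in labels]
    new_labels = hier.order_labels(list(dict.fromkeys(mapped)))
    idx = {lab: i for i, lab in enumerate(new_labels)}
    rowwise = ct_axis == "rows"
    shape = (
        (len(new_labels), m.values.shape[1]) if rowwise else (m.values.shape[0], len(new_labels))
    )
    summed = np.zeros(shape)
    for old_i, anc in enumerate(mapped):
        if rowwise:
            summed[idx[anc], :] += m.values[old_i, :]
        else:
            summed[:, idx[anc]] += m.values[:, old_i]
    if rowwise:
        matrix = PopulationMatrix(tuple(new_labels), m.col_labels, summed, m.value_kind, m.orientation)
    else:
        matrix = PopulationMatrix(m.row_labels, tuple(new_labels), summed, m.value_kind, m.orientation)
    # collapsed labels need metadata entries; keep any existing, fill the rest
    old_meta = ds.celltype_meta.df
    rows = old_meta.reindex(new_labels)
    new_meta = MetadataTable(rows)
    return ds.replace(matrix=matrix, celltype_meta=new_meta)


def transpose_view(ds: Dataset) -> Dataset:
    """Swap rows and columns; an involution (transpose o transpose = identity)."""
    m = ds.matrix
    flipped = (
        Orientation.CELLTYPES_AS_ROWS
        if m.orientation == Orientation.SAMPLES_AS_ROWS
        else Orientation.SAMPLES_AS_ROWS
    )
    matrix = PopulationMatrix(
        m.col_labels, m.row_labels, m.values.T.copy(), m.value_kind, flipped
    )
    return ds.replace(matrix=matrix)
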