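"""Seed-reproducible synthetic atlases with known ground truth.

Emulates a multi-sample single-cell atlas at the level this package consumes:
per-cell (sample, cell type) annotations, sample metadata, and a cell-type
hierarchy.  Per-sample compositions are Dirichlet-distributed, per-sample
totals log-normal, and a configurable fraction of (sample, cell type) pairs
is forced absent — structural zeros, recorded in the ground truth so tests
can distinguish them from sampling zeros.

Cells are allocated multinomially (not as independent Poissons) so each
sample's counts sum exactly to its drawn total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CellTable,
    CellTypeHierarchy,
    Dataset,
    MetadataTable,
    PopulationMatrix,
    build_population_matrix,
)
from .errors import ValidationError


@dataclass(frozen=True)
class MetadataFieldSpec:
    """One synthetic sample-metadata field.

    ``kind`` is "categorical" (draw uniformly from ``levels``) or "numeric"
    (draw uniformly from ``range``).
    """

    name: str
    kind: str
    levels: Optional[Sequence[str]] = None
    range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels:
                raise ValidationError(f"categorical field {self.name!r} needs levels")
        elif self.kind == "numeric":
            if self.range is None:
                raise ValidationError(f"numeric field {self.name!r} needs a range")
        else:
            raise ValidationError(f"metadata kind must be categorical/numeric, got {self.kind!r}")


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of one synthetic atlas.

    Defaults describe a mid-sized disease atlas: 20 samples, 12 cell types in
    a 2-level ontology, moderately uneven compositions (Dirichlet alpha 2),
    ~2000 cells per sample with 2-fold log-normal spread, and 10% of
    (sample, type) pairs structurally absent.
    """

    n_samples: int = 20
    n_celltypes: int = 12
    hierarchy_depth: int = 2
    branching: int = 4
    dirichlet_alpha: float = 2.0
    total_cells_log_mean: float = 7.6  # exp(7.6) ~ 2000 cells
    total_cells_log_sd: float = 0.7
    absent_fraction: float = 0.1
    metadata_spec: Tuple[MetadataFieldSpec, ...] = (
        MetadataFieldSpec("disease", "categorical", levels=("normal", "covid", "fibrosis")),
        MetadataFieldSpec("age", "numeric", range=(20.0, 80.0)),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_celltypes < 1:
            raise ValidationError("need at least one sample and one cell type")
        if not (0 <= self.absent_fraction < 1):
            raise ValidationError("absent_fraction must be in [0, 1)")
        if self.hierarchy_depth < 1 or self.branching < 1:
            raise ValidationError("hierarchy_depth and branching must be >= 1")
        if self.n_celltypes > self.branching**self.hierarchy_depth:
            raise ValidationError(
                f"{self.n_celltypes} cell types exceed the "
                f"{self.branching ** self.hierarchy_depth} leaves implied by "
                f"depth {self.hierarchy_depth} and branching {self.branching}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact generator bookkeeping for one atlas."""

    counts: np.ndarray  # n_samples x n_celltypes
    sample_ids: Tuple[str, ...]
    celltypes: Tuple[str, ...]
    absent_pairs: frozenset  # {(sample_id, celltype)} forced to zero
    totals: np.ndarray  # drawn per-sample totals
    cells: CellTable


def _build_hierarchy(spec: AtlasSpec) -> Tuple[CellTypeHierarchy, List[str]]:
    """Balanced forest: a single root "cell", internal groups, leaf types."""
    parent: dict = {}
    level = ["cell"]
    for d in range(1, spec.hierarchy_depth + 1):
        nxt = []
        for node in level:
            for b in range(spec.branching):
                child = (
                    f"type_{len(nxt)}" if d == spec.hierarchy_depth else f"{node}.g{b}"
                )
                parent[child] = node
                nxt.append(child)
        level = nxt
    leaves = level[: spec.n_celltypes]
    # prune unused leaves and any internal node without surviving descendants
    keep = set(leaves)
    for leaf in leaves:
        cur = leaf
        while cur in parent:
            cur = parent[cur]
            keep.add(cur)
    parent = {c: p for c, p in parent.items() if c in keep and p in keep}
    return CellTypeHierarchy(nodes=frozenset(keep), parent=parent), leaves


def generate_atlas(spec: AtlasSpec) -> Tuple[Dataset, GroundTruth]:
    """Draw one atlas; identical spec (incl. seed) gives identical output.

    One RNG stream is keyed by the seed; per-sample sub-streams are spawned
    deterministically so adding samples never reshuffles earlier ones.
    """
    root_ss = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root_ss.spawn(1)[0])
    sample_streams = root_ss.spawn(spec.n_samples + 1)[1:]

    hierarchy, celltypes = _build_hierarchy(spec)
    sample_ids = [f"sample_{i:03d}" for i in range(spec.n_samples)]
    k = spec.n_celltypes

    counts = np.zeros((spec.n_samples, k), dtype=int)
    totals = np.zeros(spec.n_samples, dtype=int)
    absent_pairs = set()
    records = []
    for si, (sid, ss) in enumerate(zip(sample_ids, sample_streams)):
        rng = np.random.default_rng(ss)
        comp = rng.dirichlet(np.full(k, spec.dirichlet_alpha))
        absent = rng.random(k) < spec.absent_fraction
        if absent.all():  # keep at least one type present per sample
            absent[rng.integers(k)] = False
        comp = np.where(absent, 0.0, comp)
        if comp.sum() == 0:  # all mass fell on absent types; spread evenly
            comp = (~absent).astype(float)
        comp = comp / comp.sum()
        n = int(np.round(rng.lognormal(spec.total_cells_log_mean, spec.total_cells_log_sd)))
        n = max(n, 1)
        draw = rng.multinomial(n, comp)
        counts[si] = draw
        totals[si] = n
        for ti, ct in enumerate(celltypes):
            if absent[ti]:
                absent_pairs.add((sid, ct))
        # expand to per-cell records (cells within a sample grouped by type)
        ci = 0
        for ti, ct in enumerate(celltypes):
            for _ in range(draw[ti]):
                records.append((f"{sid}_c{ci:05d}", sid, ct))
                ci += 1

    meta_cols: dict = {}
    for f in spec.metadata_spec:
        if f.kind == "categorical":
            meta_cols[f.name] = [
                f.levels[meta_rng.integers(len(f.levels))] for _ in sample_ids
            ]
        else:
            lo, hi = f.range
            meta_cols[f.name] = meta_rng.uniform(lo, hi, size=len(sample_ids))
    sample_meta = MetadataTable(pd.DataFrame(meta_cols, index=pd.Index(sample_ids)))

    cells = CellTable.from_records(records)
    matrix = PopulationMatrix(
        row_labels=tuple(sample_ids),
        col_labels=tuple(celltypes),
        values=counts.astype(float),
    )
    celltype_meta = MetadataTable(
        pd.DataFrame(
            {"depth": [float(hierarchy.depth(ct)) for ct in celltypes]},
            index=pd.Index(celltypes),
        )
    )
    ds = Dataset(matrix, sample_meta, celltype_meta, hierarchy)
    gt = GroundTruth(
        counts=counts,
        sample_ids=tuple(sample_ids),
        celltypes=tuple(celltypes),
        absent_pairs=frozenset(absent_pairs),
        totals=totals,
        cells=cells,
    )
    return ds, gt


def fixture_f1() -> Dataset:
    """The canonical 2-sample x 2-type worked example.

    Counts [[3, 1], [0, 2]] over samples A (covid) and B (normal) and cell
    types T and B, both children of "lymphocyte".  Small enough to verify
    every transform by hand.
    """
    matrix = PopulationMatrix(
        row_labels=("A", "B"),
        col_labels=("T", "B"),
        values=np.array([[3.0, 1.0], [0.0, 2.0]]),
    )
    sample_meta = MetadataTable(
        pd.DataFrame({"disease": ["covid", "normal"]}, index=pd.Index(["A", "B"]))
    )
    celltype_meta = MetadataTable.empty(["T", "B"])
    hierarchy = CellTypeHierarchy.from_edges([("T", "lymphocyte"), ("B", "lymphocyte")])
    return Dataset(matrix, sample_meta, celltype_meta, hierarchy)


def fixture_f1_cells() -> CellTable:
    """Per-cell table whose tally reproduces :func:`fixture_f1`'s counts."""
    return CellTable.from_records(
        [
            ("c1", "A", "T"),
            ("c2", "A", "T"),
            ("c3", "A", "T"),
            ("c4", "A", "B"),
            ("c5", "B", "B"),
            ("c6", "B", "B"),
        ]
    )
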