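# Methods

## The population matrix

The unit of analysis is the dense matrix `C` of cell counts with samples on
one axis and cell-type annotations on the other, built by tallying a per-cell
table of `(cell_id, sample_id, celltype)` records. Annotation is taken as
given (whatever algorithm or curator produced it); cells with a missing or
empty label are kept under the reserved label `unknown` rather than dropped,
and the loader reports how many. The matrix is at most hundreds of samples by
tens of cell types, so dense storage is always used; a structural distinction
between "zero cells" and "absent" is deliberately *not* kept in the matrix —
absence is count 0, surfaced through `presence_stats` and a dedicated glyph
in the renderer, so there is a single source of truth.

Label order at construction is first-appearance order in the input, which is
deterministic given the input and independent of any view; display order is
view state, owned by the sort operations.

## The transform algebra

All view transforms are pure functions `Dataset -> Dataset` and compose in a
fixed order:

    filter -> group / collapse -> normalize -> log -> sort -> transpose

The order is not arbitrary: grouping or collapsing *fractions* would average
ratios with unequal denominators, so aggregation always happens on counts;
normalization then produces either within-sample fractions (each sample's
row sums to 1 — the classical population-plot quantity; all-zero samples stay
all-zero) or within-cell-type fractions (each type's column sums to 1 —
answering what share of all cells of a type each sample contributes).
Re-normalizing an already normalized matrix is rejected: every view starts
from counts, which makes any figure reproducible from its config alone.

Numeric details:

* **Log transform**: `v -> log_b(v + pseudocount)`, default base 10 and
  pseudocount 1 so zero maps exactly to zero and absent cells stay visually
  absent after the transform. A non-positive pseudocount is rejected whenever
  zeros are present. The active transform is recorded in the figure legend so
  exports are self-describing.
* **Sorting** is a stable lexicographic multi-key sort (first key primary,
  original order as the final tiebreaker). Missing metadata sorts last
  regardless of direction — "unknown age" should never lead a view.
  Descending string keys use an inverted-comparison wrapper rather than
  negation so stability is preserved. Hierarchy order is a depth-first
  traversal of the ontology forest with siblings alphabetical (the ontology
  itself defines no sibling order).
* **Filtering** keeps or drops entities by categorical values or an inclusive
  numeric range. Entities with a missing value in the filtered field are
  dropped under `keep_values`/`numeric_range` (they cannot be shown to
  satisfy the predicate) and kept under `drop_values`.
* **Hierarchy collapse** replaces each cell type by its ancestor at the
  requested depth (itself if already at or above that depth), summing counts
  in integer arithmetic so the grand total is conserved exactly. Labels not
  present in the forest are treated as extra roots.
* **Transpose** swaps the axes and flips an orientation flag; all sample-wise
  operations consult the flag, so `normalize("within_sample")` is correct in
  either orientation and transpose is an exact involution.

Grouping on a numeric field is rejected rather than silently binned; binning
policy is a modelling choice the caller should make explicitly.

## The figure model

`layout` maps a view-applied dataset to a scene graph of panels
(heatmap, row/column sidebars, inline expanded rows, axes, legend) and marks
(`cell_rect`, `absent_glyph`, `bar_rect`, `stacked_segment`, `violin_path`,
`text`) with explicit geometry in abstract units (origin top-left, y
downward, one heatmap cell = 1×1). Layout is a pure function: identical
inputs give structurally identical models, which is what makes the render
contracts testable (exactly one mark per matrix cell, expanded-row bars
centered on their heatmap columns, stacked-segment values summing to the
entity total or to 1 in fraction mode).

Encoding choices that the underlying design leaves open:

* Heatmap color is a linear map of the (possibly log-transformed) value range
  onto a continuous scheme (default viridis). Zero-valued cells get a
  dedicated absent glyph instead of the bottom of the color ramp, because a
  very dark cell and a missing cell answer different questions.
* Categorical colors cycle a qualitative scheme (default tab10) in label
  order; per-label user overrides always win.
* Violin side panels use a Gaussian kernel density with Scott's-rule
  bandwidth over the row/column marginal, clipped to the data range, with the
  marginal's min/max/median attached to the mark; degenerate marginals
  (fewer than two distinct values) fall back to a flat slab.
* Side-panel axes follow the matrix's active transform (counts, fractions, or
  log values) and the legend records which; there is no separate sidebar
  scale.
* Interactive zoom has no meaning in a static export; its declarative
  equivalent is filtering/sorting to the region of interest in the config.

SVG export writes one element per mark with a stable id
`panel/kind/row/col`, fixed-precision coordinates and no timestamps, so
repeated exports of the same model are byte-identical. PNG export rasterizes
the same geometry with matplotlib at the requested dpi (PNG encoders embed
library-version metadata, so byte-level determinism is only promised for
SVG).

## Configuration

A `ViewConfig` is a JSON object (`schema_version: 1`). Omitted keys take the
documented defaults — the default view is the counts heatmap with total-count
bar sidebars and rows sorted by total descending; unknown keys are rejected
by name and nested errors report a JSON path. The stacked-bar preset is
`{transposed, heatmap hidden, stacked bars in the sample side panel,
within-sample normalization}`. CLI flags override config-file values, which
override defaults.

## Synthetic atlases

The generator emulates a multi-sample atlas at the level this package
consumes — it simulates *composition*, never expression. Per sample `s`:

* composition `p_s ~ Dirichlet(α·1_K)` over the `K` cell types;
* each (sample, type) pair is forced absent with probability
  `absent_fraction` (structural zeros, recorded in the ground truth;
  at least one type always stays present), and `p_s` is renormalized;
* total `N_s ~ round(LogNormal(μ, σ))`, floored at 1;
* counts `~ Multinomial(N_s, p_s)` — multinomial rather than independent
  Poissons so per-sample totals are exact and conservation tests are sharp.

The hierarchy is a balanced forest of configurable depth and branching with
the leaves as observed types; sample metadata fields are drawn uniformly
(categorical levels or a numeric range). One `SeedSequence` keyed by the seed
spawns per-sample streams, so output is reproducible and adding samples never
reshuffles earlier ones.

Defaults (20 samples, 12 types in a 2-level ontology, α = 2, ~2000 cells per
sample with 2-fold log-normal spread, 10% structural absence) describe a
mid-sized disease atlas: α = 2 gives the uneven but not degenerate
compositions typical of annotated tissue, and ~2000 cells per sample means a
truly present type essentially never draws zero cells, keeping structural and
sampling zeros distinct. What the generator does *not* emulate: annotation
noise and label mismatch between samples, batch effects, donor-level
correlation between composition and metadata, and any per-gene signal. Tests
passing on these atlases therefore validate the algebra, bookkeeping and
rendering contracts — not biological inference on real data.

Test and acceptance problem sizes are desk-scale by design: invariant suites
run over 200 atlases of 5×5 with ~30–60 cells per sample (the algebra is
size-independent, so small instances probe the same code paths), and the
end-to-end acceptance run uses a 30-sample × 14-type atlas with ~45 000
cells.

## Known limitations

* Cross-dataset label harmonization is out of scope: when two atlases
  annotate at different granularities, collapse-to-depth on a shared ontology
  is the provided mechanism, but no label mapping between vocabularies is
  attempted.
* No compositional statistics (e.g. Dirichlet-multinomial testing of
  composition differences); the package visualizes, it does not test.
* Readers cover AnnData (h5ad/zarr `obs`) and delimited text; Loom, 10x MTX
  and R containers are not supported.
* The hierarchy must be supplied explicitly as a child,parent edge list;
  ontology IDs embedded in `obs` columns are not parsed.
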