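# cellpop

Scalable cell population plots for single-cell data.

Cell population plots show how cells distribute over cell types within and
across samples. The classical form — one stacked bar per sample, one colored
segment per cell type — stops working as atlases grow: segments become tiny,
shifted baselines make lengths incomparable, and dozens of cell types exhaust
any qualitative color palette. Absent cell types (zero cells in a sample) and
universally present ones become invisible.

`cellpop` replaces the stacked bar with a composite view built around a
**sample × cell-type population matrix** `C`, where `C[s, t]` is the number
of cells in sample `s` annotated as type `t`:

* a central **heatmap** (samples as rows, cell types as columns) for overall
  trends, with zero-count cells drawn as a distinct *absent* glyph;
* any heatmap row **expandable** into an inline bar chart aligned with the
  column grid, for within-sample comparisons;
* **side panels** (bars, stacked bars, or violin/density panels) aligned with
  the rows and columns, showing totals and marginal distributions;
* a **transform algebra** over the matrix: within-sample fractions
  `C[s,t] / Σ_t C[s,t]`, within-cell-type fractions `C[s,t] / Σ_s C[s,t]`,
  log transform `log_b(v + pseudocount)`, stable multi-key sorting
  (totals, alphabetical, metadata, cell ontology order), metadata filtering,
  grouping, hierarchy collapse, and transposition;
* a **cell ontology hierarchy** (a forest, e.g. CD4+ T cell → T cell →
  lymphocyte) used for ordering and for collapsing fine-grained annotations
  to a chosen depth, with counts conserved exactly.

The traditional stacked-bar plot is recovered as a one-call preset
(`stacked_bar_preset()`): transpose, hide the heatmap, show within-sample
fractions as stacked bars.

Views are *declarative*: a JSON-serializable `ViewConfig` is turned into a
renderer-independent `FigureModel` (panels and marks with explicit geometry),
which exports to deterministic SVG (one addressable element per mark) or PNG.
This makes every pixel of a figure testable and every figure reproducible
from its config.

It is written for the scverse ecosystem: per-cell annotations are read from
AnnData `.h5ad` files or zarr stores (only the `obs` table is touched, so
multi-million-cell stores load in seconds), and also from plain delimited
count tables.

## Worked example

```python
import cellpop as cp

ds = cp.fixture_f1()                       # 2 samples x 2 cell types
print(ds.matrix.to_dataframe())
print("row totals:", cp.total_counts(ds.matrix, "rows").tolist())
print(cp.normalize(ds, "within_sample").matrix.to_dataframe())
print(cp.presence_stats(ds.matrix))
print(cp.collapse_to_depth(ds, 0).matrix.to_dataframe())

fig = cp.render_view(ds, cp.stacked_bar_preset())
cp.export_figure(fig, "stacked.svg", format="svg")
```

prints

```
     T    B
A  3.0  1.0
B  0.0  2.0
row totals: [4.0, 2.0]
      T     B
A  0.75  0.25
B  0.00  1.00
   n_samples_present  universally_present  absent_everywhere
T                  1                False              False
B                  2                 True              False
   lymphocyte
A         4.0
B         2.0
```

Sample A has 4 cells (3 T, 1 B), sample B has 2 B cells. Within-sample
normalization gives the classical stacked-bar fractions (each row sums to 1);
T cells are absent from sample B while B cells are universally present;
collapsing the hierarchy to depth 0 merges both types into their common
ancestor `lymphocyte`, conserving the 6 cells. The exported `stacked.svg`
holds one addressable `<rect>` per stacked segment — 0.75/0.25 for sample A,
0/1 for sample B — and no heatmap.

## Command line

```sh
cellpop simulate --seed 7 --out demo/              # synthetic atlas with ground truth
cellpop plot demo/atlas.zarr --out view.svg \
    --sample-meta demo/sample_meta.csv --hierarchy demo/hierarchy.csv \
    --collapse-depth 1 --normalize within_sample
cellpop plot demo/counts.csv --preset stacked-bars --out stacked.svg
cellpop convert demo/atlas.zarr --out counts.csv
```

Exit codes: 2 usage, 3 input parse, 4 config schema. Each plot writes a JSON
manifest (inputs, effective config, config hash, version) next to its output.

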