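"""Declarative figure model and exporters.

``layout`` turns a (Dataset, ViewConfig) pair into a :class:`FigureModel` — a
renderer-independent scene graph of panels and marks that tests can inspect
directly.  ``export_figure`` maps that model to SVG (one addressable element
per mark, byte-deterministic) or PNG (rasterized at the requested dpi).

Layout geometry uses abstract units with the origin at the top-left and y
increasing downward; one heatmap cell is 1x1 unit.  Exporters map abstract
units to device space.

The view composition is:

* central heatmap — samples as rows, cell types as columns (default
  orientation); zero-valued cells are drawn as a distinct absent glyph so
  absent cell types are visible at a glance;
* expandable rows — any heatmap row can be replaced inline by a bar chart
  over the columns, aligned with the column grid;
* side panels — bars, stacked bars, or violin (kernel density) panels
  aligned with the heatmap rows (right) and columns (top) showing totals or
  marginal distributions;
* legends at the bottom.

The traditional stacked-bar cell population plot is recovered by
:func:`stacked_bar_preset`: transpose, hide the heatmap, show within-sample
fractions as stacked bars in the column side panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .core import Dataset, Orientation, ValueKind, FRACTION_KINDS
from .errors import ConfigError, ValidationError
from . import transforms as tf

# ---------------------------------------------------------------------------
# ViewConfig

_SIDE_PANEL_KINDS = ("bars", "stacked_bars", "violins", "none")
_NORMALIZATIONS = ("none", "within_sample", "within_celltype")
_THEMES = ("light", "dark")
_FORMATS = ("png", "svg")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ViewConfig:
    """Declarative description of one view.

    Every field has a documented default; ``from_dict`` fills omitted keys
    and rejects unknown ones by name, so JSON configs are fully validated.
    """

    normalization: str = "none"
    log: bool = False
    log_base: float = 10.0
    log_pseudocount: float = 1.0
    show_heatmap: bool = True
    side_panel_rows: str = "bars"
    side_panel_cols: str = "bars"
    expanded_rows: Tuple[str, ...] = ()
    sort_keys: Tuple[tf.SortKey, ...] = (
        tf.SortKey(axis="rows", kind=tf.SortKind.TOTAL_COUNT, direction="descending"),
    )
    filters: Tuple[tf.FilterSpec, ...] = ()
    group_axis: str = "rows"
    group_field: Optional[str] = None
    collapse_depth: Optional[int] = None
    transposed: bool = False
    color_overrides: Dict[str, str] = field(default_factory=dict)
    heatmap_scheme: str = "viridis"
    categorical_scheme: str = "tab10"
    theme: str = "light"
    export_format: str = "svg"
    export_dpi: int = 150
    export_width: float = 800.0
    export_height: float = 600.0

    def __post_init__(self) -> None:
        if self.normalization not in _NORMALIZATIONS:
            raise ConfigError(f"normalization must be one of {_NORMALIZATIONS}")
        for name, v in (
            ("side_panel_rows", self.side_panel_rows),
            ("side_panel_cols", self.side_panel_cols),
        ):
            if v not in _SIDE_PANEL_KINDS:
                raise ConfigError(f"{name} must be one of {_SIDE_PANEL_KINDS}, got {v!r}")
        if self.theme not in _THEMES:
            raise ConfigError(f"theme must be one of {_THEMES}")
        if self.export_format not in _FORMATS:
            raise ConfigError(f"export format must be one of {_FORMATS}")
        if self.export_dpi < 72:
            raise ConfigError("export dpi must be >= 72")
        if self.group_axis not in ("rows", "cols"):
            raise ConfigError("group_axis must be rows/cols")
        object.__setattr__(self, "expanded_rows", tuple(self.expanded_rows))
        object.__setattr__(self, "sort_keys", tuple(self.sort_keys))
        object.__setattr__(self, "filters", tuple(self.filters))

    # -- JSON schema --------------------------------------------------------

    _SCALARS = {
        "normalization": str,
        "log": bool,
        "log_base": (int, float),
        "log_pseudocount": (int, float),
        "show_heatmap": bool,
        "side_panel_rows": str,
        "side_panel_cols": str,
        "group_axis": str,
        "group_field": (str, type(None)),
        "collapse_depth": (int, type(None)),
        "transposed": bool,
        "heatmap_scheme": str,
        "categorical_scheme": str,
        "theme": str,
        "export_format": str,
        "export_dpi": int,
        "export_width": (int, float),
        "export_height": (int, float),
    }

    @classmethod
    def from_dict(cls, payload: dict) -> "ViewConfig":
        if not isinstance(payload, dict):
            raise ConfigError("config must be a JSON object")
        payload = dict(payload)
        version = payload.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        kwargs: dict = {}
        for key, typ in cls._SCALARS.items():
            if key in payload:
                val = payload.pop(key)
                if typ is bool and not isinstance(val, bool):
                    raise ConfigError(f"$.{key}: expected boolean")
                if not isinstance(val, typ):
                    raise ConfigError(f"$.{key}: wrong type {type(val).__name__}")
                kwargs[key] = val
        if "expanded_rows" in payload:
            rows = payload.pop("expanded_rows")
            if not isinstance(rows, list):
                raise ConfigError("$.expanded_rows: expected a list of labels")
            kwargs["expanded_rows"] = tuple(str(r) for r in rows)
        if "color_overrides" in payload:
            co = payload.pop("color_overrides")
            if not isinstance(co, dict):
                raise ConfigError("$.color_overrides: expected an object")
            kwargs["color_overrides"] = {str(k): str(v) for k, v in co.items()}
        if "sort_keys" in payload:
            raw = payload.pop("sort_keys")
            if not isinstance(raw, list):
                raise ConfigError("$.sort_keys: expected a list")
            keys = []
            for i, item in enumerate(raw):
                try:
                    keys.append(
                        tf.SortKey(
                            axis=item.get("axis", "rows"),
                            kind=tf.SortKind(item["kind"]),
                            field=item.get("field"),
                            direction=item.get("direction", "ascending"),
                        )
                    )
                except (KeyError, ValueError, AttributeError, ValidationError) as exc:
                    raise ConfigError(f"$.sort_keys[{i}]: {exc}") from exc
            kwargs["sort_keys"] = tuple(keys)
        if "filters" in payload:
            raw = payload.pop("filters")
            if not isinstance(raw, list):
                raise ConfigError("$.filters: expected a list")
            specs = []
            for i, item in enumerate(raw):
                try:
                    mode = tf.FilterMode(item["mode"])
                    values = item["values"]
                    if mode == tf.FilterMode.NUMERIC_RANGE:
                        values = tuple(values)
                    specs.append(
                        tf.FilterSpec(
                            axis=item.get("axis", "rows"),
                            field=item["field"],
                            mode=mode,
                            values=values,
                        )
                    )
                except (KeyError, ValueError, TypeError, ValidationError) as exc:
                    raise ConfigError(f"$.filters[{i}]: {exc}") from exc
            kwargs["filters"] = tuple(specs)
        if payload:
            key = sorted(payload)[0]
            raise ConfigError(f"unknown config key: {key!r}")
        try:
            return cls(**kwargs)
        except ConfigError:
            raise

    def to_dict(self) -> dict:
        d: dict = {"schema_version": SCHEMA_VERSION}
        for key in self._SCALARS:
            d[key] = getattr(self, key)
        d["expanded_rows"] = list(self.expanded_rows)
        d["color_overrides"] = dict(self.color_overrides)
        d["sort_keys"] = [
            {
                "axis": k.axis,
                "kind": k.kind.value,
                "field": k.field,
                "direction": k.direction,
            }
            for k in self.sort_keys
        ]
        d["filters"] = [
            {
                "axis": f.axis,
                "field": f.field,
                "mode": f.mode.value,
                "values": (
                    list(f.values)
                    if f.mode == tf.FilterMode.NUMERIC_RANGE
                    else sorted(f.values)
                ),
            }
            for f in self.filters
        ]
        return d

    def replace(self, **kw) -> "ViewConfig":
        return replace(self, **kw)


def stacked_bar_preset() -> ViewConfig:
    """The traditional stacked-bar cell population plot as a preset.

    Transposed view (samples become columns), heatmap hidden, one
    within-sample-fraction stacked bar per sample in the column side panel.
    """
    return ViewConfig(
        transposed=True,
        show_heatmap=False,
        side_panel_cols="stacked_bars",
        side_panel_rows="none",
        normalization="within_sample",
    )


# ---------------------------------------------------------------------------
# FigureModel


@dataclass(frozen=True)
class Mark:
    kind: str  # cell_rect | bar_rect | stacked_segment | violin_path | absent_glyph | text
    x: float
    y: float
    width: float
    height: float
    color: str
    value: Optional[float] = None
    bound_row: Optional[str] = None
    bound_col: Optional[str] = None
    text: Optional[str] = None
    path: Optional[Tuple[Tuple[float, float], ...]] = None
    stats: Optional[Dict[str, float]] = None


@dataclass(frozen=True)
class Panel:
    panel_id: str
    kind: str  # heatmap | row_sidebar | col_sidebar | expanded_row | legend | axis
    rect: Tuple[float, float, float, float]  # x, y, w, h in abstract units
    marks: Tuple[Mark, ...]


@dataclass(frozen=True)
class FigureModel:
    panels: Tuple[Panel, ...]
    width: float
    height: float
    theme: str = "light"

    def panels_of_kind(self, kind: str) -> List[Panel]:
        return [p for p in self.panels if p.kind == kind]

    def marks_of_kind(self, kind: str) -> List[Mark]:
        return [m for p in self.panels for m in p.marks if m.kind == kind]

    def n_marks(self) -> int:
        return sum(len(p.marks) for p in self.panels)


# ---------------------------------------------------------------------------
# colors


def assign_colors(
    labels: Sequence[str],
    user_overrides: Optional[Dict[str, str]] = None,
    scheme: str = "tab10",
) -> Dict[str, str]:
    """Deterministic label -> hex color map.

    User overrides win; remaining labels cycle through the qualitative
    scheme's colors in label order.
    """
    overrides = dict(user_overrides or {})
    for lab, c in overrides.items():
        try:
            overrides[lab] = to_hex(c)
        except ValueError as exc:
            raise ValidationError(f"malformed color {c!r} for {lab!r}") from exc
    try:
        cmap = colormaps[scheme]
    except KeyError as exc:
        raise ValidationError(f"unknown color scheme {scheme!r}") from exc
    if hasattr(cmap, "colors"):
        palette = [to_hex(c) for c in cmap.colors]
    else:  # continuous scheme requested for categories: sample it
        palette = [to_hex(cmap(i / 9)) for i in range(10)]
    out = {}
    for i, lab in enumerate(labels):
        out[lab] = overrides.get(lab, palette[i % len(palette)])
    return out


def _continuous_color(value: float, vmin: float, vmax: float, scheme: str) -> str:
    cmap = colormaps[scheme]
    t = 0.0 if vmax <= vmin else (value - vmin) / (vmax - vmin)
    return to_hex(cmap(float(np.clip(t, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# apply_view: the fixed transform pipeline


def apply_view(ds: Dataset, cfg: ViewConfig) -> Dataset:
    """Compose the transforms in the canonical order.

    filter -> group/collapse -> normalize -> log -> sort -> transpose.
    """
    for spec in cfg.filters:
        ds = tf.filter(ds, spec)
    if cfg.group_field is not None:
        ds = tf.group_by(ds, cfg.group_axis, cfg.group_field)
    if cfg.collapse_depth is not None:
        ds = tf.collapse_to_depth(ds, cfg.collapse_depth)
    if cfg.normalization != "none":
        ds = tf.normalize(ds, cfg.normalization)
    if cfg.log:
        ds = tf.log_transform(ds, base=cfg.log_base, pseudocount=cfg.log_pseudocount)
    if cfg.sort_keys:
        ds = tf.sort(ds, list(cfg.sort_keys))
    if cfg.transposed:
        ds = tf.transpose_view(ds)
    return ds


# ---------------------------------------------------------------------------
# layout


_SIDEBAR_SIZE = 4.0
_GAP = 0.5
_AXIS_SIZE = 2.0
_LEGEND_H = 2.0


def _violin_path(
    values: np.ndarray, x0: float, y0: float, length: float, thickness: float, vertical: bool
) -> Tuple[Tuple[Tuple[float, float], ...], Dict[str, float]]:
    """Mirrored kernel-density outline along the panel axis.

    Scott's-rule Gaussian KDE clipped to the data range; degenerate inputs
    (fewer than two distinct values) fall back to a thin slab at full extent.
    """
    from scipy.stats import gaussian_kde

    vals = np.asarray(values, dtype=float)
    stats = {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "median": float(np.median(vals)),
    }
    lo, hi = stats["min"], stats["max"]
    grid = np.linspace(lo, hi, 33)
    if hi > lo and len(np.unique(vals)) > 1:
        kde = gaussian_kde(vals, bw_method="scott")
        dens = kde(grid)
        dens = dens / dens.max() if dens.max() > 0 else np.ones_like(dens)
    else:
        dens = np.ones_like(grid)
    span = hi - lo if hi > lo else 1.0
    pts: List[Tuple[float, float]] = []
    half = thickness / 2.0
    for g, d in zip(grid, dens):
        t = (g - lo) / span * length
        off = half * d
        pts.append((x0 + t, y0 - off) if not vertical else (x0 + off, y0 + t))
    for g, d in zip(grid[::-1], dens[::-1]):
        t = (g - lo) / span * length
        off = half * d
        pts.append((x0 + t, y0 + off) if not vertical else (x0 - off, y0 + t))
    return tuple(pts), stats


def layout(ds: Dataset, cfg: ViewConfig) -> FigureModel:
    """Deterministic scene graph for one view.

    ``ds`` must already be view-applied (see :func:`apply_view`).  Heatmap in
    the center; row sidebar right; column sidebar top; legends bottom;
    expanded rows replace their heatmap strip inline.
    """
    m = ds.matrix
    n_rows, n_cols = m.shape
    row_labels, col_labels = list(m.row_labels), list(m.col_labels)
    for lab in cfg.expanded_rows:
        if lab not in row_labels:
            raise ValidationError(f"expanded row {lab!r} not among current rows")

    vals = m.values
    vmin, vmax = float(vals.min()), float(vals.max())
    fraction_mode = m.value_kind in FRACTION_KINDS
    col_colors = assign_colors(col_labels, cfg.color_overrides, cfg.categorical_scheme)
    row_colors = assign_colors(row_labels, cfg.color_overrides, cfg.categorical_scheme)
    fg = "#111111" if cfg.theme == "light" else "#eeeeee"
    absent_fill = "#ffffff" if cfg.theme == "light" else "#1a1a1a"

    x_grid = _AXIS_SIZE  # row labels on the left
    y_grid = _AXIS_SIZE  # column labels on top
    if cfg.side_panel_cols != "none":
        y_grid += _SIDEBAR_SIZE + _GAP

    panels: List[Panel] = []
    expanded = set(cfg.expanded_rows)

    # --- column axis (labels along the top edge of the grid)
    axis_marks = [
        Mark(
            kind="text",
            x=x_grid + j + 0.5,
            y=y_grid - 0.2,
            width=1.0,
            height=_AXIS_SIZE,
            color=fg,
            bound_col=lab,
            text=lab,
        )
        for j, lab in enumerate(col_labels)
    ]
    panels.append(
        Panel("col_axis", "axis", (x_grid, y_grid - _AXIS_SIZE, n_cols, _AXIS_SIZE), tuple(axis_marks))
    )
    axis_marks = [
        Mark(
            kind="text",
            x=x_grid - 0.2,
            y=y_grid + i + 0.5,
            width=_AXIS_SIZE,
            height=1.0,
            color=fg,
            bound_row=lab,
            text=lab,
        )
        for i, lab in enumerate(row_labels)
    ]
    panels.append(
        Panel("row_axis", "axis", (0.0, y_grid, _AXIS_SIZE, n_rows), tuple(axis_marks))
    )

    # --- heatmap (skipping expanded strips)
    if cfg.show_heatmap:
        marks = []
        for i, rlab in enumerate(row_labels):
            if rlab in expanded:
                continue
            for j, clab in enumerate(col_labels):
                v = float(vals[i, j])
                if v == 0.0:
                    marks.append(
                        Mark(
                            kind="absent_glyph",
                            x=x_grid + j,
                            y=y_grid + i,
                            width=1.0,
                            height=1.0,
                            color=absent_fill,
                            value=0.0,
                            bound_row=rlab,
                            bound_col=clab,
                        )
                    )
                else:
                    marks.append(
                        Mark(
                            kind="cell_rect",
                            x=x_grid + j,
                            y=y_grid + i,
                            width=1.0,
                            height=1.0,
                            color=_continuous_color(v, vmin, vmax, cfg.heatmap_scheme),
                            value=v,
                            bound_row=rlab,
                            bound_col=clab,
                        )
                    )
        panels.append(
            Panel("heatmap", "heatmap", (x_grid, y_grid, n_cols, n_rows), tuple(marks))
        )

    # --- expanded rows: inline bar charts aligned with the column grid
    for rlab in cfg.expanded_rows:
        i = row_labels.index(rlab)
        row_vals = vals[i, :]
        peak = row_vals.max() if row_vals.max() > 0 else 1.0
        marks = []
        for j, clab in enumerate(col_labels):
            v = float(row_vals[j])
            h = 0.9 * v / peak
            marks.append(
                Mark(
                    kind="bar_rect",
                    x=x_grid + j + 0.1,
                    y=y_grid + i + (1.0 - h),
                    width=0.8,
                    height=h,
                    color=col_colors[clab],
                    value=v,
                    bound_row=rlab,
                    bound_col=clab,
                )
            )
        panels.append(
            Panel(
                f"expanded:{rlab}",
                "expanded_row",
                (x_grid, y_grid + i, float(n_cols), 1.0),
                tuple(marks),
            )
        )

    # --- side panels
    x_side = x_grid + n_cols + _GAP
    row_totals = vals.sum(axis=1)
    col_totals = vals.sum(axis=0)

    if cfg.side_panel_rows != "none":
        marks = _sidebar_marks(
            kind=cfg.side_panel_rows,
            vals=vals,
            totals=row_totals,
            labels=row_labels,
            other_labels=col_labels,
            entity_colors=row_colors,
            segment_colors=col_colors,
            origin=(x_side, y_grid),
            size=_SIDEBAR_SIZE,
            vertical_entities=True,
        )
        panels.append(
            Panel(
                "row_sidebar",
                "row_sidebar",
                (x_side, y_grid, _SIDEBAR_SIZE, float(n_rows)),
                tuple(marks),
            )
        )

    if cfg.side_panel_cols != "none":
        y_side = y_grid - _GAP - _SIDEBAR_SIZE
        marks = _sidebar_marks(
            kind=cfg.side_panel_cols,
            vals=vals.T,
            totals=col_totals,
            labels=col_labels,
            other_labels=row_labels,
            entity_colors=col_colors,
            segment_colors=row_colors,
            origin=(x_grid, y_side),
            size=_SIDEBAR_SIZE,
            vertical_entities=False,
        )
        panels.append(
            Panel(
                "col_sidebar",
                "col_sidebar",
                (x_grid, y_side, float(n_cols), _SIDEBAR_SIZE),
                tuple(marks),
            )
        )

    # --- legend (bottom): value kind, transform record, color scheme
    y_legend = y_grid + n_rows + _GAP
    scale_note = "log" if m.value_kind in (ValueKind.LOG_COUNT, ValueKind.LOG_FRACTION) else "linear"
    legend_marks = (
        Mark(
            kind="text",
            x=x_grid,
            y=y_legend + 0.8,
            width=float(n_cols),
            height=1.0,
            color=fg,
            text=f"values: {m.value_kind.value} ({scale_note} scale)",
        ),
        Mark(
            kind="text",
            x=x_grid,
            y=y_legend + 1.6,
            width=float(n_cols),
            height=1.0,
            color=fg,
            text=f"heatmap scheme: {cfg.heatmap_scheme}",
        ),
    )
    panels.append(
        Panel(
            "legend",
            "legend",
            (x_grid, y_legend, float(n_cols), _LEGEND_H),
            legend_marks,
        )
    )

    width = x_side + (_SIDEBAR_SIZE if cfg.side_panel_rows != "none" else 0.0)
    height = y_legend + _LEGEND_H
    return FigureModel(
        panels=tuple(panels), width=width, height=height, theme=cfg.theme
    )


def _sidebar_marks(
    kind: str,
    vals: np.ndarray,
    totals: np.ndarray,
    labels: Sequence[str],
    other_labels: Sequence[str],
    entity_colors: Dict[str, str],
    segment_colors: Dict[str, str],
    origin: Tuple[float, float],
    size: float,
    vertical_entities: bool,
) -> List[Mark]:
    """Marks for one side panel; entities along the heatmap edge.

    ``vals`` is oriented entities x others.  ``vertical_entities`` means one
    entity per y strip (the row sidebar); otherwise one per x strip (the
    column sidebar, where bars grow upward).
    """
    x0, y0 = origin
    marks: List[Mark] = []
    peak = totals.max() if totals.size and totals.max() > 0 else 1.0
    for i, lab in enumerate(labels):
        if kind == "bars":
            extent = size * float(totals[i]) / peak
            if vertical_entities:
                marks.append(
                    Mark(
                        kind="bar_rect",
                        x=x0,
                        y=y0 + i + 0.1,
                        width=extent,
                        height=0.8,
                        color=entity_colors[lab],
                        value=float(totals[i]),
                        bound_row=lab,
                    )
                )
            else:
                marks.append(
                    Mark(
                        kind="bar_rect",
                        x=x0 + i + 0.1,
                        y=y0 + size - extent,
                        width=0.8,
                        height=extent,
                        color=entity_colors[lab],
                        value=float(totals[i]),
                        bound_col=lab,
                    )
                )
        elif kind == "stacked_bars":
            total = float(totals[i])
            scale = size / peak
            offset = 0.0
            for j, olab in enumerate(other_labels):
                v = float(vals[i, j])
                extent = v * scale
                if vertical_entities:
                    marks.append(
                        Mark(
                            kind="stacked_segment",
                            x=x0 + offset,
                            y=y0 + i + 0.1,
                            width=extent,
                            height=0.8,
                            color=segment_colors[olab],
                            value=v,
                            bound_row=lab,
                            bound_col=olab,
                        )
                    )
                else:
                    marks.append(
                        Mark(
                            kind="stacked_segment",
                            x=x0 + i + 0.1,
                            y=y0 + size - offset - extent,
                            width=0.8,
                            height=extent,
                            color=segment_colors[olab],
                            value=v,
                            bound_col=lab,
                            bound_row=olab,
                        )
                    )
                offset += extent
        elif kind == "violins":
            row = np.asarray(vals[i, :], dtype=float)
            if vertical_entities:
                path, stats = _violin_path(
                    row, x0, y0 + i + 0.5, size, 0.8, vertical=False
                )
                marks.append(
                    Mark(
                        kind="violin_path",
                        x=x0,
                        y=y0 + i,
                        width=size,
                        height=1.0,
                        color=entity_colors[lab],
                        bound_row=lab,
                        path=path,
                        stats=stats,
                    )
                )
            else:
                path, stats = _violin_path(
                    row, x0 + i + 0.5, y0, size, 0.8, vertical=True
                )
                marks.append(
                    Mark(
                        kind="violin_path",
                        x=x0 + i,
                        y=y0,
                        width=1.0,
                        height=size,
                        color=entity_colors[lab],
                        bound_col=lab,
                        path=path,
                        stats=stats,
                    )
                )
        else:  # pragma: no cover
            raise ValidationError(f"unknown side panel kind {kind!r}")
    return marks


def render_view(ds: Dataset, cfg: ViewConfig) -> FigureModel:
    """Convenience: apply_view then layout."""
    return layout(apply_view(ds, cfg), cfg)


# ---------------------------------------------------------------------------
# export


_PX_PER_UNIT = 12.0


def _fmt(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _mark_ids(fig: FigureModel) -> List[Tuple[str, Mark]]:
    """Stable unique id per mark: panel/kind/row/col (+ ordinal on collision)."""
    seen: Dict[str, int] = {}
    out = []
    for panel in fig.panels:
        for mark in panel.marks:
            base = "/".join(
                [
                    panel.panel_id,
                    mark.kind,
                    mark.bound_row if mark.bound_row is not None else "-",
                    mark.bound_col if mark.bound_col is not None else "-",
                ]
            )
            n = seen.get(base, 0)
            seen[base] = n + 1
            out.append((base if n == 0 else f"{base}/{n}", mark))
    return out


def figure_to_svg(fig: FigureModel) -> str:
    """Deterministic SVG 1.1 text: one addressable element per mark."""
    s = _PX_PER_UNIT
    w, h = fig.width * s, fig.height * s
    bg = "#ffffff" if fig.theme == "light" else "#111111"
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<rect width="{_fmt(w)}" height="{_fmt(h)}" fill="{bg}"/>',
    ]
    for mark_id, mk in _mark_ids(fig):
        mid = mark_id.replace('"', "'")
        if mk.kind == "text":
            txt = (mk.text or "").replace("&", "&amp;").replace("<", "&lt;")
            lines.append(
                f'<text id="{mid}" x="{_fmt(mk.x * s)}" y="{_fmt(mk.y * s)}" '
                f'font-size="{_fmt(0.7 * s)}" fill="{mk.color}">{txt}</text>'
            )
        elif mk.kind == "violin_path":
            pts = " ".join(f"{_fmt(px * s)},{_fmt(py * s)}" for px, py in mk.path)
            lines.append(
                f'<polygon id="{mid}" points="{pts}" fill="{mk.color}" '
                f'fill-opacity="0.7" stroke="{mk.color}"/>'
            )
        elif mk.kind == "absent_glyph":
            x, y = mk.x * s, mk.y * s
            cw, ch = mk.width * s, mk.height * s
            lines.append(
                f'<g id="{mid}"><rect x="{_fmt(x)}" y="{_fmt(y)}" '
                f'width="{_fmt(cw)}" height="{_fmt(ch)}" fill="{mk.color}" '
                f'stroke="#cccccc" stroke-width="0.5"/>'
                f'<line x1="{_fmt(x + 0.3 * cw)}" y1="{_fmt(y + 0.5 * ch)}" '
                f'x2="{_fmt(x + 0.7 * cw)}" y2="{_fmt(y + 0.5 * ch)}" '
                f'stroke="#bbbbbb" stroke-width="0.8"/></g>'
            )
        else:  # cell_rect, bar_rect, stacked_segment
            lines.append(
                f'<rect id="{mid}" x="{_fmt(mk.x * s)}" y="{_fmt(mk.y * s)}" '
                f'width="{_fmt(mk.width * s)}" height="{_fmt(mk.height * s)}" '
                f'fill="{mk.color}"/>'
            )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def export_figure(fig: FigureModel, path: str, format: str = "svg", dpi: int = 150) -> None:
    """Write the figure to ``path`` as SVG or PNG.

    SVG output is byte-deterministic for a given model (no timestamps) and
    carries a stable ``id`` per mark.  PNG rasterizes the same geometry with
    matplotlib at the requested dpi.
    """
    if format == "svg":
        svg = figure_to_svg(fig)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(svg)
        return
    if format != "png":
        raise ValidationError(f"unsupported export format {format!r}")
    _export_png(fig, path, dpi)


def _export_png(fig: FigureModel, path: str, dpi: int) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon, Rectangle

    bg = "#ffffff" if fig.theme == "light" else "#111111"
    fig_w = max(fig.width / 8.0, 2.0)
    fig_h = max(fig.height / 8.0, 2.0)
    f, ax = plt.subplots(figsize=(fig_w, fig_h))
    f.patch.set_facecolor(bg)
    ax.set_facecolor(bg)
    ax.set_xlim(0, fig.width)
    ax.set_ylim(fig.height, 0)  # y grows downward
    ax.axis("off")
    for _, mk in _mark_ids(fig):
        if mk.kind == "text":
            ax.text(mk.x, mk.y, mk.text or "", fontsize=7, color=mk.color)
        elif mk.kind == "violin_path":
            ax.add_patch(Polygon(list(mk.path), closed=True, facecolor=mk.color, alpha=0.7))
        elif mk.kind == "absent_glyph":
            ax.add_patch(
                Rectangle(
                    (mk.x, mk.y), mk.width, mk.height,
                    facecolor=mk.color, edgecolor="#cccccc", linewidth=0.5,
                )
            )
            ax.plot(
                [mk.x + 0.3 * mk.width, mk.x + 0.7 * mk.width],
                [mk.y + 0.5 * mk.height] * 2,
                color="#bbbbbb", linewidth=0.8,
            )
        else:
            ax.add_patch(
                Rectangle((mk.x, mk.y), mk.width, mk.height, facecolor=mk.color)
            )
    f.savefig(path, dpi=dpi, facecolor=bg)
    plt.close(f)
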