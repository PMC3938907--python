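"""Lasagne-plot geometry and rendering, plus probability-tree diagrams.

The lasagne plot shows one stacked bar per wave, partitioned by current
category (colour) and, within category, by full trajectory group, with
connector bands between adjacent bars sized by the number of subjects
flowing between categories.  The testable core is :class:`FlowLayout` — the
computed band rectangles and inter-wave flows, which obey exact conservation
laws — while rendering is a thin matplotlib layer over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless; rendering is file-output only

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon, Rectangle

from .data_model import CategoricalPanel, restrict_complete_cases
from .marginal_models import MarginalTable, marginal_table
from .transition_models import ProbabilityTree, TreeNode

__all__ = [
    "Band",
    "Flow",
    "FlowLayout",
    "PlotStyle",
    "compute_flow_layout",
    "render_lasagne",
    "render_subgroup",
    "render_probability_tree",
]

# Okabe-Ito colour-blind-safe qualitative palette
_PALETTE = (
    "#0072B2", "#E69F00", "#009E73", "#D55E00",
    "#CC79A7", "#56B4E9", "#F0E442", "#999999",
)

MAX_PLOT_LEVELS = 8


@dataclass(frozen=True)
class Band:
    """One trajectory group's rectangle within a wave's stacked bar."""

    group: int
    level: str
    height: int
    offset: int


@dataclass(frozen=True)
class Flow:
    """Subjects of one trajectory group moving between adjacent waves."""

    group: int
    from_level: str
    to_level: str
    size: int


@dataclass(frozen=True)
class FlowLayout:
    """Computed lasagne-plot geometry.

    ``bands[t]`` lists the stacked rectangles of wave ``waves[t]`` bottom-up
    (offsets in subject counts); ``flows[t]`` connects waves ``t`` and
    ``t+1``.  Conservation laws: band heights at each wave sum to
    ``n_subjects``; flows out of (into) a band sum to its height.
    """

    waves: tuple[int, ...]
    levels: tuple[str, ...]
    n_subjects: int
    bands: tuple[tuple[Band, ...], ...]
    flows: tuple[tuple[Flow, ...], ...]
    group_trajectories: tuple[tuple[str, ...], ...]
    group_sizes: tuple[int, ...]

    def band_of(self, t: int, group: int) -> Band:
        for band in self.bands[t]:
            if band.group == group:
                return band
        raise KeyError(f"group {group} has no band at wave index {t}")


def compute_flow_layout(
    panel: CategoricalPanel, ordering: str = "trajectory-lex"
) -> FlowLayout:
    """Group subjects by full trajectory and stack them into per-wave bars.

    Each wave's bar is partitioned by current level (in scheme order) and,
    within a level, by trajectory group so that colour bands are contiguous
    and transitions can be traced between adjacent bars.

    ``ordering`` controls the within-level group order: ``"trajectory-lex"``
    sorts groups lexicographically by their full level sequence;
    ``"first-wave-then-trajectory"`` sorts by baseline (first-wave) level
    first, keeping baseline cohorts contiguous inside each colour block.
    """
    if panel.n_missing:
        raise ValueError(
            "panel has missing cells; apply add_missing_category or "
            "restrict_complete_cases before computing a flow layout"
        )
    if ordering not in ("trajectory-lex", "first-wave-then-trajectory"):
        raise ValueError(f"unknown ordering {ordering!r}")
    # trajectory groups, keyed by the code sequence
    groups: dict[tuple[int, ...], int] = {}
    for i in range(panel.n_subjects):
        key = tuple(int(c) for c in panel.codes[i])
        groups[key] = groups.get(key, 0) + 1
    keys = sorted(groups)
    if ordering == "first-wave-then-trajectory":
        keys = sorted(keys, key=lambda k: (k[0],) + k)
    trajs = tuple(
        tuple(panel.scheme.levels[c] for c in key) for key in keys
    )
    sizes = tuple(groups[key] for key in keys)
    n_groups = len(keys)

    bands: list[tuple[Band, ...]] = []
    for t in range(panel.n_waves):
        offset = 0
        wave_bands = []
        for j, lvl in enumerate(panel.scheme.levels):
            for g in range(n_groups):
                if keys[g][t] != j:
                    continue
                wave_bands.append(Band(g, lvl, sizes[g], offset))
                offset += sizes[g]
        bands.append(tuple(wave_bands))
    flows: list[tuple[Flow, ...]] = []
    for t in range(panel.n_waves - 1):
        flows.append(
            tuple(
                Flow(g, trajs[g][t], trajs[g][t + 1], sizes[g])
                for g in range(n_groups)
            )
        )
    return FlowLayout(
        waves=panel.waves,
        levels=panel.scheme.levels,
        n_subjects=panel.n_subjects,
        bands=tuple(bands),
        flows=tuple(flows),
        group_trajectories=trajs,
        group_sizes=sizes,
    )


@dataclass
class PlotStyle:
    """Cosmetic options for the rendered figures.

    ``colors`` maps level → colour (defaults to a colour-blind-safe
    palette in level order); a level named ``missing_label`` gets
    ``missing_color``.  ``percent_decimals`` controls the marginal table
    above the bars; ``show_counts`` switches the table from percentages to
    raw counts.
    """

    colors: dict[str, str] = field(default_factory=dict)
    missing_label: str = "missing"
    missing_color: str = "#BBBBBB"
    bar_width: float = 0.38
    flow_alpha: float = 0.35
    figsize: tuple[float, float] = (9.0, 5.5)
    percent_decimals: int = 1
    show_counts: bool = False
    font_size: float = 9.0

    def color_of(self, level: str, index: int) -> str:
        if level in self.colors:
            return self.colors[level]
        if level == self.missing_label:
            return self.missing_color
        return _PALETTE[index % len(_PALETTE)]


def _check_level_count(levels) -> None:
    if len(levels) > MAX_PLOT_LEVELS:
        raise ValueError(
            f"{len(levels)} levels exceed the plot's limit of {MAX_PLOT_LEVELS}; "
            "we recommend four categories at most for interpretability - "
            "collapse levels before plotting"
        )


def render_lasagne(
    layout: FlowLayout,
    table: MarginalTable | None = None,
    style: PlotStyle | None = None,
    path: str | None = None,
):
    """Render a flow layout as a lasagne plot; returns the figure.

    Stacked bars per wave are coloured by level; connector bands between
    adjacent bars are sized by the flows and coloured by the origin level.
    If a :class:`MarginalTable` is given, its per-wave percentages (or
    counts) are printed above each bar.  Output is deterministic given
    (layout, table, style).  If ``path`` is given the figure is saved there
    (format by extension: .svg or .png) and closed.
    """
    style = style or PlotStyle()
    _check_level_count(layout.levels)
    colors = {
        lvl: style.color_of(lvl, j) for j, lvl in enumerate(layout.levels)
    }
    fig, ax = plt.subplots(figsize=style.figsize)
    half = style.bar_width / 2.0
    for t, wave_bands in enumerate(layout.bands):
        for band in wave_bands:
            ax.add_patch(
                Rectangle(
                    (t - half, band.offset), style.bar_width, band.height,
                    facecolor=colors[band.level], edgecolor="none",
                )
            )
    for t, wave_flows in enumerate(layout.flows):
        for flow in wave_flows:
            b0 = layout.band_of(t, flow.group)
            b1 = layout.band_of(t + 1, flow.group)
            verts = [
                (t + half, b0.offset),
                (t + 1 - half, b1.offset),
                (t + 1 - half, b1.offset + b1.height),
                (t + half, b0.offset + b0.height),
            ]
            ax.add_patch(
                Polygon(
                    verts, closed=True, facecolor=colors[flow.from_level],
                    edgecolor="none", alpha=style.flow_alpha,
                )
            )
    if table is not None:
        y0 = layout.n_subjects * 1.03
        dy = layout.n_subjects * 0.05
        for r, lvl in enumerate(reversed(layout.levels)):
            if lvl not in table.proportions.columns:
                continue
            ax.text(
                -0.75, y0 + r * dy, lvl, fontsize=style.font_size,
                ha="right", va="bottom",
            )
            for t, w in enumerate(layout.waves):
                if style.show_counts:
                    txt = f"{table.counts.loc[w, lvl]:d}"
                else:
                    txt = f"{100 * table.proportions.loc[w, lvl]:.{style.percent_decimals}f}%"
                ax.text(
                    t, y0 + r * dy, txt, fontsize=style.font_size,
                    ha="center", va="bottom",
                )
        ax.set_ylim(0, y0 + len(layout.levels) * dy + dy)
    else:
        ax.set_ylim(0, layout.n_subjects * 1.02)
    handles = [
        plt.Rectangle((0, 0), 1, 1, facecolor=colors[lvl]) for lvl in layout.levels
    ]
    ax.legend(handles, layout.levels, loc="center left",
              bbox_to_anchor=(1.01, 0.5), frameon=False, fontsize=style.font_size)
    ax.set_xlim(-0.8, len(layout.waves) - 0.4)
    ax.set_xticks(range(len(layout.waves)))
    ax.set_xticklabels([str(w) for w in layout.waves])
    ax.set_xlabel("survey wave")
    ax.set_ylabel("subjects")
    for side in ("top", "right"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def render_subgroup(
    panel: CategoricalPanel,
    initial_level: str,
    initial_wave: int,
    path: str | None = None,
    ordering: str = "trajectory-lex",
    style: PlotStyle | None = None,
):
    """Lasagne plot restricted to subjects in one category at one wave.

    Useful when the number of colour bands at later waves makes the full
    plot hard to read: one plot per initial category untangles them.
    Returns (figure, n_subjects_in_subgroup).
    """
    t0 = panel.wave_index(initial_wave)
    code = panel.scheme.index(initial_level)
    keep = panel.codes[:, t0] == code
    if not keep.any():
        raise ValueError(
            f"no subject has level {initial_level!r} at wave {initial_wave}"
        )
    sub = CategoricalPanel(
        tuple(s for s, k in zip(panel.subject_ids, keep) if k),
        panel.waves,
        panel.codes[keep],
        panel.scheme,
    )
    if sub.n_missing:
        sub = restrict_complete_cases(sub)
    layout = compute_flow_layout(sub, ordering)
    fig = render_lasagne(layout, marginal_table(sub), style, path)
    return fig, sub.n_subjects


def render_probability_tree(
    tree: ProbabilityTree,
    path: str | None = None,
    style: PlotStyle | None = None,
):
    """Render a probability tree with level, count and conditional
    probability at every node; deterministic layout (leaves in level order
    top-down, internal nodes centred on their children)."""
    style = style or PlotStyle()
    _check_level_count(tree.scheme.levels)
    colors = {
        lvl: style.color_of(lvl, j) for j, lvl in enumerate(tree.scheme.levels)
    }
    positions: dict[int, tuple[float, float]] = {}
    next_leaf_y = [0.0]

    def place(node: TreeNode, depth: int) -> float:
        if not node.children:
            y = next_leaf_y[0]
            next_leaf_y[0] += 1.0
        else:
            ys = [place(child, depth + 1) for child in node.children]
            y = float(np.mean(ys))
        positions[id(node)] = (float(depth), y)
        return y

    place(tree.root, 0)
    fig, ax = plt.subplots(figsize=style.figsize)

    def draw(node: TreeNode):
        x, y = positions[id(node)]
        for child in node.children:
            cx, cy = positions[id(child)]
            ax.plot([x, cx], [y, cy], color="0.6", lw=1.0, zorder=1)
            draw(child)
        ax.scatter([x], [y], s=60, color=colors[node.level], zorder=2)
        ax.annotate(
            f"{node.level}\nn={node.count}, p={node.prob:.2f}",
            (x, y), textcoords="offset points", xytext=(0, 7),
            ha="center", fontsize=style.font_size,
        )

    draw(tree.root)
    ax.set_xticks(range(len(tree.waves)))
    ax.set_xticklabels([str(w) for w in tree.waves])
    ax.set_xlabel("survey wave")
    ax.set_yticks([])
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    ax.margins(y=0.15)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
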