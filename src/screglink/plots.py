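"""Static figure output: embeddings, marker heatmaps, volcanoes, curves.

All functions write a figure file (PNG/PDF/SVG by extension) and return the
output path; nothing interactive.  Correlation-strength colors are clipped
to (-1, 1) by default because extreme per-cell indices can exceed that range
while the interpretable scale is Pearson-like.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ValidationError

__all__ = [
    "plot_embedding_triptych",
    "plot_marker_heatmap",
    "plot_volcano",
    "plot_dynamic_curves",
]

DEFAULT_COLOR_LIMITS = (-1.0, 1.0)


def _check_limits(color_limits):
    lo, hi = color_limits
    if not lo < hi:
        raise ValidationError(f"color_limits min must be < max, got {color_limits}")
    return lo, hi


def _save(fig, output_path, dpi):
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output_path, dpi=dpi)
    plt.close(fig)
    return output_path


def plot_embedding_triptych(
    data,
    results,
    pair_key: str,
    output_path,
    color_limits=DEFAULT_COLOR_LIMITS,
    dpi: int = 150,
    point_size: float = 4.0,
):
    """Three-panel embedding: gene expression, peak accessibility, and L."""
    lo, hi = _check_limits(color_limits)
    if data.embedding is None:
        raise ValidationError("no embedding available for plotting")
    Lcol = results.pair_column(pair_key)  # raises KeyError on unknown pair
    gene_id, peak_id = pair_key.split("~", 1)
    x = np.asarray(data.rna[:, data.gene_index([gene_id])].todense()).ravel()
    y = np.asarray(data.atac[:, data.peak_index([peak_id])].todense()).ravel()
    emb = data.embedding

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    panels = [
        (x, f"{gene_id} expression", "viridis", None),
        (y, f"{peak_id} accessibility", "viridis", None),
        (np.clip(Lcol, lo, hi), "correlation strength", "RdBu_r", (lo, hi)),
    ]
    for ax, (vals, title, cmap, clim) in zip(axes, panels):
        sc = ax.scatter(emb[:, 0], emb[:, 1], c=vals, s=point_size, cmap=cmap,
                        vmin=None if clim is None else clim[0],
                        vmax=None if clim is None else clim[1])
        ax.set_title(title, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.tight_layout()
    return _save(fig, output_path, dpi)


def plot_marker_heatmap(
    results,
    markers: pd.DataFrame,
    groups: pd.Series,
    output_path,
    color_limits=DEFAULT_COLOR_LIMITS,
    dpi: int = 150,
):
    """Cells x marker-pairs heatmap of L, blocked by group.

    Rows (cells) are ordered by group label; columns (pairs) by the group
    that owns the marker.
    """
    lo, hi = _check_limits(color_limits)
    flagged = markers[markers["is_marker"]] if "is_marker" in markers else markers
    if len(flagged) == 0:
        raise ValidationError("no markers to plot")
    groups = pd.Series(groups).astype(str).reset_index(drop=True)
    cell_order = groups.sort_values(kind="mergesort").index.to_numpy()
    flagged = flagged.sort_values(["group", "q_value"], kind="mergesort")
    keys = results.pair_keys
    col_idx = [keys.index(k) for k in flagged["pair_key"] if k in keys]
    if not col_idx:
        raise ValidationError("marker pair keys not found in results")
    M = np.clip(results.L[np.ix_(cell_order, col_idx)], lo, hi)

    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(col_idx)), 5))
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=lo, vmax=hi,
                   interpolation="nearest")
    bounds = np.flatnonzero(np.diff(groups.to_numpy()[cell_order] != "") |
                            (groups.to_numpy()[cell_order][:-1] !=
                             groups.to_numpy()[cell_order][1:]))
    for b in bounds:
        ax.axhline(b + 0.5, color="black", lw=0.5)
    ax.set_xlabel("gene-peak pairs")
    ax.set_ylabel("cells (grouped)")
    fig.colorbar(im, ax=ax, label="correlation strength")
    fig.tight_layout()
    return _save(fig, output_path, dpi)


def plot_volcano(
    markers: pd.DataFrame,
    group: str,
    output_path,
    alpha: float = 0.05,
    min_delta: float = 0.1,
    dpi: int = 150,
):
    """Volcano of delta L vs -log10(q) for one group's marker family."""
    sub = markers[markers["group"].astype(str) == str(group)]
    if len(sub) == 0:
        raise KeyError(f"group {group!r} not present in marker table")
    q = np.maximum(sub["q_value"].to_numpy(), 1e-300)
    x = sub["delta_L"].to_numpy()
    y = -np.log10(q)
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = sub["is_marker"].to_numpy() if "is_marker" in sub else np.zeros(len(sub), bool)
    ax.scatter(x[~sig], y[~sig], s=8, c="grey", alpha=0.6)
    ax.scatter(x[sig], y[sig], s=10, c="crimson")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="black")
    for v in (-min_delta, min_delta):
        ax.axvline(v, ls="--", lw=0.8, c="black")
    ax.set_xlabel(r"$\Delta$ correlation strength")
    ax.set_ylabel(r"$-\log_{10}(q)$")
    ax.set_title(f"regulatory markers: {group}", fontsize=10)
    fig.tight_layout()
    return _save(fig, output_path, dpi)


def plot_dynamic_curves(
    curves,
    modules=None,
    output_path="dynamic_curves.png",
    smooth_sigma: float = 1.0,
    dpi: int = 150,
):
    """Trajectory regulation curves with optional SOM prototypes.

    Per-pair curves in grey (Gaussian-smoothed over bin index for display
    only), module prototype curves in color, and a stacked per-bin cell-type
    occupancy bar beneath.
    """
    if curves.n_bins < 2:
        raise ValidationError("need at least 2 time bins to draw curves")
    mask = curves.dynamic_mask
    C = curves.curve if mask is None else curves.curve[mask]
    Z = C - C.mean(axis=1, keepdims=True)
    sd = C.std(axis=1, ddof=0, keepdims=True)
    Z = np.divide(Z, sd, out=np.zeros_like(Z), where=sd > 0)

    fig, (ax, axo) = plt.subplots(
        2, 1, figsize=(6, 4.6), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.08},
    )
    bins = np.arange(curves.n_bins)
    for row in Z:
        ax.plot(bins, gaussian_filter1d(row, smooth_sigma), color="grey",
                lw=0.6, alpha=0.4)
    if modules is not None:
        for m, proto in enumerate(modules.prototypes):
            ax.plot(bins, gaussian_filter1d(proto, smooth_sigma), lw=2.2,
                    label=f"module {m}")
        ax.legend(fontsize=8, frameon=False)
    ax.set_ylabel("normalized correlation strength")

    # stacked manually to keep the path's deterministic group order
    bottom = np.zeros(curves.n_bins)
    for g in curves.occupancy.columns:
        vals = curves.occupancy[g].to_numpy()
        axo.bar(bins, vals, bottom=bottom, width=1.0, label=str(g))
        bottom += vals
    axo.set_ylim(0, 1)
    axo.set_ylabel("cell types", fontsize=8)
    axo.set_xlabel("pseudotime bin")
    axo.legend(fontsize=6, ncol=min(4, len(curves.occupancy.columns)),
               frameon=False, loc="upper right")
    return _save(fig, output_path, dpi)
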