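"""Downstream analysis of per-cell correlation strengths.

Given the fitted cell x pair matrix L, this module detects regulatory
markers between cell groups or conditions (rank tests on the per-cell
indices with Benjamini-Hochberg correction), quantifies regulation dynamics
along a pseudotime trajectory (time-binned mean curves, cell-type occupancy
per bin, highly variable "dynamic" pairs) and clusters dynamic temporal
patterns with a seeded self-organizing map.  A plain Pearson's-r baseline is
provided for comparison with window/cluster correlation approaches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import LocalCorrelation
from .data import PairedOmics
from .errors import ValidationError
from .pairing import PairTable
from .som import SelfOrganizingMap1D

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryCurves",
    "SOMModules",
    "find_all_markers",
    "find_markers",
    "trajectory_curves",
    "detect_dynamic",
    "dynamic_modules",
    "pearson_baseline",
]

MARKER_COLUMNS = [
    "group",
    "gene_id",
    "peak_id",
    "pair_key",
    "delta_L",
    "statistic",
    "p_value",
    "q_value",
    "n_group",
    "n_rest",
    "is_marker",
]


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def _test_columns(La: np.ndarray, Lb: np.ndarray, method: str):
    """Two-sided test of each L column between two cell sets."""
    if method == "wilcoxon":
        res = stats.ranksums(La, Lb, axis=0)
    elif method == "ttest":
        res = stats.ttest_ind(La, Lb, axis=0)
    else:
        raise ValidationError(f"unknown test method {method!r}")
    stat = np.atleast_1d(np.asarray(res.statistic, dtype=np.float64))
    pval = np.atleast_1d(np.asarray(res.pvalue, dtype=np.float64))
    # degenerate columns (all ties / zero variance) carry no evidence
    bad = ~np.isfinite(pval)
    pval[bad] = 1.0
    stat[bad] = 0.0
    return stat, pval


def _marker_frame(local: LocalCorrelation, group_name, mask_a, mask_b,
                  min_delta: float, alpha: float, method: str) -> pd.DataFrame:
    La, Lb = local.L[mask_a], local.L[mask_b]
    stat, pval = _test_columns(La, Lb, method)
    qval = multipletests(pval, method="fdr_bh")[1]
    delta = La.mean(axis=0) - Lb.mean(axis=0)
    pt = local.pair_table
    return pd.DataFrame(
        {
            "group": group_name,
            "gene_id": pt.gene_ids,
            "peak_id": pt.peak_ids,
            "pair_key": pt.pair_keys,
            "delta_L": delta,
            "statistic": stat,
            "p_value": pval,
            "q_value": qval,
            "n_group": int(mask_a.sum()),
            "n_rest": int(mask_b.sum()),
            "is_marker": (qval < alpha) & (np.abs(delta) >= min_delta),
        },
        columns=MARKER_COLUMNS,
    )


def find_all_markers(
    local: LocalCorrelation,
    groups: pd.Series,
    min_delta: float = 0.1,
    alpha: float = 0.05,
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """One-vs-rest regulatory marker detection for every group.

    For each group, every L column is compared between the group's cells and
    all other cells with a two-sided Wilcoxon rank-sum test (t-test
    optional); p-values are Benjamini-Hochberg adjusted across pairs within
    each group's family.  A pair is flagged as a marker when
    ``q_value < alpha`` and ``|delta_L| >= min_delta``.
    """
    groups = pd.Series(groups).astype(str)
    if groups.shape[0] != local.L.shape[0]:
        raise ValidationError("groups length does not match L rows")
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    frames = []
    gvals = groups.to_numpy()
    for g in labels:
        mask = gvals == g
        if mask.sum() < 3:
            logger.warning("group %r has < 3 cells; skipped", g)
            continue
        frames.append(
            _marker_frame(local, g, mask, ~mask, min_delta, alpha, method)
        )
    if not frames:
        raise ValidationError("no group has >= 3 cells")
    return pd.concat(frames, ignore_index=True)


def find_markers(
    local: LocalCorrelation,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    min_delta: float = 0.1,
    alpha: float = 0.05,
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Marker detection between two named groups/conditions (a minus b)."""
    if group_a == group_b:
        raise ValidationError("group_a and group_b must differ")
    groups = pd.Series(groups).astype(str)
    gvals = groups.to_numpy()
    mask_a, mask_b = gvals == str(group_a), gvals == str(group_b)
    for name, m in ((group_a, mask_a), (group_b, mask_b)):
        if m.sum() < 3:
            raise ValidationError(f"group {name!r} has < 3 cells")
    return _marker_frame(
        local, f"{group_a}|vs|{group_b}", mask_a, mask_b, min_delta, alpha, method
    )


# ---------------------------------------------------------------------------
# Trajectory dynamics
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryCurves:
    """Pair x time-bin mean correlation strengths along a trajectory path.

    ``curve[j, b]`` is the exact mean of L over the cells of bin b;
    ``occupancy`` holds the per-bin cell-type proportions (rows sum to 1);
    ``variability`` is the across-bin standard deviation of each curve and
    ``dynamic_mask`` flags the highly variable ("dynamic") pairs once
    :func:`detect_dynamic` has been applied.
    """

    curve: np.ndarray            # p x B binned means
    bins: pd.DataFrame           # per-bin t_min, t_max, n_cells
    occupancy: pd.DataFrame      # B x groups proportions
    pair_keys: list[str]
    path: list[str]
    binning: str
    variability: np.ndarray | None = None
    dynamic_mask: np.ndarray | None = None
    selection_rule: str | None = None

    @property
    def n_bins(self) -> int:
        return self.curve.shape[1]

    def dynamic_keys(self) -> list[str]:
        if self.dynamic_mask is None:
            raise ValidationError("dynamic pairs not yet detected")
        return [k for k, m in zip(self.pair_keys, self.dynamic_mask) if m]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.curve, index=self.pair_keys,
            columns=[f"bin_{b}" for b in range(self.n_bins)],
        ).rename_axis("pair_key").to_csv(
            out / "trajectory_curves.tsv", sep="\t", lineterminator="\n")
        self.occupancy.rename_axis("bin").to_csv(
            out / "occupancy.tsv", sep="\t", lineterminator="\n")
        meta = {
            "path": self.path,
            "binning": self.binning,
            "bins": self.bins.to_dict(orient="records"),
            "selection_rule": self.selection_rule,
        }
        if self.variability is not None:
            meta["variability"] = dict(zip(self.pair_keys, map(float, self.variability)))
        if self.dynamic_mask is not None:
            meta["dynamic_pairs"] = self.dynamic_keys()
        (out / "trajectory_bins.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True) + "\n")


def trajectory_curves(
    local: LocalCorrelation,
    data: PairedOmics,
    path: list[str],
    group_key: str,
    time_key: str = "pseudotime",
    n_bins: int = 50,
    binning: str = "equal_count",
) -> TrajectoryCurves:
    """Bin cells of a trajectory path by pseudotime and average L per bin.

    Cells are restricted to those whose group label is in ``path`` and whose
    pseudotime is present, then split into ``n_bins`` ordered bins of equal
    cell count (default) or equal pseudotime width.  Per-bin cell-type
    occupancy uses the path's own labels.
    """
    if n_bins < 3:
        raise ValidationError("n_bins must be >= 3")
    if binning not in {"equal_count", "equal_width"}:
        raise ValidationError(f"unknown binning mode {binning!r}")
    if not path:
        raise ValidationError("empty trajectory path")
    meta = data.cell_meta
    for key in (group_key, time_key):
        if key not in meta.columns:
            raise KeyError(f"{key!r} not in cell metadata")
    groups = meta[group_key].astype(str).to_numpy()
    t = pd.to_numeric(meta[time_key], errors="coerce").to_numpy(dtype=np.float64)
    sel = np.flatnonzero(np.isin(groups, [str(g) for g in path]) & np.isfinite(t))
    if len(sel) < n_bins:
        raise ValidationError(
            f"only {len(sel)} cells on the path for {n_bins} bins"
        )

    tsel = t[sel]
    order = sel[np.argsort(tsel, kind="mergesort")]
    if binning == "equal_count":
        bin_members = np.array_split(order, n_bins)
    else:
        edges = np.linspace(tsel.min(), tsel.max(), n_bins + 1)
        which = np.clip(np.searchsorted(edges, t[order], side="right") - 1, 0, n_bins - 1)
        bin_members = [order[which == b] for b in range(n_bins)]
        if any(len(m) == 0 for m in bin_members):
            raise ValidationError(
                "equal_width binning produced an empty bin; "
                "use equal_count binning or fewer bins"
            )

    p = local.L.shape[1]
    curve = np.empty((p, n_bins), dtype=np.float64)
    occ = np.zeros((n_bins, len(path)), dtype=np.float64)
    bins_meta = []
    path_labels = [str(g) for g in path]
    for b, members in enumerate(bin_members):
        curve[:, b] = local.L[members].mean(axis=0)
        gb = groups[members]
        for gi, g in enumerate(path_labels):
            occ[b, gi] = np.mean(gb == g)
        bins_meta.append(
            dict(bin=b, t_min=float(t[members].min()),
                 t_max=float(t[members].max()), n_cells=int(len(members)))
        )
    curves = TrajectoryCurves(
        curve=curve,
        bins=pd.DataFrame(bins_meta),
        occupancy=pd.DataFrame(occ, columns=path_labels),
        pair_keys=local.pair_table.pair_keys,
        path=path_labels,
        binning=binning,
    )
    curves.variability = curve.std(axis=1, ddof=0)
    return curves


def detect_dynamic(
    curves: TrajectoryCurves, method: str = "sd_threshold", k: float = 1.0
) -> TrajectoryCurves:
    """Flag highly variable pairs along the trajectory.

    Variability is the across-bin standard deviation of each binned curve.
    ``sd_threshold`` selects pairs with variability above
    ``mean + k * sd`` of all variabilities; ``top_n`` selects the ``ceil(k)``
    largest.
    """
    variability = curves.curve.std(axis=1, ddof=0)
    if method == "sd_threshold":
        cut = variability.mean() + k * variability.std(ddof=0)
        mask = variability > cut
        rule = f"sd_threshold(k={k})"
    elif method == "top_n":
        if k <= 0:
            raise ValidationError("k must be > 0 under top_n")
        n_top = min(int(np.ceil(k)), len(variability))
        top = np.argsort(-variability, kind="mergesort")[:n_top]
        mask = np.zeros(len(variability), dtype=bool)
        mask[top] = True
        rule = f"top_n(k={n_top})"
    else:
        raise ValidationError(f"unknown method {method!r}")
    return replace(
        curves, variability=variability, dynamic_mask=mask, selection_rule=rule
    )


# ---------------------------------------------------------------------------
# SOM temporal modules
# ---------------------------------------------------------------------------

@dataclass
class SOMModules:
    """Temporal-pattern module assignment of the dynamic pairs."""

    module_ids: pd.Series        # pair_key -> module id
    prototypes: np.ndarray       # m_units x B codebook curves (normalized scale)
    som_config: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.module_ids.rename("module_id").rename_axis("pair_key").to_csv(
            out / "som_modules.tsv", sep="\t", lineterminator="\n")
        (out / "som_config.json").write_text(
            json.dumps(self.som_config, indent=1, sort_keys=True) + "\n")


def _znorm_rows(X: np.ndarray):
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    ok = sd.ravel() > 0
    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z, ok


def dynamic_modules(
    curves: TrajectoryCurves,
    m_units: int = 3,
    epochs: int = 2000,
    learning_rate: float = 0.5,
    sigma: float | None = None,
    seed: int | None = None,
) -> SOMModules:
    """Cluster dynamic-pair temporal curves with a seeded 1-D SOM.

    Each dynamic curve is z-normalized across bins before training (flat
    zero-sd curves are excluded with a warning); module ids are the
    best-matching SOM units and prototypes the final codebook curves on the
    normalized scale.
    """
    if curves.dynamic_mask is None:
        raise ValidationError("run detect_dynamic before dynamic_modules")
    keys = curves.dynamic_keys()
    X = curves.curve[curves.dynamic_mask]
    if len(X) < m_units:
        raise ValidationError(
            f"{len(X)} dynamic pairs < {m_units} SOM units; use a smaller m_units"
        )
    Z, ok = _znorm_rows(X)
    if not ok.all():
        logger.warning("excluded %d flat dynamic curves from SOM", int((~ok).sum()))
        keys = [k for k, o in zip(keys, ok) if o]
        Z = Z[ok]
    if len(Z) < m_units:
        raise ValidationError(
            f"only {len(Z)} usable dynamic curves for {m_units} SOM units"
        )
    som = SelfOrganizingMap1D(
        m_units, epochs=epochs, learning_rate=learning_rate, sigma=sigma, seed=seed
    ).fit(Z)
    ids = som.predict(Z)
    config = dict(
        grid_shape=[m_units, 1],
        epochs=epochs,
        learning_rate=learning_rate,
        sigma=som.sigma,
        seed=seed,
        n_bins=curves.n_bins,
    )
    return SOMModules(
        module_ids=pd.Series(ids, index=keys, name="module_id"),
        prototypes=som.codebook_,
        som_config=config,
    )


def load_trajectory_curves(curves_dir) -> TrajectoryCurves:
    """Load a saved trajectory-curves directory (from ``TrajectoryCurves.save``)."""
    d = Path(curves_dir)
    cdf = pd.read_csv(d / "trajectory_curves.tsv", sep="\t", index_col=0)
    occupancy = pd.read_csv(d / "occupancy.tsv", sep="\t", index_col=0)
    meta = json.loads((d / "trajectory_bins.json").read_text())
    pair_keys = list(cdf.index.astype(str))
    curves = TrajectoryCurves(
        curve=cdf.to_numpy(dtype=np.float64),
        bins=pd.DataFrame(meta["bins"]),
        occupancy=occupancy,
        pair_keys=pair_keys,
        path=meta["path"],
        binning=meta["binning"],
        selection_rule=meta.get("selection_rule"),
    )
    if "variability" in meta:
        curves.variability = np.array(
            [meta["variability"][k] for k in pair_keys], dtype=np.float64)
    if "dynamic_pairs" in meta:
        dyn = set(meta["dynamic_pairs"])
        curves.dynamic_mask = np.array([k in dyn for k in pair_keys], dtype=bool)
    return curves


def load_som_modules(modules_dir) -> SOMModules:
    """Load a saved SOM-modules directory (prototypes are not persisted and
    are reconstructed as per-module mean normalized curves when needed)."""
    d = Path(modules_dir)
    ids = pd.read_csv(d / "som_modules.tsv", sep="\t", index_col=0)["module_id"]
    config = json.loads((d / "som_config.json").read_text())
    n_bins = int(config.get("n_bins", 0)) or 1
    m = int(config["grid_shape"][0])
    return SOMModules(module_ids=ids, prototypes=np.zeros((m, n_bins)),
                      som_config=config)


# ---------------------------------------------------------------------------
# Pearson baseline
# ---------------------------------------------------------------------------

def pearson_baseline(
    data: PairedOmics, pairs: PairTable, group_key: str | None = None
) -> pd.DataFrame:
    """Plain per-pair Pearson's r, overall or within each group.

    This is the conventional gene-peak linking statistic; pairs with a
    zero-variance feature get NaN with a warning.
    """
    gidx = data.gene_index(pairs.gene_ids)
    pidx = data.peak_index(pairs.peak_ids)
    X = np.asarray(data.rna[:, gidx].todense(), dtype=np.float64)
    Y = np.asarray(data.atac[:, pidx].todense(), dtype=np.float64)

    def _r(Xs, Ys):
        sx = Xs.std(axis=0, ddof=0)
        sy = Ys.std(axis=0, ddof=0)
        bad = (sx == 0) | (sy == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = ((Xs - Xs.mean(axis=0)) * (Ys - Ys.mean(axis=0))).mean(axis=0) / (sx * sy)
        r[bad] = np.nan
        if bad.any():
            logger.warning("%d zero-variance pairs have undefined r", int(bad.sum()))
        return r

    out = pd.DataFrame(index=pd.Index(pairs.pair_keys, name="pair_key"))
    if group_key is None:
        out["pearson_r"] = _r(X, Y)
        return out
    groups = data.cell_meta[group_key].astype(str)
    for g in sorted(groups.unique()):
        m = (groups == g).to_numpy()
        out[g] = _r(X[m], Y[m])
    return out
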