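"""Neighborhood-inferred single-cell gene-peak correlation strength.

The per-cell correlation strength of a gene x and a peak y in cell i is a
local bivariate spatial association index over the cell-cell neighborhood
graph:

    L_i = n * (xlag_i - xbar) * (ylag_i - ybar)
          / ( sqrt(sum_i (x_i - xbar)^2) * sqrt(sum_i (y_i - ybar)^2) )

where xlag_i = sum_j w_ij x_j is the spatial lag (the weighted average of
cell i's graph neighbors, self included).  With W row-stochastic and
population (ddof 0) z-scoring this is computed for all p pairs at once as

    L = (W Z_Y) o (W Z_X)        (o = elementwise product),

an n x p matrix whose column means give a per-pair global index analogous to
Pearson's r.  The equality of the per-cell formula and the vectorized form
holds exactly only under ddof-0 z-scoring with row-standardized W; both are
therefore fixed here.

W is built from the (weighted nearest neighbor) connectivity matrix by
setting the diagonal to ``self_weight`` (default 1.0) and row-standardizing.
Cells with no neighbors degenerate to pure self-rows, so their lag equals
their own value and their contribution reduces to the plain Pearson term.

Because single-cell data are zero inflated, an optional dropout rule zeroes
L[i, j] whenever the raw (pre-z-score) gene or peak value of cell i is 0 for
that pair: after centering, technical zeros turn into spurious negative
values that would otherwise bias the index.  The stored per-pair global
index is always the pre-zeroing column mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import PairedOmics
from .errors import StructuralError, ValidationError
from .pairing import PairTable

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMatrix",
    "LocalCorrelation",
    "build_weights",
    "spatial_lag",
    "local_correlation",
    "global_only",
    "GenePeakCorrelation",
    "LocalCorrelationResults",
]

_ROW_SUM_TOL = 1e-12


@dataclass
class WeightMatrix:
    """Row-stochastic cell-cell weights with a strictly positive diagonal."""

    W: sp.csr_matrix

    def __post_init__(self):
        self.W = self.W.tocsr()
        n, m = self.W.shape
        if n != m:
            raise StructuralError(f"weight matrix is not square: {self.W.shape}")
        if self.W.nnz and self.W.data.min() < 0:
            raise ValidationError("weight matrix has negative entries")
        rowsum = np.asarray(self.W.sum(axis=1)).ravel()
        if np.max(np.abs(rowsum - 1.0)) > _ROW_SUM_TOL:
            raise ValidationError("weight matrix rows must sum to 1")
        if np.any(self.W.diagonal() <= 0):
            raise ValidationError("weight matrix diagonal must be strictly positive")

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_weights(connectivities, self_weight: float = 1.0) -> WeightMatrix:
    """Build the row-standardized weight matrix W from a connectivity matrix.

    The diagonal is set to ``self_weight`` (the self-neighbor contribution;
    1.0 by default) before row standardization.  Isolated cells — rows that
    are zero apart from the diagonal — become pure self-rows e_i.
    """
    if self_weight <= 0:
        raise ValidationError("self_weight must be > 0")
    C = sp.csr_matrix(connectivities, dtype=np.float64)
    if C.shape[0] != C.shape[1] or C.shape[0] < 2:
        raise StructuralError(f"connectivities must be square with n >= 2, got {C.shape}")
    if C.nnz and C.data.min() < 0:
        raise ValidationError("connectivities has negative entries")
    A = C.tolil()
    A.setdiag(self_weight)
    A = A.tocsr()
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    W = sp.diags(1.0 / rowsum) @ A
    return WeightMatrix(W.tocsr())


def spatial_lag(W: WeightMatrix, v: np.ndarray) -> np.ndarray:
    """The spatial lag W @ v: per-cell weighted average over graph neighbors."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[0] != W.n:
        raise StructuralError(f"vector length {v.shape[0]} != {W.n} cells")
    return W.W @ v


@dataclass
class LocalCorrelation:
    """Cell x pair matrix L of correlation strengths plus per-pair globals.

    ``global_index[j]`` is the mean of column j of L over all cells, taken
    before any dropout zeroing; columns of L correspond one-to-one, in
    order, with rows of ``pair_table``.
    """

    L: np.ndarray
    pair_table: PairTable
    global_index: np.ndarray
    zeroed_dropouts: bool

    def __post_init__(self):
        if self.L.shape[1] != len(self.pair_table):
            raise StructuralError("L columns do not match pair table rows")
        if self.global_index.shape != (self.L.shape[1],):
            raise StructuralError("global_index length does not match L columns")


def _dense_cols(mat: sp.csr_matrix, cols: np.ndarray) -> np.ndarray:
    # Fortran order so per-column reductions have a layout-independent
    # summation order; this is what makes results bitwise-stable across
    # chunk sizes.
    return np.asfortranarray(mat[:, cols].todense(), dtype=np.float64)


def local_correlation(
    data: PairedOmics,
    pairs: PairTable,
    W: WeightMatrix,
    zero_dropouts: bool = False,
    chunk_size: int = 1000,
) -> LocalCorrelation:
    """Compute the per-cell correlation strength matrix L for all pairs.

    Pairs whose gene or peak has zero variance over cells are dropped with a
    warning (they carry no correlation information); if every pair is
    degenerate an error is raised.  Computation is chunked over pairs with
    results bitwise-independent of ``chunk_size``.
    """
    if chunk_size < 1:
        raise ValidationError("chunk_size must be >= 1")
    if W.n != data.n_cells:
        raise StructuralError(
            f"weight matrix over {W.n} cells but data has {data.n_cells}"
        )
    if len(pairs) == 0:
        raise ValidationError("empty pair table")

    gidx = data.gene_index(pairs.gene_ids)
    pidx = data.peak_index(pairs.peak_ids)
    n, p = data.n_cells, len(pairs)

    keep_cols: list[np.ndarray] = []
    L_cols: list[np.ndarray] = []
    mean_cols: list[np.ndarray] = []
    raw_zero_cols: list[np.ndarray] = []
    n_dropped = 0
    for start in range(0, p, chunk_size):
        sl = slice(start, min(start + chunk_size, p))
        X = _dense_cols(data.rna, gidx[sl])
        Y = _dense_cols(data.atac, pidx[sl])
        sx = X.std(axis=0, ddof=0)
        sy = Y.std(axis=0, ddof=0)
        ok = (sx > 0) & (sy > 0)
        n_dropped += int((~ok).sum())
        if not ok.any():
            continue
        X, Y = X[:, ok], Y[:, ok]
        Zx = (X - X.mean(axis=0)) / sx[ok]
        Zy = (Y - Y.mean(axis=0)) / sy[ok]
        Lc = np.asarray(W.W @ Zy) * np.asarray(W.W @ Zx)
        keep_cols.append(np.arange(sl.start, sl.stop)[ok])
        mean_cols.append(Lc.mean(axis=0))
        if zero_dropouts:
            raw_zero_cols.append((X == 0) | (Y == 0))
        L_cols.append(Lc)

    if not L_cols:
        raise ValidationError("all pairs are degenerate (zero-variance features)")
    if n_dropped:
        logger.warning("dropped %d zero-variance pairs of %d", n_dropped, p)

    L = np.concatenate(L_cols, axis=1)
    global_index = np.concatenate(mean_cols)
    keep = np.concatenate(keep_cols)
    if zero_dropouts:
        L = L.copy()
        L[np.concatenate(raw_zero_cols, axis=1)] = 0.0
    kept_pairs = pairs.subset(np.isin(np.arange(p), keep)) if n_dropped else pairs
    return LocalCorrelation(
        L=L, pair_table=kept_pairs, global_index=global_index,
        zeroed_dropouts=zero_dropouts,
    )


def load_local_correlation(results_dir) -> LocalCorrelation:
    """Load a saved correlation output directory (from ``Results.save``)."""
    from pathlib import Path

    from scipy.io import mmread

    d = Path(results_dir)
    pair_table = PairTable.from_tsv(d / "pairs.tsv")
    if (d / "local_L.mtx").exists():
        L = np.asarray(mmread(d / "local_L.mtx").todense(), dtype=np.float64)
    elif (d / "local_L.tsv").exists():
        L = pd.read_csv(d / "local_L.tsv", sep="\t", index_col=0).to_numpy(
            dtype=np.float64)
    else:
        raise FileNotFoundError(f"no local_L.mtx or local_L.tsv in {d}")
    gl = pd.read_csv(d / "global_L.tsv", sep="\t", index_col=0)["global_L"]
    return LocalCorrelation(
        L=L, pair_table=pair_table,
        global_index=gl.to_numpy(dtype=np.float64), zeroed_dropouts=False,
    )


def global_only(
    data: PairedOmics, pairs: PairTable, W: WeightMatrix, chunk_size: int = 1000
) -> pd.Series:
    """Per-pair global index only (column means of L), as a keyed Series."""
    res = local_correlation(data, pairs, W, zero_dropouts=False, chunk_size=chunk_size)
    return pd.Series(res.global_index, index=res.pair_table.pair_keys, name="global_L")


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class GenePeakCorrelation:
    """Model for per-cell gene-peak correlation strength over a cell graph.

    Parameters
    ----------
    data
        The paired multiome container (expression, accessibility, graph,
        metadata).
    pairs
        The gene-peak pair table; its row order fixes the columns of L.
    self_weight
        Diagonal value added to the connectivity matrix before row
        standardization.  Exposed because connectivity scales vary between
        graph constructions.
    zero_dropouts
        Zero L[i, j] whenever cell i has a raw zero in the pair's gene or
        peak (dropout correction).
    chunk_size
        Pairs per computation chunk; results are bitwise-independent of it.
    """

    def __init__(
        self,
        data: PairedOmics,
        pairs: PairTable,
        self_weight: float = 1.0,
        zero_dropouts: bool = False,
        chunk_size: int = 1000,
    ):
        self.data = data
        self.pairs = pairs
        self.self_weight = float(self_weight)
        self.zero_dropouts = bool(zero_dropouts)
        self.chunk_size = int(chunk_size)
        self.weights = build_weights(data.connectivities, self_weight=self.self_weight)

    def fit(self) -> "LocalCorrelationResults":
        local = local_correlation(
            self.data,
            self.pairs,
            self.weights,
            zero_dropouts=self.zero_dropouts,
            chunk_size=self.chunk_size,
        )
        return LocalCorrelationResults(self, local)


class LocalCorrelationResults:
    """Fitted per-cell correlation strengths and downstream analyses.

    Carries the n x p matrix ``L``, the per-pair ``global_index`` (a Series
    keyed by ``gene~peak``), and entry points for marker detection,
    trajectory dynamics, SOM temporal modules and plotting.
    """

    def __init__(self, model: GenePeakCorrelation, local: LocalCorrelation):
        self.model = model
        self.data = model.data
        self.local = local

    # -- estimates --------------------------------------------------------
    @property
    def L(self) -> np.ndarray:
        return self.local.L

    @property
    def pair_table(self) -> PairTable:
        return self.local.pair_table

    @property
    def pair_keys(self) -> list[str]:
        return self.local.pair_table.pair_keys

    @property
    def global_index(self) -> pd.Series:
        return pd.Series(self.local.global_index, index=self.pair_keys, name="global_L")

    def pair_column(self, pair_key: str) -> np.ndarray:
        try:
            j = self.pair_keys.index(pair_key)
        except ValueError:
            raise KeyError(f"unknown pair key {pair_key!r}") from None
        return self.L[:, j]

    # -- downstream analyses ---------------------------------------------
    def pearson_baseline(self, group_key: str | None = None) -> pd.DataFrame:
        from . import dynamics

        return dynamics.pearson_baseline(
            self.data, self.pair_table, group_key=group_key
        )

    def find_all_markers(self, group_key: str, min_delta: float = 0.1,
                         alpha: float = 0.05, method: str = "wilcoxon") -> pd.DataFrame:
        from . import dynamics

        groups = self.data.cell_meta[group_key]
        return dynamics.find_all_markers(
            self.local, groups, min_delta=min_delta, alpha=alpha, method=method
        )

    def find_markers(self, group_key: str, group_a: str, group_b: str,
                     min_delta: float = 0.1, alpha: float = 0.05,
                     method: str = "wilcoxon") -> pd.DataFrame:
        from . import dynamics

        groups = self.data.cell_meta[group_key]
        return dynamics.find_markers(
            self.local, groups, group_a, group_b,
            min_delta=min_delta, alpha=alpha, method=method,
        )

    def trajectory_curves(self, path: list[str], group_key: str,
                          time_key: str = "pseudotime", n_bins: int = 50,
                          binning: str = "equal_count"):
        from . import dynamics

        return dynamics.trajectory_curves(
            self.local, self.data, path, group_key=group_key,
            time_key=time_key, n_bins=n_bins, binning=binning,
        )

    # -- plotting ---------------------------------------------------------
    def plot_embedding_triptych(self, pair_key: str, output_path, **kwargs):
        from . import plots

        return plots.plot_embedding_triptych(
            self.data, self, pair_key, output_path, **kwargs
        )

    def plot_marker_heatmap(self, markers: pd.DataFrame, group_key: str,
                            output_path, **kwargs):
        from . import plots

        return plots.plot_marker_heatmap(
            self, markers, self.data.cell_meta[group_key], output_path, **kwargs
        )

    def plot_volcano(self, markers: pd.DataFrame, group: str, output_path, **kwargs):
        from . import plots

        return plots.plot_volcano(markers, group, output_path, **kwargs)

    # -- reporting / persistence ------------------------------------------
    def summary(self) -> str:
        gi = self.local.global_index
        lines = [
            "Gene-peak correlation strength results",
            "=" * 46,
            f"cells:                {self.data.n_cells}",
            f"pairs:                {len(self.pair_table)}",
            f"dropout zeroing:      {self.local.zeroed_dropouts}",
            f"self weight:          {self.model.self_weight}",
            f"global index mean:    {gi.mean():+.4f}",
            f"global index range:   [{gi.min():+.4f}, {gi.max():+.4f}]",
            "",
            "top pairs by |global index|:",
        ]
        order = np.argsort(-np.abs(gi))[:10]
        keys = self.pair_keys
        for j in order:
            lines.append(f"  {keys[j]:<40s} {gi[j]:+.4f}")
        return "\n".join(lines)

    def save(self, out_dir, dense: bool = False) -> None:
        """Write L (MTX, or TSV when ``dense``), pair table and global index."""
        from pathlib import Path

        from scipy.io import mmwrite

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if dense:
            pd.DataFrame(self.L, index=self.data.cell_ids,
                         columns=self.pair_keys).to_csv(
                out / "local_L.tsv", sep="\t", lineterminator="\n")
        else:
            mmwrite(out / "local_L.mtx", sp.coo_matrix(self.L))
        self.pair_table.to_tsv(out / "pairs.tsv")
        self.global_index.rename_axis("pair_key").to_csv(
            out / "global_L.tsv", sep="\t", lineterminator="\n")
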