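"""Paired single-cell multiome container and its on-disk formats.

The central object is :class:`PairedOmics`: a cell x gene expression matrix
(library-size-normalized, log1p-transformed), a cell x peak accessibility
matrix, a nonnegative cell-cell neighborhood connectivity matrix (typically
from a weighted-nearest-neighbor graph), per-cell metadata (group labels,
pseudotime, trajectory path membership) and an optional 2-D embedding, all
sharing one cell ordering.

On disk the bundle is plain text: Matrix Market (.mtx) matrices with TSV
sidecars (``cells.tsv``, ``genes.tsv``, ``peaks.tsv``, ``meta.tsv``) plus the
graph as MTX.  An HDF5 read path accepts the common single-cell container
dialect (``mod/rna``, ``mod/atac`` groups with X/obs/var slots and an
``obsp``/``uns`` connectivities entry); unknown slots are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import ParseError, StructuralError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PairedOmics",
    "parse_peak_id",
    "load_paired",
    "save_paired",
    "load_h5",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Base pairs between the two intervals; 0 on overlap or adjacency."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)

    def __len__(self) -> int:
        return self.end - self.start


_PEAK_COLON = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")
_PEAK_DASH = re.compile(r"^(?P<chrom>.+?)-(?P<start>\d+)-(?P<end>\d+)$")


def parse_peak_id(peak_id: str) -> GenomicInterval:
    """Parse a coordinate-encoded peak id into a :class:`GenomicInterval`.

    Accepts the ``chr1:100-200`` and ``chr1-100-200`` dialects produced by
    common peak-calling pipelines.
    """
    m = _PEAK_COLON.match(peak_id) or _PEAK_DASH.match(peak_id)
    if m is None:
        raise ParseError("cannot parse peak id", raw=peak_id)
    start, end = int(m["start"]), int(m["end"])
    if end <= start:
        raise ParseError("peak end must exceed start", raw=peak_id)
    return GenomicInterval(m["chrom"], start, end, ".")


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m, dtype=np.float64))


@dataclass
class PairedOmics:
    """Paired RNA + ATAC single-cell data with a cell-cell neighborhood graph.

    All matrices share one cell ordering; ``cell_meta`` is indexed by
    ``cell_ids`` and holds categorical group labels, optional pseudotime
    (NaN where missing) and optional trajectory path labels.
    """

    rna: sp.csr_matrix
    atac: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    peak_ids: list[str]
    connectivities: sp.csr_matrix
    cell_meta: pd.DataFrame
    embedding: np.ndarray | None = None

    def __post_init__(self):
        self.rna = _as_csr(self.rna)
        self.atac = _as_csr(self.atac)
        self.connectivities = _as_csr(self.connectivities)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.peak_ids = [str(p) for p in self.peak_ids]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.cell_ids)
        if n < 2:
            raise ValidationError("at least 2 cells are required")
        for name, ids in (
            ("cell_ids", self.cell_ids),
            ("gene_ids", self.gene_ids),
            ("peak_ids", self.peak_ids),
        ):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate entries in {name}")
        if self.rna.shape != (n, len(self.gene_ids)):
            raise StructuralError(
                f"rna matrix shape {self.rna.shape} does not match "
                f"{n} cells x {len(self.gene_ids)} genes"
            )
        if self.atac.shape != (n, len(self.peak_ids)):
            raise StructuralError(
                f"atac matrix shape {self.atac.shape} does not match "
                f"{n} cells x {len(self.peak_ids)} peaks"
            )
        if self.connectivities.shape != (n, n):
            raise StructuralError(
                f"connectivities shape {self.connectivities.shape} "
                f"does not match {n} cells"
            )
        if self.connectivities.nnz and self.connectivities.data.min() < 0:
            raise ValidationError("connectivities has negative entries")
        if len(self.cell_meta) != n:
            raise StructuralError(
                f"cell_meta has {len(self.cell_meta)} rows for {n} cells"
            )
        if list(self.cell_meta.index.astype(str)) != self.cell_ids:
            raise StructuralError("cell_meta index does not match cell_ids")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=np.float64)
            if self.embedding.shape != (n, 2):
                raise StructuralError(
                    f"embedding shape {self.embedding.shape} != ({n}, 2)"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lut[g] for g in gene_ids], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"unknown gene id {e.args[0]!r}") from None

    def peak_index(self, peak_ids) -> np.ndarray:
        lut = {p: i for i, p in enumerate(self.peak_ids)}
        try:
            return np.array([lut[p] for p in peak_ids], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"unknown peak id {e.args[0]!r}") from None

    def reorder_cells(self, order: np.ndarray) -> "PairedOmics":
        """Return a copy with cells permuted by ``order`` everywhere."""
        order = np.asarray(order, dtype=np.intp)
        if sorted(order.tolist()) != list(range(self.n_cells)):
            raise StructuralError("order is not a permutation of cells")
        return PairedOmics(
            rna=self.rna[order],
            atac=self.atac[order],
            cell_ids=[self.cell_ids[i] for i in order],
            gene_ids=list(self.gene_ids),
            peak_ids=list(self.peak_ids),
            connectivities=self.connectivities[order][:, order],
            cell_meta=self.cell_meta.iloc[order],
            embedding=None if self.embedding is None else self.embedding[order],
        )


# ---------------------------------------------------------------------------
# MTX/TSV bundle I/O
# ---------------------------------------------------------------------------

_BUNDLE = {
    "rna": "rna.mtx",
    "atac": "atac.mtx",
    "graph": "graph.mtx",
    "cells": "cells.tsv",
    "genes": "genes.tsv",
    "peaks": "peaks.tsv",
    "meta": "meta.tsv",
    "embedding": "embedding.tsv",
}


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def save_paired(data: PairedOmics, out_dir) -> Path:
    """Write ``data`` as a deterministic MTX + TSV bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / _BUNDLE["rna"], sp.coo_matrix(data.rna))
    mmwrite(out / _BUNDLE["atac"], sp.coo_matrix(data.atac))
    mmwrite(out / _BUNDLE["graph"], sp.coo_matrix(data.connectivities))
    for key, ids in (
        ("cells", data.cell_ids),
        ("genes", data.gene_ids),
        ("peaks", data.peak_ids),
    ):
        (out / _BUNDLE[key]).write_text("\n".join(ids) + "\n")
    meta = data.cell_meta.copy()
    meta.insert(0, "cell_id", data.cell_ids)
    meta.to_csv(out / _BUNDLE["meta"], sep="\t", index=False, lineterminator="\n")
    if data.embedding is not None:
        pd.DataFrame(
            data.embedding, columns=["dim1", "dim2"]
        ).to_csv(out / _BUNDLE["embedding"], sep="\t", index=False, lineterminator="\n")
    return out


def load_paired(
    rna_path,
    atac_path,
    meta_path,
    graph_path,
    cells_path=None,
    genes_path=None,
    peaks_path=None,
    embedding_path=None,
) -> PairedOmics:
    """Load a :class:`PairedOmics` from an MTX + TSV bundle.

    Cell order authority is the metadata file: matrices arriving in a
    different cell order (as listed in ``cells.tsv``) are reordered to match
    ``meta.tsv``, never the reverse.  Sidecar paths default to files named
    ``cells.tsv``/``genes.tsv``/``peaks.tsv`` next to the RNA matrix.
    """
    rna_path, atac_path = Path(rna_path), Path(atac_path)
    meta_path, graph_path = Path(meta_path), Path(graph_path)
    base = rna_path.parent
    cells_path = Path(cells_path) if cells_path else base / _BUNDLE["cells"]
    genes_path = Path(genes_path) if genes_path else base / _BUNDLE["genes"]
    peaks_path = Path(peaks_path) if peaks_path else base / _BUNDLE["peaks"]

    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise StructuralError(f"{meta_path} lacks a 'cell_id' column")
    meta = meta.set_index("cell_id")
    cell_ids = _read_ids(cells_path)
    gene_ids = _read_ids(genes_path)
    peak_ids = _read_ids(peaks_path)

    rna = _as_csr(mmread(rna_path))
    atac = _as_csr(mmread(atac_path))
    graph = _as_csr(mmread(graph_path))

    for name, mat, ncols in (
        (rna_path.name, rna, len(gene_ids)),
        (atac_path.name, atac, len(peak_ids)),
    ):
        if mat.shape != (len(cell_ids), ncols):
            raise StructuralError(
                f"{name}: shape {mat.shape} inconsistent with "
                f"{len(cell_ids)} cells x {ncols} features"
            )
    if graph.shape != (len(cell_ids), len(cell_ids)):
        raise StructuralError(
            f"{graph_path.name}: shape {graph.shape} is not square over "
            f"{len(cell_ids)} cells"
        )
    if set(meta.index) != set(cell_ids):
        raise StructuralError(
            f"{meta_path.name}: cell ids do not match {cells_path.name} "
            f"({len(meta)} vs {len(cell_ids)} cells)"
        )

    # reorder matrices to the metadata's cell order
    pos = {c: i for i, c in enumerate(cell_ids)}
    order = np.array([pos[c] for c in meta.index], dtype=np.intp)

    embedding = None
    if embedding_path is None:
        candidate = base / _BUNDLE["embedding"]
        embedding_path = candidate if candidate.exists() else None
    if embedding_path is not None:
        embedding = pd.read_csv(embedding_path, sep="\t").to_numpy(dtype=np.float64)
        embedding = embedding[order]

    return PairedOmics(
        rna=rna[order],
        atac=atac[order],
        cell_ids=list(meta.index.astype(str)),
        gene_ids=gene_ids,
        peak_ids=peak_ids,
        connectivities=graph[order][:, order],
        cell_meta=meta,
        embedding=embedding,
    )


# ---------------------------------------------------------------------------
# HDF5 container read path
# ---------------------------------------------------------------------------

def load_h5(path, rna_mod: str = "rna", atac_mod: str = "atac") -> PairedOmics:
    """Read a paired container from an HDF5 single-cell file.

    Accepts the multimodal dialect with ``mod/<rna_mod>`` and
    ``mod/<atac_mod>`` groups, each holding ``X`` and ``var``; cell metadata
    from the top-level ``obs``; the graph from ``obsp/connectivities`` or
    ``uns/connectivities``.  Only these slots are read; everything else is
    ignored.
    """
    import h5py
    from anndata.io import read_elem

    path = Path(path)
    with h5py.File(path, "r") as f:
        if "mod" not in f:
            raise StructuralError(f"{path.name}: no 'mod' group (not a paired container)")
        mods = f["mod"]
        for m in (rna_mod, atac_mod):
            if m not in mods:
                raise StructuralError(f"{path.name}: modality {m!r} missing from mod/")
        rna = _as_csr(read_elem(mods[rna_mod]["X"]))
        atac = _as_csr(read_elem(mods[atac_mod]["X"]))
        obs = read_elem(f["obs"]) if "obs" in f else read_elem(mods[rna_mod]["obs"])
        gene_ids = list(read_elem(mods[rna_mod]["var"]).index.astype(str))
        peak_ids = list(read_elem(mods[atac_mod]["var"]).index.astype(str))
        conn = None
        for slot in ("obsp", "uns"):
            if slot in f and "connectivities" in f[slot]:
                conn = _as_csr(read_elem(f[slot]["connectivities"]))
                break
        if conn is None:
            raise StructuralError(
                f"{path.name}: no connectivities found in obsp/ or uns/"
            )
        embedding = None
        if "obsm" in f:
            for key in ("X_embedding", "X_umap", "X_draw_graph_fa"):
                if key in f["obsm"]:
                    emb = np.asarray(read_elem(f["obsm"][key]), dtype=np.float64)
                    embedding = emb[:, :2]
                    break
    return PairedOmics(
        rna=rna,
        atac=atac,
        cell_ids=list(obs.index.astype(str)),
        gene_ids=gene_ids,
        peak_ids=peak_ids,
        connectivities=conn,
        cell_meta=obs,
        embedding=embedding,
    )
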