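import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screglink import PairedOmics, PairTable


def make_paired(n=6, g=4, q=5, seed=0, embedding=True) -> PairedOmics:
    """Small dense-ish paired container with a ring-lattice graph."""
    rng = np.random.default_rng(seed)
    rna = np.abs(rng.normal(1.0, 0.5, size=(n, g)))
    atac = np.abs(rng.normal(1.0, 0.5, size=(n, q)))
    rna[rng.random((n, g)) < 0.2] = 0.0
    atac[rng.random((n, q)) < 0.2] = 0.0
    conn = np.zeros((n, n))
    for i in range(n):
        conn[i, (i + 1) % n] = 0.5
        conn[i, (i - 1) % n] = 0.5
    meta = pd.DataFrame(
        {
            "group": ["a" if i < n // 2 else "b" for i in range(n)],
            "pseudotime": np.linspace(0, 1, n),
            "path": "main",
        },
        index=pd.Index([f"cell{i}" for i in range(n)], name="cell_id"),
    )
    return PairedOmics(
        rna=sp.csr_matrix(rna),
        atac=sp.csr_matrix(atac),
        cell_ids=list(meta.index),
        gene_ids=[f"gene{i}" for i in range(g)],
        peak_ids=[f"chr1:{1000 * i}-{1000 * i + 500}" for i in range(q)],
        connectivities=sp.csr_matrix(conn),
        cell_meta=meta,
        embedding=rng.normal(size=(n, 2)) if embedding else None,
    )


def all_pairs_table(data: PairedOmics) -> PairTable:
    rows = []
    for gid in data.gene_ids:
        for pk in data.peak_ids:
            from screglink import parse_peak_id

            iv = parse_peak_id(pk)
            rows.append(
                dict(gene_id=gid, peak_id=pk, distance_bp=0, relation="overlap",
                     gene_strand="+", peak_chrom=iv.chrom,
                     peak_start=iv.start, peak_end=iv.end)
            )
    return PairTable.from_pairs(rows)


@pytest.fixture
def toy_data():
    return make_paired()


@pytest.fixture
def toy_pairs(toy_data):
    return all_pairs_table(toy_data)
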