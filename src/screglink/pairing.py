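"""Data-preparation tools: sparsity QC, gene-peak pairing, motif conversion.

This module prepares the inputs of the correlation index: it computes
per-group feature sparsity (a QC metric for zero-inflated single-cell data),
pairs genes with nearby accessibility peaks by genomic window, pairs
transcription factors with their binding sites from a BED file, and converts
JASPAR position-frequency matrices into Homer-style motif files.

The resulting :class:`PairTable` fixes the column ordering of the per-cell
correlation matrix L computed downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenomicInterval, PairedOmics, parse_peak_id
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairTable",
    "SparsityReport",
    "feature_sparsity",
    "pair_by_window",
    "pair_by_binding_sites",
    "read_gene_annotation",
    "read_bed6",
    "jaspar_to_homer",
]

PAIR_COLUMNS = [
    "gene_id",
    "peak_id",
    "distance_bp",
    "relation",
    "gene_strand",
    "peak_chrom",
    "peak_start",
    "peak_end",
]


@dataclass
class PairTable:
    """Ordered gene-peak pair list with genomic-distance annotations.

    Rows are unique (gene_id, peak_id) pairs sorted by gene_id then distance
    ascending; this deterministic order defines the pair (column) indexing of
    the correlation matrix L.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PAIR_COLUMNS[:4] if c not in self.df.columns]
        if missing:
            raise ValidationError(f"pair table lacks columns {missing}")
        if self.df.duplicated(["gene_id", "peak_id"]).any():
            raise ValidationError("duplicate (gene_id, peak_id) rows")
        self.df = (
            self.df.sort_values(
                ["gene_id", "distance_bp", "peak_id"], kind="mergesort"
            ).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.df["gene_id"].to_numpy()

    @property
    def peak_ids(self) -> np.ndarray:
        return self.df["peak_id"].to_numpy()

    @property
    def pair_keys(self) -> list[str]:
        return [f"{g}~{p}" for g, p in zip(self.gene_ids, self.peak_ids)]

    def subset(self, mask) -> "PairTable":
        return PairTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "PairTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_pairs(cls, rows: list[dict]) -> "PairTable":
        df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
        return cls(df)


# ---------------------------------------------------------------------------
# Sparsity QC
# ---------------------------------------------------------------------------

@dataclass
class SparsityReport:
    """Per-group fraction of zero entries for every gene and peak."""

    genes: pd.DataFrame  # genes x groups, zero fraction in [0, 1]
    peaks: pd.DataFrame  # peaks x groups
    group_sizes: pd.Series

    def to_tsv(self, gene_path, peak_path) -> None:
        self.genes.to_csv(gene_path, sep="\t", lineterminator="\n")
        self.peaks.to_csv(peak_path, sep="\t", lineterminator="\n")


def feature_sparsity(data: PairedOmics, group_key: str) -> SparsityReport:
    """Compute the per-group zero fraction of every gene and peak.

    ``zero_fraction = (# zero entries in group) / (group size)`` exactly;
    high sparsity flags features whose correlation index would be dominated
    by dropout zeros in that group.
    """
    if group_key not in data.cell_meta.columns:
        raise KeyError(f"group key {group_key!r} not in cell metadata")
    groups = data.cell_meta[group_key].astype(str)
    labels = sorted(groups.unique())
    sizes = groups.value_counts()
    out = {}
    for name, mat, ids in (
        ("genes", data.rna, data.gene_ids),
        ("peaks", data.atac, data.peak_ids),
    ):
        cols = {}
        for g in labels:
            idx = np.flatnonzero((groups == g).to_numpy())
            nnz = np.asarray((mat[idx] != 0).sum(axis=0)).ravel()
            cols[g] = 1.0 - nnz / len(idx)
        out[name] = pd.DataFrame(cols, index=ids)
    return SparsityReport(
        genes=out["genes"], peaks=out["peaks"], group_sizes=sizes.loc[labels]
    )


# ---------------------------------------------------------------------------
# Gene-peak pairing
# ---------------------------------------------------------------------------

def _relation(gene: GenomicInterval, peak: GenomicInterval) -> str:
    if gene.intersects(peak):
        return "overlap"
    # peak entirely 5' or 3' of the gene body, labelled on the gene's strand
    peak_is_left = peak.end <= gene.start
    if gene.strand == "-":
        return "upstream" if not peak_is_left else "downstream"
    return "upstream" if peak_is_left else "downstream"


def pair_by_window(
    data: PairedOmics,
    gene_annot: dict[str, GenomicInterval],
    window_bp: int = 100_000,
) -> PairTable:
    """Pair each annotated gene with peaks within ``window_bp`` of its body.

    A pair (gene, peak) is included iff the peak interval intersects
    ``[gene.start - window_bp, gene.end + window_bp)`` on the same
    chromosome.  ``distance_bp`` is the gap between the peak and the gene
    body (0 on overlap); ``relation`` is strand-aware (upstream = 5' of the
    gene on its own strand).  Genes absent from the annotation and peaks
    with non-coordinate ids are skipped, with counts logged.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    if not gene_annot:
        raise ValidationError("empty gene annotation")

    peaks_by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    n_bad_peaks = 0
    for pk in data.peak_ids:
        try:
            iv = parse_peak_id(pk)
        except ParseError:
            n_bad_peaks += 1
            continue
        peaks_by_chrom.setdefault(iv.chrom, []).append((iv, pk))
    if n_bad_peaks:
        logger.warning("skipped %d peaks with non-coordinate ids", n_bad_peaks)

    gene_set = set(data.gene_ids)
    n_unannotated = sum(1 for g in data.gene_ids if g not in gene_annot)
    if n_unannotated:
        logger.info("%d genes missing from the annotation were skipped", n_unannotated)

    rows = []
    for gene_id, gi in sorted(gene_annot.items()):
        if gene_id not in gene_set:
            continue
        lo, hi = gi.start - window_bp, gi.end + window_bp
        for pv, peak_id in peaks_by_chrom.get(gi.chrom, ()):
            if pv.start < hi and pv.end > lo:
                rows.append(
                    dict(
                        gene_id=gene_id,
                        peak_id=peak_id,
                        distance_bp=gi.gap_to(pv),
                        relation=_relation(gi, pv),
                        gene_strand=gi.strand,
                        peak_chrom=pv.chrom,
                        peak_start=pv.start,
                        peak_end=pv.end,
                    )
                )
    if not rows:
        logger.warning("no gene-peak pairs found within %d bp", window_bp)
    return PairTable.from_pairs(rows)


def pair_by_binding_sites(
    data: PairedOmics, tf_sites: dict[str, list[GenomicInterval]]
) -> PairTable:
    """Pair transcription factors with peaks intersecting their binding sites.

    ``tf_sites`` maps TF names (which must resolve against ``gene_ids``;
    unmatched names are logged and skipped) to binding-site intervals.  A
    (tf, peak) pair is included iff the peak intersects any site; relation is
    always "overlap" and distance 0.
    """
    gene_set = set(data.gene_ids)
    unmatched = sorted(set(tf_sites) - gene_set)
    if unmatched:
        logger.warning(
            "%d TF names not found among gene ids were skipped: %s",
            len(unmatched),
            ", ".join(unmatched[:10]),
        )
    peak_ivs = []
    for pk in data.peak_ids:
        try:
            peak_ivs.append((parse_peak_id(pk), pk))
        except ParseError:
            continue
    rows = []
    for tf, sites in sorted(tf_sites.items()):
        if tf not in gene_set:
            continue
        for pv, peak_id in peak_ivs:
            if any(pv.intersects(site) for site in sites):
                rows.append(
                    dict(
                        gene_id=tf,
                        peak_id=peak_id,
                        distance_bp=0,
                        relation="overlap",
                        gene_strand=".",
                        peak_chrom=pv.chrom,
                        peak_start=pv.start,
                        peak_end=pv.end,
                    )
                )
    return PairTable.from_pairs(rows)


# ---------------------------------------------------------------------------
# Annotation readers
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path, id_attr: str | None = None, feature_type: str = "gene"
) -> dict[str, GenomicInterval]:
    """Read gene intervals from GFF3/GTF or BED into a 0-based half-open map.

    GFF3/GTF coordinates (1-based closed) are converted; BED is read as-is.
    ``id_attr`` selects the attribute carrying the gene id (default: try
    ``gene_id`` then ``ID`` then ``gene_name``).
    """
    path = Path(path)
    if path.suffix.lower() in {".bed"}:
        annot = {}
        for name, ivs in read_bed6(path).items():
            annot[name] = ivs[0]
        return annot

    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    candidates = [id_attr] if id_attr else ["gene_id", "ID", "gene_name", "Name"]
    annot: dict[str, GenomicInterval] = {}
    for feat in db.features_of_type(feature_type):
        gene_id = None
        for key in candidates:
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        if gene_id is None:
            gene_id = feat.id
        annot[gene_id] = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand or "."
        )
    if not annot:
        raise ValidationError(f"no {feature_type!r} features found in {path.name}")
    return annot


def read_bed6(path) -> dict[str, list[GenomicInterval]]:
    """Read a BED file mapping the name column to intervals.

    Strand is taken from column 6 when present.  Malformed lines raise a
    :class:`ParseError` carrying the line number.
    """
    sites: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("BED line has fewer than 4 columns", raw=line, line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", raw=line, line=lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValidationError as e:
                raise ParseError(str(e), raw=line, line=lineno)
            sites.setdefault(fields[3], []).append(iv)
    if not sites:
        raise ValidationError(f"no records in BED file {path}")
    return sites


# ---------------------------------------------------------------------------
# JASPAR PFM -> Homer motif conversion
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def jaspar_to_homer(
    pfm_path,
    out_path=None,
    pseudocount: float = 0.5,
    threshold_fraction: float = 0.8,
    log_base: float = 2.0,
) -> str:
    """Convert JASPAR PFM motifs into a Homer-style motif file.

    Each motif becomes a header line ``>consensus<TAB>name<TAB>threshold``
    followed by one row per position of 4 tab-separated base probabilities
    (A, C, G, T) with ``p = (count + pseudocount) / (total + 4*pseudocount)``.
    The detection threshold is ``threshold_fraction`` times the maximum
    attainable log-odds score against a uniform background, i.e.
    ``sum_pos log(max_p / 0.25)`` in base ``log_base``.

    Returns the file text; writes it to ``out_path`` when given.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if not (0 < threshold_fraction <= 1):
        raise ValidationError("threshold_fraction must be in (0, 1]")

    from Bio import motifs as bio_motifs

    pfm_path = Path(pfm_path)
    text = pfm_path.read_text()
    parsed = None
    for fmt in ("jaspar", "pfm"):
        try:
            with open(pfm_path) as fh:
                parsed = list(bio_motifs.parse(fh, fmt))
            if parsed:
                break
        except Exception:
            parsed = None
    if not parsed:
        raise ParseError("could not parse JASPAR PFM input", raw=pfm_path.name)

    blocks = []
    for motif in parsed:
        counts = motif.counts
        length = counts.length
        cols = np.array([[counts[b][i] for i in range(length)] for b in _BASES])
        if np.any(cols < 0):
            raise ParseError("negative counts in PFM", raw=motif.name or pfm_path.name)
        totals = cols.sum(axis=0)
        probs = (cols + pseudocount) / (totals + 4 * pseudocount)
        max_p = probs.max(axis=0)
        max_score = float(np.sum(np.log(max_p / 0.25) / math.log(log_base)))
        threshold = threshold_fraction * max_score
        consensus = "".join(_BASES[i] for i in probs.argmax(axis=0))
        name = motif.name or motif.base_id if hasattr(motif, "base_id") else motif.name
        name = name or pfm_path.stem
        lines = [f">{consensus}\t{name}\t{threshold:.10g}"]
        for i in range(length):
            lines.append("\t".join(f"{probs[b, i]:.12g}" for b in range(4)))
        blocks.append("\n".join(lines))
    out = "\n".join(blocks) + "\n"
    if out_path is not None:
        Path(out_path).write_text(out)
    return out
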