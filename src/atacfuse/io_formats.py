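"""Readers and writers for the text formats the pipeline touches.

All genomic intervals are stored 0-based half-open internally. BED input is
already 0-based half-open; GTF is 1-based inclusive and is converted at parse
time. MatrixMarket coordinates are 1-based per the standard and handled by
``scipy.io``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """A file is syntactically or semantically malformed."""


class ConsistencyError(ValueError):
    """Two files that must describe the same objects disagree."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def key(self) -> str:
        """Stable identity string in internal coordinates."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakCountMatrix:
    """Sparse peaks x cells non-negative integer count matrix.

    Rows are peaks, columns are cells, matching common scATAC conventions for
    on-disk MTX triplets.
    """

    counts: sp.csr_matrix
    peaks: list[Peak]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_peaks, n_cells = self.counts.shape
        if n_peaks != len(self.peaks):
            raise ConsistencyError(
                f"count matrix has {n_peaks} rows but {len(self.peaks)} peaks given"
            )
        if n_cells != len(self.barcodes):
            raise ConsistencyError(
                f"count matrix has {n_cells} columns but {len(self.barcodes)} barcodes given"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ConsistencyError("duplicate cell barcodes")
        keys = [p.key for p in self.peaks]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("duplicate peaks")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def peak_keys(self) -> list[str]:
        return [p.key for p in self.peaks]


@dataclass
class GeneAnnotation:
    """Gene records with 0-based half-open body coordinates.

    ``records`` columns: gene_id, chrom, strand ('+'/'-'), start, end.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "start", "end"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
        if self.records["gene_id"].duplicated().any():
            dup = self.records.loc[self.records["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r}")
        bad_strand = ~self.records["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise FormatError(
                f"unknown strand symbol {self.records.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        if (self.records["start"] >= self.records["end"]).any():
            raise FormatError("gene with body_start >= body_end")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return self.records["gene_id"].tolist()


@dataclass
class MotifAnnotation:
    """Binary peaks x motifs membership with optional per-peak GC fraction."""

    membership: sp.csr_matrix
    motif_ids: list[str]
    gc_fraction: np.ndarray | None = None
    n_binarized: int = 0  # entries coerced from >1 values on read

    def __post_init__(self) -> None:
        self.membership = sp.csr_matrix(self.membership)
        if self.membership.shape[1] != len(self.motif_ids):
            raise ConsistencyError("membership columns do not match motif_ids")
        data = self.membership.data
        if data.size and not np.all(np.isin(data, [0, 1])):
            raise FormatError("membership entries must be 0/1 after binarization")
        if self.gc_fraction is not None:
            self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
            if self.gc_fraction.shape[0] != self.membership.shape[0]:
                raise ConsistencyError("gc_fraction length does not match peaks")
            if np.any((self.gc_fraction < 0) | (self.gc_fraction > 1)):
                raise FormatError("gc_fraction values outside [0, 1]")

    @property
    def n_motifs(self) -> int:
        return len(self.motif_ids)


@dataclass
class CellLabels:
    """Barcode -> cell-type label used as clustering ground truth."""

    labels: pd.Series  # index: barcode, values: label strings

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ConsistencyError("duplicate barcodes in labels")
        self.labels = self.labels.astype(str)

    def aligned_to(self, barcodes: Sequence[str]) -> np.ndarray:
        missing = set(barcodes) - set(self.labels.index)
        if missing:
            raise ConsistencyError(
                f"{len(missing)} barcodes missing from labels, e.g. {sorted(missing)[0]!r}"
            )
        return self.labels.reindex(list(barcodes)).to_numpy()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_peak_matrix(mtx_path, peaks_bed_path, barcodes_tsv_path) -> PeakCountMatrix:
    """Read an MTX + BED + barcode-TSV triplet into a validated matrix."""
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # malformed MTX
        raise FormatError(f"cannot parse MTX file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    peaks = read_peaks_bed(peaks_bed_path)
    barcodes = _read_single_column(barcodes_tsv_path)

    if mat.shape[0] != len(peaks):
        raise ConsistencyError(
            f"MTX has {mat.shape[0]} rows but BED lists {len(peaks)} peaks"
        )
    if mat.shape[1] != len(barcodes):
        raise ConsistencyError(
            f"MTX has {mat.shape[1]} columns but {len(barcodes)} barcodes listed"
        )
    return PeakCountMatrix(counts=mat, peaks=peaks, barcodes=barcodes)


def read_peaks_bed(path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: BED line has <3 fields")
            try:
                peaks.append(Peak(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return peaks


def _read_single_column(path) -> list[str]:
    with open(path) as fh:
        return [ln.split("\t")[0].strip() for ln in fh if ln.strip()]


def read_gene_annotation(path, dialect: str = "tsv") -> GeneAnnotation:
    """Read gene records from a GTF (gene features only) or a BED-like TSV.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention; the TSV dialect is assumed already internal.
    """
    if dialect == "gtf":
        rows = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise FormatError(f"{path}:{line_no}: GTF line has <9 fields")
                if fields[2] != "gene":
                    continue
                gene_id = _parse_gtf_gene_id(fields[8], path, line_no)
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": fields[0],
                        "strand": fields[6],
                        # GTF 1-based inclusive -> 0-based half-open
                        "start": int(fields[3]) - 1,
                        "end": int(fields[4]),
                    }
                )
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    elif dialect == "tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"gene_id": str, "chrom": str, "strand": str, "start": int, "end": int},
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'gtf' or 'tsv'")
    if df.empty:
        raise FormatError(f"no gene records in {path}")
    return GeneAnnotation(records=df)


def _parse_gtf_gene_id(attributes: str, path, line_no: int) -> str:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise FormatError(f"{path}:{line_no}: GTF attributes lack gene_id")


def read_motif_annotation(path, peaks: Sequence[Peak], motif_ids=None,
                          gc_fraction=None) -> MotifAnnotation:
    """Read a peaks x motifs membership matrix (MTX or dense TSV).

    Values > 0 are binarized to 1; the number of coerced entries is recorded
    on the returned object and reported with a warning.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = sp.csr_matrix(scipy.io.mmread(str(path)))
        if motif_ids is None:
            motif_ids = [f"motif{j}" for j in range(mat.shape[1])]
    else:
        df = pd.read_csv(path, sep="\t")
        if motif_ids is None:
            motif_ids = [str(c) for c in df.columns]
        mat = sp.csr_matrix(df.to_numpy(dtype=float))
    if mat.shape[0] != len(peaks):
        raise ConsistencyError(
            f"motif matrix has {mat.shape[0]} rows but {len(peaks)} peaks"
        )
    if mat.data.size and np.any(mat.data < 0):
        raise FormatError("negative motif membership values")
    n_binarized = int(np.sum(mat.data > 1))
    if n_binarized:
        warnings.warn(f"binarized {n_binarized} membership values > 1")
    mat.data = (mat.data > 0).astype(np.int8)
    mat.eliminate_zeros()
    return MotifAnnotation(
        membership=mat,
        motif_ids=list(motif_ids),
        gc_fraction=gc_fraction,
        n_binarized=n_binarized,
    )


def read_cell_labels(path) -> CellLabels:
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"], dtype=str)
    return CellLabels(labels=pd.Series(df["label"].to_numpy(), index=df["barcode"]))


def read_embedding_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Read a barcode-indexed embedding TSV; returns (matrix, barcodes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(b) for b in df.index]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_peak_matrix(pm: PeakCountMatrix, mtx_path, peaks_bed_path, barcodes_tsv_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(pm.counts), field="integer")
    with open(peaks_bed_path, "w") as fh:
        for p in pm.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    with open(barcodes_tsv_path, "w") as fh:
        fh.write("\n".join(pm.barcodes) + "\n")


def write_embedding_tsv(path, embedding: np.ndarray, barcodes: Sequence[str],
                        prefix: str = "dim") -> None:
    emb = np.asarray(embedding, dtype=float)
    df = pd.DataFrame(
        emb, index=list(barcodes), columns=[f"{prefix}{i + 1}" for i in range(emb.shape[1])]
    )
    df.index.name = "barcode"
    # repr-precision floats so a round-trip is exact to well below 1e-12
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_results(joint, clusters=None, pseudotime=None, out_dir=".",
                  metadata: dict | None = None) -> dict[str, Path]:
    """Write a joint representation plus optional downstream outputs.

    Embedding-kind representations become a barcode-indexed TSV; graph-kind
    become an edge-list TSV. Cluster assignments and pseudotime get one TSV
    each, and run metadata is serialized to JSON.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    barcodes = list(joint.barcodes)
    if joint.kind == "embedding":
        path = out_dir / "joint_embedding.tsv"
        write_embedding_tsv(path, joint.embedding, barcodes)
        written["embedding"] = path
    else:
        path = out_dir / "joint_graph_edges.tsv"
        coo = sp.triu(joint.graph, k=0).tocoo()
        with open(path, "w") as fh:
            fh.write("barcode_i\tbarcode_j\tweight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{barcodes[i]}\t{barcodes[j]}\t{w:.17g}\n")
        written["graph"] = path

    if clusters is not None:
        path = out_dir / "clusters.tsv"
        with open(path, "w") as fh:
            fh.write("barcode\tcluster\n")
            for bc, c in zip(clusters.barcodes, clusters.labels):
                fh.write(f"{bc}\t{int(c)}\n")
        written["clusters"] = path

    if pseudotime is not None:
        path = out_dir / "pseudotime.tsv"
        with open(path, "w") as fh:
            fh.write("barcode\tpseudotime\n")
            for bc, t in zip(barcodes, np.asarray(pseudotime, dtype=float)):
                fh.write(f"{bc}\t{t:.17g}\n")
        written["pseudotime"] = path

    meta = dict(metadata or {})
    meta.setdefault("versions", _versions())
    path = out_dir / "run_metadata.json"
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    written["metadata"] = path
    return written


def _versions() -> dict[str, str]:
    import importlib.metadata as im

    out = {}
    for dist in ("atacfuse", "numpy", "scipy", "pandas", "scikit-learn"):
        try:
            out[dist] = im.version(dist)
        except im.PackageNotFoundError:
            pass
    return out
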