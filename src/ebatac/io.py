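"""Readers and writers for every on-disk artifact the pipeline touches.

All genomic coordinates are 0-based half-open; an interval's length is
``end - start`` exactly.  Formats are plain text: fragments as 4/5-column
TSV (optionally gzipped, detected by the ``.gz`` extension), peaks as BED,
count matrices as Matrix Market with one-id-per-line sidecar files, gene
and motif tables as headered TSV, and network edges as TSV or SIF.

Round trips (``write o read`` and ``read o write``) are lossless.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class FragmentRecord:
    """A mapped ATAC fragment: one Tn5-bounded insert assigned to a cell."""

    contig: str
    start: int
    end: int
    barcode: str
    support: int = 1

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("fragment contig must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")
        if self.support < 1:
            raise ValueError(f"fragment support {self.support} < 1")


class Fragments:
    """Columnar sequence of :class:`FragmentRecord`.

    Behaves like a sequence (len / iteration / indexing) while storing
    numpy columns so that millions of fragments stay cheap to hold and
    to aggregate.
    """

    __slots__ = ("contigs", "starts", "ends", "barcodes", "supports")

    def __init__(self, contigs, starts, ends, barcodes, supports=None):
        self.contigs = np.asarray(contigs, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.barcodes = np.asarray(barcodes, dtype=object)
        if supports is None:
            supports = np.ones(len(self.starts), dtype=np.int64)
        self.supports = np.asarray(supports, dtype=np.int64)
        n = len(self.starts)
        for name in ("contigs", "ends", "barcodes", "supports"):
            if len(getattr(self, name)) != n:
                raise ValueError("fragment columns have unequal lengths")
        if n:
            if (self.starts >= self.ends).any():
                bad = int(np.argmax(self.starts >= self.ends))
                raise ValueError(
                    f"fragment {bad}: start {self.starts[bad]} >= end {self.ends[bad]}"
                )
            if (self.supports < 1).any():
                raise ValueError("fragment support < 1")

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "Fragments":
        recs = list(records)
        return cls(
            [r.contig for r in recs],
            [r.start for r in recs],
            [r.end for r in recs],
            [r.barcode for r in recs],
            [r.support for r in recs],
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> FragmentRecord:
        return FragmentRecord(
            self.contigs[i],
            int(self.starts[i]),
            int(self.ends[i]),
            self.barcodes[i],
            int(self.supports[i]),
        )

    def __iter__(self) -> Iterator[FragmentRecord]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fragments):
            return NotImplemented
        return (
            len(self) == len(other)
            and (self.contigs == other.contigs).all()
            and (self.starts == other.starts).all()
            and (self.ends == other.ends).all()
            and (self.barcodes == other.barcodes).all()
            and (self.supports == other.supports).all()
        )


@dataclass(frozen=True)
class PeakInterval:
    """An accessible-chromatin peak, the unit of the peak-signal matrix."""

    peak_id: str
    contig: str
    start: int
    end: int
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, used for QC windows and gene activity."""

    gene_id: str
    contig: str
    tss: int
    strand: str
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss {self.tss} < 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class CountMatrix:
    """Sparse nonnegative peak x cell fragment counts, the pipeline root."""

    values: sp.csr_matrix
    peak_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.peak_ids), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.peak_ids)} peaks x {len(self.barcodes)} barcodes"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_barcodes(self, keep: Sequence[str]) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        cols = [index[b] for b in keep]
        return CountMatrix(self.values[:, cols].tocsr(), list(self.peak_ids), list(keep))


@dataclass
class MotifHitTable:
    """Binary motif x peak indicator with a motif -> TF gene mapping."""

    values: np.ndarray  # motifs x peaks, {0,1}
    motif_ids: list[str]
    peak_ids: list[str]
    motif_to_tf: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.motif_ids), len(self.peak_ids)):
            raise ValueError("motif table shape does not match id lists")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("motif table entries must be 0 or 1")
        missing = [m for m in self.motif_ids if m not in self.motif_to_tf]
        if missing:
            raise ValueError(f"motifs without a TF mapping: {missing}")

    def peaks_for_motif(self, motif_id: str) -> list[str]:
        row = self.motif_ids.index(motif_id)
        return [self.peak_ids[j] for j in np.flatnonzero(self.values[row])]


@dataclass(frozen=True)
class EdgeRecord:
    """A directed TF -> target edge of the regulatory network."""

    source_tf: str
    target_gene: str
    weight: float
    n_loops: int
    group: str

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("edge weight must be >= 0")
        if self.n_loops < 1:
            raise ValueError("edge must be supported by >= 1 loop")


# ---------------------------------------------------------------------------
# fragments


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> Fragments:
    """Read a 4/5-column fragments TSV (contig, start, end, barcode[, support])."""
    contigs, starts, ends, barcodes, supports = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 or 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
                support = int(parts[4]) if len(parts) == 5 else 1
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            if support < 1:
                raise FormatError(f"{path}: line {lineno}: support {support} < 1")
            if not parts[0]:
                raise FormatError(f"{path}: line {lineno}: empty contig")
            contigs.append(parts[0])
            starts.append(start)
            ends.append(end)
            barcodes.append(parts[3])
            supports.append(support)
    return Fragments(contigs, starts, ends, barcodes, supports)


def write_fragments(fragments: Fragments | Iterable[FragmentRecord], path) -> None:
    """Write fragments as a 5-column TSV (gzipped if path ends in .gz)."""
    if not isinstance(fragments, Fragments):
        fragments = Fragments.from_records(fragments)
    with _open_text(path, "wt") as fh:
        for i in range(len(fragments)):
            fh.write(
                f"{fragments.contigs[i]}\t{fragments.starts[i]}\t{fragments.ends[i]}"
                f"\t{fragments.barcodes[i]}\t{fragments.supports[i]}\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED)


def read_peaks(path) -> list[PeakInterval]:
    """Read peaks from BED3+ (optional 4th name and 5th gc_fraction column)."""
    peaks: list[PeakInterval] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from None
            peak_id = parts[3] if len(parts) > 3 and parts[3] else f"peak_{lineno}"
            gc = float("nan")
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    gc = float(parts[4])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric gc_fraction"
                    ) from None
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            if peak_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate peak_id {peak_id}")
            seen.add(peak_id)
            peaks.append(PeakInterval(peak_id, parts[0], start, end, gc))
    return peaks


def write_peaks(peaks: Sequence[PeakInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for p in peaks:
            gc = "." if np.isnan(p.gc_fraction) else format(p.gc_fraction, ".6g")
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.peak_id}\t{gc}\n")


# ---------------------------------------------------------------------------
# counts (Matrix Market + sidecars)


def _read_sidecar(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def read_counts(matrix_path, peaks_path, barcodes_path) -> CountMatrix:
    """Read a peak x cell count matrix with one-id-per-line sidecar files."""
    mat = sp.csr_matrix(mmread(str(matrix_path)))
    peak_ids = _read_sidecar(peaks_path)
    barcodes = _read_sidecar(barcodes_path)
    if mat.shape != (len(peak_ids), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but sidecars list "
            f"{len(peak_ids)} peaks and {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entry in count matrix")
    return CountMatrix(mat, peak_ids, barcodes)


def write_counts(counts: CountMatrix, matrix_path, peaks_path, barcodes_path) -> None:
    mmwrite(str(matrix_path), sp.coo_matrix(counts.values))
    with _open_text(peaks_path, "wt") as fh:
        fh.writelines(f"{p}\n" for p in counts.peak_ids)
    with _open_text(barcodes_path, "wt") as fh:
        fh.writelines(f"{b}\n" for b in counts.barcodes)


# ---------------------------------------------------------------------------
# gene / motif tables

GENE_COLUMNS = ("gene_id", "contig", "tss", "strand", "is_tf")
MOTIF_COLUMNS = ("motif_id", "tf_gene", "peak_id")


def read_gene_table(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_COLUMNS:
            raise FormatError(f"{path}: expected header {GENE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 fields")
            gene_id, contig, tss, strand, is_tf = parts
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneModel(gene_id, contig, int(tss), strand, is_tf in ("1", "True", "true"))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.contig}\t{g.tss}\t{g.strand}\t{int(g.is_tf)}\n")


def read_motif_table(path, peak_ids: Sequence[str]) -> MotifHitTable:
    """Read a long-format motif-hit TSV (motif_id, tf_gene, peak_id).

    ``peak_ids`` supplies the peak axis; motif rows referencing unknown
    peaks are an error listing the offenders.
    """
    peak_index = {p: j for j, p in enumerate(peak_ids)}
    motif_order: list[str] = []
    motif_to_tf: dict[str, str] = {}
    hits: dict[str, set[int]] = {}
    unknown: list[str] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MOTIF_COLUMNS:
            raise FormatError(f"{path}: expected header {MOTIF_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            motif_id, tf_gene, peak_id = parts
            if motif_id in motif_to_tf and motif_to_tf[motif_id] != tf_gene:
                raise FormatError(
                    f"{path}: line {lineno}: motif {motif_id} maps to both "
                    f"{motif_to_tf[motif_id]} and {tf_gene}"
                )
            if motif_id not in motif_to_tf:
                motif_to_tf[motif_id] = tf_gene
                motif_order.append(motif_id)
                hits[motif_id] = set()
            if peak_id not in peak_index:
                unknown.append(f"line {lineno}: {peak_id}")
                continue
            hits[motif_id].add(peak_index[peak_id])
    if unknown:
        raise FormatError(f"{path}: motif hits reference unknown peaks: {unknown}")
    values = np.zeros((len(motif_order), len(peak_ids)), dtype=np.int8)
    for i, m in enumerate(motif_order):
        values[i, sorted(hits[m])] = 1
    return MotifHitTable(values, motif_order, list(peak_ids), motif_to_tf)


def write_motif_table(table: MotifHitTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(MOTIF_COLUMNS) + "\n")
        for i, m in enumerate(table.motif_ids):
            tf = table.motif_to_tf[m]
            for j in np.flatnonzero(table.values[i]):
                fh.write(f"{m}\t{tf}\t{table.peak_ids[j]}\n")


def read_tables(gene_path, motif_path, peak_ids: Sequence[str]):
    """Read the gene model table and the motif-hit table together."""
    return read_gene_table(gene_path), read_motif_table(motif_path, peak_ids)


# ---------------------------------------------------------------------------
# edge lists

EDGE_COLUMNS = ("source", "target", "weight", "n_loops", "group")


def write_edge_list(edges: Sequence[EdgeRecord], path, format: str = "tsv") -> None:
    """Write network edges as TSV (default) or Cytoscape-importable SIF."""
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    with _open_text(path, "wt") as fh:
        if format == "tsv":
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for e in edges:
                fh.write(
                    f"{e.source_tf}\t{e.target_gene}\t{format_float(e.weight)}"
                    f"\t{e.n_loops}\t{e.group}\n"
                )
        else:
            for e in edges:
                fh.write(f"{e.source_tf}\tregulates\t{e.target_gene}\n")


def format_float(x: float) -> str:
    """Serialize a weight with 6 significant digits."""
    return format(float(x), ".6g")


def read_edge_list(path) -> list[EdgeRecord]:
    edges: list[EdgeRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_COLUMNS:
            raise FormatError(f"{path}: expected header {EDGE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 fields")
            edges.append(
                EdgeRecord(parts[0], parts[1], float(parts[2]), int(parts[3]), parts[4])
            )
    return edges
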