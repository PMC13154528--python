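"""Per-cell quality control: fragment counts, TSS reads, TSS enrichment.

Both ends of every fragment are treated as Tn5 insertion events (the
standard ATAC convention).  For each insertion the nearest TSS on its
contig defines a signed offset; the TSS enrichment score compares the
insertion density in a central window around the TSS against the density
in the two outermost edge windows of the flank.  All windows are
symmetric and half-open, so a perfectly flat insertion profile scores 1
(up to the stabilizing pseudocount in the denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Fragments, GeneModel


@dataclass
class QCRecord:
    barcode: str
    n_fragments: int
    reads_in_tss: int
    tss_enrichment: float
    passed: bool = False

    def __post_init__(self) -> None:
        if self.reads_in_tss > 2 * self.n_fragments:
            raise ValueError(
                f"{self.barcode}: reads_in_tss {self.reads_in_tss} exceeds twice "
                f"the fragment count {self.n_fragments}"
            )


def compute_qc(
    fragments: Fragments,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    center_bp: int = 50,
    edge_bp: int = 100,
    pseudocount: float = 0.1,
    barcodes: Sequence[str] | None = None,
) -> list[QCRecord]:
    """Compute per-cell QC metrics from fragments and a gene model.

    ``barcodes`` optionally names the full cell universe, so cells that
    contributed no fragments still get a (zeroed) record.
    """
    if not isinstance(fragments, Fragments):
        fragments = Fragments.from_records(fragments)
    if not genes:
        raise ValueError("compute_qc requires a non-empty gene set")
    if not (0 < center_bp <= flank_bp and 0 < edge_bp <= flank_bp):
        raise ValueError("window sizes must satisfy 0 < center,edge <= flank")

    if barcodes is None:
        cells = sorted(set(fragments.barcodes.tolist()))
    else:
        cells = list(barcodes)
        extra = set(fragments.barcodes.tolist()) - set(cells)
        if extra:
            raise ValueError(f"fragments reference barcodes outside the universe: {sorted(extra)[:5]}")
    cell_index = {b: i for i, b in enumerate(cells)}
    n_cells = len(cells)

    tss_by_contig: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_contig.setdefault(g.contig, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_contig = {c: np.array(sorted(v)) for c, v in tss_by_contig.items()}

    n_frag = np.zeros(n_cells, dtype=np.int64)
    in_tss = np.zeros(n_cells, dtype=np.int64)
    center_ct = np.zeros(n_cells, dtype=np.float64)
    edge_ct = np.zeros(n_cells, dtype=np.float64)

    if len(fragments):
        codes = np.fromiter(
            (cell_index[b] for b in fragments.barcodes), dtype=np.int64, count=len(fragments)
        )
        np.add.at(n_frag, codes, fragments.supports)

        # both fragment ends as insertion positions (end is exclusive)
        pos = np.concatenate([fragments.starts, fragments.ends - 1])
        icodes = np.concatenate([codes, codes])
        isupp = np.concatenate([fragments.supports, fragments.supports])
        icontig = np.concatenate([fragments.contigs, fragments.contigs])

        for contig, tss in tss_by_contig.items():
            mask = icontig == contig
            if not mask.any():
                continue
            p = pos[mask]
            idx = np.searchsorted(tss, p)
            left = tss[np.clip(idx - 1, 0, len(tss) - 1)]
            right = tss[np.clip(idx, 0, len(tss) - 1)]
            delta = np.where(np.abs(p - left) <= np.abs(p - right), p - left, p - right)
            c = icodes[mask]
            s = isupp[mask]
            flank = (delta >= -flank_bp) & (delta < flank_bp)
            np.add.at(in_tss, c[flank], s[flank])
            cen = (delta >= -center_bp) & (delta < center_bp)
            np.add.at(center_ct, c[cen], s[cen])
            edge = ((delta >= -flank_bp) & (delta < -flank_bp + edge_bp)) | (
                (delta >= flank_bp - edge_bp) & (delta < flank_bp)
            )
            np.add.at(edge_ct, c[edge], s[edge])

    center_density = center_ct / (2 * center_bp)
    edge_density = edge_ct / (2 * edge_bp)
    enrichment = np.where(
        n_frag > 0, center_density / (edge_density + pseudocount), 0.0
    )
    return [
        QCRecord(b, int(n_frag[i]), int(in_tss[i]), float(enrichment[i]))
        for i, b in enumerate(cells)
    ]


def filter_cells(
    qc: Iterable[QCRecord],
    min_frag: float = 10**4.5,
    max_frag: float = 1e5,
    min_log10_tss: float = 3.5,
    max_log10_tss: float = 4.5,
) -> list[str]:
    """Apply the retention filters; bounds are inclusive on both sides.

    Marks each record's ``passed`` flag and returns retained barcodes in
    input order.  Cells with zero TSS reads always fail (log10 undefined).
    """
    if min_frag > max_frag:
        raise ValueError(f"min_frag {min_frag} > max_frag {max_frag}")
    if min_log10_tss > max_log10_tss:
        raise ValueError(f"min_log10_tss {min_log10_tss} > max_log10_tss {max_log10_tss}")
    retained: list[str] = []
    for rec in qc:
        ok = min_frag <= rec.n_fragments <= max_frag
        if rec.reads_in_tss <= 0:
            ok = False
        else:
            ok = ok and min_log10_tss <= math.log10(rec.reads_in_tss) <= max_log10_tss
        rec.passed = bool(ok)
        if ok:
            retained.append(rec.barcode)
    return retained


def remove_doublets(qc: list[QCRecord]) -> list[QCRecord]:
    """Doublet-removal hook.

    Doublet inference is out of scope; this no-op preserves the pipeline
    seam where an inference step (e.g. simulated-doublet projection)
    would drop records.  It returns the input unchanged.
    """
    return qc
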