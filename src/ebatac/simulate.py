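"""Synthetic embryoid-body scATAC data with planted ground truth.

The generator emulates a spontaneous embryoid-body differentiation
experiment sampled at two stages (D4, D8) and containing seven cell
populations: embryonic stem cells (ESC), three terminal germ layers
(END, MES, ECT) and three "early committed" intermediates (EC_END,
EC_MES, EC_ECT) whose chromatin is a probability mixture of the ESC
state and one germ-layer state.

The genome is a single synthetic contig.  Genes sit every 200 kb and are
assigned round-robin to four lineage pools (ESC, END, MES, ECT), so any
two genes of the same pool are >= 800 kb apart; this keeps co-active
peaks of one regulatory program from forming spurious short-range
correlated pairs and leaves the planted enhancer-promoter loop as the
only co-accessible pair within the loop-calling window.  Each gene
carries one promoter peak (TSS +/- 250 bp) and ``enhancers_per_target``
enhancer peaks 5-100 kb away.

Each type's marker TFs own planted regulons (sets of target genes drawn
from the type's pool); a cell's "active program" is the union of its
type's marker-TF promoter peaks and all regulon targets' enhancer and
promoter peaks.  Active peaks are open with probability ``p1``, all
others with ``p0``; counts are Poisson with a log-normal per-cell depth.
The first marker TF of each germ layer gets a ``master_regulon_boost``-fold
regulon, planting one master regulator per lineage.  Non-marker "extra"
TFs are themselves regulon targets of the markers, giving each lineage
downstream TF genes (so TF->TF network edges exist) and a set of
lineage-specific non-marker TFs.

All randomness flows from a single seed through named substreams
(reference / counts / fragments), so each stage is reproducible on its
own.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, Fragments, GeneModel, MotifHitTable, PeakInterval

TYPE_LABELS = ("ESC", "END", "MES", "ECT", "EC_END", "EC_MES", "EC_ECT")
STAGES = ("D4", "D8")
POOL_TYPES = ("ESC", "END", "MES", "ECT")
GERM_LAYERS = ("END", "MES", "ECT")

DEFAULT_MARKER_TFS: dict[str, list[str]] = {
    "ESC": ["POU5F1", "NANOG"],
    "END": ["SOX17", "GATA6", "FOXA2"],
    "MES": ["EOMES", "TBXT", "MESP1", "MIXL1"],
    "ECT": ["TFAP2A", "GRHL2", "PAX6", "NEUROD1"],
}

# D4 is rich in ESC and early-committed cells, D8 in terminal germ layers.
DEFAULT_CELLS: dict[str, dict[str, int]] = {
    "D4": {"ESC": 80, "END": 30, "MES": 30, "ECT": 30,
           "EC_END": 70, "EC_MES": 70, "EC_ECT": 70},
    "D8": {"ESC": 20, "END": 70, "MES": 70, "ECT": 70,
           "EC_END": 30, "EC_MES": 30, "EC_ECT": 30},
}

GENE_SPACING = 200_000
CONTIG = "chrS"
PROMOTER_HALF_WIDTH = 250
ENHANCER_HALF_WIDTH = 200
MIN_ENHANCER_OFFSET = 5_000
MAX_ENHANCER_OFFSET = 100_000


def substream_seed(seed: int, name: str) -> int:
    """Derive a named, stage-local seed below 2**31 from one global seed."""
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimDesign:
    """Parameters of the synthetic embryoid-body experiment.

    ``p0``/``p1`` are baseline/active per-peak open probabilities; the
    early-committed mixture weight ``alpha`` blends ESC and lineage open
    probabilities.  Per-cell depth is LogNormal(depth_mu, depth_sigma);
    background fragments per cell are Poisson(bg_rate * depth).
    """

    cells_per_type_per_stage: dict[str, dict[str, int]] = field(
        default_factory=lambda: {s: dict(DEFAULT_CELLS[s]) for s in STAGES}
    )
    n_genes: int = 300
    n_tfs: int = 28
    enhancers_per_target: int = 1
    marker_tfs: dict[str, list[str]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_MARKER_TFS.items()}
    )
    regulon_size: int = 8
    master_regulon_boost: int = 2
    p0: float = 0.05
    p1: float = 0.85
    alpha: float = 0.5
    depth_mu: float = 2.1
    depth_sigma: float = 0.35
    bg_rate: float = 40.0
    motif_bg_rate: float = 0.001
    seed: int = 0

    type_labels: tuple[str, ...] = TYPE_LABELS

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_marker_tfs(self) -> int:
        return sum(len(v) for v in self.marker_tfs.values())

    def validate(self) -> None:
        # p0 == p1 is allowed as a deliberately degenerate design in which
        # cell identity is unrecoverable from chromatin
        if not 0 <= self.p0 <= self.p1 <= 1 or self.p1 == 0:
            raise ValueError(f"need 0 <= p0 <= p1 <= 1, p1 > 0; got p0={self.p0}, p1={self.p1}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for stage, row in self.cells_per_type_per_stage.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage}")
            for t, n in row.items():
                if t not in TYPE_LABELS:
                    raise ValueError(f"unknown cell type {t}")
                if n < 0:
                    raise ValueError(f"negative cell count for {stage}/{t}")
        if set(self.marker_tfs) != set(POOL_TYPES):
            raise ValueError(f"marker_tfs must cover exactly {POOL_TYPES}")
        if any(len(v) == 0 for v in self.marker_tfs.values()):
            raise ValueError("each marker set must be non-empty")
        if self.n_tfs < self.n_marker_tfs:
            raise ValueError(
                f"n_tfs={self.n_tfs} smaller than the {self.n_marker_tfs} marker TFs"
            )
        if self.regulon_size < 0 or self.n_genes < 1:
            raise ValueError("counts must be >= 0")
        if self.enhancers_per_target == 0 and self.regulon_size > 0:
            raise ValueError(
                "enhancers_per_target=0 with regulon_size>0: regulon targets "
                "would be unreachable by loops"
            )


@dataclass
class Reference:
    """The synthetic genome annotation emitted by :func:`build_reference`."""

    peaks: list[PeakInterval]
    genes: list[GeneModel]
    motif_hits: MotifHitTable
    true_loops: list[tuple[str, str]]
    regulons: dict[str, list[str]]          # TF -> target genes
    tf_type: dict[str, str]                 # TF -> pool type
    programs: dict[str, set[str]]           # pool type -> active peak ids
    contig_length: int

    @property
    def promoter_peak(self) -> dict[str, str]:
        return {g.gene_id: f"{g.gene_id}_prom" for g in self.genes}


@dataclass
class GroundTruth:
    """Simulator-emitted labels and planted structure (the acceptance surface)."""

    cell_type: dict[str, str]
    stage: dict[str, str]
    true_pseudotime: dict[str, float]
    regulon_edges: list[tuple[str, str]]
    true_loops: list[tuple[str, str]]
    marker_sets: dict[str, list[str]]
    tf_type: dict[str, str]
    depths: dict[str, float]


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` items proportionally to ``weights`` (deterministic)."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def build_reference(design: SimDesign) -> Reference:
    """Lay out genes, peaks, planted regulons, motif hits and true loops."""
    design.validate()
    rng = np.random.default_rng(substream_seed(design.seed, "reference"))

    n_extra = design.n_tfs - design.n_marker_tfs
    # novel (non-marker) TFs are planted for the germ layers only: they are
    # the lineage-specific discoveries the downstream ranking should surface
    extra_per_pool = _largest_remainder(
        [0.0 if t == "ESC" else 1.0 for t in POOL_TYPES], n_extra
    ) if n_extra else [0] * len(POOL_TYPES)

    # --- assign gene names to interleaved pool slots
    pool_slots: dict[str, list[int]] = {
        t: list(range(i, design.n_genes, len(POOL_TYPES)))
        for i, t in enumerate(POOL_TYPES)
    }
    gene_names: dict[int, tuple[str, bool]] = {}
    pool_extras: dict[str, list[str]] = {}
    for pi, t in enumerate(POOL_TYPES):
        slots = pool_slots[t]
        names = list(design.marker_tfs[t])
        extras = [f"TF_{t}_{k:02d}" for k in range(extra_per_pool[pi])]
        pool_extras[t] = extras
        needed = len(names) + len(extras)
        if needed > len(slots):
            raise ValueError(
                f"pool {t} has {len(slots)} gene slots but needs {needed} TF genes; "
                "increase n_genes"
            )
        for j, name in enumerate(names + extras):
            gene_names[slots[j]] = (name, True)
    for i in range(design.n_genes):
        if i not in gene_names:
            gene_names[i] = (f"GENE_{i:04d}", False)

    genes = []
    for i in range(design.n_genes):
        name, is_tf = gene_names[i]
        tss = 200_000 + i * GENE_SPACING
        genes.append(GeneModel(name, CONTIG, tss, "+" if i % 2 == 0 else "-", is_tf))
    contig_length = 200_000 + design.n_genes * GENE_SPACING + 200_000

    # --- peaks: one promoter per gene, E enhancers at seeded offsets
    peaks: list[PeakInterval] = []
    enhancer_ids: dict[str, list[str]] = {}
    for g in genes:
        peaks.append(
            PeakInterval(
                f"{g.gene_id}_prom", CONTIG,
                g.tss - PROMOTER_HALF_WIDTH, g.tss + PROMOTER_HALF_WIDTH,
            )
        )
        enhancer_ids[g.gene_id] = []
        for j in range(design.enhancers_per_target):
            offset = int(rng.integers(MIN_ENHANCER_OFFSET, MAX_ENHANCER_OFFSET + 1))
            sign = 1 if rng.random() < 0.5 else -1
            center = g.tss + sign * offset
            pid = f"{g.gene_id}_enh{j}"
            peaks.append(
                PeakInterval(
                    pid, CONTIG,
                    center - ENHANCER_HALF_WIDTH, center + ENHANCER_HALF_WIDTH,
                )
            )
            enhancer_ids[g.gene_id].append(pid)
    gc = rng.uniform(0.3, 0.7, size=len(peaks))
    peaks = [
        PeakInterval(p.peak_id, p.contig, p.start, p.end, float(g))
        for p, g in zip(peaks, gc)
    ]
    peaks.sort(key=lambda p: (p.contig, p.start, p.peak_id))

    # --- regulons
    gene_pool_type = {gene_names[i][0]: POOL_TYPES[i % len(POOL_TYPES)]
                      for i in range(design.n_genes)}
    regulons: dict[str, list[str]] = {}
    tf_type: dict[str, str] = {}
    for t in POOL_TYPES:
        markers = design.marker_tfs[t]
        for m in markers:
            tf_type[m] = t
        for e in pool_extras[t]:
            tf_type[e] = t
        # Equal per-pool target budgets keep each type's active program the
        # same share of total accessible mass (as in real data, where one
        # lineage program is a small, near-constant fraction of the
        # accessible genome); within a pool the master TF takes the
        # boosted share of the budget.
        budget = design.regulon_size * max(len(v) for v in design.marker_tfs.values())
        weights = [
            design.master_regulon_boost if t in GERM_LAYERS and j == 0 else 1
            for j in range(len(markers))
        ]
        sizes = _largest_remainder(weights, budget)
        # distribute the pool's extra TFs among marker regulons, proportional
        # to regulon size, so the master also has the most downstream TFs
        extra_counts = (
            _largest_remainder(sizes, len(pool_extras[t])) if pool_extras[t] else
            [0] * len(markers)
        )
        if max(extra_counts, default=0) > min(sizes, default=0):
            raise ValueError(f"pool {t}: regulon_size too small for its extra TFs")
        nontf_pool = [
            gene_names[i][0] for i in pool_slots[t]
            if not gene_names[i][1]
        ]
        need_nontf = sum(sizes) - len(pool_extras[t])
        if need_nontf > len(nontf_pool):
            raise ValueError(
                f"pool {t} needs {need_nontf} non-TF target genes but has "
                f"{len(nontf_pool)}; increase n_genes"
            )
        chosen = rng.choice(len(nontf_pool), size=need_nontf, replace=False)
        nontf_targets = [nontf_pool[i] for i in chosen]
        extras_iter = iter(pool_extras[t])
        pos = 0
        for m, size, n_ex in zip(markers, sizes, extra_counts):
            targets = [next(extras_iter) for _ in range(n_ex)]
            take = size - n_ex
            targets += nontf_targets[pos: pos + take]
            pos += take
            regulons[m] = targets
        # extra TFs regulate non-TF genes already active in this pool's program
        marker_nontf_targets = [g for m in markers for g in regulons[m]
                                if g in set(nontf_targets)]
        for e in pool_extras[t]:
            if design.regulon_size > len(marker_nontf_targets):
                raise ValueError(
                    f"pool {t}: not enough active non-TF targets for extra-TF regulons"
                )
            idx = rng.choice(len(marker_nontf_targets),
                             size=design.regulon_size, replace=False)
            regulons[e] = [marker_nontf_targets[i] for i in idx]

    # --- motif hits: own promoter + every target's enhancers, plus noise
    peak_ids = [p.peak_id for p in peaks]
    peak_index = {p: j for j, p in enumerate(peak_ids)}
    tf_order = [m for t in POOL_TYPES for m in design.marker_tfs[t]] + [
        e for t in POOL_TYPES for e in pool_extras[t]
    ]
    motif_ids = [f"M_{tf}" for tf in tf_order]
    hits = np.zeros((len(tf_order), len(peak_ids)), dtype=np.int8)
    for i, tf in enumerate(tf_order):
        hits[i, peak_index[f"{tf}_prom"]] = 1
        for target in regulons[tf]:
            for pid in enhancer_ids[target]:
                hits[i, peak_index[pid]] = 1
    noise = rng.random((len(tf_order), len(peak_ids))) < design.motif_bg_rate
    hits = np.maximum(hits, noise.astype(np.int8))
    motif_hits = MotifHitTable(
        hits, motif_ids, peak_ids, {m: tf for m, tf in zip(motif_ids, tf_order)}
    )

    # --- planted loops: every regulon target's enhancers to its own promoter
    loop_set: set[tuple[str, str]] = set()
    start_of = {p.peak_id: p.start for p in peaks}
    for tf, targets in regulons.items():
        for target in targets:
            prom = f"{target}_prom"
            for enh in enhancer_ids[target]:
                a, b = sorted((enh, prom), key=lambda pid: start_of[pid])
                loop_set.add((a, b))
    true_loops = sorted(loop_set)

    # --- active programs per pool type
    programs: dict[str, set[str]] = {}
    for t in POOL_TYPES:
        active: set[str] = set()
        for m in design.marker_tfs[t]:
            active.add(f"{m}_prom")
            for target in regulons[m]:
                active.add(f"{target}_prom")
                active.update(enhancer_ids[target])
        programs[t] = active

    return Reference(
        peaks=peaks,
        genes=genes,
        motif_hits=motif_hits,
        true_loops=true_loops,
        regulons=regulons,
        tf_type=tf_type,
        programs=programs,
        contig_length=contig_length,
    )


def open_probabilities(reference: Reference, design: SimDesign) -> np.ndarray:
    """Per-peak open probability for each of the seven cell types."""
    peak_ids = [p.peak_id for p in reference.peaks]
    pi = np.full((len(peak_ids), len(TYPE_LABELS)), design.p0)
    col = {t: j for j, t in enumerate(TYPE_LABELS)}
    for t in POOL_TYPES:
        active = np.fromiter(
            (pid in reference.programs[t] for pid in peak_ids), dtype=bool
        )
        pi[active, col[t]] = design.p1
    for layer in GERM_LAYERS:
        pi[:, col[f"EC_{layer}"]] = (
            design.alpha * pi[:, col["ESC"]] + (1 - design.alpha) * pi[:, col[layer]]
        )
    return pi


def simulate_counts(
    reference: Reference, design: SimDesign, seed: int | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Draw the peak x cell count matrix and its ground truth."""
    rng = np.random.default_rng(
        substream_seed(design.seed if seed is None else seed, "counts")
    )
    pi = open_probabilities(reference, design)
    col = {t: j for j, t in enumerate(TYPE_LABELS)}

    barcodes: list[str] = []
    cell_type: dict[str, str] = {}
    stage_of: dict[str, str] = {}
    for stage in STAGES:
        for t in TYPE_LABELS:
            n = design.cells_per_type_per_stage.get(stage, {}).get(t, 0)
            for i in range(n):
                bc = f"{stage}_{t}_{i:04d}"
                barcodes.append(bc)
                cell_type[bc] = t
                stage_of[bc] = stage

    n_cells = len(barcodes)
    depths = rng.lognormal(design.depth_mu, design.depth_sigma, size=n_cells)
    type_cols = np.array([col[cell_type[b]] for b in barcodes])
    lam = pi[:, type_cols] * depths[None, :]
    counts = rng.poisson(lam)
    matrix = CountMatrix(
        sp.csr_matrix(counts), [p.peak_id for p in reference.peaks], barcodes
    )

    pseudotime: dict[str, float] = {}
    for b in barcodes:
        t = cell_type[b]
        if t == "ESC":
            lo, hi = 0.0, 0.2
        elif t.startswith("EC_"):
            lo, hi = 0.35, 0.65
        else:
            lo, hi = 0.8, 1.0
        pseudotime[b] = float(rng.uniform(lo, hi))

    truth = GroundTruth(
        cell_type=cell_type,
        stage=stage_of,
        true_pseudotime=pseudotime,
        regulon_edges=sorted(
            (tf, target) for tf, targets in reference.regulons.items()
            for target in targets
        ),
        true_loops=list(reference.true_loops),
        marker_sets={t: list(v) for t, v in design.marker_tfs.items()},
        tf_type=dict(reference.tf_type),
        depths={b: float(d) for b, d in zip(barcodes, depths)},
    )
    return matrix, truth


def emit_fragments(
    counts: CountMatrix,
    peaks: Sequence[PeakInterval],
    design: SimDesign,
    seed: int | None = None,
    depths: dict[str, float] | None = None,
    contig_length: int | None = None,
) -> Fragments:
    """Place every counted fragment inside its peak, plus background.

    ``depths`` supplies the per-cell depth lambda_c used for the background
    Poisson rate; when absent, the cell's scaled total count stands in.
    """
    rng = np.random.default_rng(
        substream_seed(design.seed if seed is None else seed, "fragments")
    )
    peak_by_id = {p.peak_id: p for p in peaks}
    ordered = [peak_by_id[pid] for pid in counts.peak_ids]
    if contig_length is None:
        contig_length = max(p.end for p in ordered) + 200_000
    contig = ordered[0].contig if ordered else CONTIG

    X = counts.values.tocsc()
    contigs: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    cell_col: list[str] = []

    def _emit(start_arr: np.ndarray, bc: str) -> None:
        lengths = np.clip(np.rint(rng.normal(200, 50, size=len(start_arr))), 50, 600)
        end_arr = np.minimum(start_arr + lengths.astype(np.int64), contig_length)
        contigs.extend([contig] * len(start_arr))
        starts.extend(start_arr.tolist())
        ends.extend(end_arr.tolist())
        cell_col.extend([bc] * len(start_arr))

    mean_open = float(np.mean([design.p0, design.p1]))
    for c, bc in enumerate(counts.barcodes):
        colstart, colend = X.indptr[c], X.indptr[c + 1]
        rows = X.indices[colstart:colend]
        vals = X.data[colstart:colend]
        peak_starts = []
        for r, v in zip(rows, vals):
            p = ordered[r]
            peak_starts.append(rng.integers(p.start, p.end, size=int(v)))
        if peak_starts:
            _emit(np.concatenate(peak_starts).astype(np.int64), bc)
        if depths is not None:
            lam_c = depths[bc]
        else:
            total = float(vals.sum())
            lam_c = total / max(len(ordered) * mean_open, 1.0)
        n_bg = int(rng.poisson(design.bg_rate * lam_c))
        if n_bg:
            _emit(rng.integers(0, contig_length - 50, size=n_bg).astype(np.int64), bc)

    return Fragments(contigs, starts, ends, cell_col)
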