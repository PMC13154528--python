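"""Stage orchestration: run stages on disk with logs, digests and reruns.

Every stage reads its inputs from the run directory (or from user-supplied
paths for real data), writes its outputs atomically (temp-then-rename) and
appends a JSON-lines log entry recording the stage name, parameters, seed
substream and input/output digests.  Logs carry no timestamps, so two runs
with the same configuration and seed are byte-identical, including the log.
``run_all`` skips a prefix of stages whose parameters and output digests
are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import consistency as cs
from . import io as eio
from . import loops as lp
from . import matrices as mx
from . import network as nw
from . import qc as qcmod
from . import trajectory as tj
from .config import STAGE_ORDER, PipelineConfig

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@contextmanager
def atomic_path(path: Path):
    """Yield a temp path; rename it onto ``path`` on success."""
    # keep the final suffix so writers that key on it (e.g. .mtx) behave
    tmp = path.with_name(f"{path.stem}.tmp{os.getpid()}{path.suffix}")
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with atomic_path(path) as tmp:
        df.to_csv(tmp, sep="\t", index=index, float_format=FLOAT_FMT)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage {stage!r}: missing input file {path}")
    return path


class Run:
    """File layout and stage implementations for one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = config.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)

    # --- file layout -----------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def input_path(self, key: str, default_name: str, stage: str) -> Path:
        user = self.config.section("paths").get(key, "")
        if user:
            return _require(Path(user), stage)
        return _require(self.path(default_name), stage)

    # --- logging / digests ----------------------------------------------
    def _log(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]) -> None:
        entry = {
            "stage": stage,
            "seed": self.config.stage_seed(stage),
            "params": params,
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        with open(self.path("logs.jsonl"), "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        manifest_path = self.path("manifest.json")
        manifest = {}
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
        manifest[stage] = {
            "params": json.dumps(params, sort_keys=True),
            "seed": entry["seed"],
            "outputs": entry["outputs"],
        }
        with atomic_path(manifest_path) as tmp:
            tmp.write_text(json.dumps(manifest, sort_keys=True, indent=1))

    def up_to_date(self, stage: str) -> bool:
        manifest_path = self.path("manifest.json")
        if not manifest_path.exists():
            return False
        manifest = json.loads(manifest_path.read_text())
        if stage not in manifest:
            return False
        entry = manifest[stage]
        params = self.config.section(stage) if stage in self.config.data else {}
        if entry["params"] != json.dumps(params, sort_keys=True):
            return False
        if entry["seed"] != self.config.stage_seed(stage):
            return False
        for name, digest in entry["outputs"].items():
            p = self.path(name)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    # --- shared readers ---------------------------------------------------
    def read_counts_retained(self) -> eio.CountMatrix:
        counts = eio.read_counts(
            self.input_path("counts", "counts.mtx", "matrices"),
            self.input_path("counts_peaks", "counts.peaks.txt", "matrices"),
            self.input_path("counts_barcodes", "counts.barcodes.txt", "matrices"),
        )
        retained_path = self.path("retained_barcodes.txt")
        if retained_path.exists():
            retained = [
                b for b in retained_path.read_text().splitlines() if b
            ]
            counts = counts.select_barcodes(retained)
        return counts

    def read_embedding(self) -> mx.EmbeddingMatrix:
        df = pd.read_csv(_require(self.path("embedding.tsv"), "consistency"), sep="\t")
        return mx.EmbeddingMatrix(
            coords=df.drop(columns=["barcode"]).to_numpy(),
            barcodes=df["barcode"].tolist(),
        )

    def read_consistency(self) -> cs.ConsistencyMatrix:
        values, tf_names, barcodes = self._read_dense_mtx("consistency")
        return cs.ConsistencyMatrix(values, tf_names, barcodes)

    def read_labeling(self) -> tuple[cl.ClusterLabeling, pd.DataFrame]:
        df = pd.read_csv(_require(self.path("clusters.tsv"), "trajectory"), sep="\t")
        annotation = dict(
            df.drop_duplicates("cluster")[["cluster", "annotation"]].itertuples(
                index=False, name=None
            )
        )
        labeling = cl.ClusterLabeling(
            dict(zip(df["barcode"], df["cluster"].astype(int))),
            {int(k): v for k, v in annotation.items()},
        )
        return labeling, df

    def marker_panel(self) -> cl.MarkerPanel:
        return cl.MarkerPanel(
            {t: list(v) for t, v in self.config.section("cluster")["panel"].items()}
        )

    # --- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        from . import simulate as sim

        design = self.config.design()
        reference = sim.build_reference(design)
        counts, truth = sim.simulate_counts(reference, design)
        fragments = sim.emit_fragments(
            counts, reference.peaks, design,
            depths=truth.depths, contig_length=reference.contig_length,
        )
        with atomic_path(self.path("fragments.tsv")) as tmp:
            eio.write_fragments(fragments, tmp)
        with atomic_path(self.path("peaks.bed")) as tmp:
            eio.write_peaks(reference.peaks, tmp)
        with atomic_path(self.path("counts.mtx")) as m, \
             atomic_path(self.path("counts.peaks.txt")) as p, \
             atomic_path(self.path("counts.barcodes.txt")) as b:
            eio.write_counts(counts, m, p, b)
        with atomic_path(self.path("genes.tsv")) as tmp:
            eio.write_gene_table(reference.genes, tmp)
        with atomic_path(self.path("motif_hits.tsv")) as tmp:
            eio.write_motif_table(reference.motif_hits, tmp)
        _write_tsv(
            pd.DataFrame(
                {
                    "barcode": counts.barcodes,
                    "cell_type": [truth.cell_type[b] for b in counts.barcodes],
                    "stage": [truth.stage[b] for b in counts.barcodes],
                    "pseudotime": [truth.true_pseudotime[b] for b in counts.barcodes],
                    "depth": [truth.depths[b] for b in counts.barcodes],
                }
            ),
            self.path("truth_cells.tsv"),
        )
        _write_tsv(
            pd.DataFrame(truth.regulon_edges, columns=["tf", "target"]),
            self.path("truth_regulons.tsv"),
        )
        _write_tsv(
            pd.DataFrame(truth.true_loops, columns=["peak_a", "peak_b"]),
            self.path("truth_loops.tsv"),
        )
        _write_tsv(
            pd.DataFrame(sorted(truth.tf_type.items()), columns=["tf", "type"]),
            self.path("truth_tf_types.tsv"),
        )
        self._log(
            "simulate", self.config.section("simulate"), [],
            [self.path(n) for n in (
                "fragments.tsv", "peaks.bed", "counts.mtx", "counts.peaks.txt",
                "counts.barcodes.txt", "genes.tsv", "motif_hits.tsv",
                "truth_cells.tsv", "truth_regulons.tsv", "truth_loops.tsv",
                "truth_tf_types.tsv",
            )],
        )

    def stage_qc(self) -> None:
        params = self.config.section("qc")
        frag_path = self.input_path("fragments", "fragments.tsv", "qc")
        gene_path = self.input_path("genes", "genes.tsv", "qc")
        fragments = eio.read_fragments(frag_path)
        genes = eio.read_gene_table(gene_path)
        barcodes = None
        bc_path = self.path("counts.barcodes.txt")
        if bc_path.exists():
            barcodes = [b for b in bc_path.read_text().splitlines() if b]
        records = qcmod.compute_qc(
            fragments, genes,
            flank_bp=params["flank_bp"], center_bp=params["center_bp"],
            edge_bp=params["edge_bp"], pseudocount=params["pseudocount"],
            barcodes=barcodes,
        )
        records = qcmod.remove_doublets(records)
        retained = qcmod.filter_cells(
            records,
            min_frag=params["min_frag"], max_frag=params["max_frag"],
            min_log10_tss=params["min_log10_tss"],
            max_log10_tss=params["max_log10_tss"],
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "barcode": [r.barcode for r in records],
                    "n_fragments": [r.n_fragments for r in records],
                    "reads_in_tss": [r.reads_in_tss for r in records],
                    "tss_enrichment": [r.tss_enrichment for r in records],
                    "passed": [int(r.passed) for r in records],
                }
            ),
            self.path("qc_report.tsv"),
        )
        with atomic_path(self.path("retained_barcodes.txt")) as tmp:
            tmp.write_text("".join(f"{b}\n" for b in retained))
        self._log(
            "qc", params, [frag_path, gene_path],
            [self.path("qc_report.tsv"), self.path("retained_barcodes.txt")],
        )

    def stage_matrices(self) -> None:
        params = self.config.section("matrices")
        counts = self.read_counts_retained()
        peaks = eio.read_peaks(self.input_path("peaks", "peaks.bed", "matrices"))
        genes = eio.read_gene_table(self.input_path("genes", "genes.tsv", "matrices"))
        motifs = eio.read_motif_table(
            self.input_path("motifs", "motif_hits.tsv", "matrices"), counts.peak_ids
        )
        embedding = mx.tfidf_lsi(
            counts, n_components=params["n_components"], binarize=params["binarize"]
        )
        emb_df = pd.DataFrame(
            embedding.coords,
            columns=[f"LSI{j + 1}" for j in range(embedding.n_components)],
        )
        emb_df.insert(0, "barcode", embedding.barcodes)
        _write_tsv(emb_df, self.path("embedding.tsv"))

        activity = mx.gene_activity(
            counts, peaks, genes,
            decay_bp=params["decay_bp"], max_dist=params["max_dist"],
            scale=params["scale"],
        )
        self._write_dense_mtx(
            activity.values, activity.gene_ids, activity.barcodes, "gene_activity"
        )
        binding = mx.motif_deviations(
            counts, motifs, peaks,
            n_background=params["n_background"], n_neighbors=params["n_neighbors"],
            seed=self.config.stage_seed("matrices"),
        )
        self._write_dense_mtx(
            binding.values, binding.motif_ids, binding.barcodes, "binding"
        )
        _write_tsv(
            pd.DataFrame({"motif_id": binding.motif_ids, "tf": binding.tf_names}),
            self.path("binding_tfs.tsv"),
        )
        self._log(
            "matrices", params,
            [self.path("counts.mtx")],
            [self.path(n) for n in (
                "embedding.tsv", "gene_activity.mtx", "gene_activity.rows.txt",
                "gene_activity.cols.txt", "binding.mtx", "binding.rows.txt",
                "binding.cols.txt", "binding_tfs.tsv",
            )],
        )

    def _write_dense_mtx(self, values, row_ids, col_ids, stem: str) -> None:
        import scipy.sparse as sp
        from scipy.io import mmwrite

        with atomic_path(self.path(f"{stem}.mtx")) as tmp:
            mmwrite(str(tmp), sp.coo_matrix(np.asarray(values)))
        with atomic_path(self.path(f"{stem}.rows.txt")) as tmp:
            tmp.write_text("".join(f"{r}\n" for r in row_ids))
        with atomic_path(self.path(f"{stem}.cols.txt")) as tmp:
            tmp.write_text("".join(f"{c}\n" for c in col_ids))

    def _read_dense_mtx(self, stem: str) -> tuple[np.ndarray, list[str], list[str]]:
        from scipy.io import mmread

        values = np.asarray(
            mmread(str(_require(self.path(f"{stem}.mtx"), "consistency"))).todense()
        )
        rows = [r for r in self.path(f"{stem}.rows.txt").read_text().splitlines() if r]
        cols = [c for c in self.path(f"{stem}.cols.txt").read_text().splitlines() if c]
        return values, rows, cols

    def stage_consistency(self) -> None:
        params = self.config.section("consistency")
        embedding = self.read_embedding()
        activity, gene_ids, act_cells = self._read_dense_mtx("gene_activity")
        binding, motif_ids, bind_cells = self._read_dense_mtx("binding")
        if act_cells != bind_cells or act_cells != embedding.barcodes:
            raise StageError("consistency: cell axes of the input matrices disagree")
        tf_table = pd.read_csv(self.path("binding_tfs.tsv"), sep="\t")
        tf_map = cs.TFMap(
            {row.tf: (row.tf, row.motif_id) for row in tf_table.itertuples()}
        )
        k = params["k"]
        gene_z = cs.standardize_rows(cs.knn_smooth(activity, embedding, k=k))
        binding_z = cs.standardize_rows(cs.knn_smooth(binding, embedding, k=k))
        C = cs.consistency(gene_z, binding_z, tf_map, gene_ids, motif_ids, act_cells)
        self._write_dense_mtx(C.values, C.tf_names, C.barcodes, "consistency")
        with atomic_path(self.path("consistency_excluded.txt")) as tmp:
            tmp.write_text("".join(f"{t}\n" for t in C.excluded_tfs))
        self._log(
            "consistency", params,
            [self.path("embedding.tsv"), self.path("gene_activity.mtx"),
             self.path("binding.mtx")],
            [self.path(n) for n in (
                "consistency.mtx", "consistency.rows.txt", "consistency.cols.txt",
                "consistency_excluded.txt",
            )],
        )

    def stage_cluster(self) -> None:
        params = self.config.section("cluster")
        C = self.read_consistency()
        panel = self.marker_panel()
        C_markers = C.restrict(panel.all_tfs)
        labels = cl.kmeans_consistency(
            C_markers, k=params["k"], seed=self.config.stage_seed("cluster"),
            n_init=params["n_init"], max_iter=params["max_iter"],
        )
        labeling = cl.annotate_clusters(C, labels, panel, tau=params["tau"])
        _write_tsv(
            pd.DataFrame(
                {
                    "barcode": C.barcodes,
                    "cluster": labels,
                    "annotation": [
                        labeling.annotation_of_cluster[int(c)] for c in labels
                    ],
                }
            ),
            self.path("clusters.tsv"),
        )
        stages = self._cell_stages()
        outputs = [self.path("clusters.tsv"), self.path("specific_tfs.tsv")]
        if stages is not None:
            composition = cl.composition_by_stage(labeling, stages)
            _write_tsv(composition, self.path("composition.tsv"), index=True)
            outputs.append(self.path("composition.tsv"))
        ranked = cl.specific_tfs(C, labels, n=10)
        rows = [
            {"cluster": cid, "annotation": labeling.annotation_of_cluster[cid],
             "rank": i + 1, "tf": tf, "specificity": score}
            for cid, items in ranked.items()
            for i, (tf, score) in enumerate(items)
        ]
        _write_tsv(pd.DataFrame(rows), self.path("specific_tfs.tsv"))
        self._log("cluster", params, [self.path("consistency.mtx")], outputs)

    def _cell_stages(self) -> dict[str, str] | None:
        user = self.config.section("paths").get("stages_table", "")
        path = Path(user) if user else self.path("truth_cells.tsv")
        if not path.exists():
            warnings.warn("no stage table available; skipping composition output")
            return None
        df = pd.read_csv(path, sep="\t")
        return dict(zip(df["barcode"], df["stage"]))

    def stage_trajectory(self) -> None:
        params = self.config.section("trajectory")
        C = self.read_consistency()
        labeling, cluster_df = self.read_labeling()
        panel = self.marker_panel()
        C_markers = C.restrict(panel.all_tfs)
        labels = np.array([labeling.cluster_of[b] for b in C_markers.barcodes])
        n_comp = min(params["n_components"], len(set(labels.tolist())) - 1)
        embedding = tj.lda_embed(C_markers, labels, n_components=n_comp)
        emb_df = pd.DataFrame(
            embedding.coords, columns=[f"LD{j + 1}" for j in range(n_comp)]
        )
        emb_df.insert(0, "barcode", embedding.barcodes)
        _write_tsv(emb_df, self.path("lda_embedding.tsv"))

        pt_rows = []
        outputs = [self.path("lda_embedding.tsv"), self.path("pseudotime.tsv")]
        present = set(labeling.annotation_of_cluster.values())
        for layer in panel.germ_layers:
            spec = tj.LineageSpec(
                layer, profile_tfs=panel.sets["ESC"] + panel.sets[layer]
            )
            if not set(spec.members) <= present:
                warnings.warn(
                    f"lineage {layer}: annotations {set(spec.members) - present} "
                    "absent; skipping"
                )
                continue
            assignment = tj.lineage_pseudotime(
                embedding, labeling, spec, n_bins=params["n_bins"]
            )
            profile, counts = tj.bin_profile(
                C, assignment, spec, n_bins=params["n_bins"]
            )
            profile.loc["cell_count"] = counts
            out = self.path(f"bin_profile_{layer}.tsv")
            _write_tsv(profile, out, index=True)
            outputs.append(out)
            pt_rows += [
                {"barcode": b, "lineage": layer, "pseudotime": p,
                 "bin": assignment.bin_of[b]}
                for b, p in assignment.pt.items()
            ]
        _write_tsv(pd.DataFrame(pt_rows), self.path("pseudotime.tsv"))
        self._log(
            "trajectory", params,
            [self.path("consistency.mtx"), self.path("clusters.tsv")], outputs,
        )

    def stage_loops(self) -> None:
        params = self.config.section("loops")
        counts = self.read_counts_retained()
        peaks = eio.read_peaks(self.input_path("peaks", "peaks.bed", "loops"))
        embedding = self.read_embedding()
        metacells = lp.make_metacells(
            embedding, target_size=params["target_size"],
            seed=self.config.stage_seed("loops"),
        )
        peak_order = {p.peak_id: p for p in peaks}
        sorted_peaks = sorted(peaks, key=lambda p: (p.contig, p.start, p.peak_id))
        pairs = lp.candidate_pairs(
            sorted_peaks, min_dist=params["min_dist"], max_dist=params["max_dist"]
        )
        r, flagged = lp.coaccessibility(counts, metacells, pairs)
        called = lp.call_loops(pairs, r, threshold=params["threshold"])

        totals = np.asarray(counts.values.sum(axis=0)).ravel()
        sig = np.log1p(
            counts.values.toarray() * 1e4 / np.maximum(totals, 1.0)[None, :]
        )
        k = self.config.section("consistency")["k"]
        peak_z = cs.standardize_rows(cs.knn_smooth(sig, embedding, k=k))
        labeling, _ = self.read_labeling()
        groups = {b: labeling.annotation_of(b) for b in counts.barcodes}
        signals = lp.loop_signal(peak_z, counts.peak_ids, called, groups, counts.barcodes)

        _write_tsv(
            pd.DataFrame({"barcode": counts.barcodes, "metacell": metacells}),
            self.path("metacells.tsv"),
        )
        loop_df = pd.DataFrame(
            {
                "contig_a": [peak_order[l.anchor_a].contig for l in called],
                "start_a": [peak_order[l.anchor_a].start for l in called],
                "end_a": [peak_order[l.anchor_a].end for l in called],
                "contig_b": [peak_order[l.anchor_b].contig for l in called],
                "start_b": [peak_order[l.anchor_b].start for l in called],
                "end_b": [peak_order[l.anchor_b].end for l in called],
                "anchor_a": [l.anchor_a for l in called],
                "anchor_b": [l.anchor_b for l in called],
                "distance": [l.distance for l in called],
                "r": [l.coaccessibility for l in called],
            }
        )
        _write_tsv(loop_df, self.path("loops.tsv"))
        _write_tsv(
            signals.rename_axis("loop_id"), self.path("loop_signal.tsv"), index=True
        )
        self._log(
            "loops", params,
            [self.path("counts.mtx"), self.path("embedding.tsv"),
             self.path("clusters.tsv")],
            [self.path(n) for n in ("metacells.tsv", "loops.tsv", "loop_signal.tsv")],
        )

    def stage_network(self) -> None:
        params = self.config.section("network")
        peaks = eio.read_peaks(self.input_path("peaks", "peaks.bed", "network"))
        genes = eio.read_gene_table(self.input_path("genes", "genes.tsv", "network"))
        C = self.read_consistency()
        motifs = eio.read_motif_table(
            self.input_path("motifs", "motif_hits.tsv", "network"),
            [p.peak_id for p in peaks],
        )
        loop_df = pd.read_csv(_require(self.path("loops.tsv"), "network"), sep="\t")
        called = [
            lp.Loop(row.anchor_a, row.anchor_b, int(row.distance), float(row.r))
            for row in loop_df.itertuples()
        ]
        signals = pd.read_csv(self.path("loop_signal.tsv"), sep="\t", index_col=0)
        labeling, _ = self.read_labeling()
        tss_map = nw.tss_proximal_peaks(peaks, genes, window=params["tss_window"])
        candidates = nw.candidate_edges(motifs, called, tss_map)

        all_edges: list[eio.EdgeRecord] = []
        degree_rows = []
        group_names = sorted(
            a for a in set(labeling.annotation_of_cluster.values()) if a != "unassigned"
        )
        for group in group_names:
            cells = [
                b for b in C.barcodes if labeling.annotation_of(b) == group
            ]
            edges = nw.edge_weights(candidates, signals, C, group, cells)
            all_edges += edges
            for net_name, net in (
                ("tf", nw.tf_tf_network(edges, genes)),
                ("full", nw.build_network(edges, genes)),
            ):
                for rank, (tf, deg) in enumerate(nw.weighted_out_degree(net), start=1):
                    degree_rows.append(
                        {"group": group, "network": net_name, "rank": rank,
                         "gene": tf, "weighted_out_degree": deg}
                    )
        with atomic_path(self.path("network_edges.tsv")) as tmp:
            eio.write_edge_list(all_edges, tmp, format="tsv")
        with atomic_path(self.path("network_edges.sif")) as tmp:
            eio.write_edge_list(all_edges, tmp, format="sif")
        _write_tsv(pd.DataFrame(degree_rows), self.path("outdegree.tsv"))
        self._log(
            "network", params,
            [self.path("loops.tsv"), self.path("loop_signal.tsv"),
             self.path("consistency.mtx"), self.path("clusters.tsv")],
            [self.path(n) for n in (
                "network_edges.tsv", "network_edges.sif", "outdegree.tsv",
            )],
        )


STAGE_FUNCS = {
    "simulate": Run.stage_simulate,
    "qc": Run.stage_qc,
    "matrices": Run.stage_matrices,
    "consistency": Run.stage_consistency,
    "cluster": Run.stage_cluster,
    "trajectory": Run.stage_trajectory,
    "loops": Run.stage_loops,
    "network": Run.stage_network,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    """Run one named stage; unknown names list the valid stages."""
    if name not in STAGE_FUNCS:
        raise StageError(
            f"unknown stage {name!r}; valid stages are {list(STAGE_ORDER)}"
        )
    STAGE_FUNCS[name](Run(config))


def run_all(config: PipelineConfig, force: bool = False) -> list[str]:
    """Run the configured stages in order; skip an unchanged prefix.

    Returns the names of the stages that actually ran.
    """
    run = Run(config)
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    ran: list[str] = []
    dirty = force
    for name in ordered:
        if not dirty and run.up_to_date(name):
            continue
        dirty = True
        STAGE_FUNCS[name](run)
        ran.append(name)
    return ran
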