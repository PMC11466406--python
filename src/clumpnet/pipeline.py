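"""End-to-end orchestration of the smoothing / GRN / MDS / clustering stages.

Two modes mirror the two published workflows:

* ``manual`` -- clump profiles are built on the genes of a single minimum
  dominating set and the tree is cut at a user-supplied k.
* ``auto``   -- profiles use the full control-node set (critical plus
  intermittent nodes), cluster support comes from the multiscale bootstrap,
  and k is chosen automatically as the smallest cut maximizing the ARI
  against the confident (AU-filtered) partition.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import cluster as cl
from . import grn as gr
from .io import (CountMatrix, Embedding, Graph, ResamplingConfig, TFCatalog,
                 ValidationError)
from .mds import ControlSet, enumerate_optimal_mds
from .smoothing import knn_smooth

_CLUSTER_STREAM = 3


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    smoothed: CountMatrix
    graphs: list
    support: "object"                 # pandas DataFrame with p/q columns
    lam_node: float
    lam_edge: float
    consensus: Graph
    control: ControlSet
    clumps: cl.ClumpPartition
    profile_genes: list
    profiles: cl.ProfileMatrix
    tree: cl.ClusterTree
    confident: cl.Partition | None
    chosen_k: int
    clump_clusters: cl.Partition
    cell_clusters: cl.Partition
    timings: dict = field(default_factory=dict)


def run_pipeline(counts: CountMatrix, embedding: Embedding, tfs: TFCatalog,
                 cfg: ResamplingConfig, *, mode: str = "auto",
                 k_clusters: int | None = None, n_solutions: int = 15,
                 res_grid=None, boot_B: int = 1000, alpha: float = 0.05,
                 scales=cl.DEFAULT_SCALES, k_range=None,
                 skip_smoothing: bool = False,
                 profile_source: str = "original") -> PipelineResult:
    """Run the full procedure and return every intermediate artifact.

    ``profile_source`` selects the expression used for clump profiles:
    the library-normalized log1p of the ``original`` counts (default) or of
    the ``smoothed`` counts.
    """
    if mode not in ("auto", "manual"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "manual" and k_clusters is None:
        raise ValidationError("manual mode requires k_clusters")
    cfg.validate(counts.n_cells)
    timings: dict = {}

    t0 = time.perf_counter()
    emb = embedding.aligned_to(counts)
    smoothed = counts if skip_smoothing else knn_smooth(counts, emb, cfg.k)
    timings["smooth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    graphs, support = gr.run_grn_ensemble(smoothed, tfs, cfg)
    if not graphs:
        raise ValidationError("all GRN specimens were skipped; nothing to test")
    timings["grn_ensemble"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    lam_node, lam_edge = gr.run_null_ensemble(smoothed, tfs, cfg)
    n_universe = len(tfs.intersect(smoothed.gene_ids))
    support = gr.significance_table(support, lam_node, lam_edge,
                                    len(graphs), n_universe)
    consensus = gr.consensus_grn(graphs, support, cfg.q_threshold)
    timings["null_and_consensus"] = time.perf_counter() - t0
    if consensus.n_vertices == 0:
        raise ValidationError("consensus network is empty; no control nodes to "
                              "profile (lower q stringency or revisit inputs)")

    t0 = time.perf_counter()
    control = enumerate_optimal_mds(consensus, n_solutions=n_solutions)
    timings["mds"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clumps = cl.make_clumps(counts, cfg.k, res_grid=res_grid, seed=cfg.seed)
    source = smoothed if profile_source == "smoothed" else counts
    expr = cl.lognormalize(source)
    genes = (sorted(control.control_nodes) if mode == "auto"
             else sorted(control.solutions[0]))
    profiles = cl.clump_profiles(expr, clumps, genes)

    # drop zero-variance clumps (Pearson distance undefined on them)
    sd = profiles.values.std(axis=1)
    dropped = np.flatnonzero(sd == 0)
    if dropped.size:
        warnings.warn(f"dropping {dropped.size} zero-variance clumps from the "
                      "clump tree; their cells stay unassigned", stacklevel=2)
        keep = sd > 0
        profiles = cl.ProfileMatrix(profiles.values[keep],
                                    profiles.clump_ids[keep], profiles.gene_ids)
    timings["profiles"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tree = cl.ward_tree(profiles)
    confident = None
    if mode == "auto":
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, _CLUSTER_STREAM])
        tree = cl.multiscale_bootstrap(profiles, tree, scales=scales,
                                       B=boot_B, rng=rng)
        confident = cl.pick_confident(tree, alpha=alpha)
        chosen_k = cl.choose_k(tree, confident, k_range=k_range)
    else:
        chosen_k = int(k_clusters)
    clump_clusters = cl.cut_tree(tree, chosen_k)
    timings["cluster"] = time.perf_counter() - t0

    cell_clusters = _cells_from_clumps(clumps, clump_clusters)
    return PipelineResult(smoothed=smoothed, graphs=graphs, support=support,
                          lam_node=lam_node, lam_edge=lam_edge,
                          consensus=consensus, control=control, clumps=clumps,
                          profile_genes=genes, profiles=profiles, tree=tree,
                          confident=confident, chosen_k=chosen_k,
                          clump_clusters=clump_clusters,
                          cell_clusters=cell_clusters, timings=timings)


def _cells_from_clumps(clumps: cl.ClumpPartition,
                       clump_clusters: cl.Partition) -> cl.Partition:
    """Cell partition from a clump clustering that may omit dropped clumps."""
    pos = {m: i for i, m in enumerate(clump_clusters.members.tolist())}
    lab = np.array([clump_clusters.labels[pos[c]] if c in pos else -1
                    for c in clumps.clump_ids.tolist()])
    return cl.Partition(clumps.cell_ids, lab[clumps.labels])
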