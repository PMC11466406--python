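"""Clump generation and control-gene-based clustering of clumps.

Cells are first over-partitioned into small communities ("clumps") with
Louvain at the highest resolution whose smallest community still holds at
least 80% of the smoothing parameter k. Each clump is summarized by the
mean log-normalized expression of the control genes, clumps are clustered
with Ward's method on 1 - Pearson correlation, and cluster support is
quantified with multiscale-bootstrap AU p-values. The number of clusters is
chosen automatically as the smallest cut whose adjusted Rand index against
the confident (AU-filtered) partition is maximal.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import comb
from scipy.stats import norm

from .io import CountMatrix, ValidationError

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ClumpPartition:
    """Cell -> clump assignment from the resolution search."""

    labels: np.ndarray        # int clump id per cell
    cell_ids: np.ndarray
    resolution: float
    min_size: int

    @property
    def n_clumps(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def clump_ids(self) -> np.ndarray:
        return np.arange(self.n_clumps)


@dataclass
class ProfileMatrix:
    """Clumps x control-genes mean expression profiles."""

    values: np.ndarray
    clump_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile values must be finite")
        self.clump_ids = np.asarray(self.clump_ids)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.clump_ids), len(self.gene_ids)):
            raise ValidationError("profile shape does not match ids")


@dataclass
class ClusterTree:
    """Ward dendrogram over clumps with optional per-node BP/AU support.

    Internal nodes are indexed 0..n-2 in scipy linkage order (node i is
    merge row i, cluster id n+i); the last row is the root. ``au`` is NaN
    for nodes without a meaningful AU value -- in particular the root,
    whose bootstrap probability is identically 1 and carries no
    information.
    """

    Z: np.ndarray
    clump_ids: np.ndarray
    au: np.ndarray | None = None
    bp: np.ndarray | None = None          # (n-1, n_scales)
    scales: tuple | None = None
    au_fallback: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.clump_ids)

    def node_leafsets(self) -> list:
        """Leaf index bitmask per internal node, in linkage order."""
        return _node_masks(self.Z, self.n_leaves)


@dataclass
class Partition:
    """Cluster labels over a member set; -1 flags unassigned members."""

    members: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.members) != len(self.labels):
            raise ValidationError("members and labels differ in length")

    @property
    def n_assigned(self) -> int:
        return int(np.count_nonzero(self.labels >= 0))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))

    def with_singletons(self) -> "Partition":
        """Unassigned members become their own singleton clusters."""
        labels = self.labels.copy()
        nxt = labels.max() + 1 if np.any(labels >= 0) else 0
        for i in np.flatnonzero(labels < 0):
            labels[i] = nxt
            nxt += 1
        return Partition(self.members, labels)


# ---------------------------------------------------------------------------
# clump generation
# ---------------------------------------------------------------------------


def lognormalize(counts: CountMatrix, target: float = 1e4) -> pd.DataFrame:
    """Library-size normalization to ``target`` counts per cell, then log1p."""
    totals = counts.values.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    x = np.log1p(counts.values / totals * target)
    return pd.DataFrame(x, index=counts.cell_ids, columns=counts.gene_ids)


def _louvain(sources, targets, n, resolution, seed):
    import igraph

    igraph.set_random_number_generator(random.Random(int(seed)))
    g = igraph.Graph(n=n, edges=list(zip(sources, targets)), directed=False)
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def make_clumps(counts: CountMatrix, k: int, res_grid=None, seed: int = 0,
                n_pcs: int = 30, n_neighbors: int = 15) -> ClumpPartition:
    """Louvain clumps at the highest resolution respecting the size floor.

    The standard normalize -> log1p -> PCA -> kNN graph is built from the
    original counts; Louvain runs at each resolution of ``res_grid``
    (ascending) and the highest resolution whose smallest community has at
    least ``ceil(0.8 * k)`` cells is returned. If no resolution satisfies
    the floor, the lowest-resolution result is returned with a warning.
    """
    if res_grid is None:
        res_grid = (0.5, 1, 2, 4, 6, 8, 10, 12, 15, 20)
    res_grid = sorted(float(r) for r in res_grid)
    if not res_grid:
        raise ValidationError("res_grid is empty")
    floor = math.ceil(0.8 * k)

    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    x = lognormalize(counts).to_numpy()
    x = x - x.mean(axis=0)
    n_comp = max(1, min(n_pcs, min(x.shape) - 1))
    pcs = PCA(n_components=n_comp, random_state=int(seed) & 0x7FFFFFFF).fit_transform(x)
    knn = kneighbors_graph(pcs, n_neighbors=min(n_neighbors, counts.n_cells - 1),
                           include_self=False)
    sym = knn.maximum(knn.T).tocoo()
    upper = sym.row < sym.col
    sources, targets = sym.row[upper], sym.col[upper]

    for res in reversed(res_grid):
        labels = _louvain(sources, targets, counts.n_cells, res, seed)
        sizes = np.bincount(labels)
        if sizes.min() >= floor:
            return ClumpPartition(labels, counts.cell_ids, res, int(sizes.min()))
    warnings.warn("no resolution satisfies the clump size floor; "
                  "returning the lowest-resolution result", stacklevel=2)
    return ClumpPartition(labels, counts.cell_ids, res_grid[0], int(sizes.min()))


def clump_profiles(expr: pd.DataFrame, clumps: ClumpPartition, genes) -> ProfileMatrix:
    """Mean expression of ``genes`` per clump.

    ``expr`` is a cells x genes DataFrame (typically the log-normalized
    original counts) aligned with the clump partition.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    if not np.array_equal(expr.index.to_numpy(), clumps.cell_ids):
        raise ValidationError("expression rows do not match clump partition cells")
    x = expr[genes].to_numpy(dtype=float)
    n_clumps = clumps.n_clumps
    sums = np.zeros((n_clumps, len(genes)))
    np.add.at(sums, clumps.labels, x)
    counts = np.bincount(clumps.labels, minlength=n_clumps).astype(float)
    return ProfileMatrix(sums / counts[:, None], clumps.clump_ids,
                         np.array(genes, dtype=object))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def _pearson_distance(values: np.ndarray, strict: bool = True) -> np.ndarray:
    sd = values.std(axis=1)
    if strict and np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValidationError(
            f"zero-variance profile rows {bad.tolist()}: Pearson distance is "
            "undefined; drop or merge these clumps before clustering")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def _ward_classic(d: np.ndarray) -> np.ndarray:
    """Textbook Lance-Williams Ward agglomeration on the raw dissimilarity.

    Kept as a cross-checking alternative to the (default) squared-distance
    update; O(n^3) but only ever used on clump-scale inputs.
    """
    n = d.shape[0]
    d = d.astype(float).copy()
    sizes = np.ones(n)
    active = list(range(n))
    ids = list(range(n))
    z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                if d[i, j] < best[0] - 1e-15:
                    best = (d[i, j], ai, bi)
        h, ai, bi = best
        i, j = active[ai], active[bi]
        z[step] = (ids[ai], ids[bi], h, sizes[i] + sizes[j])
        for other in active:
            if other in (i, j):
                continue
            tot = sizes[i] + sizes[j] + sizes[other]
            d_new = ((sizes[i] + sizes[other]) * d[i, other]
                     + (sizes[j] + sizes[other]) * d[j, other]
                     - sizes[other] * d[i, j]) / tot
            d[i, other] = d[other, i] = d_new
        sizes[i] += sizes[j]
        ids[ai] = n + step
        del active[bi], ids[bi]
    return z


def ward_tree(profiles: ProfileMatrix, variant: str = "squared") -> ClusterTree:
    """Ward dendrogram on the 1 - Pearson dissimilarity between profiles.

    ``variant="squared"`` (default) uses the modern squared-distance Ward
    update; ``variant="classic"`` applies the textbook recurrence to the
    raw dissimilarities for cross-checking.
    """
    if profiles.values.shape[0] < 2:
        raise ValidationError("need at least two clumps to cluster")
    d = _pearson_distance(profiles.values)
    if variant == "squared":
        z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    elif variant == "classic":
        z = _ward_classic(d)
    else:
        raise ValidationError(f"unknown Ward variant {variant!r}")
    return ClusterTree(z, profiles.clump_ids)


def _node_masks(z: np.ndarray, n: int) -> list:
    masks = [0] * (2 * n - 1)
    for i in range(n):
        masks[i] = 1 << i
    for step in range(n - 1):
        a, b = int(z[step, 0]), int(z[step, 1])
        masks[n + step] = masks[a] | masks[b]
    return masks[n:]


def cut_tree(tree: ClusterTree, k: int) -> Partition:
    """Cut the dendrogram into exactly ``k`` clusters of clumps."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    labels = hierarchy.cut_tree(tree.Z, n_clusters=k).ravel().astype(int)
    return Partition(tree.clump_ids, labels)


# ---------------------------------------------------------------------------
# multiscale bootstrap AU values
# ---------------------------------------------------------------------------


def multiscale_bootstrap(profiles: ProfileMatrix, tree: ClusterTree,
                         scales=DEFAULT_SCALES, B: int = 1000,
                         rng=None) -> ClusterTree:
    """Per-node BP (per scale) and AU values by feature-column resampling.

    For each scale r, B bootstrap resamples of ``round(r * p)`` feature
    columns (with replacement) are re-clustered and BP_r(node) is the
    fraction of bootstrap trees containing the node's exact clump set. The
    AU extrapolation fits the signed-distance model
    ``z_r = v * sqrt(rt) + c / sqrt(rt)`` with ``z_r = qnorm(1 - BP_r)`` and
    ``rt = round(r*p)/p`` by weighted least squares (binomial weights),
    giving ``AU = 1 - Phi(v - c)``. Only non-degenerate scales
    (0 < BP < 1) enter the fit; nodes with fewer than three usable scales
    fall back to the clipped BP at the scale nearest 1 and are flagged.
    The root node receives AU = NaN (its BP is identically 1).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    values = profiles.values
    n, p = values.shape
    if p < 2:
        raise ValidationError("need at least two feature columns to bootstrap")
    scales = tuple(float(s) for s in scales)
    sizes = [max(1, int(round(r * p))) for r in scales]
    usable_scale = np.array([s >= 2 for s in sizes], dtype=bool)
    if not np.all(usable_scale):
        warnings.warn("scales with fewer than 2 resampled features skipped", stacklevel=2)

    masks0 = tree.node_leafsets()
    n_nodes = len(masks0)
    bp_counts = np.zeros((n_nodes, len(scales)))
    for si, ps in enumerate(sizes):
        if not usable_scale[si]:
            continue
        for _ in range(B):
            cols = rng.integers(0, p, size=ps)
            d = _pearson_distance(values[:, cols], strict=False)
            zb = hierarchy.linkage(squareform(d, checks=False), method="ward")
            found = set(_node_masks(zb, n))
            for ni, mk in enumerate(masks0):
                if mk in found:
                    bp_counts[ni, si] += 1
    bp = bp_counts / B

    rt = np.array([s / p for s in sizes])
    au = np.full(n_nodes, np.nan)
    fallback = np.zeros(n_nodes, dtype=bool)
    for ni in range(n_nodes - 1):  # root (last node) excluded: its BP is always 1
        au[ni], fallback[ni] = fit_au(bp_counts[ni], rt, B, usable_scale)
    fallback[n_nodes - 1] = True
    return replace(tree, au=au, bp=bp, scales=scales, au_fallback=fallback)


def fit_au(bp_counts: np.ndarray, rt: np.ndarray, B: int,
           usable_scale: np.ndarray | None = None) -> tuple:
    """AU extrapolation for one node from per-scale bootstrap hit counts.

    Fits ``z_r = v*sqrt(rt) + c/sqrt(rt)`` (``z_r = qnorm(1 - BP_r)``) by
    weighted least squares over the non-degenerate scales (0 < BP < 1) and
    returns ``(AU, fallback)`` with ``AU = 1 - Phi(v - c)``. With fewer
    than three usable scales the clipped BP at the scale nearest 1 is
    returned and flagged as a fallback.
    """
    bp_counts = np.asarray(bp_counts, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if usable_scale is None:
        usable_scale = np.ones(rt.size, dtype=bool)
    bp = bp_counts / B
    lo_clip, hi_clip = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    ref_scale = int(np.argmin(np.abs(rt - 1.0)))
    ok = usable_scale & (bp_counts > 0) & (bp_counts < B)
    if ok.sum() >= 3:
        bb = np.clip(bp[ok], lo_clip, hi_clip)
        z = norm.ppf(1.0 - bb)
        sq = np.sqrt(rt[ok])
        x = np.column_stack([sq, 1.0 / sq])
        w = B * norm.pdf(z) ** 2 / (bb * (1.0 - bb))
        xtw = x.T * w
        try:
            v, c = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            return float(np.clip(bp[ref_scale], lo_clip, hi_clip)), True
        return float(1.0 - norm.cdf(v - c)), False
    return float(np.clip(bp[ref_scale], lo_clip, hi_clip)), True


def pick_confident(tree: ClusterTree, alpha: float = 0.05) -> Partition:
    """Maximal (outermost) nodes with AU >= 1 - alpha become clusters.

    Clumps not covered by any confident node remain unassigned (-1).
    """
    if tree.au is None:
        raise ValidationError("tree has no AU values; run multiscale_bootstrap")
    n = tree.n_leaves
    z = tree.Z
    labels = np.full(n, -1, dtype=int)
    next_label = 0

    def leaves_of(node: int) -> list:
        if node < n:
            return [node]
        row = node - n
        return leaves_of(int(z[row, 0])) + leaves_of(int(z[row, 1]))

    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        a = tree.au[node - n]
        if np.isfinite(a) and a >= 1.0 - alpha:
            nonlocal_leaves = leaves_of(node)
            labels[nonlocal_leaves] = next_label
            next_label += 1
        else:
            row = node - n
            stack.append(int(z[row, 0]))
            stack.append(int(z[row, 1]))
    return Partition(tree.clump_ids, labels)


# ---------------------------------------------------------------------------
# partition comparison and k selection
# ---------------------------------------------------------------------------


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two full partitions."""
    if set(a.members.tolist()) != set(b.members.tolist()):
        raise ValidationError("partitions cover different member sets")
    if np.any(a.labels < 0) or np.any(b.labels < 0):
        raise ValidationError("partitions must be fully assigned "
                              "(use with_singletons() for partial ones)")
    # align b to a's member order
    pos = {m: i for i, m in enumerate(b.members.tolist())}
    lb = b.labels[[pos[m] for m in a.members.tolist()]]
    la = a.labels
    n = la.size
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    cont = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(cont, (ia, ib), 1)
    index = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    if denom == 0:
        return 1.0  # both partitions degenerate and identical in structure
    return float((index - expected) / denom)


def choose_k(tree: ClusterTree, confident: Partition, k_range=None) -> int:
    """Smallest k whose cut maximizes ARI against the confident partition.

    Unassigned clumps of the confident partition are treated as
    singletons.
    """
    if confident.n_assigned == 0:
        raise ValidationError("confident partition is empty; choose k manually")
    n = tree.n_leaves
    if k_range is None:
        k_range = range(2, min(30, n - 1) + 1)
    k_range = [int(k) for k in k_range if 1 <= k <= n]
    if not k_range:
        raise ValidationError("empty k_range")
    ref = confident.with_singletons()
    best_k, best_ari = None, -np.inf
    for k in k_range:
        ari = adjusted_rand_index(cut_tree(tree, k), ref)
        if ari > best_ari + 1e-12:
            best_k, best_ari = k, ari
    return best_k


def expand_to_cells(clumps: ClumpPartition, clustering: Partition) -> Partition:
    """Propagate a clump-level clustering to the member cells."""
    pos = {m: i for i, m in enumerate(clustering.members.tolist())}
    missing = [c for c in clumps.clump_ids.tolist() if c not in pos]
    if missing:
        raise ValidationError(f"clumps missing from clustering: {missing}")
    lab = np.array([clustering.labels[pos[c]] for c in clumps.clump_ids.tolist()])
    if np.any(lab < 0):
        raise ValidationError("clustering leaves some clumps unlabeled")
    return Partition(clumps.cell_ids, lab[clumps.labels])


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick string with AU values as internal node labels."""
    n = tree.n_leaves
    z = tree.Z

    def fmt(node: int, parent_h: float) -> str:
        if node < n:
            return f"{tree.clump_ids[node]}:{parent_h:.6g}"
        row = node - n
        h = z[row, 2]
        left = fmt(int(z[row, 0]), h)
        right = fmt(int(z[row, 1]), h)
        label = ""
        if tree.au is not None and np.isfinite(tree.au[row]):
            label = f"{tree.au[row]:.4f}"
        return f"({left},{right}){label}:{max(parent_h - h, 0.0):.6g}"

    root = 2 * n - 2
    return fmt(root, z[-1, 2]) + ";"
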