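"""Resampled mutual-information network inference and the shuffled-name null.

The inference layer repeats {sample N cells -> select variable genes (vst)
-> restrict to transcription factors -> ARACNe with Miller-Madow MI on
equal-width bins} M times. In parallel, the same procedure runs on
name-shuffled data (M_hat resamples x K shuffles) to estimate how often a
node or edge appears by chance. Appearance counts over the M specimens are
tested against a Poisson(lambda*M) null; Benjamini-Yekutieli-adjusted
q-values below the threshold define the consensus network.

The node null rate needs no resampling: under name shuffling a gene is
selected as variable with probability n_hvg / n_genes exactly. The edge
rate is estimated from the shuffled specimens, pooled across TF pairs
(name shuffling makes pairs exchangeable).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import poisson

from .io import CountMatrix, Graph, ResamplingConfig, TFCatalog, ValidationError

_GRN_STREAM = 1
_NULL_STREAM = 2


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent substream for (seed, stream, indices...)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


# ---------------------------------------------------------------------------
# resampling primitives
# ---------------------------------------------------------------------------


def sample_cells(m: CountMatrix, N: int, rng: np.random.Generator,
                 replace: bool = False) -> CountMatrix:
    """Draw ``N`` cells uniformly (without replacement by default)."""
    if not replace and N > m.n_cells:
        raise ValidationError(f"cannot draw {N} of {m.n_cells} cells without replacement")
    idx = rng.choice(m.n_cells, size=N, replace=replace)
    if replace:
        # bootstrap duplicates need distinct ids
        ids = np.array([f"{m.cell_ids[i]}#{k}" for k, i in enumerate(idx)],
                       dtype=object)
        return CountMatrix(m.values[idx], ids, m.gene_ids)
    return m.select_cells(idx)


def shuffle_gene_names(m: CountMatrix, rng: np.random.Generator) -> CountMatrix:
    """Permute gene names uniformly, leaving the values untouched."""
    perm = rng.permutation(m.n_genes)
    return CountMatrix(m.values, m.cell_ids, m.gene_ids[perm])


# ---------------------------------------------------------------------------
# variable-gene selection (vst)
# ---------------------------------------------------------------------------


def _loess(x: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2) -> np.ndarray:
    """Local polynomial (tricube-weighted) regression evaluated at ``x``.

    Windows are the ``ceil(span*n)`` nearest points; with very few points
    the degree drops to 1 (and to the identity below 3 points) so the fit
    never interpolates exactly through every observation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        return y.copy()
    if n <= degree + 2:
        degree = 1
    q = int(np.ceil(span * n))
    q = min(n, max(q, degree + 2))

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    lo = np.empty(n, dtype=np.intp)
    j = 0
    for i in range(n):
        while j + q < n and xs[j + q] - xs[i] < xs[i] - xs[j]:
            j += 1
        lo[i] = j
    idx = lo[:, None] + np.arange(q)[None, :]
    xw, yw = xs[idx], ys[idx]
    d = np.abs(xw - xs[:, None])
    dmax = d.max(axis=1)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (d / dmax[:, None]) ** 3) ** 3
    np.clip(w, 0.0, None, out=w)
    w += 1e-9  # keep windows of tied distances nonsingular

    t = xw - xs[:, None]
    a = np.stack([t**p for p in range(degree + 1)], axis=2)  # (n, q, deg+1)
    m = np.einsum("nq,nqa,nqb->nab", w, a, a)
    b = np.einsum("nq,nqa,nq->na", w, a, yw)
    m[:, np.arange(degree + 1), np.arange(degree + 1)] += 1e-10
    coef = np.linalg.solve(m, b[..., None])[..., 0]
    fitted = np.empty(n)
    fitted[order] = coef[:, 0]
    return fitted


def vst_scores(values: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Standardized variance per gene (the vst variable-gene statistic).

    Per-gene raw mean and variance; loess trend of log10 variance on log10
    mean over genes with positive variance; counts standardized by the
    trend-expected standard deviation, clipped at sqrt(n_cells); the score
    is the variance of the clipped standardized values. Constant genes
    score 0.
    """
    values = np.asarray(values)
    n = values.shape[0]
    mu = values.mean(axis=0)
    if n < 2:
        return np.zeros(values.shape[1])
    var = values.var(axis=0, ddof=1)
    scores = np.zeros(values.shape[1])
    pos = var > 0
    if not np.any(pos):
        return scores
    fit = _loess(np.log10(mu[pos]), np.log10(var[pos]), span=span, degree=2)
    exp_sd = np.sqrt(np.power(10.0, fit))
    z = (values[:, pos] - mu[pos]) / exp_sd
    np.minimum(z, math.sqrt(n), out=z)
    scores[pos] = (z**2).sum(axis=0) / (n - 1)
    return scores


def select_variable_genes_vst(m: CountMatrix, n_top: int) -> list:
    """Top ``n_top`` genes ranked by the vst standardized variance."""
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    scores = vst_scores(m.values)
    n_expressed = int(np.count_nonzero(scores > 0))
    if n_expressed < n_top:
        warnings.warn(
            f"only {n_expressed} genes with positive standardized variance; "
            f"returning all ranked genes", stacklevel=2)
    order = np.argsort(-scores, kind="stable")[:n_top]
    return [m.gene_ids[i] for i in order]


# ---------------------------------------------------------------------------
# discretization and mutual information
# ---------------------------------------------------------------------------


def discretize_equal_width(values: np.ndarray, B: int) -> np.ndarray:
    """Per-gene equal-width binning of ``[min, max]`` into ``B`` intervals.

    The maximum maps to bin ``B-1``; a constant gene maps to bin 0.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0)
    width = (values.max(axis=0) - lo) / B
    width[width == 0] = 1.0  # constant gene -> all bin 0
    bins = np.floor((values - lo) / width).astype(np.int64)
    np.clip(bins, 0, B - 1, out=bins)
    return bins


def _entropy_mm(counts: np.ndarray, n: int) -> np.ndarray:
    """Miller-Madow entropy (nats) for rows of a count table."""
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    h = -(p * logp).sum(axis=-1)
    m_occ = np.count_nonzero(counts, axis=-1)
    return h + (m_occ - 1) / (2.0 * n)


def mi_miller_madow(x: np.ndarray, y: np.ndarray) -> float:
    """Miller-Madow-corrected mutual information of two bin vectors (nats).

    ``MI = Hmm(x) + Hmm(y) - Hmm(x, y)``; the bias correction can make the
    estimate slightly negative, which is clipped only at network
    construction time, not here.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D bin vectors")
    n = x.size
    if n < 1:
        raise ValidationError("empty input")
    bx, by = int(x.max()) + 1, int(y.max()) + 1
    hx = _entropy_mm(np.bincount(x, minlength=bx)[None, :], n)[0]
    hy = _entropy_mm(np.bincount(y, minlength=by)[None, :], n)[0]
    hxy = _entropy_mm(np.bincount(x * by + y, minlength=bx * by)[None, :], n)[0]
    return float(hx + hy - hxy)


try:  # numba accelerates the all-pairs MI kernel; numpy path is equivalent
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

if _njit is not None:

    @_njit(cache=False)
    def _mi_kernel(bins, B):  # pragma: no cover - exercised via _pairwise_mi
        n, g = bins.shape
        marg = np.zeros((g, B), np.int64)
        for j in range(g):
            for i in range(n):
                marg[j, bins[i, j]] += 1
        hm = np.zeros(g)
        for j in range(g):
            h = 0.0
            m = 0
            for b in range(B):
                c = marg[j, b]
                if c > 0:
                    p = c / n
                    h -= p * np.log(p)
                    m += 1
            hm[j] = h + (m - 1) / (2.0 * n)
        out = np.zeros((g, g))
        joint = np.zeros(B * B, np.int64)
        for a in range(g - 1):
            for b in range(a + 1, g):
                for t in range(B * B):
                    joint[t] = 0
                for i in range(n):
                    joint[bins[i, a] * B + bins[i, b]] += 1
                h = 0.0
                m = 0
                for t in range(B * B):
                    c = joint[t]
                    if c > 0:
                        p = c / n
                        h -= p * np.log(p)
                        m += 1
                hj = h + (m - 1) / (2.0 * n)
                out[a, b] = hm[a] + hm[b] - hj
                out[b, a] = out[a, b]
        return out


def _pairwise_mi(bins: np.ndarray, B: int) -> np.ndarray:
    """All-pairs Miller-Madow MI matrix for a cells x genes bin matrix."""
    if _njit is not None:
        return _mi_kernel(np.ascontiguousarray(bins), B)
    n, g = bins.shape
    b2 = B * B
    marg = np.zeros((g, B), dtype=np.int64)
    for j in range(g):
        marg[j, :] = np.bincount(bins[:, j], minlength=B)
    hm = _entropy_mm(marg, n)
    out = np.zeros((g, g))
    for i in range(g - 1):
        rest = bins[:, i + 1:]
        codes = bins[:, i][:, None] * B + rest
        codes += np.arange(g - i - 1, dtype=np.int64)[None, :] * b2
        cnt = np.bincount(codes.ravel(), minlength=(g - i - 1) * b2)
        hj = _entropy_mm(cnt.reshape(-1, b2), n)
        out[i, i + 1:] = hm[i] + hm[i + 1:] - hj
    return out + out.T


def _dpi_prune(mi: np.ndarray, eps: float, chunk: int = 64) -> np.ndarray:
    """Mask of edges removed by the data processing inequality.

    Edge (i, j) is removed when some third gene k satisfies
    ``mi[i, j] < min(mi[i, k], mi[j, k]) - eps`` (the strictly weakest edge
    of a triangle). Absent edges (MI 0) never support a pruning path.
    """
    g = mi.shape[0]
    removed = np.zeros((g, g), dtype=bool)
    if not np.isfinite(eps):
        return removed
    for start in range(0, g, chunk):
        stop = min(start + chunk, g)
        t = np.minimum(mi[start:stop, None, :], mi[None, :, :]).max(axis=2)
        removed[start:stop] = (mi[start:stop] > 0) & (mi[start:stop] < t - eps)
    return removed


def aracne_network(m: CountMatrix, B: int | None = None, dpi_eps: float = 0.0) -> Graph:
    """ARACNe-style network: all-pairs Miller-Madow MI plus DPI pruning.

    Negative MI estimates are clipped to zero before graph construction;
    edges with MI <= 0 are absent. With fewer than three genes the DPI step
    is skipped (there are no triangles).
    """
    n, g_n = m.values.shape
    if B is None:
        B = max(2, int(math.isqrt(n)))
    if g_n < 3:
        warnings.warn("fewer than 3 genes: returning MI graph without DPI", stacklevel=2)
    bins = discretize_equal_width(m.values, B)
    mi = _pairwise_mi(bins, B)
    np.fill_diagonal(mi, 0.0)
    np.clip(mi, 0.0, None, out=mi)
    removed = _dpi_prune(mi, dpi_eps) if g_n >= 3 else np.zeros_like(mi, dtype=bool)
    g = Graph(vertices=m.gene_ids)
    ii, jj = np.nonzero(np.triu(mi, 1) > 0)
    for i, j in zip(ii, jj):
        if not (removed[i, j] or removed[j, i]):
            g.add_edge(m.gene_ids[i], m.gene_ids[j], mi[i, j])
    return g


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def _edge_id(u: str, v: str) -> str:
    return f"{u}|{v}" if u < v else f"{v}|{u}"


def _specimen_graph(sub: CountMatrix, tfs: TFCatalog, cfg: ResamplingConfig) -> Graph | None:
    hvg = select_variable_genes_vst(sub, cfg.n_hvg)
    sel = tfs.intersect(hvg)
    if len(sel) < 3:
        return None
    B = cfg.bins or max(2, int(math.isqrt(sub.n_cells)))
    return aracne_network(sub.select_genes(sel), B=B, dpi_eps=cfg.dpi_eps)


def run_grn_ensemble(smoothed: CountMatrix, tfs: TFCatalog,
                     cfg: ResamplingConfig) -> tuple:
    """M independent {sample -> vst HVG -> TF restrict -> ARACNe} runs.

    Returns the list of specimen graphs and a support table with the
    appearance count of every observed node and edge (plus summed edge MI,
    used later for consensus weights). Specimens yielding fewer than three
    variable TFs are skipped with a warning.
    """
    cfg.validate(smoothed.n_cells)
    N = cfg.resolve_n(smoothed.n_cells)
    graphs = []
    skipped = 0
    for m_i in range(cfg.M):
        rng = _rng(cfg.seed, _GRN_STREAM, m_i)
        sub = sample_cells(smoothed, N, rng, replace=cfg.with_replacement)
        g = _specimen_graph(sub, tfs, cfg)
        if g is None:
            skipped += 1
            continue
        graphs.append(g)
    if skipped:
        warnings.warn(f"skipped {skipped} specimens with < 3 variable TFs", stacklevel=2)
    return graphs, build_support(graphs)


def build_support(graphs: Sequence[Graph]) -> pd.DataFrame:
    """Appearance counts (and summed edge MI) over specimen graphs."""
    node_counts: dict = {}
    edge_counts: dict = {}
    edge_wsum: dict = {}
    for g in graphs:
        for v in g.vertices:
            node_counts[v] = node_counts.get(v, 0) + 1
        for (u, v), w in g.edges.items():
            eid = _edge_id(u, v)
            edge_counts[eid] = edge_counts.get(eid, 0) + 1
            edge_wsum[eid] = edge_wsum.get(eid, 0.0) + w
    rows = [("node", k, c, np.nan) for k, c in node_counts.items()]
    rows += [("edge", k, c, edge_wsum[k]) for k, c in edge_counts.items()]
    df = pd.DataFrame(rows, columns=["type", "id", "count", "weight_sum"])
    return df.sort_values(["type", "id"], kind="stable", ignore_index=True)


def run_null_ensemble(smoothed: CountMatrix, tfs: TFCatalog, cfg: ResamplingConfig,
                      pooled: bool = True):
    """Null appearance rates from name-shuffled resamples.

    ``lambda_node`` is analytic (n_hvg / n_genes). ``lambda_edge`` pools
    edge occurrences across all TF pairs over the M_hat x K shuffled
    specimens, divided by the number of candidate pairs C(|TF universe|, 2).
    With ``pooled=False`` a per-pair rate table is returned instead; at
    feasible shuffle counts most pairs are never observed, so the per-pair
    estimate is degenerate (rate 0) and is intended for fidelity
    experiments only.

    Variable-gene ranking is computed once per resample and shared across
    the K shuffles: selection is name-blind, so shuffling names before
    selection is equivalent to selecting and then relabeling.
    """
    cfg.validate(smoothed.n_cells)
    N = cfg.resolve_n(smoothed.n_cells)
    genes = np.asarray(smoothed.gene_ids, dtype=object)
    n_genes = genes.size
    lam_node = min(1.0, cfg.n_hvg / n_genes)
    tf_universe = tfs.intersect(genes)
    n_candidates = int(comb(len(tf_universe), 2, exact=True))
    tf_mask_by_gene = np.array([g in tfs for g in genes], dtype=bool)

    total_edges = 0
    per_pair: dict = {}
    n_specimens = cfg.M_hat * cfg.K
    for m_i in range(cfg.M_hat):
        rng = _rng(cfg.seed, _NULL_STREAM, m_i)
        sub = sample_cells(smoothed, N, rng, replace=cfg.with_replacement)
        scores = vst_scores(sub.values)
        top = np.argsort(-scores, kind="stable")[: cfg.n_hvg]
        for k_i in range(cfg.K):
            rngk = _rng(cfg.seed, _NULL_STREAM, m_i, k_i)
            perm = rngk.permutation(n_genes)
            names_top = genes[perm[top]]
            keep = tf_mask_by_gene[perm[top]]
            cols = top[keep]
            if cols.size < 2:
                continue
            sel = CountMatrix(sub.values[:, cols], sub.cell_ids, names_top[keep])
            B = cfg.bins or max(2, int(math.isqrt(sub.n_cells)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = aracne_network(sel, B=B, dpi_eps=cfg.dpi_eps)
            total_edges += g.n_edges
            if not pooled:
                for (u, v) in g.edges:
                    eid = _edge_id(u, v)
                    per_pair[eid] = per_pair.get(eid, 0) + 1
    if n_candidates == 0:
        lam_edge = 0.0
    else:
        lam_edge = total_edges / (n_specimens * n_candidates)
    if pooled:
        return lam_node, lam_edge
    rates = {k: c / n_specimens for k, c in per_pair.items()}
    return lam_node, lam_edge, rates


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def poisson_tail_p(count: int, lam: float, M: int) -> float:
    """Upper-tail Poisson p-value: P(X >= count) with X ~ Poisson(lam * M)."""
    if count < 0 or lam < 0 or M < 1:
        raise ValidationError("count and lam must be >= 0 and M >= 1")
    if count == 0:
        return 1.0
    p = float(poisson.sf(count - 1, lam * M))
    return max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]


def adjust_by(pvals: Iterable[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values.

    ``m_total`` allows a hypothesis family larger than the supplied vector;
    the implicit members are treated as p = 1 and can never lower a
    q-value, so only the observed p-values need to be materialized.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = int(m_total) if m_total is not None else p.size
    if m < p.size:
        raise ValidationError("m_total smaller than number of p-values")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = c_m * m * ranked / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(raw[::-1])[::-1]
    np.clip(q, None, 1.0, out=q)
    out = np.empty_like(q)
    out[order] = q
    return out


def significance_table(support: pd.DataFrame, lam_node: float, lam_edge: float,
                       M: int, n_tf_universe: int) -> pd.DataFrame:
    """Attach null rates, Poisson p-values and BY q-values to a support table.

    Nodes and edges are adjusted as separate families; the family sizes are
    the TF universe and all C(universe, 2) candidate pairs, which is why
    ``adjust_by`` receives an explicit total.
    """
    df = support.copy()
    df["lam"] = np.where(df["type"] == "node", lam_node, lam_edge)
    df["p"] = [poisson_tail_p(int(c), float(l), M) for c, l in zip(df["count"], df["lam"])]
    df["q"] = np.nan
    for typ, m_total in (("node", n_tf_universe),
                         ("edge", int(comb(n_tf_universe, 2, exact=True)))):
        mask = df["type"] == typ
        if mask.any():
            df.loc[mask, "q"] = adjust_by(df.loc[mask, "p"], m_total=max(m_total, mask.sum()))
    return df


def consensus_grn(graphs: Sequence[Graph], support: pd.DataFrame,
                  q_threshold: float) -> Graph:
    """Consensus network of significant nodes and edges.

    An edge survives only when its own q-value and both endpoint node
    q-values pass the threshold; its weight is the mean MI over the
    specimens that contain it.
    """
    if "q" not in support.columns:
        raise ValidationError("support table lacks q-values; run significance_table first")
    sig = support[support["q"] < q_threshold]
    nodes = set(sig.loc[sig["type"] == "node", "id"])
    g = Graph(vertices=sorted(nodes))
    for _, row in sig[sig["type"] == "edge"].iterrows():
        u, v = row["id"].split("|")
        if u in nodes and v in nodes:
            g.add_edge(u, v, row["weight_sum"] / row["count"])
    if g.n_vertices == 0:
        warnings.warn("consensus network is empty at the given threshold", stacklevel=2)
    return g
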