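"""k-NN smoothing of counts on a 2-D embedding.

Each cell's counts are replaced by the truncated (floored) mean of its k
nearest neighbors in the embedding, Euclidean distance, self included. The
floor keeps the matrix integral, so the smoothed output is again a valid
count matrix and the rest of the pipeline is unchanged.
"""

from __future__ import annotations

import numpy as np

from .io import CountMatrix, Embedding, ValidationError


def _knn_indices(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Indices of the k nearest cells per cell (self first, ties by index).

    A stable argsort over exact distances gives the deterministic
    index-order tie-break; the self distance is forced below zero so the
    query cell is always part of its own neighborhood (k=1 is identity).
    """
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.intp)
    sq = np.einsum("ij,ij->i", coords, coords)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d2 = sq[None, :] - 2.0 * block @ coords.T + np.einsum("ij,ij->i", block, block)[:, None]
        d2[np.arange(stop - start), np.arange(start, stop)] = -1.0
        out[start:stop] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


def knn_smooth(counts: CountMatrix, emb: Embedding, k: int) -> CountMatrix:
    """Smooth counts over the k-nearest-neighbor graph of the embedding.

    Entry ``(c, g)`` of the result is ``floor(mean(counts[nn_k(c), g]))``
    where ``nn_k(c)`` are the k nearest cells to ``c`` (self included).
    """
    if not np.array_equal(counts.cell_ids, emb.cell_ids):
        raise ValidationError("embedding cell ids do not match counts")
    if not 1 <= k <= counts.n_cells:
        raise ValidationError(f"k={k} out of range [1, {counts.n_cells}]")
    idx = _knn_indices(emb.coords, k)
    values = counts.values
    out = np.empty_like(values)
    chunk = max(1, 2**22 // max(1, k * counts.n_genes))
    for start in range(0, counts.n_cells, chunk):
        stop = min(start + chunk, counts.n_cells)
        # integer sum then floor division: exact truncation of the mean
        out[start:stop] = values[idx[start:stop]].sum(axis=1) // k
    return CountMatrix(out, counts.cell_ids, counts.gene_ids)


def compute_embedding(counts: CountMatrix, n_pcs: int = 30, seed: int = 0) -> Embedding:
    """Convenience normalize -> log1p -> PCA -> UMAP embedding.

    The pipeline contract only requires coordinates; this helper exists so
    datasets without a precomputed embedding can still be run end to end.
    """
    import umap  # deferred: optional convenience path

    from .cluster import lognormalize

    x = lognormalize(counts).to_numpy()
    x = x - x.mean(axis=0)
    from sklearn.decomposition import PCA

    n_comp = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(pcs)
    return Embedding(np.asarray(coords, dtype=float), counts.cell_ids)
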