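"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the shape of droplet scRNA-seq data: negative
binomial counts, a handful of discrete cell types, type-specific
transcription-factor programs in which active regulators are elevated and
their targets co-vary with the regulator's latent activity, and a 2-D
embedding of well-separated type blobs. Everything is determined by the
seed, so fixtures are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, Embedding, Graph, TFCatalog, ValidationError


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the planted-regulator generative model.

    ``effect_size`` is the log-fold elevation of an active regulator's mean;
    ``noise_sd`` is the standard deviation of the Gaussian noise added to a
    target's log-mean around the linear response to its regulator;
    ``nb_dispersion`` is the NB overdispersion alpha in var = mu(1 + alpha*mu).
    """

    n_cells: int = 1500
    n_genes: int = 1000
    n_types: int = 3
    n_regulators: int = 5            # per type
    targets_per_regulator: int = 10
    nb_dispersion: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.8
    seed: int = 0
    base_mean: float = 1.0           # baseline counts per cell per gene
    activity_sd: float = 1.0         # within-type spread of regulator activity
    decoy_tf_fraction: float = 0.2
    embedding_sep: float = 10.0
    embedding_sd: float = 1.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    cell_type: np.ndarray                  # type id per cell
    regulators: dict                       # type id -> tuple of regulator symbols
    edges: tuple                           # planted (regulator, target) pairs
    params: SimulationParams

    @property
    def edge_set(self) -> set:
        return {tuple(sorted(e)) for e in self.edges}


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu(1 + alpha*mu); alpha=0 is Poisson."""
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_dataset(params: SimulationParams | None = None):
    """Generate (CountMatrix, Embedding, TFCatalog, SyntheticTruth).

    Per type, its regulators carry latent activity ``effect_size + noise``
    (zero mean activity elsewhere); each planted target's log-mean follows
    its regulator's activity plus Gaussian noise, inducing the
    regulator-target mutual information the network stage must detect.
    Background genes are iid negative binomial. The embedding places the
    types on a circle with Gaussian within-type spread.
    """
    p = params or SimulationParams()
    if p.n_types < 2:
        raise ValidationError("need at least 2 cell types")
    n_reg = p.n_types * p.n_regulators
    n_planted = n_reg * (1 + p.targets_per_regulator)
    if n_planted > p.n_genes:
        raise ValidationError(
            f"gene budget infeasible: {n_planted} planted genes > {p.n_genes}")
    rng = np.random.default_rng(p.seed)

    genes = np.array([f"G{i:04d}" for i in range(p.n_genes)], dtype=object)
    cells = np.array([f"cell{i:05d}" for i in range(p.n_cells)], dtype=object)
    cell_type = rng.integers(0, p.n_types, size=p.n_cells)

    reg_idx = np.arange(n_reg)
    tgt_idx = np.arange(n_reg, n_planted).reshape(n_reg, p.targets_per_regulator)
    regulators = {
        t: tuple(genes[reg_idx[t * p.n_regulators:(t + 1) * p.n_regulators]])
        for t in range(p.n_types)
    }
    edges = tuple(
        (str(genes[reg_idx[r]]), str(genes[j]))
        for r in range(n_reg) for j in tgt_idx[r]
    )

    log_base = np.log(p.base_mean)
    logmean = np.full((p.n_cells, p.n_genes), log_base)
    # background gene-level heterogeneity: lognormal means spanning the
    # whole expression range, so the HVG trend has a reference at every mean
    bg = np.ones(p.n_genes, dtype=bool)
    bg[:n_planted] = False
    logmean[:, bg] += rng.normal(0.0, 1.5, size=bg.sum())[None, :]

    # regulator latent activity and target response
    owner_type = np.repeat(np.arange(p.n_types), p.n_regulators)
    active = (cell_type[:, None] == owner_type[None, :]).astype(float)
    activity = p.effect_size * active + rng.normal(0.0, p.activity_sd,
                                                   size=(p.n_cells, n_reg))
    logmean[:, reg_idx] = log_base + activity
    for r in range(n_reg):
        noise = rng.normal(0.0, p.noise_sd,
                           size=(p.n_cells, p.targets_per_regulator))
        logmean[:, tgt_idx[r]] = log_base + activity[:, [r]] + noise

    counts = _nb_counts(rng, np.exp(logmean), p.nb_dispersion)

    # TF catalog: planted genes plus decoys drawn from the background
    n_decoys = int(round(p.decoy_tf_fraction * p.n_genes))
    decoy_pool = np.flatnonzero(bg)
    decoys = rng.choice(decoy_pool, size=min(n_decoys, decoy_pool.size),
                        replace=False)
    tf_syms = frozenset(genes[:n_planted]) | frozenset(genes[decoys])

    angles = 2 * np.pi * np.arange(p.n_types) / p.n_types
    centers = p.embedding_sep * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = centers[cell_type] + rng.normal(0.0, p.embedding_sd,
                                             size=(p.n_cells, 2))

    truth = SyntheticTruth(cell_type=cell_type, regulators=regulators,
                           edges=edges, params=p)
    return (CountMatrix(counts, cells, genes), Embedding(coords, cells),
            TFCatalog(tf_syms), truth)


def planted3(seed: int = 0):
    """The standard three-type planted-regulator fixture plus pipeline config.

    Returns (counts, embedding, tf catalog, truth, config). The resampling
    scale (M=20, M_hat=100, K=10, n_hvg=200) is sized so a full pipeline
    run on the fixture completes in minutes on one CPU while keeping the
    selected-to-total gene ratio of the same order as in full-size runs.
    """
    from .io import ResamplingConfig

    counts, emb, tfs, truth = simulate_dataset(SimulationParams(seed=seed))
    cfg = ResamplingConfig(k=10, N=600, M=20, M_hat=100, K=10, n_hvg=200,
                           q_threshold=1e-5, seed=seed)
    return counts, emb, tfs, truth, cfg


def iid_noise(n_cells: int = 600, n_genes: int = 300, seed: int = 0):
    """A structureless fixture: independent NB genes, no planted programs.

    Used to check null calibration -- the significance filter should leave
    the consensus network empty. Returns (counts, embedding, tf catalog,
    config); the TF catalog is a random 20% of the genes and the embedding
    a single Gaussian blob. The config draws N at the lower bound of the
    standard one-third-to-half range: resampled specimens from a single
    fixed dataset are not independent, and the Poisson appearance model is
    closest to its independence assumption when specimen overlap is small
    (see the methods note on null calibration).
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:04d}" for i in range(n_genes)], dtype=object)
    cells = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    means = np.exp(np.log(1.0) + rng.normal(0.0, 1.5, size=n_genes))
    counts = _nb_counts(rng, np.broadcast_to(means, (n_cells, n_genes)).copy(), 0.5)
    coords = rng.normal(0.0, 1.0, size=(n_cells, 2))
    tf_idx = rng.choice(n_genes, size=int(round(0.2 * n_genes)), replace=False)
    from .io import ResamplingConfig

    cfg = ResamplingConfig(k=10, N=200, M=20, M_hat=100, K=10, n_hvg=60,
                           q_threshold=1e-5, seed=seed)
    return (CountMatrix(counts, cells, genes), Embedding(coords, cells),
            TFCatalog(frozenset(genes[tf_idx])), cfg)


def simulate_random_graph(n: int, prob: float, seed: int | np.random.Generator = 0) -> Graph:
    """Erdos-Renyi G(n, p) with unit weights (used for MDS oracle testing)."""
    if not 0.0 <= prob <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    verts = [f"v{i}" for i in range(n)]
    g = Graph(vertices=verts)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < prob:
                g.add_edge(verts[i], verts[j], 1.0)
    return g


def simulate_profile_blocks(n_clumps: int, n_genes: int, k_blocks: int,
                            sep: float, seed: int = 0):
    """Block-structured profile matrix plus ground-truth block labels.

    Each block has a gene-wise center drawn N(0, sep^2); profiles are the
    block center plus unit Gaussian noise, so ``sep`` is the between-block
    separation in noise-SD units. Clumps are assigned to blocks round-robin
    (balanced).
    """
    if k_blocks > n_clumps:
        raise ValidationError("more blocks than clumps")
    from .cluster import ProfileMatrix

    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, sep, size=(k_blocks, n_genes))
    labels = np.arange(n_clumps) % k_blocks
    values = centers[labels] + rng.normal(0.0, 1.0, size=(n_clumps, n_genes))
    profiles = ProfileMatrix(values, np.arange(n_clumps),
                             np.array([f"g{j}" for j in range(n_genes)], dtype=object))
    return profiles, labels
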