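"""Core data containers and readers/writers.

Conventions used throughout the package:

* Count matrices are dense ``cells x genes`` arrays of nonnegative integers.
  The 10x on-disk convention (genes x cells) is transposed at read time.
* Gene symbols are matched case-sensitively after an optional, single
  case-normalization pass (default: none).
* Networks are undirected, MI-weighted graphs over gene symbols; edge
  identity is the unordered symbol pair.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer expression counts with identifiers.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array. Float inputs are accepted only when
        every entry is integral, and are cast to ``int64``.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns respectively.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-D")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("counts must be finite")
            if np.any(self.values != np.floor(self.values)):
                raise ValidationError("counts must be integers")
            self.values = self.values.astype(np.int64)
        elif not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("counts must be an integer array")
        else:
            self.values = self.values.astype(np.int64, copy=False)
        if np.any(self.values < 0):
            raise ValidationError("counts must be nonnegative")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValidationError("cell_ids length does not match rows")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValidationError("gene_ids length does not match columns")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def select_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[index], self.cell_ids[index], self.gene_ids)

    def select_genes(self, genes: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValidationError(f"genes not present: {missing[:10]}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix(self.values[:, idx], self.cell_ids, self.gene_ids[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class Embedding:
    """A 2-D per-cell embedding (typically UMAP coordinates)."""

    coords: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding must be n_cells x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding coordinates must be finite")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell_ids length does not match coords")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in embedding")

    def aligned_to(self, counts: CountMatrix) -> "Embedding":
        """Reorder rows to match ``counts.cell_ids`` exactly."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            idx = np.array([pos[c] for c in counts.cell_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise ValidationError(f"cell {exc} missing from embedding") from exc
        return Embedding(self.coords[idx], self.cell_ids[idx])


@dataclass(frozen=True)
class TFCatalog:
    """A catalog of transcription-factor gene symbols."""

    symbols: frozenset

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError("TF catalog is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def intersect(self, genes: Iterable[str]) -> list:
        """Catalog members present in ``genes``, in the order of ``genes``."""
        return [g for g in genes if g in self.symbols]


@dataclass
class ResamplingConfig:
    """Parameters of the resampling / significance layer.

    Defaults follow the published procedure: ``M=100`` GRN resamples,
    ``M_hat=1000`` null resamples with ``K=100`` name shuffles each
    (1e5 shuffled specimens), 2000 vst-ranked variable genes, and a
    significance cutoff of ``q < 1e-5``. ``N=None`` means 40% of the cells,
    capped at 20000.
    """

    k: int = 10
    N: int | None = None
    M: int = 100
    M_hat: int = 1000
    K: int = 100
    n_hvg: int = 2000
    q_threshold: float = 1e-5
    seed: int = 0
    with_replacement: bool = False
    bins: int | None = None  # None -> floor(sqrt(N)) per specimen
    dpi_eps: float = 0.0

    def resolve_n(self, n_cells: int) -> int:
        if self.N is not None:
            n = int(self.N)
        else:
            n = min(20000, max(1, int(round(0.4 * n_cells))))
        if not 1 <= n <= n_cells:
            raise ValidationError(f"N={n} out of range for {n_cells} cells")
        return n

    def validate(self, n_cells: int | None = None) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if n_cells is not None and self.k > n_cells:
            raise ValidationError("k exceeds number of cells")
        if self.M < 1 or self.M_hat < 1 or self.K < 1:
            raise ValidationError("M, M_hat and K must be >= 1")
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValidationError("q_threshold must be in (0, 1)")
        if n_cells is not None:
            self.resolve_n(n_cells)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "N": self.N, "M": self.M, "M_hat": self.M_hat,
            "K": self.K, "n_hvg": self.n_hvg, "q_threshold": self.q_threshold,
            "seed": self.seed, "with_replacement": self.with_replacement,
            "bins": self.bins, "dpi_eps": self.dpi_eps,
        }


class Graph:
    """A small undirected weighted graph keyed by gene symbols.

    Edge weights are MI values and must be >= 0; self-loops are rejected.
    Vertex order is insertion order (used for deterministic matrix layouts).
    """

    def __init__(self, vertices: Iterable[str] = (), edges: Mapping | Iterable | None = None):
        self._vertices: dict = {}
        self._edges: dict = {}
        for v in vertices:
            self.add_vertex(v)
        if edges:
            items = edges.items() if hasattr(edges, "items") else edges
            for (u, v), w in items:
                self.add_edge(u, v, w)

    # -- construction -------------------------------------------------
    def add_vertex(self, v: str) -> None:
        self._vertices.setdefault(v, None)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValidationError("self-loops are not allowed")
        if not np.isfinite(weight) or weight < 0:
            raise ValidationError("edge weights must be finite and >= 0")
        self.add_vertex(u)
        self.add_vertex(v)
        self._edges[(u, v) if u < v else (v, u)] = float(weight)

    # -- queries -------------------------------------------------------
    @property
    def vertices(self) -> tuple:
        return tuple(self._vertices)

    @property
    def edges(self) -> dict:
        return dict(self._edges)

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self._edges

    def weight(self, u: str, v: str) -> float:
        return self._edges[(u, v) if u < v else (v, u)]

    def neighbors(self, v: str) -> set:
        out = set()
        for (a, b) in self._edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def adjacency(self) -> tuple:
        """Return (vertex list, boolean adjacency matrix)."""
        verts = list(self._vertices)
        pos = {v: i for i, v in enumerate(verts)}
        a = np.zeros((len(verts), len(verts)), dtype=bool)
        for (u, v) in self._edges:
            a[pos[u], pos[v]] = a[pos[v], pos[u]] = True
        return verts, a

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        if set(self._vertices) != set(other._vertices):
            return False
        if set(self._edges) != set(other._edges):
            return False
        return all(
            math.isclose(w, other._edges[e], rel_tol=0.0, abs_tol=1e-12)
            for e, w in self._edges.items()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(|V|={self.n_vertices}, |E|={self.n_edges})"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _normalize_case(ids: np.ndarray, case: str | None) -> np.ndarray:
    if case is None:
        return ids
    if case == "upper":
        return np.array([str(s).upper() for s in ids], dtype=object)
    if case == "lower":
        return np.array([str(s).lower() for s in ids], dtype=object)
    raise ValidationError(f"unknown case normalization {case!r}")


def read_counts(path: str | os.PathLike, format: str | None = None,
                case: str | None = None) -> CountMatrix:
    """Read a count matrix from ``mtx_dir``, ``csv`` or ``tsv``.

    ``mtx_dir`` expects a 10x-style directory with ``matrix.mtx``,
    ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``, optionally
    gzipped; the on-disk genes x cells orientation is transposed. Dense
    CSV/TSV files carry cell ids in the first column and gene ids in the
    header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"

    if format == "mtx_dir":
        from scipy.io import mmread

        def _find(*names):
            for n in names:
                for suffix in ("", ".gz"):
                    p = path / (n + suffix)
                    if p.exists():
                        return p
            raise FileNotFoundError(f"none of {names} in {path}")

        mat = mmread(_find("matrix.mtx"))
        feats = pd.read_csv(_find("features.tsv", "genes.tsv"), sep="\t", header=None)
        barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)
        gene_col = 1 if feats.shape[1] > 1 else 0
        values = np.asarray(mat.todense()).T  # genes x cells on disk
        genes = _normalize_case(feats[gene_col].to_numpy(dtype=object), case)
        return CountMatrix(values, barcodes[0].to_numpy(dtype=object), genes)

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        genes = _normalize_case(df.columns.to_numpy(dtype=object), case)
        return CountMatrix(values, df.index.to_numpy(dtype=object), genes)

    raise ValidationError(f"unknown counts format {format!r}")


def read_embedding(path: str | os.PathLike) -> Embedding:
    """Read a cell id + two coordinate columns table (CSV or TSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise ValidationError("embedding table needs two coordinate columns")
    return Embedding(df.iloc[:, :2].to_numpy(dtype=float),
                     df.index.to_numpy(dtype=object))


def read_gene_list(path: str | os.PathLike, case: str | None = None) -> TFCatalog:
    """Read a one-symbol-per-line gene list; '#' comments are skipped."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if s:
                symbols.append(s)
    symbols = list(_normalize_case(np.array(symbols, dtype=object), case))
    if not symbols:
        raise ValidationError(f"no gene symbols found in {path}")
    return TFCatalog(frozenset(symbols))


# ---------------------------------------------------------------------------
# graph I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = "gene_a\tgene_b\tweight"


def write_graph(g: Graph, path: str | os.PathLike, format: str = "edge_tsv") -> None:
    """Write a graph as 3-column edge TSV or GraphML.

    The edge TSV lists isolated vertices as rows with empty ``gene_b`` and
    ``weight`` so round-trips preserve the vertex set.
    """
    path = Path(path)
    if format == "edge_tsv":
        touched = set()
        for (u, v) in g.edges:
            touched.add(u)
            touched.add(v)
        with open(path, "w") as fh:
            fh.write(_EDGE_HEADER + "\n")
            for (u, v), w in sorted(g.edges.items()):
                fh.write(f"{u}\t{v}\t{w!r}\n")
            for v in g.vertices:
                if v not in touched:
                    fh.write(f"{v}\t\t\n")
        return
    if format == "graphml":
        import networkx as nx

        nxg = nx.Graph()
        nxg.add_nodes_from(g.vertices)
        for (u, v), w in g.edges.items():
            nxg.add_edge(u, v, weight=w)
        nx.write_graphml(nxg, path)
        return
    raise ValidationError(f"unknown graph format {format!r}")


def read_graph(path: str | os.PathLike, format: str | None = None) -> Graph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edge_tsv"
    g = Graph()
    if format == "edge_tsv":
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != _EDGE_HEADER.strip():
                raise ValidationError(f"unexpected edge TSV header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or parts[1] == "":
                    g.add_vertex(parts[0])
                else:
                    g.add_edge(parts[0], parts[1], float(parts[2]))
        return g
    if format == "graphml":
        import networkx as nx

        nxg = nx.read_graphml(path)
        for v in nxg.nodes:
            g.add_vertex(str(v))
        for u, v, data in nxg.edges(data=True):
            g.add_edge(str(u), str(v), float(data.get("weight", 1.0)))
        return g
    raise ValidationError(f"unknown graph format {format!r}")


def write_metadata(path: str | os.PathLike, config: Mapping, seed: int,
                   extra: Mapping | None = None) -> None:
    """Write the JSON run-metadata sidecar next to an artifact."""
    from . import __version__

    meta = {"config": dict(config), "seed": int(seed), "version": __version__}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")
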