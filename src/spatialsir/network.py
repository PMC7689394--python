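"""Spatial modular ("cities in a country") network generator.

Nodes sit on a periodic L x L square lattice partitioned into square
communities of linear size zeta.  Inside each community the wiring is
Erdős–Rényi G(n, p) with mean degree ``k_intra`` (K); between
lattice-adjacent communities there are sparse inter-links: the mean
total inter-degree per node is ``k_inter``, so each community carries
``Q = k_inter * zeta**2`` inter-links, each attached uniformly to one of
its four grid neighbours (periodic wrap at both the node-lattice and the
community-grid level).

Because every inter-link contributes degree to both of its endpoints,
the generator draws ``Poisson(k_inter / 2)`` link *stubs* per node; the
drawn plus received halves add up to a per-node inter-degree of
``k_inter`` and a per-neighbour-pair link count of mean ``Q/4``, the
quantities the threshold theory (:mod:`spatialsir.theory`) is written
in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ModelParams",
    "SpatialModularNetwork",
    "DegreeSummary",
    "build_network",
    "community_grid_neighbors",
    "degree_summary",
    "write_network",
    "read_network",
]

INTRA, INTER = 0, 1
_KIND_NAME = {INTRA: "intra", INTER: "inter"}
_KIND_CODE = {v: k for k, v in _KIND_NAME.items()}


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters of the spatial modular network.

    Attributes
    ----------
    L : int
        Linear size of the node lattice (N = L**2 nodes).
    zeta : int
        Linear size of a community (N_c = zeta**2 nodes per city).
        Must divide L exactly.
    k_intra : float
        Mean intra-community (within-city) degree K.
    k_inter : float
        Mean per-node inter-community degree.  The per-community total
        is Q = k_inter * zeta**2.
    """

    L: int
    zeta: int
    k_intra: float
    k_inter: float

    def __post_init__(self) -> None:
        if self.L < 1 or self.zeta < 1:
            raise ParameterError("L and zeta must be positive integers")
        if self.L % self.zeta != 0:
            raise ParameterError(
                f"L={self.L} must be an exact multiple of zeta={self.zeta} "
                "so the community grid tiles the lattice"
            )
        if self.k_intra < 0 or self.k_inter < 0:
            raise ParameterError("mean degrees must be non-negative")
        if self.community_size > 1 and self.k_intra >= self.community_size:
            raise ParameterError(
                f"k_intra={self.k_intra} must be < N_c={self.community_size} "
                "(ER wiring probability must stay below 1)"
            )

    @property
    def n_nodes(self) -> int:
        """N = L**2."""
        return self.L * self.L

    @property
    def community_size(self) -> int:
        """N_c = zeta**2."""
        return self.zeta * self.zeta

    @property
    def n_communities(self) -> int:
        """n = N / N_c."""
        return self.n_nodes // self.community_size

    @property
    def grid_side(self) -> int:
        """Linear size of the community grid, L / zeta."""
        return self.L // self.zeta

    @property
    def Q(self) -> float:
        """Mean number of inter-links per community, k_inter * zeta**2."""
        return self.k_inter * self.community_size

    def as_dict(self) -> dict:
        return {"L": self.L, "zeta": self.zeta, "k_intra": self.k_intra, "k_inter": self.k_inter}


@dataclass
class SpatialModularNetwork:
    """A generated network: coordinates, community labels and typed edges.

    Edges are stored canonically as (u < v) pairs in two parallel int64
    arrays plus a kind array (0 = intra, 1 = inter), sorted
    lexicographically — generation is bit-reproducible given
    (params, seed).
    """

    params: Optional[ModelParams]
    seed: Optional[int]
    coords: np.ndarray  # (N, 2) int32, (x, y) in [0, L)
    community: np.ndarray  # (N,) int32
    edge_u: np.ndarray  # (E,) int64, u < v
    edge_v: np.ndarray
    edge_kind: np.ndarray  # (E,) uint8
    _csr_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_u.shape[0]

    @property
    def L(self) -> Optional[int]:
        return self.params.L if self.params is not None else None

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency (indptr, indices) over all edges; cached."""
        if self._csr_cache is None:
            self._csr_cache = build_csr(self.n_nodes, self.edge_u, self.edge_v)
        return self._csr_cache

    def edge_keys(self) -> np.ndarray:
        """Canonical u*N+v key per edge (useful for set comparisons)."""
        return self.edge_u * self.n_nodes + self.edge_v

    def replace_edges(
        self, edge_u: np.ndarray, edge_v: np.ndarray, edge_kind: np.ndarray
    ) -> "SpatialModularNetwork":
        """A copy of this network with a different edge set."""
        return SpatialModularNetwork(
            params=self.params,
            seed=self.seed,
            coords=self.coords,
            community=self.community,
            edge_u=edge_u,
            edge_v=edge_v,
            edge_kind=edge_kind,
        )

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges: Sequence[tuple[int, int]], kind: str = "intra"
    ) -> "SpatialModularNetwork":
        """Wrap an arbitrary small graph (no spatial structure) so it can
        be fed to the SIR simulator; nodes are laid out on a line."""
        eu, ev = [], []
        seen = set()
        for a, b in edges:
            if a == b:
                raise ParameterError("self-loops are not allowed")
            u, v = (a, b) if a < b else (b, a)
            if not (0 <= u and v < n_nodes):
                raise ParameterError("edge endpoint out of range")
            if (u, v) in seen:
                raise ParameterError("duplicate edge")
            seen.add((u, v))
            eu.append(u)
            ev.append(v)
        order = np.lexsort((np.asarray(ev, dtype=np.int64), np.asarray(eu, dtype=np.int64)))
        eu = np.asarray(eu, dtype=np.int64)[order]
        ev = np.asarray(ev, dtype=np.int64)[order]
        coords = np.zeros((n_nodes, 2), dtype=np.int32)
        coords[:, 0] = np.arange(n_nodes)
        return cls(
            params=None,
            seed=None,
            coords=coords,
            community=np.zeros(n_nodes, dtype=np.int32),
            edge_u=eu,
            edge_v=ev,
            edge_kind=np.full(eu.shape[0], _KIND_CODE[kind], dtype=np.uint8),
        )


@dataclass(frozen=True)
class DegreeSummary:
    mean_intra_degree: float
    mean_inter_degree: float
    community_inter_counts: np.ndarray  # (n,) inter-links touching each community


def build_csr(n_nodes: int, edge_u: np.ndarray, edge_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR adjacency from an undirected edge list."""
    src = np.concatenate([edge_u, edge_v])
    dst = np.concatenate([edge_v, edge_u])
    order = np.lexsort((dst, src))
    src = src[order]
    dst = dst[order]
    counts = np.bincount(src, minlength=n_nodes)
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, dst.astype(np.int64)


def community_grid_neighbors(community_index: int, params: ModelParams) -> list[int]:
    """The 4 orthogonal neighbours (up, down, left, right) of a community
    on the periodic community grid, row-major indexed.  Always 4 entries;
    repeats occur only when the grid side is < 3."""
    g = params.grid_side
    n = params.n_communities
    if not (0 <= community_index < n):
        raise ParameterError(f"community index {community_index} out of range [0, {n})")
    row, col = divmod(community_index, g)
    return [
        ((row - 1) % g) * g + col,
        ((row + 1) % g) * g + col,
        row * g + (col - 1) % g,
        row * g + (col + 1) % g,
    ]


def _neighbor_table(params: ModelParams) -> np.ndarray:
    """(n, 4) array of neighbour community indices."""
    g = params.grid_side
    idx = np.arange(params.n_communities)
    row, col = np.divmod(idx, g)
    return np.stack(
        [
            ((row - 1) % g) * g + col,
            ((row + 1) % g) * g + col,
            row * g + (col - 1) % g,
            row * g + (col + 1) % g,
        ],
        axis=1,
    )


def _decode_pair_index(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the row-major linear index over unordered pairs i < j of
    range(n): k = i*(2n - i - 1)/2 + (j - i - 1)."""
    k = k.astype(np.int64)
    b = 2 * n - 1
    i = ((b - np.sqrt(b * b - 8.0 * k)) // 2).astype(np.int64)
    i = np.clip(i, 0, n - 2)
    # float sqrt can land one row off; fix both directions
    for _ in range(2):
        base = i * (2 * n - i - 1) // 2
        i = np.where(base > k, i - 1, i)
        base = i * (2 * n - i - 1) // 2
        overflow = k - base >= (n - 1 - i)
        i = np.where(overflow, i + 1, i)
    base = i * (2 * n - i - 1) // 2
    j = k - base + i + 1
    return i, j


def _local_to_node(comm: np.ndarray, local: np.ndarray, params: ModelParams) -> np.ndarray:
    """Map (community index, local index in [0, N_c)) to a node id."""
    g, z, L = params.grid_side, params.zeta, params.L
    crow, ccol = np.divmod(comm.astype(np.int64), g)
    lrow, lcol = np.divmod(local.astype(np.int64), z)
    return (crow * z + lrow) * L + (ccol * z + lcol)


def build_network(params: ModelParams, seed: int) -> SpatialModularNetwork:
    """Generate one network realization.

    Intra wiring is G(N_c, p) with p = K/(N_c - 1) per community,
    realized by drawing the Binomial edge count and then a uniform
    distinct subset of node pairs (equivalent in distribution to
    independent Bernoulli pairs).  Inter wiring draws Poisson(k_inter/2)
    stubs per node; each stub picks one of the community's 4 grid
    neighbours uniformly, then a uniform node there.  Self-loops cannot
    arise (endpoints lie in different communities) except on the
    degenerate 1x1 community grid, where no inter-links are generated at
    all so that the zeta = L limit is a pure ER network.  Duplicate
    edges are discarded.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
    N = params.n_nodes
    Nc = params.community_size
    n = params.n_communities
    L = params.L

    xs = np.arange(N, dtype=np.int64) % L
    ys = np.arange(N, dtype=np.int64) // L
    coords = np.stack([xs, ys], axis=1).astype(np.int32)
    g = params.grid_side
    community = ((ys // params.zeta) * g + (xs // params.zeta)).astype(np.int32)

    # --- intra-community ER wiring -----------------------------------
    intra_u_parts, intra_v_parts = [], []
    if params.k_intra > 0 and Nc > 1:
        p = params.k_intra / (Nc - 1)
        M = Nc * (Nc - 1) // 2
        comm_ids = np.arange(n)
        local_base = np.arange(Nc, dtype=np.int64)
        for c in comm_ids:
            m = rng.binomial(M, p)
            if m == 0:
                continue
            lin = rng.choice(M, size=m, replace=False)
            li, lj = _decode_pair_index(lin, Nc)
            cc = np.full(m, c, dtype=np.int64)
            intra_u_parts.append(_local_to_node(cc, local_base[li], params))
            intra_v_parts.append(_local_to_node(cc, local_base[lj], params))
    if intra_u_parts:
        iu = np.concatenate(intra_u_parts)
        iv = np.concatenate(intra_v_parts)
        iu, iv = np.minimum(iu, iv), np.maximum(iu, iv)
    else:
        iu = iv = np.empty(0, dtype=np.int64)

    # --- inter-community wiring --------------------------------------
    if params.k_inter > 0 and g > 1:
        stub_counts = rng.poisson(params.k_inter / 2.0, N)
        src = np.repeat(np.arange(N, dtype=np.int64), stub_counts)
        if src.size:
            table = _neighbor_table(params)
            dirs = rng.integers(0, 4, size=src.size)
            tgt_comm = table[community[src], dirs]
            tgt_local = rng.integers(0, Nc, size=src.size)
            tgt = _local_to_node(tgt_comm, tgt_local, params)
            ju = np.minimum(src, tgt)
            jv = np.maximum(src, tgt)
            keys = np.unique(ju * N + jv)  # drop duplicate inter edges
            ju, jv = np.divmod(keys, N)
        else:
            ju = jv = np.empty(0, dtype=np.int64)
    else:
        ju = jv = np.empty(0, dtype=np.int64)

    # duplicates across kinds are impossible (inter endpoints straddle
    # communities, intra endpoints share one) so a plain concat suffices
    edge_u = np.concatenate([iu, ju])
    edge_v = np.concatenate([iv, jv])
    edge_kind = np.concatenate(
        [np.zeros(iu.size, dtype=np.uint8), np.ones(ju.size, dtype=np.uint8)]
    )
    order = np.lexsort((edge_v, edge_u))
    net = SpatialModularNetwork(
        params=params,
        seed=int(seed),
        coords=coords,
        community=community,
        edge_u=edge_u[order],
        edge_v=edge_v[order],
        edge_kind=edge_kind[order],
    )
    return net


def degree_summary(net: SpatialModularNetwork) -> DegreeSummary:
    """Empirical mean intra/inter degrees and per-community inter-link
    counts (each inter edge counts toward both endpoint communities, so
    the per-community mean estimates Q)."""
    N = net.n_nodes
    intra = net.edge_kind == INTRA
    inter = ~intra
    n_comm = int(net.community.max()) + 1 if N else 0
    counts = np.zeros(n_comm, dtype=np.int64)
    if inter.any():
        cu = net.community[net.edge_u[inter]]
        cv = net.community[net.edge_v[inter]]
        counts = np.bincount(cu, minlength=n_comm) + np.bincount(cv, minlength=n_comm)
    return DegreeSummary(
        mean_intra_degree=2.0 * intra.sum() / N if N else 0.0,
        mean_inter_degree=2.0 * inter.sum() / N if N else 0.0,
        community_inter_counts=counts,
    )


# --------------------------------------------------------------------
# I/O: TSV node/edge tables + JSON sidecar, lossless round trip
# --------------------------------------------------------------------

def write_network(net: SpatialModularNetwork, prefix: str | Path) -> dict[str, str]:
    """Write nodes.tsv, edges.tsv and meta.json under the given prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nodes_path = prefix.with_suffix(".nodes.tsv")
    edges_path = prefix.with_suffix(".edges.tsv")
    meta_path = prefix.with_suffix(".meta.json")
    with open(nodes_path, "w") as fh:
        fh.write("id\tx\ty\tcommunity\n")
        for i in range(net.n_nodes):
            fh.write(f"{i}\t{net.coords[i, 0]}\t{net.coords[i, 1]}\t{net.community[i]}\n")
    with open(edges_path, "w") as fh:
        fh.write("u\tv\tkind\n")
        for u, v, k in zip(net.edge_u, net.edge_v, net.edge_kind):
            fh.write(f"{u}\t{v}\t{_KIND_NAME[int(k)]}\n")
    meta = {
        "params": net.params.as_dict() if net.params else None,
        "seed": net.seed,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"nodes": str(nodes_path), "edges": str(edges_path), "meta": str(meta_path)}


def read_network(prefix: str | Path) -> SpatialModularNetwork:
    """Read a network written by :func:`write_network`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    params = ModelParams(**meta["params"]) if meta["params"] else None
    nodes = np.loadtxt(prefix.with_suffix(".nodes.tsv"), skiprows=1, dtype=np.int64, ndmin=2)
    n_nodes = nodes.shape[0]
    coords = nodes[:, 1:3].astype(np.int32)
    community = nodes[:, 3].astype(np.int32)
    eu, ev, kinds = [], [], []
    with open(prefix.with_suffix(".edges.tsv")) as fh:
        next(fh)
        for line in fh:
            u, v, k = line.split()
            eu.append(int(u))
            ev.append(int(v))
            kinds.append(_KIND_CODE[k])
    return SpatialModularNetwork(
        params=params,
        seed=meta["seed"],
        coords=coords,
        community=community,
        edge_u=np.asarray(eu, dtype=np.int64),
        edge_v=np.asarray(ev, dtype=np.int64),
        edge_kind=np.asarray(kinds, dtype=np.uint8),
    )
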