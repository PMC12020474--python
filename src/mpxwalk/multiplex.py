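"""Multiplex assembly: supra-adjacency and column-stochastic transition matrix.

A multiplex network keeps ``L`` layers over a shared (union) node universe of
size ``n``.  Each node owns one *copy* per layer; copies of the same node in
different layers are linked by virtual interlayer edges.  Both structures are
encoded in an ``(n*L) x (n*L)`` supra-adjacency matrix whose diagonal blocks
are the per-layer adjacency matrices (over the union node ordering) and whose
off-diagonal blocks carry the virtual edges.

The walk operates on the column-stochastic transition matrix ``T``: from copy
``(i, l)`` a walker moves to an intra-layer neighbour ``j`` with probability
``(1 - delta) * w_ij / s_il`` (``s_il`` the weighted degree of ``i`` in layer
``l``) and jumps to a coupled copy ``(i, k)`` with probability ``delta / c``
(``c`` the number of coupled copies).  When a copy has no coupled copies all
mass stays intra-layer; when it has no intra-layer edges all mass crosses
layers; copies with neither are left as explicit zero (dangling) columns and
handled at walk time.

Copy ordering is layer-major: copy ``(node i, layer l)`` sits at flat index
``l * n + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import EmptyLayerError, MultiplexBuildError
from .io import Flist, NetworkLayer, read_layers

COUPLING_MODES = ("presence", "union")


@dataclass
class Multiplex:
    """Ordered layers plus the derived supra matrices.

    Attributes
    ----------
    layers
        The ordered :class:`~mpxwalk.io.NetworkLayer` objects (count ``L``).
    nodes
        Sorted union of all layer node sets (count ``n``).
    presence
        Boolean ``n x L`` table; ``presence[i, l]`` is True iff node ``i``
        appears in layer ``l``'s edge list.
    delta
        Global interlayer jump probability in ``[0, 1]``.
    coupling_mode
        ``"presence"`` couples a node's copies only between layers that
        contain the node; ``"union"`` couples all ``L`` copies of every node.
    supra
        Sparse ``(n*L) x (n*L)`` supra-adjacency matrix.
    transition
        Sparse column-stochastic transition matrix of the same shape.
    """

    layers: list[NetworkLayer]
    nodes: list[str]
    presence: np.ndarray
    delta: float
    coupling_mode: str = "presence"
    supra: sp.spmatrix | None = None
    transition: sp.spmatrix | None = None
    node_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def copy_index(self, gene: str, layer: int) -> int:
        """Flat supra index of the copy of ``gene`` in layer ``layer``."""
        return layer * self.n_nodes + self.node_index[gene]

    def layer_adjacency(self, layer: int) -> sp.csr_matrix:
        """Weighted adjacency of one layer over the union node ordering."""
        return _layer_adjacency(self.layers[layer], self.node_index, self.n_nodes)

    def equals(self, other: "Multiplex", tol: float = 1e-12) -> bool:
        """Structural equality: layers, node universe, delta and matrices."""
        if (
            self.layer_names != other.layer_names
            or self.nodes != other.nodes
            or self.delta != other.delta
            or self.coupling_mode != other.coupling_mode
        ):
            return False
        for lyr_a, lyr_b in zip(self.layers, other.layers):
            if lyr_a.canonical().edges != lyr_b.canonical().edges:
                return False
        for a, b in ((self.supra, other.supra), (self.transition, other.transition)):
            if a is None or b is None:
                if a is not b:
                    return False
                continue
            diff = (a - b).tocoo()
            if diff.nnz and np.abs(diff.data).max() > tol:
                return False
        return True


def _layer_adjacency(
    layer: NetworkLayer, node_index: dict[str, int], n: int
) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for u, v, w in layer.edges:
        iu, iv = node_index[u], node_index[v]
        rows.append(iu)
        cols.append(iv)
        vals.append(w)
        if not layer.directed:
            rows.append(iv)
            cols.append(iu)
            vals.append(w)
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    a.sum_duplicates()
    return a.tocsr()


def make_multiplex(
    flist: Flist,
    delta: float = 0.5,
    coupling_mode: str = "presence",
    n_workers: int = 1,
    duplicate_policy: str = "first",
) -> Multiplex:
    """Read the layers named by an flist manifest and assemble the multiplex.

    ``delta`` is the global probability of the walker switching layers at a
    step.  ``n_workers`` parallelizes the per-layer block construction; the
    result is identical for any worker count because blocks are assembled in
    manifest order.
    """
    layers = read_layers(flist, duplicate_policy)
    return make_multiplex_from_layers(layers, delta, coupling_mode, n_workers=n_workers)


def make_multiplex_from_layers(
    layers: list[NetworkLayer],
    delta: float = 0.5,
    coupling_mode: str = "presence",
    build_matrices: bool = True,
    n_workers: int = 1,
) -> Multiplex:
    """Assemble a :class:`Multiplex` from already-loaded layers."""
    if not layers:
        raise MultiplexBuildError("a multiplex needs at least one layer")
    if not 0.0 <= delta <= 1.0:
        raise MultiplexBuildError(f"delta must lie in [0, 1], got {delta}")
    if coupling_mode not in COUPLING_MODES:
        raise MultiplexBuildError(
            f"coupling_mode must be one of {COUPLING_MODES}, got {coupling_mode!r}"
        )
    for lyr in layers:
        if not lyr.nodes:
            raise EmptyLayerError(f"layer {lyr.name!r} has an empty node set")

    nodes = sorted(set().union(*(lyr.nodes for lyr in layers)))
    node_index = {g: i for i, g in enumerate(nodes)}
    n, L = len(nodes), len(layers)
    presence = np.zeros((n, L), dtype=bool)
    for l, lyr in enumerate(layers):
        for g in lyr.nodes:
            presence[node_index[g], l] = True

    mpx = Multiplex(layers, nodes, presence, delta, coupling_mode,
                    node_index=node_index)
    if build_matrices:
        mpx.supra = supra_adjacency(mpx, n_workers=n_workers)
        mpx.transition = transition_matrix(mpx, n_workers=n_workers)
    return mpx


def _coupling_counts(mpx: Multiplex) -> np.ndarray:
    """Number of coupled copies for each (node, layer) copy, shape ``n x L``.

    In "presence" mode a copy couples to the node's copies in the other
    layers that also contain the node — and only if this copy's own layer
    contains it (absent copies remain uncoupled).  In "union" mode every copy
    couples to all other ``L - 1`` copies.
    """
    n, L = mpx.n_nodes, mpx.n_layers
    if mpx.coupling_mode == "union":
        return np.full((n, L), L - 1, dtype=np.int64)
    layer_counts = mpx.presence.sum(axis=1)  # layers containing each node
    c = np.where(mpx.presence, layer_counts[:, None] - 1, 0)
    return c.astype(np.int64)


def supra_adjacency(mpx: Multiplex, n_workers: int = 1) -> sp.csr_matrix:
    """Build the supra-adjacency matrix.

    Diagonal block ``l`` is layer ``l``'s weighted adjacency over the union
    ordering.  Off-diagonal block ``(l, k)`` is the identity restricted to
    nodes present in both layers ("presence" mode) or the full identity
    ("union" mode).  Symmetric whenever all layers are undirected.
    """
    n, L = mpx.n_nodes, mpx.n_layers
    diag = _per_layer(mpx, _layer_adjacency_task, n_workers)
    blocks = [[None] * L for _ in range(L)]
    for l in range(L):
        blocks[l][l] = diag[l]
        for k in range(L):
            if k == l:
                continue
            if mpx.coupling_mode == "union":
                blocks[l][k] = sp.identity(n, format="csr")
            else:
                shared = (mpx.presence[:, l] & mpx.presence[:, k]).astype(float)
                blocks[l][k] = sp.diags(shared, format="csr")
    return sp.bmat(blocks, format="csr")


def _layer_adjacency_task(mpx: Multiplex, l: int) -> sp.csr_matrix:
    return _layer_adjacency(mpx.layers[l], mpx.node_index, mpx.n_nodes)


def _per_layer(mpx: Multiplex, task, n_workers: int):
    """Run a per-layer task, optionally across threads, in layer order."""
    if n_workers <= 1 or mpx.n_layers == 1:
        return [task(mpx, l) for l in range(mpx.n_layers)]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_workers, prefer="threads")(
        delayed(task)(mpx, l) for l in range(mpx.n_layers)
    )


def transition_matrix(mpx: Multiplex, n_workers: int = 1) -> sp.csc_matrix:
    """Build the column-stochastic transition matrix of the walk.

    Every column corresponding to a copy with intra-layer edges or coupled
    copies sums to exactly 1; fully dangling columns are left zero and are
    redirected to the seed distribution during the walk.
    """
    n, L = mpx.n_nodes, mpx.n_layers
    delta = mpx.delta
    c = _coupling_counts(mpx)  # n x L

    adj = _per_layer(mpx, _layer_adjacency_task, n_workers)
    # Column i of block l must distribute the copy's outgoing mass, so for
    # directed layers we orient entries as W[j, i] = w(i -> j).
    walk = [
        a.T.tocsr() if mpx.layers[l].directed else a for l, a in enumerate(adj)
    ]
    strengths = np.column_stack(
        [np.asarray(w.sum(axis=0)).ravel() for w in walk]
    )  # n x L out-strengths (weighted degree for undirected layers)

    blocks = [[None] * L for _ in range(L)]
    for l in range(L):
        s = strengths[:, l]
        has_intra = s > 0
        has_coupling = c[:, l] > 0
        # intra factor: (1-delta) when coupled, 1 when this copy is uncoupled
        intra_factor = np.where(has_coupling, 1.0 - delta, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            col_scale = np.where(has_intra, intra_factor / np.where(s > 0, s, 1.0), 0.0)
        blocks[l][l] = (walk[l] @ sp.diags(col_scale)).tocsr()
        # interlayer factor: delta when the copy has intra edges, else all mass
        inter_mass = np.where(has_intra, delta, 1.0)
        for k in range(L):
            if k == l:
                continue
            coupled = _coupled_pair(mpx, l, k)
            with np.errstate(divide="ignore", invalid="ignore"):
                entry = np.where(
                    coupled & has_coupling,
                    inter_mass / np.where(c[:, l] > 0, c[:, l], 1.0),
                    0.0,
                )
            # entry lives at row (i, k), column (i, l)
            blocks[k][l] = sp.diags(entry, format="csr")
    return sp.bmat(blocks, format="csc")


def _coupled_pair(mpx: Multiplex, l: int, k: int) -> np.ndarray:
    """Boolean vector: is copy (i, l) coupled to copy (i, k)?"""
    if mpx.coupling_mode == "union":
        return np.ones(mpx.n_nodes, dtype=bool)
    return mpx.presence[:, l] & mpx.presence[:, k]


def dangling_columns(mpx: Multiplex) -> np.ndarray:
    """Boolean mask over copies whose transition column is entirely zero."""
    colsums = np.asarray(mpx.transition.sum(axis=0)).ravel()
    return colsums == 0.0
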