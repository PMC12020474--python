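"""Network-context tools: LOE ranking, layer-annotated shortest paths,
layer aggregation, and rewired null multiplexes.

``run_loe`` ranks every multiplex gene by RWR proximity to a seed set and
can return the induced subnetwork around the top-ranked genes, with one edge
row per (gene pair, layer) so the individual lines of evidence stay visible.

``shortest_paths`` finds shortest source-to-target paths on the unweighted
union of all layers (hop metric) and reports each path edge once per layer
carrying it, together with the layer-normalized weight
``weight_norm = w / (total edge weight of that layer)``.

``rewire_multiplex`` builds the null model used to calibrate chance
performance: every layer is independently randomized while preserving its
node set and edge count (degree-preserving double-edge swaps by default, or
plain Erdős–Rényi resampling with the same counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSet, NetworkLayer
from .multiplex import Multiplex, make_multiplex_from_layers
from .rwr import RWRParams, RWRResult, make_seed_vector, random_walk_restart

PATH_COLUMNS = [
    "from", "to", "weight", "type", "weight_norm",
    "path_name", "path_length", "path_elements",
]


@dataclass
class Subnetwork:
    """Induced subnetwork around top-ranked genes.

    ``nodes`` has one row per gene (score, rank, seed / second-set flags);
    ``edges`` one row per (pair, layer) so multi-edges are preserved.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame


def run_loe(
    mpx: Multiplex,
    seeds1: GeneSet,
    seeds2: GeneSet | None = None,
    params: RWRParams | None = None,
    top_n: int | None = None,
) -> tuple[RWRResult, Subnetwork | None]:
    """Rank all genes by RWR from ``seeds1``; optionally extract context.

    A second gene set only flags its members in the ranked output (it does
    not alter the walk).  With ``top_n``, the subnetwork induced on
    ``seeds1`` plus the ``top_n`` best-ranked genes is returned with all
    layer edges among them.
    """
    if params is None:
        params = RWRParams()
    seed_vec = make_seed_vector(mpx, seeds1, params.tau)
    result = random_walk_restart(mpx, seed_vec, params)
    if top_n is None:
        return result, None

    ranked = ~np.isnan(result.ranks)
    n_ranked = int(ranked.sum())
    if top_n > n_ranked:
        warnings.warn(
            f"top_n={top_n} exceeds the {n_ranked} ranked genes; clamping",
            stacklevel=2,
        )
        top_n = n_ranked
    df = result.as_frame()
    top_genes = df.loc[~df["seed"], "gene"].head(top_n).tolist()
    keep = set(seed_vec.used_members) | set(top_genes)

    flag2 = set(seeds2.members) if seeds2 is not None else set()
    node_rows = df[df["gene"].isin(keep)].copy()
    node_rows["in_second_set"] = node_rows["gene"].isin(flag2)
    edge_rows = []
    for lyr in mpx.layers:
        for u, v, w in lyr.edges:
            if u in keep and v in keep:
                edge_rows.append(
                    {"source": u, "target": v, "layer": lyr.name, "weight": w}
                )
    edges = pd.DataFrame(edge_rows,
                         columns=["source", "target", "layer", "weight"])
    return result, Subnetwork(node_rows.reset_index(drop=True), edges)


def _union_graph(mpx: Multiplex) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(mpx.nodes)
    for lyr in mpx.layers:
        for u, v, _ in lyr.edges:
            g.add_edge(u, v)
    return g


def _lexicographic_shortest_path(g: nx.Graph, s: str, t: str) -> list[str] | None:
    """Lexicographically smallest among all shortest s-t paths (BFS layers)."""
    try:
        paths = nx.all_shortest_paths(g, s, t)
        return min(paths)
    except nx.NetworkXNoPath:
        return None


def shortest_paths(
    mpx: Multiplex,
    sources: GeneSet,
    targets: GeneSet,
    all_paths: bool = False,
) -> pd.DataFrame:
    """Layer-annotated shortest paths between two gene sets.

    Paths are computed on the unweighted union of all layers; every path edge
    is emitted once per layer containing it.  ``path_length`` counts nodes.
    By default one deterministic (lexicographically smallest) path per pair
    is reported; ``all_paths=True`` enumerates every shortest path.
    Unreachable pairs yield a single row with ``type="NO_PATH"``.
    """
    g = _union_graph(mpx)
    layer_totals = {lyr.name: lyr.total_weight() for lyr in mpx.layers}
    layer_edges: dict[str, dict[tuple[str, str], float]] = {
        lyr.name: {lyr.edge_key(u, v): w for u, v, w in lyr.edges}
        for lyr in mpx.layers
    }
    rows = []
    for s in sources.members:
        if s not in g:
            warnings.warn(f"source gene {s!r} absent from multiplex; skipped",
                          stacklevel=2)
            continue
        for t in targets.members:
            if t == s:
                continue
            if t not in g:
                warnings.warn(
                    f"target gene {t!r} absent from multiplex; skipped",
                    stacklevel=2,
                )
                continue
            if all_paths:
                try:
                    paths = sorted(nx.all_shortest_paths(g, s, t))
                except nx.NetworkXNoPath:
                    paths = []
            else:
                p = _lexicographic_shortest_path(g, s, t)
                paths = [p] if p is not None else []
            if not paths:
                rows.append(
                    {"from": s, "to": t, "weight": np.nan, "type": "NO_PATH",
                     "weight_norm": np.nan, "path_name": f"{s}_{t}",
                     "path_length": 0, "path_elements": ""}
                )
                continue
            for path in paths:
                elements = "->".join(path)
                for u, v in zip(path[:-1], path[1:]):
                    key = (u, v) if u <= v else (v, u)
                    for lyr in mpx.layers:
                        w = layer_edges[lyr.name].get(
                            key if not lyr.directed else (u, v)
                        )
                        if lyr.directed and w is None:
                            w = layer_edges[lyr.name].get((v, u))
                        if w is None:
                            continue
                        rows.append(
                            {
                                "from": u,
                                "to": v,
                                "weight": w,
                                "type": lyr.name,
                                "weight_norm": w / layer_totals[lyr.name],
                                "path_name": f"{s}_{t}",
                                "path_length": len(path),
                                "path_elements": elements,
                            }
                        )
    return pd.DataFrame(rows, columns=PATH_COLUMNS)


def merged_with_all_layers(mpx: Multiplex) -> pd.DataFrame:
    """Aggregate layers keeping multi-edges: one row per (pair, layer)."""
    rows = [
        {"source": u, "target": v, "weight": w, "layer": lyr.name}
        for lyr in mpx.layers
        for u, v, w in lyr.canonical().edges
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "layer"])


def merged_with_all_edgecounts(mpx: Multiplex) -> pd.DataFrame:
    """Aggregate layers into a weighted monoplex.

    Each gene pair appears once with weight equal to the summed weight of its
    edges across layers — for unweighted layers, the number of layers
    containing the pair.
    """
    multi = merged_with_all_layers(mpx)
    return (
        multi.groupby(["source", "target"], as_index=False)["weight"]
        .sum()
        .sort_values(["source", "target"], kind="stable")
        .reset_index(drop=True)
    )


def _rewire_layer_swap(
    layer: NetworkLayer, rng: np.random.Generator, nswap_factor: int
) -> NetworkLayer:
    g = nx.Graph()
    g.add_nodes_from(layer.nodes)
    g.add_edges_from((u, v) for u, v, _ in layer.edges)
    m = g.number_of_edges()
    if m < 2 or g.number_of_nodes() < 4:
        warnings.warn(
            f"layer {layer.name!r} too small to rewire; returned unchanged",
            stacklevel=3,
        )
        return layer
    nswap = nswap_factor * m
    try:
        nx.double_edge_swap(
            g, nswap=nswap, max_tries=100 * nswap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    except nx.NetworkXAlgorithmError:
        # ran out of tries; keep whatever swaps succeeded
        pass
    edges = [(u, v, 1.0) for u, v in g.edges()]
    return NetworkLayer(layer.name, edges, directed=False)


def _rewire_layer_er(
    layer: NetworkLayer, rng: np.random.Generator
) -> NetworkLayer:
    nodes = sorted(layer.nodes)
    m = layer.n_edges
    g = nx.gnm_random_graph(len(nodes), m,
                            seed=int(rng.integers(0, 2**31 - 1)))
    relabel = {i: nodes[i] for i in range(len(nodes))}
    edges = [(relabel[u], relabel[v], 1.0) for u, v in g.edges()]
    return NetworkLayer(layer.name, edges, directed=False)


def rewire_multiplex(
    mpx: Multiplex,
    rng_seed: int | None = None,
    method: str = "swap",
    nswap_factor: int = 10,
) -> Multiplex:
    """Randomize every layer, preserving per-layer node and edge counts.

    ``method="swap"`` (default) performs degree-preserving double-edge swaps
    — the degree sequence of each layer is kept, which implies the stated
    node/edge preservation.  ``method="er"`` resamples each layer as a
    uniform random graph with the same node set and edge count (the weaker,
    count-only null).  Rewired edges are unweighted.  Deterministic for a
    given ``rng_seed``.
    """
    if method not in ("swap", "er"):
        raise ValueError(f"method must be 'swap' or 'er', got {method!r}")
    rng = np.random.default_rng(rng_seed)
    new_layers = []
    for lyr in mpx.layers:
        if method == "swap":
            new_layers.append(_rewire_layer_swap(lyr, rng, nswap_factor))
        else:
            new_layers.append(_rewire_layer_er(lyr, rng))
    return make_multiplex_from_layers(
        new_layers, delta=mpx.delta, coupling_mode=mpx.coupling_mode
    )
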