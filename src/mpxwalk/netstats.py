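"""Layer and multiplex statistics: basic stats, edge-set similarity, tau.

Edge-set similarity metrics treat every layer as an unweighted, undirected
set of endpoint pairs: ``jaccard = |A & B| / |A | B|`` and
``overlap = |A & B| / min(|A|, |B|)``.  Both are symmetric, lie in [0, 1],
and jaccard equals 1 exactly when the two edge sets coincide.

``calculate_tau`` turns per-layer similarity to a gold-standard reference
network into seed-layer weights proportional to that similarity, rescaled to
sum to the layer count ``L`` (the constraint the walk expects).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyLayerError
from .io import NetworkLayer
from .multiplex import Multiplex

METRICS = ("jaccard", "overlap")


def _undirected_edge_set(layer: NetworkLayer) -> set[tuple[str, str]]:
    """Edge identity for similarity: unordered endpoint pair, weight ignored."""
    return {(u, v) if u <= v else (v, u) for u, v, _ in layer.edges}


def basic_statistics(layer: NetworkLayer) -> tuple[int, int, int]:
    """Node count, edge count, and diameter of one layer.

    The diameter is the longest finite shortest-path length, i.e. the maximum
    over connected components; pairs in different components are ignored so
    disconnected layers still yield a finite value.
    """
    if not layer.edges:
        raise EmptyLayerError(f"layer {layer.name!r} is empty")
    g = layer.to_graph().to_undirected()
    diameter = max(
        nx.diameter(g.subgraph(comp)) for comp in nx.connected_components(g)
    )
    return g.number_of_nodes(), g.number_of_edges(), diameter


def basic_statistics_table(layers: list[NetworkLayer]) -> pd.DataFrame:
    """Per-layer stats table with columns name/nodes/edges/diameter."""
    rows = []
    for lyr in layers:
        n, m, d = basic_statistics(lyr)
        rows.append({"name": lyr.name, "nodes": n, "edges": m, "diameter": d})
    return pd.DataFrame(rows)


def _similarity(a: set, b: set, metric: str) -> float:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    return inter / min(len(a), len(b))


def net_to_net_similarity(
    a: NetworkLayer, b: NetworkLayer, metric: str = "jaccard"
) -> float:
    """Edge-set similarity between two networks."""
    return _similarity(_undirected_edge_set(a), _undirected_edge_set(b), metric)


def pairwise_layer_similarity(
    mpx: Multiplex, metric: str = "jaccard"
) -> pd.DataFrame:
    """L x L edge-set similarity matrix between all multiplex layers."""
    sets = [_undirected_edge_set(lyr) for lyr in mpx.layers]
    names = mpx.layer_names
    L = len(sets)
    out = np.ones((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            out[i, j] = out[j, i] = _similarity(sets[i], sets[j], metric)
    return pd.DataFrame(out, index=names, columns=names)


def multiplex_layers_to_refnet(
    mpx: Multiplex, ref: NetworkLayer, metric: str = "jaccard"
) -> pd.Series:
    """Similarity of each layer to a reference (gold-standard) network."""
    ref_set = _undirected_edge_set(ref)
    vals = [
        _similarity(_undirected_edge_set(lyr), ref_set, metric)
        for lyr in mpx.layers
    ]
    return pd.Series(vals, index=mpx.layer_names, name=f"{metric}_to_ref")


def calculate_tau(
    mpx: Multiplex, ref: NetworkLayer, metric: str = "jaccard"
) -> np.ndarray:
    """Seed-layer weights proportional to each layer's overlap with ``ref``.

    ``tau_l = L * s_l / sum_k s_k`` where ``s_l`` is the layer's edge-set
    similarity to the reference.  When every layer has zero similarity the
    uniform vector is returned with a warning.
    """
    if not ref.edges:
        raise EmptyLayerError("reference network is empty")
    sims = multiplex_layers_to_refnet(mpx, ref, metric).to_numpy()
    total = sims.sum()
    if total == 0:
        warnings.warn(
            "all layers have zero similarity to the reference; "
            "returning uniform tau",
            stacklevel=2,
        )
        return np.ones(mpx.n_layers)
    return mpx.n_layers * sims / total
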