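"""Deterministic generators for synthetic test inputs.

Three families:

* Erdős–Rényi multiplexes — ``L`` independent random layers over a shared
  node universe, by edge count (G(n, m)) or edge probability (G(n, p)).
* Two small didactic multiplexes: a three-layer toy whose union holds four
  nodes with one node missing from the last layer (exercises the
  presence-based interlayer coupling), and a two-layer toy (layer 1 a
  two-node path A-B, layer 2 a clique on A, B, C, D) used to demonstrate
  per-layer tau seed weighting.
* Planted-module multiplexes — dense gene modules (edge probability
  ``p_in`` inside a module, ``p_out`` elsewhere, independently per layer)
  emulating functionally cohesive gene sets; the matching
  :class:`~mpxwalk.io.GeneSet` objects are emitted alongside.

All generators are seeded and reproducible: the same arguments and seed give
byte-identical layer files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .errors import EmptyLayerError
from .io import Flist, FlistRow, GeneSet, NetworkLayer, write_edge_list, write_gene_set
from .multiplex import Multiplex, make_multiplex_from_layers


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def er_layers(
    n: int,
    L: int,
    m: int | None = None,
    p: float | None = None,
    rng_seed: int | None = None,
) -> list[NetworkLayer]:
    """``L`` independent Erdős–Rényi layers over a shared node universe.

    Give either an edge count ``m`` (G(n, m)) or an edge probability ``p``
    (G(n, p)).  Layers that come out empty raise, since empty layers are not
    allowed in a multiplex.
    """
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 nodes and L >= 1 layers")
    if (m is None) == (p is None):
        raise ValueError("give exactly one of m (edge count) or p (probability)")
    if m is not None and m > n * (n - 1) // 2:
        raise ValueError(f"m={m} exceeds the {n * (n - 1) // 2} possible edges")
    rng = np.random.default_rng(rng_seed)
    names = _gene_names(n)
    layers = []
    for l in range(L):
        seed = int(rng.integers(0, 2**31 - 1))
        if m is not None:
            g = nx.gnm_random_graph(n, m, seed=seed)
        else:
            g = nx.fast_gnp_random_graph(n, p, seed=seed)
        if g.number_of_edges() == 0:
            raise EmptyLayerError(
                f"ER layer {l} came out empty (n={n}, m={m}, p={p})"
            )
        edges = sorted(
            (names[min(u, v)], names[max(u, v)], 1.0) for u, v in g.edges()
        )
        layers.append(NetworkLayer(f"er{l:02d}", edges))
    return layers


def write_flist(layers: list[NetworkLayer], outdir: str | Path) -> Path:
    """Write each layer as a TSV edge list plus the flist manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flist_path = outdir / "layers.flist"
    with open(flist_path, "w", encoding="utf-8") as fh:
        for lyr in layers:
            layer_path = outdir / f"{lyr.name}.tsv"
            write_edge_list(lyr, layer_path)
            fh.write(f"{layer_path.name}\t{lyr.name}\n")
    return flist_path


def er_multiplex(
    n: int,
    L: int,
    m: int | None = None,
    p: float | None = None,
    rng_seed: int | None = None,
    outdir: str | Path | None = None,
    delta: float = 0.5,
) -> tuple[Multiplex, Path | None]:
    """Build an ER multiplex; optionally write layer files and the flist."""
    layers = er_layers(n, L, m, p, rng_seed)
    flist_path = write_flist(layers, outdir) if outdir is not None else None
    return make_multiplex_from_layers(layers, delta=delta), flist_path


def three_layer_toy(delta: float = 0.5, coupling_mode: str = "presence") -> Multiplex:
    """Three small layers over union {a, b, c, d}; layer 3 lacks node b.

    Because node b is absent from the last layer, presence-mode coupling
    gives its copy there no interlayer virtual edges.
    """
    layers = [
        NetworkLayer("L1", [("a", "b", 1.0), ("c", "d", 1.0)]),
        NetworkLayer("L2", [("a", "b", 1.0), ("b", "c", 1.0)]),
        NetworkLayer("L3", [("a", "c", 1.0), ("c", "d", 1.0)]),
    ]
    return make_multiplex_from_layers(layers, delta=delta,
                                      coupling_mode=coupling_mode)


def tau_toy(delta: float = 0.5) -> Multiplex:
    """Two-layer tau demonstration multiplex.

    Layer 1 is the two-node path A-B; layer 2 is the 4-clique on
    {A, B, C, D}.  Nodes C and D exist only in layer 2, so down-weighting
    that layer's seed mass (tau) must lower their walk scores.
    """
    path = NetworkLayer("path", [("A", "B", 1.0)])
    clique_edges = [
        ("A", "B", 1.0), ("A", "C", 1.0), ("A", "D", 1.0),
        ("B", "C", 1.0), ("B", "D", 1.0), ("C", "D", 1.0),
    ]
    clique = NetworkLayer("clique", clique_edges)
    return make_multiplex_from_layers([path, clique], delta=delta)


def planted_module_multiplex(
    n: int,
    L: int,
    n_modules: int,
    module_size: int,
    p_in: float,
    p_out: float,
    rng_seed: int | None = None,
    delta: float = 0.5,
) -> tuple[Multiplex, list[GeneSet]]:
    """Multiplex with dense planted modules plus the matching gene sets.

    The first ``n_modules * module_size`` genes are split into consecutive
    modules.  In every layer, within-module pairs connect with probability
    ``p_in`` and all other pairs with ``p_out`` (``p_in > p_out`` required).
    """
    if p_in <= p_out:
        raise ValueError("planted modules need p_in > p_out")
    if n_modules * module_size > n:
        raise ValueError("modules exceed the node universe")
    rng = np.random.default_rng(rng_seed)
    names = np.array(_gene_names(n), dtype=object)
    module_of = np.full(n, -1)
    for k in range(n_modules):
        module_of[k * module_size:(k + 1) * module_size] = k

    iu, ju = np.triu_indices(n, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    p_edge = np.where(same, p_in, p_out)
    layers = []
    for l in range(L):
        mask = rng.random(iu.size) < p_edge
        edges = [
            (names[i], names[j], 1.0) for i, j in zip(iu[mask], ju[mask])
        ]
        if not edges:
            raise EmptyLayerError(f"planted layer {l} came out empty")
        layers.append(NetworkLayer(f"pl{l:02d}", edges))
    genesets = [
        GeneSet(f"module{k:02d}",
                list(names[k * module_size:(k + 1) * module_size]))
        for k in range(n_modules)
    ]
    return make_multiplex_from_layers(layers, delta=delta), genesets


def write_fixture(
    kind: str, outdir: str | Path, rng_seed: int | None = None, **kwargs
) -> Path:
    """CLI-facing generator: write layer files, an flist and any gene sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "er":
        layers = er_layers(
            kwargs.get("n", 50), kwargs.get("L", 3),
            kwargs.get("m"), kwargs.get("p", 0.1 if kwargs.get("m") is None else None),
            rng_seed,
        )
        return write_flist(layers, outdir)
    if kind == "toy3":
        return write_flist(three_layer_toy().layers, outdir)
    if kind == "tau":
        return write_flist(tau_toy().layers, outdir)
    if kind == "planted":
        mpx, genesets = planted_module_multiplex(
            kwargs.get("n", 500), kwargs.get("L", 3),
            kwargs.get("n_modules", 10), kwargs.get("module_size", 20),
            kwargs.get("p_in", 0.3), kwargs.get("p_out", 0.01),
            rng_seed,
        )
        flist_path = write_flist(mpx.layers, outdir)
        write_gene_set(genesets, outdir / "modules.genesets.tsv")
        return flist_path
    raise ValueError(f"unknown fixture kind {kind!r}")
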