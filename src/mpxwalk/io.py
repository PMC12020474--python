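"""Readers and writers for the file formats the toolkit touches.

Input formats
-------------
flist manifest
    Delimited text, one row per layer: ``path<TAB>name[<TAB>group[<TAB>directed]]``.
    Row order defines the block order of the supra-adjacency matrix.
edge list
    Delimited text with two or three columns: source gene, target gene and an
    optional positive weight (default 1).  Delimiter is auto-detected among
    tab, comma and space.  Gene identifiers are opaque case-sensitive strings;
    no species assumption is made.
gene set
    Delimited text with rows ``setid  gene  [weight]``; one :class:`GeneSet`
    per distinct set id, member order following file order.

Multiplex archives are portable zip files holding canonical per-layer edge
lists plus JSON metadata (delta, coupling mode, layer order, node universe)
and, optionally, the cached sparse matrices; matrices are recomputed on load
when absent.
"""

from __future__ import annotations

import io as _io
import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import (
    ArchiveError,
    ArchiveVersionError,
    DuplicateLayerNameError,
    EdgeListError,
    EmptyLayerError,
    FlistError,
    GeneSetError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .multiplex import Multiplex

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1

_TRUE_STRINGS = {"1", "true", "t", "yes", "y", "directed"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlistRow:
    """One manifest row: a layer file path, its label and optional tags."""

    path: str
    name: str
    group: int | None = None
    directed: bool = False


@dataclass(frozen=True)
class Flist:
    """Ordered manifest of network layers.

    Layer names must be unique and non-empty; row order is preserved because
    it defines the block order in the supra-adjacency matrix.
    """

    rows: tuple[FlistRow, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if any(not n for n in names):
            raise FlistError("flist contains an empty layer name")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateLayerNameError(
                f"duplicate layer name(s) in flist: {sorted(dupes)}"
            )
        if any(not r.path for r in self.rows):
            raise FlistError("flist contains an empty path field")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rows]


@dataclass
class NetworkLayer:
    """One named edge list over gene identifiers (one line of evidence).

    Edges are stored as ``(source, target, weight)`` triples.  For undirected
    layers the canonical key of an edge is the sorted endpoint pair; duplicate
    keys are collapsed at load time.  All weights are positive.
    """

    name: str
    edges: list[tuple[str, str, float]]
    directed: bool = False

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for u, v, _ in self.edges:
            out.add(u)
            out.add(v)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_key(self, u: str, v: str) -> tuple[str, str]:
        """Canonical dictionary key for the edge ``u -- v``."""
        if self.directed:
            return (u, v)
        return (u, v) if u <= v else (v, u)

    def edge_keys(self) -> set[tuple[str, str]]:
        return {self.edge_key(u, v) for u, v, _ in self.edges}

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def canonical(self) -> "NetworkLayer":
        """Return a copy with canonically ordered endpoints and sorted edges."""
        edges = sorted((*self.edge_key(u, v), float(w)) for u, v, w in self.edges)
        return NetworkLayer(self.name, edges, self.directed)

    def to_graph(self):
        """Materialize as a :mod:`networkx` graph (weights on edges)."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class GeneSet:
    """A labelled gene set, optionally with positive per-gene weights."""

    setid: str
    members: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise GeneSetError(f"gene set {self.setid!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise GeneSetError(f"gene set {self.setid!r} has duplicate members")
        if self.weights is None:
            self.weights = [1.0] * len(self.members)
        if len(self.weights) != len(self.members):
            raise GeneSetError(
                f"gene set {self.setid!r}: weights and members differ in length"
            )
        if any(w < 0 for w in self.weights):
            raise GeneSetError(f"gene set {self.setid!r} has a negative weight")

    def __len__(self) -> int:
        return len(self.members)

    def weight_of(self, gene: str) -> float:
        return self.weights[self.members.index(gene)]


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _split_row(line: str) -> list[str]:
    """Split one data row on tab, comma or whitespace (auto-detected)."""
    line = line.rstrip("\n").rstrip("\r")
    if "\t" in line:
        return [f.strip() for f in line.split("\t") if f.strip()]
    if "," in line:
        return [f.strip() for f in line.split(",") if f.strip()]
    return line.split()


def _data_lines(path: Path) -> list[list[str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(_split_row(line))
    return rows


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_flist(path: str | Path) -> Flist:
    """Read a layer manifest.

    Each row lists the path to one layer's edge-list file and a short layer
    label, with optional integer group and directed-flag columns.  Paths are
    resolved relative to the flist file's own directory when not absolute.
    """
    path = Path(path)
    if not path.is_file():
        raise FlistError(f"flist not found: {path}")
    rows = []
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise FlistError(f"flist row has fewer than 2 columns: {fields}")
        layer_path = Path(fields[0])
        if not layer_path.is_absolute():
            layer_path = path.parent / layer_path
        group = int(fields[2]) if len(fields) > 2 and fields[2] else None
        directed = (
            fields[3].strip().lower() in _TRUE_STRINGS if len(fields) > 3 else False
        )
        rows.append(FlistRow(str(layer_path), fields[1], group, directed))
    if not rows:
        raise FlistError(f"flist is empty: {path}")
    return Flist(tuple(rows))


def read_edge_list(
    path: str | Path,
    name: str,
    directed: bool = False,
    duplicate_policy: str = "first",
) -> NetworkLayer:
    """Read one delimited edge list into a :class:`NetworkLayer`.

    A missing weight column means unit weights.  Self-loops are dropped (with
    a logged count); duplicate edge keys are collapsed keeping the first
    weight (``duplicate_policy="first"``, the default, with a warning) or
    summing weights (``"sum"``).
    """
    path = Path(path)
    if not path.is_file():
        raise EdgeListError(f"edge list not found: {path}")
    rows = _data_lines(path)
    if not rows:
        raise EmptyLayerError(f"edge list is empty: {path}")
    if duplicate_policy not in ("first", "sum"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    seen: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    self_loops = 0
    duplicates = 0
    for fields in rows:
        if len(fields) < 2 or len(fields) > 3:
            raise EdgeListError(
                f"{path}: expected 2 or 3 columns, got {len(fields)}: {fields}"
            )
        u, v = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise EdgeListError(
                    f"{path}: non-numeric weight {fields[2]!r}"
                ) from exc
        else:
            w = 1.0
        if w <= 0:
            raise EdgeListError(f"{path}: non-positive weight {w} on edge {u}--{v}")
        if u == v:
            self_loops += 1
            continue
        key = (u, v) if directed or u <= v else (v, u)
        if key in seen:
            duplicates += 1
            if duplicate_policy == "sum":
                seen[key] += w
            continue
        seen[key] = w
        order.append(key)

    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    if duplicates:
        warnings.warn(
            f"{path}: collapsed {duplicates} duplicate edge(s) "
            f"(policy={duplicate_policy})",
            stacklevel=2,
        )
    if not order:
        raise EmptyLayerError(f"{path}: no edges survive cleaning")
    edges = [(u, v, seen[(u, v)]) for u, v in order]
    return NetworkLayer(name, edges, directed)


def read_layers(flist: Flist, duplicate_policy: str = "first") -> list[NetworkLayer]:
    """Read every layer listed in a manifest, in manifest order."""
    return [
        read_edge_list(r.path, r.name, r.directed, duplicate_policy)
        for r in flist.rows
    ]


def write_edge_list(layer: NetworkLayer, path: str | Path) -> None:
    """Write a layer as a canonical 3-column TSV edge list (no header)."""
    canon = layer.canonical()
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in canon.edges:
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_gene_set(path: str | Path) -> list[GeneSet]:
    """Read gene sets from delimited rows ``setid  gene  [weight]``.

    Returns one :class:`GeneSet` per distinct set id, in order of first
    appearance; member order follows file order.  Duplicate members within a
    set are dropped with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise GeneSetError(f"gene-set file not found: {path}")
    rows = _data_lines(path)
    if not rows:
        raise GeneSetError(f"gene-set file is empty: {path}")
    members: dict[str, list[str]] = {}
    weights: dict[str, list[float]] = {}
    dup = 0
    for fields in rows:
        if len(fields) < 2:
            raise GeneSetError(f"{path}: gene-set row needs >=2 columns: {fields}")
        setid, gene = fields[0], fields[1]
        w = 1.0
        if len(fields) > 2:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise GeneSetError(f"{path}: non-numeric weight {fields[2]!r}") from exc
        if w < 0:
            raise GeneSetError(f"{path}: negative weight {w} for gene {gene}")
        if gene in members.setdefault(setid, []):
            dup += 1
            continue
        members[setid].append(gene)
        weights.setdefault(setid, []).append(w)
    if dup:
        warnings.warn(f"{path}: dropped {dup} duplicate gene-set member(s)",
                      stacklevel=2)
    return [GeneSet(sid, members[sid], weights[sid]) for sid in members]


def write_gene_set(genesets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as TSV rows ``setid  gene  weight`` (no header)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in genesets:
            for gene, w in zip(gs.members, gs.weights):
                fh.write(f"{gs.setid}\t{gene}\t{w:.17g}\n")


# ---------------------------------------------------------------------------
# Multiplex archive
# ---------------------------------------------------------------------------

def save_multiplex(
    mpx: "Multiplex", path: str | Path, cache_matrices: bool = True
) -> None:
    """Serialize a multiplex to a portable zip archive.

    The archive holds canonical per-layer edge lists and JSON metadata; with
    ``cache_matrices=True`` the sparse supra-adjacency and transition matrices
    are included and reused on load, otherwise they are recomputed.
    """
    path = Path(path)
    meta = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "delta": mpx.delta,
        "coupling_mode": mpx.coupling_mode,
        "layer_names": [lyr.name for lyr in mpx.layers],
        "layer_directed": [lyr.directed for lyr in mpx.layers],
        "nodes": list(mpx.nodes),
    }
    def _entry(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical inputs give byte-identical archives
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(_entry("meta.json"), json.dumps(meta, indent=1))
        for i, lyr in enumerate(mpx.layers):
            buf = _io.StringIO()
            for u, v, w in lyr.canonical().edges:
                buf.write(f"{u}\t{v}\t{w:.17g}\n")
            zf.writestr(_entry(f"layers/{i:03d}.tsv"), buf.getvalue())
        if cache_matrices:
            for attr in ("supra", "transition"):
                buf_b = _io.BytesIO()
                sp.save_npz(buf_b, getattr(mpx, attr).tocsr())
                zf.writestr(_entry(f"matrices/{attr}.npz"), buf_b.getvalue())


def load_multiplex(path: str | Path) -> "Multiplex":
    """Load a multiplex archive written by :func:`save_multiplex`."""
    from .multiplex import make_multiplex_from_layers

    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
        names = set(zf.namelist())
        meta = json.loads(zf.read("meta.json"))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as exc:
        raise ArchiveError(f"corrupt or unreadable multiplex archive: {path}") from exc
    version = meta.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ArchiveVersionError(
            f"{path}: archive format version {version!r}, "
            f"expected {ARCHIVE_FORMAT_VERSION}"
        )
    layers = []
    for i, (name, directed) in enumerate(
        zip(meta["layer_names"], meta["layer_directed"])
    ):
        member = f"layers/{i:03d}.tsv"
        if member not in names:
            raise ArchiveError(f"{path}: missing layer table {member}")
        edges = []
        for line in zf.read(member).decode("utf-8").splitlines():
            u, v, w = line.split("\t")
            edges.append((u, v, float(w)))
        layers.append(NetworkLayer(name, edges, directed))
    mpx = make_multiplex_from_layers(
        layers,
        delta=meta["delta"],
        coupling_mode=meta["coupling_mode"],
        build_matrices="matrices/supra.npz" not in names,
    )
    if "matrices/supra.npz" in names:
        mpx.supra = sp.load_npz(_io.BytesIO(zf.read("matrices/supra.npz"))).tocsr()
        mpx.transition = sp.load_npz(
            _io.BytesIO(zf.read("matrices/transition.npz"))
        ).tocsc()
    if list(mpx.nodes) != meta["nodes"]:
        raise ArchiveError(f"{path}: node universe mismatch between layers and meta")
    return mpx


def write_table(df, path: str | Path) -> None:
    """Write a tabular output as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)
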