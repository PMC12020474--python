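"""Random walk with restart on a multiplex, with per-layer tau seed weighting.

The walker starts from a seed distribution ``p0`` over (node, layer) copies
and iterates ``p <- (1 - r) * T @ p + r * p0`` until the L1 change falls
below tolerance.  ``r`` is the restart probability; ``T`` the
column-stochastic supra transition matrix.  Mass arriving at dangling copies
(zero columns of ``T``) is redirected to ``p0`` each step so that total
probability is conserved exactly.

The per-layer ``tau`` vector biases the *seed* mass toward chosen layers:
the raw mass placed on seed ``g``'s copy in layer ``l`` is
``gene_weight(g) * tau_l`` if the layer contains ``g`` and zero otherwise,
then the whole vector is normalized to sum 1.  This is the per-layer
semantics (each layer's seeds scale with that layer's tau), not a per-seed
reweighting shared across layers.  ``tau`` is constrained to sum to ``L``
and is rescaled (with a warning) when it does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoSeedsError
from .io import GeneSet
from .multiplex import Multiplex, dangling_columns


@dataclass
class RWRParams:
    """Walk parameters.

    restart
        Probability ``r`` in ``(0, 1]`` of teleporting back to the seed
        distribution at each step (default 0.7).
    tau
        Per-layer seed weights; ``None`` means uniform.  Rescaled to sum to
        the layer count ``L``.
    tol
        Convergence threshold on the L1 change between iterations.
    max_iter
        Iteration cap; exceeding it returns ``converged=False`` with a
        warning rather than raising.
    """

    restart: float = 0.7
    tau: np.ndarray | None = None
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart <= 1.0:
            raise ValueError(f"restart must lie in (0, 1], got {self.restart}")
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)
            if np.any(self.tau < 0):
                raise ValueError("tau weights must be non-negative")


def normalize_tau(tau: np.ndarray | None, n_layers: int) -> np.ndarray:
    """Return tau rescaled to sum to the layer count (warning if rescaled)."""
    if tau is None:
        return np.ones(n_layers)
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (n_layers,):
        raise ValueError(f"tau must have length {n_layers}, got {tau.shape}")
    total = tau.sum()
    if total <= 0:
        raise ValueError("tau must have positive sum")
    if not np.isclose(total, n_layers, rtol=0, atol=1e-12):
        warnings.warn(
            f"tau sums to {total:g}, rescaling to sum to L={n_layers}",
            stacklevel=2,
        )
        tau = tau * (n_layers / total)
    return tau


@dataclass
class SeedVector:
    """Tau-weighted initial probability over (node, layer) copies."""

    seeds: GeneSet
    p0: np.ndarray
    used_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.p0.sum() - 1.0) > 1e-9:
            raise ValueError("seed vector must sum to 1")


@dataclass
class RWRResult:
    """Per-gene aggregated scores and competition ranks of non-seed genes."""

    genes: list[str]
    scores: np.ndarray
    ranks: np.ndarray  # NaN for seed genes, competition ("min") rank otherwise
    seed_flags: np.ndarray
    stationary: np.ndarray
    iterations: int
    converged: bool
    geneset_id: str = ""

    def as_frame(self) -> pd.DataFrame:
        """Ranked-table view sorted by descending score (seeds last)."""
        df = pd.DataFrame(
            {
                "gene": self.genes,
                "score": self.scores,
                "rank": self.ranks,
                "seed": self.seed_flags,
                "geneset_id": self.geneset_id,
            }
        )
        return df.sort_values(
            ["seed", "score", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)


def make_seed_vector(
    mpx: Multiplex, seeds: GeneSet, tau: np.ndarray | None = None
) -> SeedVector:
    """Build the tau-weighted seed distribution.

    Seeds absent from every layer are dropped with a warning listing them; if
    no seed carries positive mass a :class:`~mpxwalk.errors.NoSeedsError` is
    raised.
    """
    n, L = mpx.n_nodes, mpx.n_layers
    tau = normalize_tau(tau, L)
    p0 = np.zeros(n * L)
    missing = []
    for gene, gw in zip(seeds.members, seeds.weights):
        idx = mpx.node_index.get(gene)
        if idx is None:
            missing.append(gene)
            continue
        for l in range(L):
            if mpx.presence[idx, l]:
                p0[l * n + idx] = gw * tau[l]
    if missing:
        warnings.warn(
            f"seed gene(s) not in any layer, ignored: {missing}", stacklevel=2
        )
    total = p0.sum()
    if total <= 0:
        raise NoSeedsError(
            f"no seed of gene set {seeds.setid!r} carries positive mass "
            "(all absent from the multiplex or zeroed by tau/weights)"
        )
    used = [g for g in seeds.members if g not in missing]
    return SeedVector(seeds, p0 / total, used)


def aggregate_scores(stationary: np.ndarray, mpx: Multiplex) -> np.ndarray:
    """Collapse a copy-level probability vector to one score per gene."""
    return stationary.reshape(mpx.n_layers, mpx.n_nodes).sum(axis=0)


def _competition_ranks(
    scores: np.ndarray, seed_mask: np.ndarray
) -> np.ndarray:
    """Competition ("min") ranks of non-seed genes by descending score."""
    ranks = np.full(scores.shape, np.nan)
    free = ~seed_mask
    s = scores[free]
    if s.size:
        ranks[free] = pd.Series(s).rank(method="min", ascending=False).to_numpy()
    return ranks


def random_walk_restart(
    mpx: Multiplex, seed_vec: SeedVector, params: RWRParams | None = None
) -> RWRResult:
    """Iterate the walk to its stationary distribution and rank genes.

    Returns per-gene scores (copy probabilities summed over layers), with
    competition ranks over non-seed genes; seed genes are flagged and left
    unranked.  Probability mass is conserved at every iteration.
    """
    if params is None:
        params = RWRParams()
    T = mpx.transition
    if T is None:
        raise ValueError("multiplex has no transition matrix")
    r = params.restart
    p0 = seed_vec.p0
    dangling = dangling_columns(mpx)
    any_dangling = bool(dangling.any())

    p = p0.copy()
    iterations = 0
    converged = True
    if r < 1.0:
        converged = False
        for iterations in range(1, params.max_iter + 1):
            q = T @ p
            if any_dangling:
                q = q + p[dangling].sum() * p0
            p_new = (1.0 - r) * q + r * p0
            change = np.abs(p_new - p).sum()
            p = p_new
            if change < params.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"RWR did not converge in {params.max_iter} iterations "
                f"(last L1 change {change:.3g})",
                stacklevel=2,
            )

    scores = aggregate_scores(p, mpx)
    seed_mask = np.zeros(mpx.n_nodes, dtype=bool)
    for g in seed_vec.used_members:
        seed_mask[mpx.node_index[g]] = True
    ranks = _competition_ranks(scores, seed_mask)
    return RWRResult(
        genes=list(mpx.nodes),
        scores=scores,
        ranks=ranks,
        seed_flags=seed_mask,
        stationary=p,
        iterations=iterations,
        converged=converged,
        geneset_id=seed_vec.seeds.setid,
    )
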