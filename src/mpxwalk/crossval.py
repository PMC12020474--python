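"""Cross-validation of gene sets on a multiplex by held-out RWR ranking.

A gold-standard gene set is split into folds; each fold's training genes
become the walk's seeds and the held-out genes are scored by where they land
in the ranked list of non-seed genes.  If the network encodes the set's
functional cohesion, held-out genes rank near the top; on a randomly rewired
network ranking is uninformative and AUROC concentrates near 0.5.

Fold schemes
------------
kfold
    Seeded random partition into ``K`` near-equal folds; every gene is held
    out exactly once and trains in the other ``K - 1`` folds.
loo
    ``N`` folds, one gene held out per fold.
singletons
    ``N`` folds, a single training seed per fold; the other ``N - 1`` genes
    are the held-out positives.

Metrics per fold treat held-out genes as positives and all other ranked
(non-seed) genes as negatives: AUROC via the rank-sum (Mann-Whitney)
identity with midrank tie correction, AUPRC by stepwise precision-recall
summation, and precision/recall at cutoffs ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import FoldError, MetricError, NoSeedsError
from .io import GeneSet
from .multiplex import Multiplex
from .rwr import RWRParams, make_seed_vector, random_walk_restart

FOLD_METHODS = ("kfold", "loo", "singletons")
DEFAULT_K_GRID = (10, 50, 100)


@dataclass
class FoldPlan:
    """A resolved fold scheme: (train seeds, held-out genes) per fold."""

    method: str
    K: int
    folds: list[tuple[list[str], list[str]]]
    rng_seed: int | None = None


@dataclass
class CVReport:
    """All cross-validation outputs for one gene set.

    fullranks
        One row per (fold, ranked gene): score, rank, held-out flag.
    meanranks
        Per-gene mean rank over the folds where the gene was ranked, plus its
        competition re-rank among all ranked genes.
    metrics
        Per-fold AUROC, AUPRC and precision/recall at each cutoff.
    summary
        Mean and SD of each metric across folds.
    """

    geneset_id: str
    method: str
    K: int
    fullranks: pd.DataFrame
    meanranks: pd.DataFrame
    metrics: pd.DataFrame
    summary: pd.DataFrame


def make_folds(
    geneset: GeneSet,
    method: str = "kfold",
    K: int | None = None,
    rng_seed: int | None = None,
) -> FoldPlan:
    """Partition a gene set into cross-validation folds."""
    if method not in FOLD_METHODS:
        raise FoldError(f"method must be one of {FOLD_METHODS}, got {method!r}")
    genes = list(geneset.members)
    N = len(genes)
    if N < 2:
        raise FoldError(f"gene set {geneset.setid!r} has fewer than 2 members")
    if method == "kfold":
        if K is None or not 2 <= K <= N:
            raise FoldError(f"kfold requires 2 <= K <= N={N}, got K={K}")
        rng = np.random.default_rng(rng_seed)
        shuffled = list(np.array(genes, dtype=object)[rng.permutation(N)])
        parts = [list(p) for p in np.array_split(shuffled, K)]
        folds = [
            (sorted(set(genes) - set(part)), part) for part in parts
        ]
        return FoldPlan("kfold", K, folds, rng_seed)
    if method == "loo":
        folds = [(genes[:i] + genes[i + 1:], [g]) for i, g in enumerate(genes)]
        return FoldPlan("loo", N, folds, rng_seed)
    folds = [([g], genes[:i] + genes[i + 1:]) for i, g in enumerate(genes)]
    return FoldPlan("singletons", N, folds, rng_seed)


def rank_metrics(
    scores: np.ndarray,
    positives: np.ndarray,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
) -> dict[str, float]:
    """Retrieval metrics for one ranked list.

    ``positives`` is a boolean mask over ``scores``.  AUROC uses the
    rank-sum identity with midranks, so fully tied scores yield 0.5; AUPRC is
    the stepwise precision-recall sum (equal-score items are broken by input
    order, stably).
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    npos = int(positives.sum())
    nneg = int((~positives).sum())
    if npos == 0:
        raise MetricError("rank metrics need at least one positive")
    if nneg == 0:
        raise MetricError("rank metrics need at least one negative")
    # AUROC: midranks of ascending scores; Mann-Whitney identity.
    asc_ranks = scipy.stats.rankdata(scores, method="average")
    auroc = (asc_ranks[positives].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    # AUPRC: stepwise summation over the descending-score order.
    order = np.argsort(-scores, kind="stable")
    hits = np.cumsum(positives[order])
    ks = np.arange(1, scores.size + 1)
    precision = hits / ks
    auprc = float(precision[positives[order]].sum() / npos)
    out = {"AUROC": float(auroc), "AUPRC": auprc}
    for k in k_grid:
        kk = min(k, scores.size)
        topk_hits = int(hits[kk - 1])
        out[f"P@{k}"] = topk_hits / k
        out[f"R@{k}"] = topk_hits / npos
    return out


def rerank(meanranks: np.ndarray | pd.Series) -> np.ndarray:
    """Competition ("min") rank of ascending mean ranks; ties share ranks."""
    s = pd.Series(np.asarray(meanranks, dtype=float))
    if s.empty:
        raise ValueError("rerank needs a non-empty input")
    return s.rank(method="min", ascending=True).to_numpy().astype(int)


def run_cv(
    mpx: Multiplex,
    geneset: GeneSet,
    method: str = "kfold",
    K: int | None = 5,
    params: RWRParams | None = None,
    rng_seed: int | None = None,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
) -> CVReport:
    """Run RWR cross-validation of one gene set against a multiplex."""
    if params is None:
        params = RWRParams()
    present = [g for g in geneset.members if g in mpx.node_index]
    absent = [g for g in geneset.members if g not in mpx.node_index]
    if absent:
        warnings.warn(
            f"gene set {geneset.setid!r}: dropped members absent from the "
            f"multiplex: {absent}",
            stacklevel=2,
        )
    if len(present) < 2:
        raise NoSeedsError(
            f"gene set {geneset.setid!r}: fewer than 2 members in the multiplex"
        )
    weights = [geneset.weight_of(g) for g in present]
    gs = GeneSet(geneset.setid, present, weights)
    plan = make_folds(gs, method, K if method == "kfold" else None, rng_seed)

    full_rows = []
    metric_rows = []
    for fold_id, (train, held) in enumerate(plan.folds):
        train_w = [gs.weight_of(g) for g in train]
        seed_vec = make_seed_vector(mpx, GeneSet(gs.setid, train, train_w),
                                    params.tau)
        res = random_walk_restart(mpx, seed_vec, params)
        ranked = ~np.isnan(res.ranks)
        held_mask = np.zeros(mpx.n_nodes, dtype=bool)
        for g in held:
            held_mask[mpx.node_index[g]] = True
        genes = np.array(res.genes, dtype=object)
        fold_df = pd.DataFrame(
            {
                "fold": fold_id,
                "gene": genes[ranked],
                "score": res.scores[ranked],
                "rank": res.ranks[ranked].astype(int),
                "held_out": held_mask[ranked],
            }
        )
        full_rows.append(fold_df)
        metric_rows.append(
            {"fold": fold_id,
             **rank_metrics(res.scores[ranked], held_mask[ranked], k_grid)}
        )

    fullranks = pd.concat(full_rows, ignore_index=True)
    meanranks = (
        fullranks.groupby("gene", sort=True)["rank"]
        .mean()
        .rename("meanrank")
        .reset_index()
    )
    meanranks = meanranks.sort_values(
        ["meanrank", "gene"], kind="stable"
    ).reset_index(drop=True)
    meanranks["rerank"] = rerank(meanranks["meanrank"].to_numpy())
    metrics = pd.DataFrame(metric_rows)
    stats = metrics.drop(columns="fold")
    summary = pd.DataFrame(
        {"metric": stats.columns, "mean": stats.mean().to_numpy(),
         "sd": stats.std(ddof=1).to_numpy()}
    )
    summary.insert(0, "geneset_id", gs.setid)
    return CVReport(gs.setid, plan.method, plan.K, fullranks, meanranks,
                    metrics, summary)
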