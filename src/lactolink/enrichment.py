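"""Preranked gene-set enrichment and Fisher-exact MeanRank TF prioritization.

Genes are ranked by sign(log2FC) * -log10(p) from a DE result, so the head
of the list holds genes both strongly up and significant, the tail strongly
down and significant. The enrichment score of a set is the signed maximum
deviation of a weighted running sum over the ranked list (increment
|score|^weight at set members, constant decrement elsewhere), with a
gene-label permutation null and leading-edge extraction.

The TF route mirrors the ChEA3 MeanRank integration: per library, every
TF-target set is scored against the input gene list by the one-sided Fisher
exact test (the same hypergeometric upper tail as the co-occurrence
module), BH-adjusted within the library, deduplicated to each TF's best
set, converted to integer ranks, and the ranks averaged across libraries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._stats import bh_adjust, hypergeom_upper_tail
from .data import GeneSetLibrary

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def rank_metric(de_results: pd.DataFrame, p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Ranked gene list scored by sign(log2fc) * -log10(max(p, p_floor)).

    Needs columns ``gene``, ``log2fc``, ``pvalue``. Ordered descending by
    score; ties broken by |log2fc| descending, then gene name. Genes with a
    missing p-value are excluded (logged).
    """
    df = de_results[["gene", "log2fc", "pvalue"]].copy()
    missing = df["pvalue"].isna() | df["log2fc"].isna()
    if missing.any():
        logger.info("excluding %d genes without p-values from ranking", int(missing.sum()))
        df = df[~missing]
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene in DE results")
    score = np.sign(df["log2fc"]) * -np.log10(np.maximum(df["pvalue"], p_floor))
    df["score"] = score
    df["abs_lfc"] = df["log2fc"].abs()
    df = df.sort_values(
        by=["score", "abs_lfc", "gene"], ascending=[False, False, True], kind="stable"
    ).drop(columns="abs_lfc")
    return df.reset_index(drop=True)


def _running_es(scores: np.ndarray, hit: np.ndarray, weight: float):
    """Signed maximum deviation of the weighted running sum, plus its index.

    Hits increment |score|^weight / sum_set |score|^weight; misses decrement
    1/(N - N_hit).
    """
    n = scores.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight
    denom = w[hit].sum()
    if denom == 0:
        # all member scores are exactly 0 under this weight: fall back to equal steps
        steps_hit = np.full(n, 1.0 / n_hit)
    else:
        steps_hit = w / denom
    steps = np.where(hit, steps_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_enrichment(
    ranked: pd.DataFrame,
    library: GeneSetLibrary,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Weighted running-sum enrichment of each library set in a ranked list.

    Permutation p-values come from gene-label permutations that preserve
    set size: within the sign-matched null tail, doubled and capped at 1.
    Leading edge: hit genes at or before the ES extremum for positive ES,
    at or after it for negative ES. Sets with no overlap with the universe
    are skipped, as are sets covering the whole universe.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    n = genes.size
    rng = np.random.default_rng(seed)

    rows = []
    for set_name, members in library.sets.items():
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if idx.size == 0:
            logger.info("set %r has no overlap with the ranked universe; skipped", set_name)
            continue
        if idx.size == n:
            logger.info("set %r covers the entire universe; skipped", set_name)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, ext = _running_es(scores, hit, weight)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=idx.size, replace=False)] = True
            null[b], _ = _running_es(scores, perm, weight)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_tail = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p_one = (1 + extreme) / (1 + n_tail)
        p = min(1.0, 2.0 * p_one)

        if es >= 0:
            le_idx = idx[idx <= ext]
        else:
            le_idx = idx[idx >= ext]
        rows.append(
            {
                "set_name": set_name,
                "es": es,
                "pvalue": p,
                "size": int(idx.size),
                "leading_edge": list(genes[le_idx]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def fisher_overlap_test(input_set, tf_set, background_size: int) -> float:
    """One-sided (enrichment) Fisher exact p for the overlap of two sets.

    Equivalent to the hypergeometric upper tail
    P(X >= |input & tf|) with X ~ Hypergeom(background, |tf|, |input|).
    """
    input_set, tf_set = set(input_set), set(tf_set)
    if not input_set:
        raise ValueError("input set is empty")
    if len(input_set) > background_size or len(tf_set) > background_size:
        raise ValueError("sets larger than the background universe")
    k = len(input_set & tf_set)
    return hypergeom_upper_tail(k, background_size, len(tf_set), len(input_set))


def _tf_of(set_name: str) -> str:
    """TF symbol from a library set name: the first token before a space or
    underscore."""
    return set_name.replace("_", " ").split(" ")[0]


def meanrank_tf(input_set, libraries, background_size: int) -> pd.DataFrame:
    """MeanRank TF prioritization across TF-target libraries.

    Per library: Fisher-exact p per set, BH within the library, each TF
    reduced to its lowest-p set, integer ranks 1..k by ascending adjusted p
    (ties by raw p then TF name). A TF's score is the mean of its ranks
    over the libraries that contain it; output ascends by mean score.
    """
    if not libraries:
        raise ValueError("need at least one library")
    input_set = set(input_set)
    per_library_ranks: dict[str, pd.Series] = {}
    for lib in libraries:
        names = list(lib.sets)
        pvals = np.array(
            [fisher_overlap_test(input_set, lib.sets[s], background_size) for s in names]
        )
        padj = bh_adjust(pvals)
        table = pd.DataFrame({"set_name": names, "pvalue": pvals, "p_adjusted": padj})
        table["tf"] = [_tf_of(s) for s in names]
        # keep each TF's lowest-raw-p set
        table = table.sort_values(["tf", "pvalue", "set_name"], kind="stable")
        best = table.groupby("tf", sort=False).first().reset_index()
        best = best.sort_values(["p_adjusted", "pvalue", "tf"], kind="stable")
        best["rank"] = np.arange(1, len(best) + 1)
        per_library_ranks[lib.name] = best.set_index("tf")["rank"]

    all_tfs = sorted(set().union(*[set(r.index) for r in per_library_ranks.values()]))
    rows = []
    for tf in all_tfs:
        ranks = {
            lib: int(r.loc[tf]) for lib, r in per_library_ranks.items() if tf in r.index
        }
        rows.append(
            {
                "tf": tf,
                "mean_rank": float(np.mean(list(ranks.values()))),
                "n_libraries": len(ranks),
                "library_ranks": ranks,
            }
        )
    out = pd.DataFrame(rows).sort_values(["mean_rank", "tf"], kind="stable")
    return out.reset_index(drop=True)


class PrerankedGSEA(BaseEstimator):
    """Preranked enrichment over a gene-set library.

    Attributes
    ----------
    results_ : DataFrame with ES, permutation p, BH p, and leading edge per set.
    """

    def __init__(self, weight: float = 1.0, n_perm: int = 1000, seed: int | None = None):
        self.weight = weight
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, ranked: pd.DataFrame, library: GeneSetLibrary):
        self.results_ = preranked_enrichment(
            ranked, library, weight=self.weight, n_perm=self.n_perm, seed=self.seed
        )
        return self


class MeanRankTF(BaseEstimator):
    """ChEA3-style MeanRank TF aggregation over several libraries."""

    def __init__(self, background_size: int = 20000):
        self.background_size = background_size

    def fit(self, input_set, libraries):
        self.results_ = meanrank_tf(input_set, libraries, self.background_size)
        return self
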