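"""Per-sample binarized gene-gene co-occurrence analysis.

For a gene pair within one sample and cell type, detection (count >= 1) is
binarized and the number of doubly-detected cells is compared to the
hypergeometric expectation given each gene's marginal detection count: the
upper tail P(X >= k) asks whether the genes appear in the same cells more
often than chance. A pair is only tested in samples where both genes are
detected in at least 2% of the cells of that cell type AND in at least 5
cells; reproducibility is then summarized as the percentage of eligible
samples in which the test is significant at alpha.

No multiplicity correction is applied across pairs within a sample: the
per-sample test is raw p <= alpha, and reproducibility across independent
samples is the guard against false positives. Interpret single-sample
significance accordingly.
"""

from __future__ import annotations

import dataclasses

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

from ._stats import hypergeom_upper_tail

MIN_CELLS_DETECTED = 5
MIN_FRACTION_DETECTED = 0.02


@dataclasses.dataclass(frozen=True)
class CooccurrenceInput:
    """Margins of one co-occurrence table.

    N cells of the cell type in the sample; K detect gene A, n detect gene
    B, k detect both.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"margins exceed population: {self}")
        if not (max(0, self.K + self.n - self.N) <= self.k <= min(self.K, self.n)):
            raise ValueError(f"overlap outside support: {self}")


def cooccurrence_test(inp: CooccurrenceInput) -> float:
    """Inclusive upper-tail hypergeometric p-value P(X >= k)."""
    return hypergeom_upper_tail(inp.k, inp.N, inp.K, inp.n)


def _detection(adata: ad.AnnData, sample: str, cell_type: str, genes):
    mask = (adata.obs["sample_id"].astype(str) == str(sample)) & (
        adata.obs["cell_type"].astype(str) == str(cell_type)
    )
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    sub = adata[mask.to_numpy(), list(genes)]
    X = sub.X
    det = (X > 0).toarray() if sp.issparse(X) else np.asarray(X) > 0
    return det  # cells x genes boolean


def _eligible(N: int, detected: int) -> bool:
    return detected >= MIN_CELLS_DETECTED and detected >= MIN_FRACTION_DETECTED * N


def pair_eligibility(
    adata: ad.AnnData, sample: str, cell_type: str, gene_a: str, gene_b: str
) -> tuple[bool, CooccurrenceInput]:
    """Eligibility of a pair in one sample, plus its co-occurrence margins.

    Eligible iff each gene is detected in >= 2% of the N cells and in >= 5
    cells. Margins are returned regardless of eligibility.
    """
    det = _detection(adata, sample, cell_type, [gene_a, gene_b])
    N = det.shape[0]
    K = int(det[:, 0].sum())
    n = int(det[:, 1].sum())
    k = int((det[:, 0] & det[:, 1]).sum())
    return _eligible(N, K) and _eligible(N, n), CooccurrenceInput(N=N, K=K, n=n, k=k)


def _canonical_pairs(pairs):
    out = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair of a gene with itself: {a!r}")
        out.append((a, b) if a <= b else (b, a))
    return out


def sample_coexpression(
    adata: ad.AnnData, pairs, cell_type: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Run the eligibility-gated co-occurrence test per pair per sample.

    Returns one record per (pair, sample) with the margins, the eligibility
    flag, and (where eligible) the p-value and significance at alpha.
    """
    pairs = _canonical_pairs(pairs)
    gene_list = sorted({g for p in pairs for g in p})
    missing = [g for g in gene_list if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    col = {g: i for i, g in enumerate(gene_list)}

    ct_mask = (adata.obs["cell_type"].astype(str) == str(cell_type)).to_numpy()
    sub = adata[ct_mask, gene_list]
    X = sub.X
    det = (X > 0).toarray() if sp.issparse(X) else np.asarray(X) > 0
    sample_ids = sub.obs["sample_id"].astype(str).to_numpy()

    records = []
    for sample in pd.unique(sample_ids):
        rows = det[sample_ids == sample]
        N = rows.shape[0]
        marg = rows.sum(axis=0)
        overlap = rows.T.astype(np.int32) @ rows.astype(np.int32)
        for a, b in pairs:
            K, n = int(marg[col[a]]), int(marg[col[b]])
            k = int(overlap[col[a], col[b]])
            eligible = _eligible(N, K) and _eligible(N, n)
            p = hypergeom_upper_tail(k, N, K, n) if eligible else np.nan
            records.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "cell_type": cell_type,
                    "sample_id": sample,
                    "N": N,
                    "K": K,
                    "n": n,
                    "k": k,
                    "eligible": eligible,
                    "p_value": p,
                    "significant": bool(eligible and p <= alpha),
                }
            )
    return pd.DataFrame.from_records(records)


def reproducibility_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-(pair, sample) records into cross-sample reproducibility.

    pct_significant is 100 * n_significant / n_eligible, reported as missing
    (NaN) for pairs with no eligible sample.
    """
    grouped = records.groupby(["gene_a", "gene_b", "cell_type"], sort=True)
    summary = pd.DataFrame(
        {
            "n_eligible_samples": grouped["eligible"].sum().astype(int),
            "n_significant_samples": grouped["significant"].sum().astype(int),
        }
    ).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        summary["pct_significant"] = np.where(
            summary["n_eligible_samples"] > 0,
            100.0 * summary["n_significant_samples"] / summary["n_eligible_samples"],
            np.nan,
        )
    return summary


def cluster_top_pairs(summary: pd.DataFrame, top_n: int = 200):
    """Median-linkage (WPGMC) clustering of the most reproducible pairs.

    Selects the top_n pairs by pct_significant (ties: n_eligible_samples
    descending, then pair name), builds each pair's feature vector from
    pct_significant across cell types, and clusters on Euclidean distance.
    Returns (linkage matrix, leaf order, selected pair labels).
    """
    defined = summary.dropna(subset=["pct_significant"]).copy()
    defined["pair"] = defined["gene_a"] + "|" + defined["gene_b"]
    per_pair = defined.groupby("pair").agg(
        best_pct=("pct_significant", "max"),
        best_eligible=("n_eligible_samples", "max"),
    )
    ranked = per_pair.sort_values(
        by=["best_pct", "best_eligible", "pair"],
        ascending=[False, False, True],
        kind="stable",
    )
    selected = list(ranked.index[:top_n])
    if len(selected) < 2:
        raise ValueError("need at least 2 pairs with defined pct_significant")
    features = (
        defined[defined["pair"].isin(selected)]
        .pivot_table(index="pair", columns="cell_type", values="pct_significant")
        .reindex(selected)
        .fillna(0.0)
    )
    Z = linkage(features.to_numpy(), method="median", metric="euclidean")
    order = [selected[i] for i in leaves_list(Z)]
    return Z, order, selected


class CooccurrenceAnalyzer(BaseEstimator):
    """Reproducible co-occurrence screening for a set of gene pairs.

    Parameters
    ----------
    cell_type : str
        Cell-type label whose cells define each sample's population.
    alpha : float, default 0.05
        Raw per-sample significance threshold.
    top_n : int, default 200
        Number of pairs clustered by :meth:`cluster_top_pairs`.

    Attributes
    ----------
    records_ : DataFrame of per-(pair, sample) test records.
    summary_ : DataFrame of per-pair reproducibility percentages.
    """

    def __init__(self, cell_type: str = "LC2", alpha: float = 0.05, top_n: int = 200):
        self.cell_type = cell_type
        self.alpha = alpha
        self.top_n = top_n

    def fit(self, adata: ad.AnnData, pairs):
        self.records_ = sample_coexpression(adata, pairs, self.cell_type, self.alpha)
        self.summary_ = reproducibility_summary(self.records_)
        return self

    def cluster_top_pairs(self):
        return cluster_top_pairs(self.summary_, self.top_n)
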