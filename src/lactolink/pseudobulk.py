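"""Pseudobulk aggregation, cell-type proportions, and size-factor normalization.

Summing raw counts over the cells of each (sample, cell type) group turns
sparse single-cell data into bulk-style count vectors on which negative
binomial GLMs are well behaved; library-size differences between the
resulting rows are absorbed by median-of-ratios size factors.
"""

from __future__ import annotations

import dataclasses

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


class NormalizationError(ValueError):
    """Size factors cannot be computed for this table."""


@dataclasses.dataclass
class PseudobulkTable:
    """Summed counts per (sample_id, cell_type) row with attached covariates.

    ``counts`` is genes-as-columns with a (sample_id, cell_type) MultiIndex;
    ``meta`` shares that index and carries donor_id, study_id,
    time_postpartum_days, and n_cells_aggregated. ``size_factors`` is
    populated by :func:`size_factors` (or ``with_size_factors``).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same row index")
        if (self.meta["n_cells_aggregated"] < 1).any():
            raise ValueError("every pseudobulk row must aggregate >= 1 cell")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    def subset_cell_type(self, cell_type: str) -> "PseudobulkTable":
        """Rows of one cell type, re-indexed by sample_id."""
        mask = self.meta.index.get_level_values("cell_type") == cell_type
        if not mask.any():
            raise KeyError(f"no pseudobulk rows for cell type {cell_type!r}")
        counts = self.counts.loc[mask].droplevel("cell_type")
        meta = self.meta.loc[mask].droplevel("cell_type")
        sf = None
        if self.size_factors is not None:
            sf = self.size_factors.loc[mask].droplevel("cell_type")
        return PseudobulkTable(counts=counts.copy(), meta=meta.copy(), size_factors=sf)

    def with_size_factors(self) -> "PseudobulkTable":
        return dataclasses.replace(self, size_factors=size_factors(self))


def aggregate_pseudobulk(adata: ad.AnnData, cell_types) -> PseudobulkTable:
    """Sum counts over cells within each (sample, requested cell type) group.

    Emits one row per group with at least one cell; sample-level covariates
    (donor, study, time postpartum) are carried over.
    """
    cell_types = list(cell_types)
    present = set(adata.obs["cell_type"].astype(str))
    missing = [ct for ct in cell_types if ct not in present]
    if missing:
        raise KeyError(f"cell types not present in data: {missing}")
    mask = adata.obs["cell_type"].astype(str).isin(cell_types).to_numpy()
    if not mask.any():
        raise ValueError("no cells of any requested type")

    sub = adata[mask]
    keys = pd.MultiIndex.from_frame(
        sub.obs[["sample_id", "cell_type"]].astype(str),
        names=["sample_id", "cell_type"],
    )
    codes, uniques = pd.factorize(keys, sort=True)
    uniques = pd.MultiIndex.from_tuples(uniques, names=["sample_id", "cell_type"])
    n_groups, n_cells = len(uniques), sub.n_obs
    # indicator @ X sums rows per group without densifying
    indicator = sp.csr_matrix(
        (np.ones(n_cells), (codes, np.arange(n_cells))), shape=(n_groups, n_cells)
    )
    X = sub.X if sp.issparse(sub.X) else sp.csr_matrix(np.asarray(sub.X))
    summed = np.asarray((indicator @ X).todense())

    counts = pd.DataFrame(summed, index=uniques, columns=sub.var_names).astype(np.int64)
    obs = sub.obs.copy()
    obs["_code"] = codes
    grouped = obs.groupby("_code", observed=True)
    meta = pd.DataFrame(
        {
            "donor_id": grouped["donor_id"].first().astype(str),
            "study_id": grouped["study_id"].first().astype(str),
            "time_postpartum_days": grouped["time_postpartum_days"].first(),
            "n_cells_aggregated": grouped.size(),
        }
    )
    meta.index = uniques
    return PseudobulkTable(counts=counts, meta=meta)


def cell_type_proportions(adata: ad.AnnData) -> pd.DataFrame:
    """Per-sample cell-type composition: fraction of each sample's cells.

    Rows are samples, columns cell types; rows sum to 1.
    """
    obs = adata.obs
    if obs["cell_type"].isna().any():
        raise ValueError("every cell needs a cell_type")
    tab = pd.crosstab(obs["sample_id"].astype(str), obs["cell_type"].astype(str))
    props = tab.div(tab.sum(axis=1), axis=0)
    props.index.name = "sample_id"
    props.columns.name = "cell_type"
    return props


def size_factors(pb: PseudobulkTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes observed in every row.

    For each gene nonzero in all rows, compute its geometric mean across
    rows; a row's factor is the median over those genes of count/geomean.
    """
    counts = pb.counts if isinstance(pb, PseudobulkTable) else pb
    if len(counts) < 2:
        raise NormalizationError("size factors need at least 2 rows")
    mat = counts.to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=0)
    if not eligible.any():
        raise NormalizationError("no gene has nonzero counts in every row")
    logs = np.log(mat[:, eligible])
    log_geomean = logs.mean(axis=0)
    factors = np.exp(np.median(logs - log_geomean, axis=1))
    if not np.all(np.isfinite(factors) & (factors > 0)):
        raise NormalizationError("non-finite or non-positive size factor")
    return pd.Series(factors, index=counts.index, name="size_factor")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million within each row."""
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("cannot CPM-normalize a row with zero total counts")
    return counts.div(totals, axis=0) * 1e6
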