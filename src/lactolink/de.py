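"""Negative-binomial GLM differential expression on pseudobulk counts.

Two designs are supported, mirroring the two questions the package asks of
pseudobulk data:

* **cluster** — LC1 vs LC2 across studies: per gene a NB GLM (log link,
  size factors as offsets) with fixed effects ``~ study + cell_type``, Wald
  test on the cell-type coefficient;
* **hmo** — gene ~ HMO concentration within one cell type: full model
  ``~ donor + z(time) + z(HMO)`` against the reduced ``~ donor + z(time)``,
  likelihood-ratio test with 1 df; the association sign comes from the
  full-model HMO coefficient.

Per-gene dispersions alpha (variance mu + alpha*mu^2) are estimated by a
design-aware method of moments refined by Cox-Reid adjusted profile
likelihood. No fold-change or dispersion shrinkage is
applied: estimates here are plain maximum-likelihood per gene, which
differs by design from shrinkage-based DE packages. Effects are reported on
the log2 scale. Non-converged genes are flagged and excluded from the BH
family.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse  # noqa: F401  (anndata interplay)
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from ._stats import bh_adjust
from .association import standardize
from .pseudobulk import PseudobulkTable, cpm

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
MAX_ITER = 100
TOL = 1e-8


class DesignError(ValueError):
    """The design matrix is rank deficient or otherwise unusable."""


@dataclasses.dataclass
class DEDesign:
    """Covariate structure for a DE contrast.

    ``full`` lists the full-model covariate columns in order; ``reduced``
    (LRT only) must be a strict subset missing exactly the tested term.
    """

    full: list[str]
    tested: str
    reduced: list[str] | None = None

    def __post_init__(self):
        if self.tested not in self.full:
            raise DesignError("tested term must be a full-model covariate")
        if self.reduced is not None:
            extra = set(self.reduced) - set(self.full)
            if extra:
                raise DesignError(f"reduced covariates not in full model: {sorted(extra)}")
            if self.tested in self.reduced:
                raise DesignError("tested term must be absent from the reduced model")


def _encode(meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Design matrix: intercept + dummy-encoded categoricals (first level
    dropped) + numeric columns as-is."""
    cols = {"Intercept": np.ones(len(meta))}
    for cov in covariates:
        v = meta[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols[cov] = v.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(v.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if c != "Intercept"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


def estimate_dispersion(
    pb: PseudobulkTable,
    design: pd.DataFrame | None = None,
    refine: bool = False,
    floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Per-gene NB dispersion alpha from size-factor-normalized counts.

    Without a design, the moment estimator is
    ``alpha = max(floor, (s^2 - mu) / mu^2)`` on normalized counts. With a
    design matrix (rows aligned to ``pb``), per-gene means are first fit by
    a Poisson GLM with the design and log-size-factor offsets, and the
    moments are taken on the residuals,

        alpha = max(floor, n/(n-p) * sum((y - mu)^2 - mu) / sum(mu^2)),

    so covariate-driven mean structure (cluster, donor, concentration) is
    not mistaken for overdispersion. ``refine=True`` re-fits each alpha by
    profile NB likelihood around the fitted means. All-zero genes get the
    floor and are flagged.
    """
    if len(pb) < 3:
        raise ValueError("dispersion estimation needs >= 3 rows")
    sf = pb.size_factors
    if sf is None:
        raise ValueError("compute size factors first (PseudobulkTable.with_size_factors)")
    raw = pb.counts.to_numpy(dtype=float)
    sfv = sf.to_numpy()
    norm = raw / sfv[:, None]
    base_mean = norm.mean(axis=0)
    all_zero = base_mean == 0
    n = raw.shape[0]

    if design is None:
        s2 = norm.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = (s2 - base_mean) / base_mean**2
        alpha = np.where(all_zero, floor, np.maximum(floor, mom))
        fitted = base_mean[None, :] * sfv[:, None]
        X = np.ones((n, 1))
    else:
        X = np.asarray(design, dtype=float)
        if X.shape[0] != n:
            raise DesignError("design rows must match pseudobulk rows")
        p = X.shape[1]
        if n <= p:
            raise DesignError("need more rows than design columns")
        offset = np.log(sfv)
        fitted = np.empty_like(raw)
        alpha = np.full(raw.shape[1], floor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j in range(raw.shape[1]):
                if all_zero[j]:
                    fitted[:, j] = 0.0
                    continue
                try:
                    mu = sm.GLM(raw[:, j], X, family=sm.families.Poisson(),
                                offset=offset).fit(maxiter=MAX_ITER).mu
                except Exception:
                    mu = base_mean[j] * sfv
                fitted[:, j] = mu
                mom = (n / (n - p)) * np.sum((raw[:, j] - mu) ** 2 - mu) / np.sum(mu**2)
                alpha[j] = max(floor, mom)

    if refine:
        for j in range(raw.shape[1]):
            if all_zero[j]:
                continue
            alpha[j] = _cox_reid_alpha(raw[:, j], np.maximum(fitted[:, j], 1e-12),
                                       X, floor=floor)

    return pd.DataFrame(
        {"alpha": alpha, "all_zero": all_zero, "base_mean": base_mean}, index=pb.genes
    )


def _cox_reid_alpha(y, mu, X, floor: float = DISPERSION_FLOOR) -> float:
    """Cox-Reid adjusted profile-likelihood dispersion at fixed fitted means.

    Maximizes the NB log-likelihood minus 0.5*logdet(X'WX) over log(alpha);
    the adjustment removes the downward bias of plain profile ML when the
    mean model consumes a non-trivial share of the residual df.
    """
    def neg_apl(log_a):
        a = np.exp(log_a)
        r = 1.0 / a
        ll = np.sum(stats.nbinom.logpmf(y, r, r / (r + mu)))
        W = mu / (1.0 + a * mu)
        sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
        if sign <= 0:
            return 1e12
        return -(ll - 0.5 * logdet)

    res = minimize_scalar(neg_apl, bounds=(np.log(1e-6), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-3})
    if not res.success:
        return floor
    return max(floor, float(np.exp(res.x)))


def _fit_nb(y, X, alpha, offset):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                         family=fam, offset=offset).fit(maxiter=MAX_ITER, tol=TOL)
            return res, bool(res.converged)
        except Exception:
            return None, False


def _finish(results: pd.DataFrame) -> pd.DataFrame:
    pv = results["pvalue"].to_numpy().copy()
    pv[~results["converged"].to_numpy()] = np.nan  # excluded from the BH family
    results["p_adjusted"] = bh_adjust(pv)
    return results


def de_wald(pb: PseudobulkTable, design: DEDesign | None = None,
            dispersions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wald-test DE on a categorical contrast (default: study + cell_type).

    The tested coefficient is the dummy of the tested covariate's second
    level; effects are log2 fold changes. BH correction across converged
    genes.
    """
    if design is None:
        design = DEDesign(full=["study_id", "cell_type"], tested="cell_type")
    pb = pb.with_size_factors() if pb.size_factors is None else pb
    meta = pb.meta.copy()
    for cov in design.full:
        if cov == "cell_type" and cov not in meta.columns:
            meta[cov] = meta.index.get_level_values("cell_type")
    X = _encode(meta, design.full)
    if dispersions is None:
        dispersions = estimate_dispersion(pb, design=X, refine=True)
    tested_cols = [c for c in X.columns if c.startswith(design.tested + "_")]
    if pd.api.types.is_numeric_dtype(meta.get(design.tested, pd.Series(dtype=object))):
        tested_cols = [design.tested]
    if len(tested_cols) != 1:
        raise DesignError(
            f"tested term {design.tested!r} must encode to exactly one column; got {tested_cols}"
        )
    j = list(X.columns).index(tested_cols[0])
    offset = np.log(pb.size_factors.to_numpy())

    rows = []
    for gene in pb.genes:
        y = pb.counts[gene].to_numpy()
        alpha = float(dispersions.loc[gene, "alpha"])
        res, converged = _fit_nb(y, X, alpha, offset)
        if res is None:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, alpha, False))
            continue
        beta, se = float(res.params[j]), float(res.bse[j])
        z = beta / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((gene, beta / LN2, se / LN2, z, p, alpha, converged))
    out = pd.DataFrame(
        rows, columns=["gene", "log2fc", "se", "stat", "pvalue", "alpha", "converged"]
    )
    out["base_mean"] = dispersions.loc[out["gene"], "base_mean"].to_numpy()
    out["df"] = np.nan
    return _finish(out)


def de_hmo_lrt(pb: PseudobulkTable, panel: pd.DataFrame, hmo: str,
               cell_type: str | None = None,
               dispersions: pd.DataFrame | None = None) -> pd.DataFrame:
    """LRT for gene ~ z(HMO) with donor and z(time) as nuisance covariates.

    The full model adds the standardized concentration to donor indicator
    and standardized-time fixed effects; the statistic is
    2*(llf_full - llf_reduced) on 1 df, with the sign of association read
    off the full-model HMO coefficient (log2 per SD of concentration).
    """
    if hmo not in panel.columns:
        raise KeyError(f"HMO {hmo!r} not in panel")
    sub = pb.subset_cell_type(cell_type) if cell_type is not None else pb
    shared = sub.counts.index.intersection(panel.index)
    dropped = len(sub) - len(shared)
    if dropped:
        logger.info("dropping %d pseudobulk rows without HMO data", dropped)
    if len(shared) < 3:
        raise ValueError("need >= 3 matched samples for the LRT design")
    counts = sub.counts.loc[shared]
    meta = sub.meta.loc[shared].copy()
    meta["z_time"] = standardize(meta["time_postpartum_days"])
    meta["z_hmo"] = standardize(panel.loc[shared, hmo])

    matched = PseudobulkTable(counts=counts, meta=meta).with_size_factors()
    X_full = _encode(meta, ["donor_id", "z_time", "z_hmo"])
    X_red = X_full.drop(columns="z_hmo")
    if dispersions is None:
        dispersions = estimate_dispersion(matched, design=X_full, refine=True)
    j = list(X_full.columns).index("z_hmo")
    offset = np.log(matched.size_factors.to_numpy())

    rows = []
    for gene in matched.genes:
        y = counts[gene].to_numpy()
        alpha = float(dispersions.loc[gene, "alpha"])
        full, conv_f = _fit_nb(y, X_full, alpha, offset)
        red, conv_r = _fit_nb(y, X_red, alpha, offset)
        converged = conv_f and conv_r
        if full is None or red is None:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, alpha, False))
            continue
        stat = max(0.0, 2.0 * (full.llf - red.llf))
        p = float(stats.chi2.sf(stat, df=1))
        beta, se = float(full.params[j]), float(full.bse[j])
        rows.append((gene, beta / LN2, se / LN2, stat, p, alpha, converged))
    out = pd.DataFrame(
        rows, columns=["gene", "log2fc", "se", "stat", "pvalue", "alpha", "converged"]
    )
    out["base_mean"] = dispersions.loc[out["gene"], "base_mean"].to_numpy()
    out["df"] = 1.0
    return _finish(out)


def per_sample_log2fc(pb: PseudobulkTable, type_a: str = "LC1", type_b: str = "LC2",
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Within-sample log2((CPM_A + pc) / (CPM_B + pc)) per gene.

    Samples missing either cell type are excluded (logged).
    """
    idx = pb.counts.index
    samples_a = set(idx[idx.get_level_values("cell_type") == type_a].get_level_values("sample_id"))
    samples_b = set(idx[idx.get_level_values("cell_type") == type_b].get_level_values("sample_id"))
    both = sorted(samples_a & samples_b)
    skipped = (samples_a | samples_b) - set(both)
    if skipped:
        logger.info("excluding %d samples missing one cell type: %s", len(skipped), sorted(skipped))
    if not both:
        raise ValueError(f"no sample has both {type_a!r} and {type_b!r} rows")
    norm = cpm(pb.counts)
    a = norm.loc[[(s, type_a) for s in both]].droplevel("cell_type")
    b = norm.loc[[(s, type_b) for s in both]].droplevel("cell_type")
    lfc = np.log2((a + pseudocount) / (b + pseudocount))
    lfc.index.name = "sample_id"
    return lfc


def correlate_lfc_time(lfc: pd.DataFrame, times: pd.Series, method: str = "spearman") -> pd.DataFrame:
    """Per-gene correlation of within-sample log2FC with time postpartum.

    Returns rho, p, and BH-adjusted p per gene; genes with a constant LFC
    vector are reported missing.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    shared = lfc.index.intersection(times.dropna().index)
    if len(shared) < 3:
        raise ValueError("need >= 3 samples with both LFC and time")
    t = times.loc[shared].to_numpy(dtype=float)
    rows = []
    for gene in lfc.columns:
        v = lfc.loc[shared, gene].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            rows.append((gene, np.nan, np.nan))
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(v, t)
        else:
            rho, p = stats.pearsonr(v, t)
        rows.append((gene, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "rho", "pvalue"])
    out["p_adjusted"] = bh_adjust(out["pvalue"].to_numpy())
    return out


class PseudobulkDE(BaseEstimator):
    """NB-GLM differential expression over a pseudobulk table.

    Parameters
    ----------
    design : {"cluster", "hmo"}
        "cluster" runs the Wald contrast on ``~ study + cell_type``;
        "hmo" runs the 1-df LRT for a standardized HMO concentration on top
        of donor + time nuisance covariates.
    hmo : str, optional
        Concentration column tested when ``design="hmo"``.
    cell_type : str, optional
        Restrict the HMO design to one cell type's pseudobulk rows.

    Attributes
    ----------
    results_ : DataFrame with per-gene effect, SE, statistic, p, BH p.
    dispersions_ : DataFrame of per-gene alpha estimates.
    """

    def __init__(self, design: str = "cluster", hmo: str | None = None,
                 cell_type: str | None = None):
        self.design = design
        self.hmo = hmo
        self.cell_type = cell_type

    def fit(self, pb: PseudobulkTable, panel: pd.DataFrame | None = None):
        if self.design == "cluster":
            self.results_ = de_wald(pb)
        elif self.design == "hmo":
            if panel is None or self.hmo is None:
                raise ValueError("the HMO design needs a panel and an hmo name")
            self.results_ = de_hmo_lrt(pb, panel, self.hmo, cell_type=self.cell_type)
        else:
            raise ValueError("design must be 'cluster' or 'hmo'")
        self.dispersions_ = self.results_.set_index("gene")[["alpha", "base_mean"]]
        return self
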