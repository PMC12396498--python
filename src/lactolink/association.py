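"""Donor-random-intercept associations of HMO concentrations with time and
cell-type proportions.

Each HMO is modeled on the z-score scale:

    z(conc) = b0 + b1 * z(time postpartum) [+ b2 * z(proportion)] + u_donor + e

with a random intercept u_donor per donor, fit by maximum likelihood
(statsmodels MixedLM, lbfgs). Wald p-values use a t reference with
between-within denominator degrees of freedom, which stays calibrated at
cohort sizes of a few dozen samples. BH
correction is applied across HMOs within one family per model: the time
model forms a single family, and each cell type's proportion models form
their own family.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._stats import bh_adjust
from .data import hmo_columns


class DegenerateInputError(ValueError):
    """The input has no variation to model."""


def standardize(v) -> np.ndarray:
    """Classic z-score with sample SD (ddof=1)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("standardize requires finite values")
    if np.unique(v).size < 2:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (v - v.mean()) / v.std(ddof=1)


@dataclasses.dataclass
class AssociationResult:
    response: str
    term: str
    estimate: float
    se: float
    pvalue: float
    p_adjusted: float | None
    n_samples: int
    n_donors: int
    converged: bool


def _fit_mixedlm(df: pd.DataFrame, response: str, fixed: list[str]):
    endog = df[response].to_numpy()
    exog = sm.add_constant(df[fixed].to_numpy())
    model = sm.MixedLM(endog, exog, groups=df["donor_id"].to_numpy())
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs first (the reference fit method); fall back to other
        # optimizers when it stalls, keeping the converged flag honest
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                candidate = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            if res is None:
                res = candidate
            if candidate.converged:
                res, converged = candidate, True
                break
    return res, converged


def _prepare(panel: pd.DataFrame, hmo: str) -> pd.DataFrame:
    if hmo not in panel.columns:
        raise KeyError(f"HMO {hmo!r} not in panel")
    df = panel[[hmo, "donor_id", "time_postpartum_days"]].copy()
    if df["time_postpartum_days"].isna().any():
        raise ValueError("samples with missing time postpartum must be removed first")
    if df["donor_id"].nunique() < 2:
        raise ValueError("random donor intercept needs >= 2 donors")
    df["z_y"] = standardize(df[hmo])
    df["z_t"] = standardize(df["time_postpartum_days"])
    return df


def _result(res, converged, df, response, term, coef_idx, n_fixed) -> AssociationResult:
    n_samples = len(df)
    n_donors = df["donor_id"].nunique()
    if res is None:
        return AssociationResult(response, term, np.nan, np.nan, np.nan, None,
                                 n_samples, n_donors, False)
    est = float(res.params[coef_idx])
    se = float(res.bse[coef_idx])
    # Wald t with between-within denominator df: covariates here vary within
    # donors, so df = n_samples - n_donors - (fixed effects beyond the
    # intercept). A plain normal reference is visibly anti-conservative at
    # cohort sizes of tens of samples.
    dof = max(1, n_samples - n_donors - n_fixed)
    p = float(2.0 * stats.t.sf(abs(est / se), dof)) if (converged and se > 0) else np.nan
    return AssociationResult(response, term, est, se, p, None, n_samples, n_donors, converged)


def fit_time_model(panel: pd.DataFrame, hmo: str) -> AssociationResult:
    """z(HMO) ~ z(time) with a donor random intercept; returns the time term."""
    df = _prepare(panel, hmo)
    res, converged = _fit_mixedlm(df, "z_y", ["z_t"])
    return _result(res, converged, df, hmo, "time_postpartum", coef_idx=1, n_fixed=1)


def fit_proportion_model(
    panel: pd.DataFrame, props: pd.DataFrame, hmo: str, cell_type: str
) -> AssociationResult:
    """z(HMO) ~ z(time) + z(proportion) with a donor random intercept.

    Returns the proportion term. Samples are the intersection of the panel
    and the proportion table.
    """
    if cell_type not in props.columns:
        raise KeyError(f"cell type {cell_type!r} not in proportion table")
    shared = panel.index.intersection(props.index)
    df = _prepare(panel.loc[shared], hmo)
    prop = props.loc[shared, cell_type]
    df["z_p"] = standardize(prop)
    res, converged = _fit_mixedlm(df, "z_y", ["z_t", "z_p"])
    return _result(res, converged, df, hmo, f"proportion_{cell_type}", coef_idx=2, n_fixed=2)


def _results_frame(results: list[AssociationResult], family=None) -> pd.DataFrame:
    out = pd.DataFrame([dataclasses.asdict(r) for r in results])
    out["p_adjusted"] = bh_adjust(out["pvalue"].to_numpy(), groups=family)
    return out


class TimeAssociationLMM(BaseEstimator):
    """HMO ~ time associations across a panel, BH-corrected as one family.

    Attributes
    ----------
    results_ : DataFrame with one row per HMO (estimate, SE, p, BH p).
    """

    def fit(self, panel: pd.DataFrame, hmos=None):
        hmos = list(hmos) if hmos is not None else hmo_columns(panel)
        self.results_ = _results_frame([fit_time_model(panel, h) for h in hmos])
        return self


class ProportionAssociationLMM(BaseEstimator):
    """HMO ~ time + cell-type proportion associations, one BH family per
    cell type."""

    def __init__(self, cell_types=("LC1", "LC2")):
        self.cell_types = cell_types

    def fit(self, panel: pd.DataFrame, props: pd.DataFrame, hmos=None):
        hmos = list(hmos) if hmos is not None else hmo_columns(panel)
        results, family = [], []
        for ct in self.cell_types:
            for h in hmos:
                results.append(fit_proportion_model(panel, props, h, ct))
                family.append(ct)
        self.results_ = _results_frame(results, family=np.asarray(family))
        return self
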