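"""Residual feed intake (RFI) phenotypes from weekly intake records.

RFI is the part of an animal's dry-matter intake (DMI) not explained by
production, maintenance and environment.  It is derived here from a linear
mixed model on animal-week records,

    dmi = mu + YSC + ParAge + b1*dim + b2*milk_e + b3*mbw + ration + e,

with fixed year-season-of-calving (YSC) and parity-by-age (ParAge) classes,
fixed slopes on days-in-milk, milk energy and metabolic body weight
(BW^0.75), a random ration-cohort effect ration ~ N(0, I sigma_r^2) and
residual e ~ N(0, I sigma_e^2).  Variance components are estimated by
restricted maximum likelihood (REML), profiled over the single variance
ratio gamma = sigma_r^2 / sigma_e^2; fixed effects are the GLS solution at
the REML variances and cohort effects are their BLUPs.  Weekly RFI values
are the residuals of this model and the per-animal RFI phenotype is the
plain mean of that animal's weekly residuals.

The grouped structure (each record belongs to exactly one cohort) makes the
whole restricted likelihood available in closed form per candidate gamma:
V = sigma_e^2 (I + gamma Z Z') is block compound-symmetric, so V^{-1} and
log|V| reduce to per-cohort sums.  The one-dimensional profile is maximised
by bounded scalar search.

Fixed effects use sum-to-zero contrasts with an explicit intercept; any
full-rank parameterization gives identical residuals, which is all that
downstream code consumes.

The collection-of-weekly-records type is a pandas DataFrame with columns
``REQUIRED_COLUMNS`` (``birth_date`` may tag along and is ignored here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "RfiModelFit",
    "fit_rfi_model",
    "weekly_residuals",
    "aggregate_rfi",
    "derive_rfi_phenotypes",
]

REQUIRED_COLUMNS = ("animal_id", "dim", "dmi", "milk_e", "mbw",
                    "ysc", "par_age", "ration")

_COVARIATES = ("dim", "milk_e", "mbw")


class ModelSpecificationError(ValueError):
    """Raised for unusable designs (rank deficiency, missing levels...)."""


@dataclass
class RfiModelFit:
    """REML fit of the DMI mixed model.

    Categorical effects are stored per level on the sum-to-zero scale
    (each factor's effects sum to zero; ``mu`` carries the grand mean).
    ``ration_blups`` shrink toward zero as ``sigma2_ration`` does.
    """

    mu: float
    ysc_effects: pd.Series
    par_age_effects: pd.Series
    beta_dim: float
    beta_milk_e: float
    beta_mbw: float
    sigma2_ration: float
    sigma2_resid: float
    ration_blups: pd.Series
    converged: bool
    log_likelihood: float
    n_records: int

    @property
    def gamma(self) -> float:
        """Variance ratio sigma_r^2 / sigma_e^2."""
        return self.sigma2_ration / self.sigma2_resid

    def report(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "mu": self.mu,
            "beta_dim": self.beta_dim,
            "beta_milk_e": self.beta_milk_e,
            "beta_mbw": self.beta_mbw,
            "sigma2_ration": self.sigma2_ration,
            "sigma2_resid": self.sigma2_resid,
            "ysc_effects": self.ysc_effects.to_dict(),
            "par_age_effects": self.par_age_effects.to_dict(),
            "ration_blups": self.ration_blups.to_dict(),
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "n_records": self.n_records,
        }


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ModelSpecificationError(f"weekly records lack columns: {missing}")
    if len(records) == 0:
        raise ModelSpecificationError("no weekly records supplied")
    for col in ("dmi", "dim", "milk_e", "mbw"):
        if not np.isfinite(records[col].to_numpy(float)).all():
            raise ModelSpecificationError(f"non-finite values in column {col!r}")
    return records


def _sum_to_zero(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """n × (L−1) sum-to-zero contrast columns for integer level codes."""
    X = np.zeros((len(codes), max(n_levels - 1, 0)))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def _design(
    records: pd.DataFrame,
    ysc_levels: Sequence[str] | None = None,
    par_levels: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Fixed-effect design matrix: intercept | YSC | ParAge | covariates."""

    def codes(col: str, levels: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
        values = records[col].astype(str)
        if levels is None:
            levels = sorted(values.unique())
        lookup = {lv: i for i, lv in enumerate(levels)}
        unseen = sorted(set(values) - set(levels))
        if unseen:
            raise ModelSpecificationError(
                f"unseen {col} levels not present in the fit: {unseen[:5]}"
            )
        return values.map(lookup).to_numpy(int), list(levels)

    ysc_codes, ysc_lv = codes("ysc", ysc_levels)
    par_codes, par_lv = codes("par_age", par_levels)
    blocks = [
        np.ones((len(records), 1)),
        _sum_to_zero(ysc_codes, len(ysc_lv)),
        _sum_to_zero(par_codes, len(par_lv)),
        records[list(_COVARIATES)].to_numpy(float),
    ]
    names = (["mu"]
             + [f"ysc[{lv}]" for lv in ysc_lv[:-1]]
             + [f"par_age[{lv}]" for lv in par_lv[:-1]]
             + list(_COVARIATES))
    return np.hstack(blocks), names, ysc_lv, par_lv


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in np.flatnonzero(diag < tol)]
    if bad:
        raise ModelSpecificationError(
            "fixed-effect design is rank deficient; confounded columns: "
            + ", ".join(bad)
        )


def fit_rfi_model(
    records: pd.DataFrame,
    fix_gamma: float | None = None,
    gamma_upper: float = 1e3,
    tol: float = 1e-8,
) -> RfiModelFit:
    """REML fit of the one-random-effect DMI mixed model.

    Parameters
    ----------
    records : DataFrame with ``REQUIRED_COLUMNS``
        One row per animal-week.
    fix_gamma : float, optional
        Fix the variance ratio sigma_r^2/sigma_e^2 instead of estimating it;
        ``fix_gamma=0`` reduces the fixed effects to ordinary least squares.
    gamma_upper : float
        Upper bound of the profile search.
    tol : float
        Absolute tolerance on gamma in the bounded scalar optimization.
    """
    records = _check_records(records)
    rations = records["ration"].astype(str)
    ration_levels = sorted(rations.unique())
    if len(ration_levels) < 2 and fix_gamma is None:
        raise ModelSpecificationError(
            "need at least 2 ration cohorts to separate cohort and residual "
            "variance; supply fix_gamma to bypass"
        )
    X, names, ysc_lv, par_lv = _design(records)
    _check_rank(X, names)
    y = records["dmi"].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ModelSpecificationError(f"{n} records cannot identify {p} fixed effects")

    group_codes = rations.map({lv: i for i, lv in enumerate(ration_levels)}).to_numpy(int)
    q = len(ration_levels)
    m_k = np.bincount(group_codes, minlength=q).astype(float)
    # per-cohort sufficient statistics
    S = np.zeros((q, p))          # column sums of X per cohort
    np.add.at(S, group_codes, X)
    t = np.bincount(group_codes, weights=y, minlength=q)  # y sums per cohort
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(gamma: float):
        """GLS pieces and restricted log-likelihood at a variance ratio."""
        delta = gamma / (1.0 + gamma * m_k)          # per-cohort V^{-1} correction
        XtVX = XtX - (S * delta[:, None]).T @ S
        XtVy = Xty - S.T @ (delta * t)
        yVy = yty - float(delta @ (t * t))
        beta = np.linalg.solve(XtVX, XtVy)
        quad = yVy - float(XtVy @ beta)              # y' P y
        sigma2 = quad / (n - p)
        logdet_V = float(np.log1p(gamma * m_k).sum())
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        ll = -0.5 * ((n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                     + logdet_V + logdet_XtVX)
        return beta, sigma2, ll

    if fix_gamma is not None:
        if fix_gamma < 0:
            raise ModelSpecificationError("fix_gamma must be nonnegative")
        gamma, converged = float(fix_gamma), True
    else:
        res = optimize.minimize_scalar(
            lambda g: -profile(g)[2],
            bounds=(0.0, gamma_upper), method="bounded",
            options={"xatol": tol},
        )
        gamma = float(res.x)
        converged = bool(res.success)
        if gamma > 0.999 * gamma_upper:
            warnings.warn("REML variance ratio at the search bound; "
                          "estimates may be unreliable", RuntimeWarning)
            converged = False
        if not converged:
            warnings.warn("REML profile optimization did not converge",
                          RuntimeWarning)

    beta, sigma2, ll = profile(gamma)
    resid_fixed = y - X @ beta
    s_k = np.bincount(group_codes, weights=resid_fixed, minlength=q)
    blups = gamma * s_k / (1.0 + gamma * m_k)

    n_ysc, n_par = len(ysc_lv), len(par_lv)
    b_ysc = beta[1:n_ysc]
    b_par = beta[n_ysc:n_ysc + n_par - 1]
    ysc_effects = pd.Series(np.append(b_ysc, -b_ysc.sum()), index=ysc_lv)
    par_effects = pd.Series(np.append(b_par, -b_par.sum()), index=par_lv)
    beta_dim, beta_milk_e, beta_mbw = beta[-3:]

    logger.info("fit_rfi_model: n=%d, gamma=%.4g, sigma2_r=%.4g, sigma2_e=%.4g",
                n, gamma, gamma * sigma2, sigma2)
    return RfiModelFit(
        mu=float(beta[0]),
        ysc_effects=ysc_effects,
        par_age_effects=par_effects,
        beta_dim=float(beta_dim),
        beta_milk_e=float(beta_milk_e),
        beta_mbw=float(beta_mbw),
        sigma2_ration=float(gamma * sigma2),
        sigma2_resid=float(sigma2),
        ration_blups=pd.Series(blups, index=ration_levels),
        converged=converged,
        log_likelihood=float(ll),
        n_records=n,
    )


def weekly_residuals(fit: RfiModelFit, records: pd.DataFrame) -> np.ndarray:
    """Weekly RFI values: observed DMI minus the full fitted mean.

    The fitted mean includes the ration BLUP, so cohort differences are
    removed from the phenotype.  Records with YSC, ParAge or ration levels
    absent from the fit raise; silent zeros would bias the phenotype.
    """
    records = _check_records(records)
    for col, table in (("ysc", fit.ysc_effects),
                       ("par_age", fit.par_age_effects),
                       ("ration", fit.ration_blups)):
        unseen = sorted(set(records[col].astype(str)) - set(table.index))
        if unseen:
            raise ModelSpecificationError(
                f"unseen {col} levels not present in the fit: {unseen[:5]}"
            )
    fitted = (
        fit.mu
        + fit.ysc_effects.reindex(records["ysc"].astype(str)).to_numpy(float)
        + fit.par_age_effects.reindex(records["par_age"].astype(str)).to_numpy(float)
        + fit.beta_dim * records["dim"].to_numpy(float)
        + fit.beta_milk_e * records["milk_e"].to_numpy(float)
        + fit.beta_mbw * records["mbw"].to_numpy(float)
        + fit.ration_blups.reindex(records["ration"].astype(str)).to_numpy(float)
    )
    return records["dmi"].to_numpy(float) - fitted


def aggregate_rfi(records: pd.DataFrame, residuals: np.ndarray) -> pd.DataFrame:
    """Per-animal RFI: arithmetic mean of that animal's weekly residuals.

    Returns a DataFrame ``animal_id, rfi, n_weeks`` (one row per animal
    with at least one record, in order of first appearance).
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(records):
        raise ValueError("residuals and records lengths differ")
    frame = pd.DataFrame({
        "animal_id": records["animal_id"].to_numpy(),
        "resid": residuals,
    })
    grouped = frame.groupby("animal_id", sort=False)["resid"].agg(["mean", "size"])
    out = grouped.reset_index()
    out.columns = ["animal_id", "rfi", "n_weeks"]
    return out


def derive_rfi_phenotypes(
    records: pd.DataFrame, **fit_kwargs
) -> tuple[pd.DataFrame, RfiModelFit]:
    """Fit the model, compute weekly residuals and average them per animal."""
    fit = fit_rfi_model(records, **fit_kwargs)
    resid = weekly_residuals(fit, records)
    return aggregate_rfi(records, resid), fit
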