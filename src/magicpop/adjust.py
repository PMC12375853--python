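"""Phenotype adjustment for augmented field designs.

An augmented design grows each test line once and a small set of checks
(here, the founders) in every block with replication.  Block effects and
the error variance are therefore estimable from the checks alone, and test
lines can be adjusted for design effects they could not estimate by
themselves.  The model is

    y = X beta + P w + Z g + e

with blocks (beta, sum-to-zero coded) and checks (w) fixed and the test
lines g random, g ~ N(0, s2_g I), e ~ N(0, s2_e I), fitted by REML.  Since
every test line is observed once, V is diagonal given the variance ratio
and the restricted likelihood profiles to a one-dimensional search.

The adjusted value of a line is its empirical BLUP plus the grand mean
(default), or, with the lines-fixed BLUE option, its record minus the
check-estimated block effect.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_diag

__all__ = ["AdjustmentModel", "fit_augmented", "detect_outliers"]


@dataclass
class AdjustmentModel:
    """Fitted augmented-design model for one trait."""

    trait: str
    method: str  # "blup" or "blue"
    grand_mean: float
    block_effects: pd.Series  # sum-to-zero coded
    check_effects: pd.Series
    line_effects: pd.Series  # BLUPs (or BLUEs) per test line
    adjusted: pd.Series  # adjusted phenotype per line
    sigma2_g: float
    sigma2_e: float
    wald_block: tuple[float, int, float]  # statistic, df, p-value
    records: pd.DataFrame  # the records used in the fit
    fitted: np.ndarray  # conditional fitted values per record
    residuals: np.ndarray  # conditional residuals per record
    use_row: bool = False

    @property
    def shrinkage(self) -> float:
        g = self.sigma2_g / (self.sigma2_g + self.sigma2_e)
        return g


def _design(records: pd.DataFrame, use_row: bool = False):
    blocks = np.sort(records["block"].unique())
    checks = np.sort(records.loc[records["is_check"], "line_id"].unique())
    lines = np.sort(records.loc[~records["is_check"], "line_id"].unique())
    for b in blocks:
        sub = records[records["block"] == b]
        if not sub["is_check"].any():
            raise ValueError(f"block {b} contains no check records; design effects are not estimable")
    rep = records[records["is_check"]].groupby("line_id").size()
    unreplicated = rep[rep < 2].index.tolist()
    if unreplicated:
        warnings.warn(f"checks with a single replicate: {unreplicated}", stacklevel=2)

    n = len(records)
    block_idx = pd.Categorical(records["block"], categories=blocks).codes
    # sum-to-zero block coding: n_blocks - 1 columns
    Xb = np.zeros((n, len(blocks) - 1))
    for j in range(len(blocks) - 1):
        Xb[block_idx == j, j] = 1.0
    Xb[block_idx == len(blocks) - 1, :] = -1.0
    Xc = np.zeros((n, len(checks)))
    for j, c in enumerate(checks):
        Xc[(records["line_id"] == c).to_numpy() & records["is_check"].to_numpy(), j] = 1.0
    cols = [np.ones(n), Xb, Xc]
    if use_row:
        if "row" not in records.columns:
            raise ValueError("use_row=True requires a 'row' column in the records")
        rows_lv = np.sort(records["row"].unique())
        row_idx = pd.Categorical(records["row"], categories=rows_lv).codes
        Xr = np.zeros((n, len(rows_lv) - 1))
        for j in range(len(rows_lv) - 1):
            Xr[row_idx == j, j] = 1.0
        Xr[row_idx == len(rows_lv) - 1, :] = -1.0
        cols.append(Xr)
    X = np.column_stack(cols)
    is_line = (~records["is_check"]).to_numpy().astype(float)
    return X, is_line, blocks, checks, lines, block_idx


def fit_augmented(
    records: pd.DataFrame,
    trait: str | None = None,
    method: str = "blup",
    use_row: bool = False,
) -> AdjustmentModel:
    """Fit the augmented-design model and adjust line phenotypes.

    Parameters
    ----------
    records
        Tidy table with columns line_id, trait, block, value, is_check.
    trait
        Which trait to fit (required if the table holds several).
    method
        "blup" (lines random; default) or "blue" (lines fixed: blocks and
        checks estimated from check records only, lines adjusted by
        subtracting the estimated block effect).
    use_row
        Include a second fixed field factor from a ``row`` column
        (sum-to-zero coded); off by default.
    """
    if trait is None:
        traits = records["trait"].unique()
        if len(traits) != 1:
            raise ValueError(f"records contain traits {list(traits)}; specify one")
        trait = traits[0]
    rec = records[records["trait"] == trait].reset_index(drop=True)
    if method not in ("blup", "blue"):
        raise ValueError("method must be 'blup' or 'blue'")
    X, is_line, blocks, checks, lines, block_idx = _design(rec, use_row=use_row)
    y = rec["value"].to_numpy(dtype=np.float64)
    n_blocks = len(blocks)

    if method == "blup":
        fit = reml_diag(y, X, is_line)
        beta = fit.beta
        mu = beta[0]
        block_eff = _expand_blocks(beta[1:n_blocks], n_blocks)
        check_eff = beta[n_blocks : n_blocks + len(checks)]
        resid_marg = y - X @ beta
        gamma = fit.gamma
        g = gamma / (1.0 + gamma) * resid_marg * is_line
        sigma2_g, sigma2_e = fit.sigma2_u, fit.sigma2_e
        vcov = fit.vcov_beta
        fitted = X @ beta + g
        line_vals = pd.Series(
            {
                lid: mu + g[i]
                for lid, i, il in zip(rec["line_id"], range(len(rec)), is_line)
                if il
            }
        )
        line_effects = line_vals - mu
    else:
        chk = rec["is_check"].to_numpy()
        Xck = X[chk][:, : n_blocks]  # intercept + blocks
        Xck = np.column_stack([Xck, X[chk][:, n_blocks:]])
        fitck = _ols(y[chk], Xck)
        beta = np.zeros(X.shape[1])
        beta[: n_blocks] = fitck["beta"][: n_blocks]
        beta[n_blocks:] = fitck["beta"][n_blocks:]
        mu = beta[0]
        block_eff = _expand_blocks(beta[1:n_blocks], n_blocks)
        check_eff = beta[n_blocks : n_blocks + len(checks)]
        sigma2_e = fitck["sigma2"]
        sigma2_g = float("nan")
        vcov = fitck["vcov"]
        adj = y - block_eff[block_idx]
        g = np.where(is_line > 0, adj - mu, 0.0)
        # lines are fixed: their records are fitted exactly
        fitted = np.where(is_line > 0, y, X @ beta)
        line_vals = pd.Series(
            {lid: adj[i] for lid, i, il in zip(rec["line_id"], range(len(rec)), is_line) if il}
        )
        line_effects = line_vals - mu

    resid = y - fitted
    # Wald test for the block fixed effects
    bidx = np.arange(1, n_blocks)
    if n_blocks > 1:
        vb = vcov[np.ix_(bidx, bidx)]
        bb = beta[bidx]
        stat = float(bb @ np.linalg.solve(vb, bb))
        df = n_blocks - 1
        pval = float(stats.chi2.sf(stat, df))
    else:
        stat, df, pval = 0.0, 0, 1.0

    return AdjustmentModel(
        trait=trait,
        method=method,
        grand_mean=float(mu),
        block_effects=pd.Series(block_eff, index=blocks),
        check_effects=pd.Series(check_eff, index=checks),
        line_effects=line_effects,
        adjusted=line_vals,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        wald_block=(stat, df, pval),
        records=rec,
        fitted=fitted,
        residuals=resid,
        use_row=use_row,
    )


def _expand_blocks(coef: np.ndarray, n_blocks: int) -> np.ndarray:
    """Sum-to-zero coding back to one effect per block."""
    return np.concatenate([coef, [-coef.sum()]]) if n_blocks > 1 else np.zeros(1)


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    dof = max(len(y) - np.linalg.matrix_rank(X), 1)
    sigma2 = float(r @ r) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    return {"beta": beta, "sigma2": sigma2, "vcov": sigma2 * XtX_inv}


def detect_outliers(
    model: AdjustmentModel,
    sd_threshold: float = 3.0,
) -> tuple[np.ndarray, AdjustmentModel]:
    """Flag records with large standardized conditional residuals and refit.

    A record is flagged when |residual| / sigma_e exceeds ``sd_threshold``;
    the model is refitted once on the remaining records.  Returns the flag
    mask (aligned to ``model.records``) and the refitted model.
    """
    if not np.isfinite(sd_threshold) and sd_threshold > 0:
        return np.zeros(len(model.records), dtype=bool), model
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    z = model.residuals / np.sqrt(model.sigma2_e)
    flags = np.abs(z) > sd_threshold
    if not flags.any():
        return flags, model
    clean = model.records[~flags]
    refit = fit_augmented(clean, trait=model.trait, method=model.method, use_row=model.use_row)
    return flags, refit
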