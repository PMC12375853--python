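"""Profiled REML for single-variance-ratio mixed models.

All mixed models in this package reduce to

    y = X b + u + e,   u ~ N(0, s2_u * G),   e ~ N(0, s2_e * I)

with V = s2_e * (I + gamma * G), gamma = s2_u / s2_e.  When G is diagonal
(or has been diagonalized by rotating y and X with its eigenvectors) the
restricted likelihood profiles down to a one-dimensional search over gamma;
s2_e is then available in closed form.  This covers the augmented-design
adjustment model (G diagonal in the observation basis), RR-BLUP (G = XcXc',
diagonalized spectrally) and the P3D kinship GWAS null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["REMLFit", "reml_diag"]


@dataclass
class REMLFit:
    gamma: float  # variance ratio s2_u / s2_e
    sigma2_u: float
    sigma2_e: float
    beta: np.ndarray  # GLS fixed effects at gamma-hat
    vcov_beta: np.ndarray  # s2_e * (X' W X)^-1
    weights: np.ndarray  # diagonal of (I + gamma*D)^-1
    neg2_reml: float


def _profile(log10_gamma: float, y, X, d, n, p):
    gamma = 10.0**log10_gamma
    w = 1.0 / (1.0 + gamma * d)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    r = y - X @ beta
    quad = float(r @ (w * r))
    quad = max(quad, 1e-300)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    crit = (
        -np.log(w).sum() + logdet_XtWX + (n - p) * np.log(quad)
    )
    return crit, gamma, w, beta, XtWX, quad


def reml_diag(
    y: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    log10_bounds: tuple[float, float] = (-8.0, 8.0),
) -> REMLFit:
    """REML fit of V* = I + gamma * diag(d) by profiled likelihood.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (already rotated if G was dense).
    d
        Diagonal of G in this basis (eigenvalues, or 0/1 indicators).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    d = np.asarray(d, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed effects than observations")

    res = minimize_scalar(
        lambda lg: _profile(lg, y, X, d, n, p)[0],
        bounds=log10_bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    crit, gamma, w, beta, XtWX, quad = _profile(res.x, y, X, d, n, p)
    sigma2_e = quad / (n - p)
    return REMLFit(
        gamma=gamma,
        sigma2_u=gamma * sigma2_e,
        sigma2_e=sigma2_e,
        beta=beta,
        vcov_beta=sigma2_e * np.linalg.inv(XtWX),
        weights=w,
        neg2_reml=crit,
    )
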