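"""Genome-wide association scan, significance calling and QTL merging.

The scan engine is a per-marker linear model with the leading genotype
principal components as covariates to absorb residual structure, with an
optional single-kinship mixed model (VanRaden genomic relationship,
variance components estimated once on the null model and reused per marker
— the "P3D" shortcut).  Associations at or above a -log10(p) threshold are
called significant, and significant markers on the same chromosome whose
pairwise LD reaches a linkage threshold are merged into QTL regions by
single-linkage connected components.

The engine is pluggable: any per-marker result table with columns
(marker_id, chromosome, position_bp, beta, se, minus_log10_p) — e.g. an
external multi-locus scan — can be fed to the calling/merging steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_diag
from .sim import MarkerMap

__all__ = [
    "QTLRegion",
    "gwas_scan",
    "call_significant",
    "merge_qtl",
    "genomic_inflation",
    "vanraden_kinship",
]


def _pcs(dosage: np.ndarray, n_pcs: int) -> np.ndarray:
    W = dosage - dosage.mean(axis=0)
    if n_pcs == 0:
        return np.empty((dosage.shape[0], 0))
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


def vanraden_kinship(dosage: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from centered dosages."""
    d = np.asarray(dosage, dtype=np.float64)
    p = d.mean(axis=0) / 2.0
    W = d - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0:
        raise ValueError("kinship undefined: all markers monomorphic")
    return W @ W.T / c


def gwas_scan(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    mmap: MarkerMap,
    n_pcs: int = 4,
    use_kinship: bool = False,
) -> pd.DataFrame:
    """Per-marker association tests for one trait.

    Returns a table with one row per marker: effect estimate, standard
    error, -log10 p-value and an ``untestable`` flag for constant markers.
    With ``use_kinship`` the null-model variance components are estimated by
    REML on the eigenbasis of the kinship matrix and every marker is tested
    by GLS in that rotated space.
    """
    X = np.asarray(dosage, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = X.shape
    if len(y) != n:
        raise ValueError("phenotype not aligned to dosage rows")
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of lines")
    C = np.column_stack([np.ones(n), _pcs(X, n_pcs)])

    if use_kinship:
        K = vanraden_kinship(X)
        evals, evecs = np.linalg.eigh(K)
        evals = np.clip(evals, 0.0, None)
        yr, Cr = evecs.T @ y, evecs.T @ C
        fit = reml_diag(yr, Cr, evals)
        w = 1.0 / (1.0 + fit.gamma * evals)
        Xr = evecs.T @ X
        beta, se, nlp, untestable = _weighted_marker_tests(yr, Cr, Xr, w)
    else:
        w = np.ones(n)
        beta, se, nlp, untestable = _weighted_marker_tests(y, C, X, w)

    return pd.DataFrame(
        {
            "marker_id": mmap.marker_id,
            "chromosome": mmap.chromosome,
            "position_bp": mmap.position_bp,
            "beta": beta,
            "se": se,
            "minus_log10_p": nlp,
            "untestable": untestable,
        }
    )


def _weighted_marker_tests(y, C, X, w):
    """Vectorized per-marker GLS t-tests with covariates C and weights w.

    Projects the covariates out of y and each marker under the weighted
    inner product, then tests the marker slope; equivalent to fitting
    y ~ C + x_j marker by marker.
    """
    n, m = X.shape
    p = C.shape[1]
    sw = np.sqrt(w)
    Cw = C * sw[:, None]
    yw = y * sw
    Q, _ = np.linalg.qr(Cw)
    y_res = yw - Q @ (Q.T @ yw)
    Xw = X * sw[:, None]
    X_res = Xw - Q @ (Q.T @ Xw)

    xx = np.einsum("ij,ij->j", X_res, X_res)
    untestable = xx <= 1e-12
    xx_safe = np.where(untestable, 1.0, xx)
    xy = X_res.T @ y_res
    beta = xy / xx_safe
    yy = float(y_res @ y_res)
    df = n - p - 1
    rss = np.maximum(yy - beta * xy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / xx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    nlp = -np.log10(np.clip(pvals, 1e-300, None))
    beta[untestable] = np.nan
    se[untestable] = np.nan
    nlp[untestable] = np.nan
    return beta, se, nlp, untestable


def call_significant(results: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Markers at or above the -log10(p) threshold (boundary inclusive)."""
    return results[results["minus_log10_p"] >= threshold].copy()


@dataclass
class QTLRegion:
    """A set of significant markers merged by linkage disequilibrium."""

    trait: str
    chromosome: int
    members: list[str]
    lead_marker: str
    lead_position_bp: int
    lead_minus_log10_p: float
    span_bp: tuple[int, int]

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "chromosome": self.chromosome,
            "n_markers": len(self.members),
            "lead_marker": self.lead_marker,
            "lead_position_bp": self.lead_position_bp,
            "lead_minus_log10_p": self.lead_minus_log10_p,
            "start_bp": self.span_bp[0],
            "end_bp": self.span_bp[1],
            "members": ";".join(self.members),
        }


def merge_qtl(
    significant: pd.DataFrame,
    r2_link: float,
    ld_table: pd.DataFrame | None = None,
    dosage: np.ndarray | None = None,
    mmap: MarkerMap | None = None,
    trait: str = "",
) -> list[QTLRegion]:
    """Merge significant markers into QTL regions by single-linkage LD.

    Two significant markers on the same chromosome are linked when their
    pairwise r^2 is at least ``r2_link``; connected components of the
    linkage graph become QTL regions.  LD is looked up in ``ld_table`` and,
    for pairs absent from it, computed on the fly from ``dosage`` (aligned
    to ``mmap``).  The lead marker maximizes -log10 p, ties broken toward
    the smaller bp position.
    """
    if len(significant) == 0:
        return []
    sig = significant.sort_values(["chromosome", "position_bp"]).reset_index(drop=True)
    k = len(sig)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    ld_lookup = {}
    if ld_table is not None:
        for a, b, r2 in zip(ld_table["marker_a"], ld_table["marker_b"], ld_table["r2"]):
            ld_lookup[(a, b)] = r2
            ld_lookup[(b, a)] = r2
    col = {}
    if mmap is not None:
        col = {mid: j for j, mid in enumerate(mmap.marker_id)}

    for i in range(k):
        for j in range(i + 1, k):
            if sig.loc[i, "chromosome"] != sig.loc[j, "chromosome"]:
                continue
            a, b = sig.loc[i, "marker_id"], sig.loc[j, "marker_id"]
            r2 = ld_lookup.get((a, b))
            if r2 is None:
                if dosage is None or mmap is None:
                    raise ValueError(
                        f"no LD available for pair ({a}, {b}) and no dosages to compute it"
                    )
                xa, xb = dosage[:, col[a]], dosage[:, col[b]]
                r2 = float(np.corrcoef(xa, xb)[0, 1] ** 2)
            if r2 >= r2_link:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    regions = []
    for members in groups.values():
        sub = sig.loc[members].sort_values(
            ["minus_log10_p", "position_bp"], ascending=[False, True]
        )
        lead = sub.iloc[0]
        regions.append(
            QTLRegion(
                trait=trait,
                chromosome=int(lead["chromosome"]),
                members=sig.loc[members, "marker_id"].tolist(),
                lead_marker=lead["marker_id"],
                lead_position_bp=int(lead["position_bp"]),
                lead_minus_log10_p=float(lead["minus_log10_p"]),
                span_bp=(
                    int(sig.loc[members, "position_bp"].min()),
                    int(sig.loc[members, "position_bp"].max()),
                ),
            )
        )
    regions.sort(key=lambda r: (r.chromosome, r.span_bp[0]))
    return regions


def effective_tests(dosage: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of independent tests (simpleM-style).

    Counts the leading eigenvalues of the marker correlation matrix needed
    to explain ``var_explained`` of its total variance — a cheap report for
    readers who prefer an effective-test multiple-testing view over a fixed
    -log10(p) threshold.  Constant markers are ignored.
    """
    d = np.asarray(dosage, dtype=np.float64)
    d = d[:, d.std(axis=0) > 0]
    if d.shape[1] == 0:
        raise ValueError("no polymorphic markers")
    corr = np.corrcoef(d, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    evals = np.clip(evals, 0, None)
    frac = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(frac, var_explained) + 1)


def genomic_inflation(results: pd.DataFrame) -> float:
    """Genomic inflation factor lambda by the median chi-square method."""
    nlp = results["minus_log10_p"].dropna().to_numpy()
    pvals = 10.0 ** (-nlp)
    chi2 = stats.chi2.isf(pvals, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
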