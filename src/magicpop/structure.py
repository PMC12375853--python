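"""Population structure and linkage-disequilibrium characterization.

Rogers genetic distance, classical multidimensional scaling (principal
coordinates), k-means clustering with silhouette-selected k, complete-
linkage ordering for heatmaps, pairwise r-squared LD tables with a physical
distance cap, LOESS LD-decay curves, and MAF/heterozygosity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .sim import MarkerMap

__all__ = [
    "StructureResult",
    "DecayCurve",
    "rogers_distance",
    "classical_mds",
    "cluster_lines",
    "pairwise_ld",
    "ld_decay",
    "maf_het_summary",
]


def rogers_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise Rogers genetic distance between individuals.

    Per locus, an individual's allele-frequency vector is read from its
    dosage (0 -> (1,0); 1 -> (1/2,1/2); 2 -> (0,1)) and the locus
    contributes sqrt(0.5 * sum_alleles (p_i - p_j)^2); the distance is the
    mean contribution over loci.  For biallelic dosages this equals
    mean(|d_i - d_j|) / 2, which is how it is computed here.  Rogers
    distance is a metric with values in [0, 1].
    """
    d = np.asarray(dosage, dtype=np.float64)
    if d.ndim != 2 or d.shape[1] == 0:
        raise ValueError("dosage must be a non-empty 2-D matrix")
    dist = pdist(d, metric="cityblock") / (2.0 * d.shape[1])
    return squareform(dist)


@dataclass
class StructureResult:
    """MDS embedding plus clustering of a distance matrix."""

    coordinates: np.ndarray  # (n, k)
    percent_variance: np.ndarray  # per retained axis
    labels: np.ndarray | None = None
    chosen_k: int | None = None
    dendrogram_order: np.ndarray | None = None
    linkage: np.ndarray | None = None


def classical_mds(dist: np.ndarray, k: int = 4) -> StructureResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and eigendecomposes it;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), and the percent
    variance of an axis is its eigenvalue over the sum of positive
    eigenvalues.  If fewer than ``k`` positive eigenvalues exist the
    embedding is truncated with a warning.
    """
    D = np.asarray(dist, dtype=np.float64)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating embedding from k={k}",
            stacklevel=2,
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pct = 100.0 * evals[:k] / evals[pos].sum()
    return StructureResult(coordinates=coords, percent_variance=pct)


def cluster_lines(dist: np.ndarray, k_range=range(2, 11), n_init: int = 25,
                  random_state: int = 0) -> StructureResult:
    """Cluster individuals from a distance matrix.

    k-means runs on the full classical-MDS embedding for each k in
    ``k_range``; the k with the highest mean silhouette (computed on the
    precomputed distances) wins.  A complete-linkage tree is also built for
    heatmap leaf ordering.  Degenerate input (all points identical) is
    flagged with chosen_k = 1 and a single cluster.
    """
    D = np.asarray(dist, dtype=np.float64)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2: silhouette is undefined for k=1")
    link = complete(squareform(D, checks=False))
    order = leaves_list(link)
    if np.allclose(D, 0):
        return StructureResult(
            coordinates=np.zeros((n, 1)),
            percent_variance=np.array([0.0]),
            labels=np.zeros(n, dtype=int),
            chosen_k=1,
            dendrogram_order=order,
            linkage=link,
        )
    with warnings.catch_warnings():
        # truncation to the available positive eigenvalues is expected here
        warnings.simplefilter("ignore", UserWarning)
        embed = classical_mds(D, k=min(n - 1, 10))
    best = None
    for k in k_range:
        if k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state)
        labels = km.fit_predict(embed.coordinates)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        raise ValueError("no k in k_range produced a valid clustering")
    _, k, labels = best
    return StructureResult(
        coordinates=embed.coordinates,
        percent_variance=embed.percent_variance,
        labels=labels,
        chosen_k=k,
        dendrogram_order=order,
        linkage=link,
    )


def pairwise_ld(
    dosage: np.ndarray,
    mmap: MarkerMap,
    max_dist: int = 50_000_000,
) -> pd.DataFrame:
    """Within-chromosome pairwise LD (r^2) up to a physical distance cap.

    All marker pairs on the same chromosome separated by at most
    ``max_dist`` bp are reported; more distant pairs are treated as
    unlinked and omitted.  r^2 is the squared Pearson correlation of dosage
    vectors.  Pairs involving monomorphic markers are skipped (their count
    is stored in ``df.attrs['n_skipped_monomorphic']``).
    """
    d = np.asarray(dosage, dtype=np.float64)
    rows_chrom, rows_a, rows_b, rows_dist, rows_r2 = [], [], [], [], []
    n_skipped = 0
    for s, e in mmap.chrom_slices():
        block = d[:, s:e]
        bp = mmap.position_bp[s:e]
        sd = block.std(axis=0)
        poly = sd > 0
        m = e - s
        if m < 2:
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(block, rowvar=False)
        iu, ju = np.triu_indices(m, k=1)
        sep = bp[ju] - bp[iu]
        ok_dist = sep <= max_dist
        ok_poly = poly[iu] & poly[ju]
        n_skipped += int((ok_dist & ~ok_poly).sum())
        keep = ok_dist & ok_poly
        rows_chrom.append(np.full(keep.sum(), mmap.chromosome[s]))
        rows_a.append(mmap.marker_id[s:e][iu[keep]])
        rows_b.append(mmap.marker_id[s:e][ju[keep]])
        rows_dist.append(sep[keep])
        rows_r2.append(corr[iu[keep], ju[keep]] ** 2)
    df = pd.DataFrame(
        {
            "chromosome": np.concatenate(rows_chrom) if rows_chrom else [],
            "marker_a": np.concatenate(rows_a) if rows_a else [],
            "marker_b": np.concatenate(rows_b) if rows_b else [],
            "dist_bp": np.concatenate(rows_dist) if rows_dist else [],
            "r2": np.concatenate(rows_r2) if rows_r2 else [],
        }
    )
    df.attrs["n_skipped_monomorphic"] = n_skipped
    return df


@dataclass
class DecayCurve:
    """Smoothed r^2 as a function of physical distance."""

    distance: np.ndarray  # evaluation grid, bp
    r2: np.ndarray  # fitted curve
    decay_distance: float | None  # first crossing of the threshold, or None
    threshold: float

    @property
    def crossed(self) -> bool:
        return self.decay_distance is not None


def ld_decay(
    table: pd.DataFrame,
    loess_span: float = 0.3,
    threshold: float = 0.2,
    grid_size: int = 1000,
) -> DecayCurve:
    """LOESS fit of r^2 on distance and the decay distance at a threshold.

    The decay distance is the smallest grid distance at which the fitted
    curve drops to or below ``threshold`` (located by linear interpolation
    between grid points); if the curve never crosses, ``decay_distance`` is
    None and the curve is flagged as not crossed.
    """
    if len(table) == 0:
        raise ValueError("empty LD table")
    if len(table) < 10:
        raise ValueError("too few LD pairs for LOESS; increase the span or supply more pairs")
    x = table["dist_bp"].to_numpy(dtype=np.float64)
    y = table["r2"].to_numpy(dtype=np.float64)
    # delta makes the smoother linear-time on large tables without visibly
    # changing the fit at genomic scales
    delta = 0.005 * (x.max() - x.min()) if len(x) > 5000 else 0.0
    fitted = lowess(y, x, frac=loess_span, delta=delta, return_sorted=True)
    grid = np.linspace(0.0, x.max(), grid_size)
    curve = np.interp(grid, fitted[:, 0], fitted[:, 1])
    decay = None
    if threshold >= curve[0]:
        decay = 0.0
    else:
        below = np.flatnonzero(curve <= threshold)
        if below.size:
            j = below[0]
            x0, x1 = grid[j - 1], grid[j]
            y0, y1 = curve[j - 1], curve[j]
            decay = x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0) if y0 != y1 else x1
    return DecayCurve(distance=grid, r2=curve, decay_distance=decay, threshold=threshold)


def maf_het_summary(dosage: np.ndarray) -> dict:
    """Mean MAF and observed heterozygosity with per-marker/per-line tables.

    MAF per marker is min(p, 1-p) of the alternate-allele frequency;
    observed heterozygosity per marker is the fraction of dosage-1
    genotypes.  Missing entries are excluded marker-wise.
    """
    d = np.asarray(dosage, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
        isone = np.where(np.isnan(d), np.nan, (d == 1.0).astype(np.float64))
        het_marker = np.nanmean(isone, axis=0)
        het_line = np.nanmean(isone, axis=1)
    m = np.minimum(p, 1 - p)
    return {
        "mean_maf": float(np.nanmean(m)),
        "mean_het": float(np.nanmean(het_marker)),
        "per_marker": pd.DataFrame({"maf": m, "het": het_marker}),
        "per_line": pd.DataFrame({"het": het_line}),
    }
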