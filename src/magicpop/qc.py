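"""Marker curation for SNP dosage matrices.

Filters mirror a standard whole-genome-sequencing QC chain for inbred-line
populations: genotypes below a read-depth floor are set missing, samples
with excessive missingness are dropped, then markers are removed for low
minor allele frequency (boundary inclusive), high missingness or
monomorphism, and finally near-duplicate markers (correlation above a
threshold) are pruned in map order.

Dosage matrices are float arrays (samples x markers) with values in
{0, 1, 2} and NaN marking missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .sim import MarkerMap

__all__ = ["QCConfig", "QCReport", "filter_markers", "prune_correlated", "impute_simple"]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for marker/sample curation.

    Defaults: remove markers with MAF <= 0.01, set genotypes with read depth
    < 5 missing, drop markers missing in > 50% of samples and samples
    missing > 50% of markers, prune markers correlated > 0.99 with an
    already-kept marker.  (An imputation-accuracy filter such as Minimac
    R^2 > 0.95 applies only to reference-panel imputation, which this
    package does not perform; it is recorded here for provenance only.)
    """

    maf_max_remove: float = 0.01
    depth_min: int = 5
    snp_missing_max: float = 0.5
    sample_missing_max: float = 0.5
    corr_prune: float = 0.99

    def __post_init__(self):
        if not 0 <= self.maf_max_remove < 0.5:
            raise ValueError("maf_max_remove must be in [0, 0.5)")
        for name in ("snp_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.corr_prune <= 1:
            raise ValueError("corr_prune must be in (0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts plus surviving indices."""

    n_markers_in: int
    n_samples_in: int
    genotypes_set_missing_depth: int = 0
    samples_removed_missing: int = 0
    markers_removed_maf: int = 0
    markers_removed_missing: int = 0
    markers_removed_monomorphic: int = 0
    markers_removed_correlated: int = 0
    surviving_markers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    surviving_samples: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_markers_out(self) -> int:
        return len(self.surviving_markers)

    @property
    def n_samples_out(self) -> int:
        return len(self.surviving_samples)

    def summary(self) -> dict:
        return {
            "markers_in": self.n_markers_in,
            "samples_in": self.n_samples_in,
            "genotypes_set_missing_depth": self.genotypes_set_missing_depth,
            "samples_removed_missing": self.samples_removed_missing,
            "markers_removed_maf": self.markers_removed_maf,
            "markers_removed_missing": self.markers_removed_missing,
            "markers_removed_monomorphic": self.markers_removed_monomorphic,
            "markers_removed_correlated": self.markers_removed_correlated,
            "markers_out": self.n_markers_out,
            "samples_out": self.n_samples_out,
        }


def _as_float_nan(dosage: np.ndarray) -> np.ndarray:
    d = np.array(dosage, dtype=np.float64, copy=True)
    return d


def maf(dosage: np.ndarray) -> np.ndarray:
    """Per-marker minor allele frequency; missing entries excluded."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_markers(
    dosage: np.ndarray,
    depth: np.ndarray | None = None,
    config: QCConfig | None = None,
) -> tuple[np.ndarray, QCReport]:
    """Apply depth, sample-missingness and marker filters, in that order.

    Order matters and is fixed: (1) genotypes with depth below the floor are
    set missing; (2) samples above the missing-rate cap are dropped; (3) MAF
    and marker missingness are recomputed on the surviving samples and
    markers failing MAF (inclusive boundary), missingness, or monomorphism
    are removed.  Running the filter twice with the same config is a no-op
    on the second pass.

    Returns the filtered matrix and a :class:`QCReport`; surviving indices
    refer to the input axes.
    """
    config = config or QCConfig()
    d = _as_float_nan(dosage)
    n_s, n_m = d.shape
    report = QCReport(n_markers_in=n_m, n_samples_in=n_s)

    if depth is not None:
        depth = np.asarray(depth)
        low = (depth < config.depth_min) & ~np.isnan(d)
        report.genotypes_set_missing_depth = int(low.sum())
        d[low] = np.nan

    sample_missing = np.isnan(d).mean(axis=1)
    keep_s = sample_missing <= config.sample_missing_max
    report.samples_removed_missing = int((~keep_s).sum())
    d = d[keep_s]
    if d.shape[0] == 0:
        raise ValueError("no samples survive the sample missing-rate filter")

    m = maf(d)
    marker_missing = np.isnan(d).mean(axis=0)
    all_missing = marker_missing >= 1.0
    bad_maf = (m <= config.maf_max_remove) & ~all_missing
    bad_missing = marker_missing > config.snp_missing_max
    mono = (m == 0) | all_missing
    # itemize: monomorphic counted separately from the MAF rule
    report.markers_removed_monomorphic = int(mono.sum())
    report.markers_removed_maf = int((bad_maf & ~mono).sum())
    report.markers_removed_missing = int((bad_missing & ~bad_maf & ~mono).sum())
    keep_m = ~(bad_maf | bad_missing | mono)
    if not keep_m.any():
        raise ValueError("no markers survive the marker filters (last rule: MAF/missing/monomorphic)")

    report.surviving_markers = np.flatnonzero(keep_m)
    report.surviving_samples = np.flatnonzero(keep_s)
    return d[:, keep_m], report


def prune_correlated(
    dosage: np.ndarray,
    mmap: MarkerMap | None = None,
    threshold: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy left-to-right redundancy pruning within chromosomes.

    Scanning markers in map order, a marker is dropped when its Pearson
    correlation with any already-kept marker on the same chromosome exceeds
    ``threshold``.  The first marker of every chromosome is always kept.
    Constant markers (undefined correlation) are dropped with a warning.

    Requires complete dosages (impute first).  When ``mmap`` is None all
    markers are treated as one chromosome.

    Returns (pruned matrix, kept indices, dropped indices).
    """
    d = np.asarray(dosage, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("prune_correlated requires complete dosages; impute first")
    n_m = d.shape[1]
    slices = mmap.chrom_slices() if mmap is not None else [(0, n_m)]
    kept: list[int] = []
    dropped: list[int] = []
    for s, e in slices:
        block = d[:, s:e]
        sd = block.std(axis=0)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant marker(s) dropped (correlation undefined)",
                stacklevel=2,
            )
        centered = block - block.mean(axis=0)
        denom = np.where(sd > 0, sd, 1.0) * np.sqrt(block.shape[0])
        z = centered / denom  # unit columns; z_a . z_b = corr(a, b)
        kept_local: list[int] = []
        for j in range(e - s):
            if const[j]:
                dropped.append(s + j)
                continue
            if kept_local:
                r = z[:, kept_local].T @ z[:, j]
                if (r > threshold).any():
                    dropped.append(s + j)
                    continue
            kept_local.append(j)
            kept.append(s + j)
    kept_arr = np.array(kept, dtype=int)
    return d[:, kept_arr], kept_arr, np.array(dropped, dtype=int)


def impute_simple(dosage: np.ndarray) -> np.ndarray:
    """Fill missing genotypes with the marker's modal dosage.

    Ties are broken toward the lower dosage class.  A marker with no
    observed genotype is an error.
    """
    d = _as_float_nan(dosage)
    miss = np.isnan(d)
    if not miss.any():
        return d
    if miss.all(axis=0).any():
        raise ValueError("marker with all genotypes missing cannot be imputed")
    counts = np.stack([(d == v).sum(axis=0) for v in (0.0, 1.0, 2.0)])
    mode = counts.argmax(axis=0).astype(np.float64)  # argmax takes first max: lower dosage
    fill = np.broadcast_to(mode, d.shape)
    d[miss] = fill[miss]
    return d
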