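"""Haplotype-block local-GEBV mapping.

The chain: (1) partition each chromosome's markers into LD blocks with a
tolerance-aware genome scan; (2) estimate all marker effects simultaneously
by RR-BLUP; (3) sum effects within blocks to get per-line and per-haplotype
"local" genomic estimated breeding values (GEBVs); (4) rank blocks by the
variance of their haplotypes' local GEBVs — high-variance blocks flag QTL;
(5) catalogue haplotypes with frequency classes, test their phenotypic
effects, and analyze in-silico stacking of desirable haplotypes at the
top-variance blocks.

Lines are assumed near-homozygous (inbred); haplotype identity is the exact
dosage string over a block's markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_diag
from .sim import MarkerMap

__all__ = [
    "LDBlockSet",
    "RidgeModel",
    "LocalGEBVMatrix",
    "HaplotypeCatalog",
    "build_ld_blocks",
    "fit_rrblup",
    "local_gebv",
    "catalog_haplotypes",
    "block_variance",
    "haplotype_anova",
    "stack_haplotypes",
]


@dataclass
class LDBlockSet:
    """An exhaustive partition of each chromosome's markers into LD blocks.

    ``blocks`` holds global marker-index arrays, contiguous in map order;
    singleton blocks are allowed.  Block ids are ``b000001`` ... in genome
    order.
    """

    blocks: list[np.ndarray]
    map: MarkerMap
    r2_threshold: float = 0.5
    tolerance: int = 3

    @property
    def block_ids(self) -> list[str]:
        return [f"b{i + 1:06d}" for i in range(len(self.blocks))]

    def marker_to_block(self) -> np.ndarray:
        out = np.empty(self.map.n_markers, dtype=np.int64)
        for b, idx in enumerate(self.blocks):
            out[idx] = b
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bid, idx in zip(self.block_ids, self.blocks):
            rows.append(
                {
                    "block_id": bid,
                    "chromosome": int(self.map.chromosome[idx[0]]),
                    "start_bp": int(self.map.position_bp[idx[0]]),
                    "end_bp": int(self.map.position_bp[idx[-1]]),
                    "n_markers": len(idx),
                }
            )
        return pd.DataFrame(rows)


def build_ld_blocks(
    dosage: np.ndarray,
    mmap: MarkerMap,
    r2_threshold: float = 0.5,
    t: int = 3,
) -> LDBlockSet:
    """Genome scan grouping markers into LD blocks with marker tolerance.

    Per chromosome, scanning left to right: a new block is seeded when an
    adjacent marker pair reaches ``r2_threshold``; the block then extends
    rightward while candidate flanking markers have r^2 >= threshold with
    the block's current outer (rightmost passing) member.  A failing
    flanker is tolerated — included in the block — provided a passing
    marker occurs within the next ``t`` candidates; after more than ``t``
    consecutive failures the block closes at its last passing member and
    the scan resumes with the first unassigned marker.  Markers never
    absorbed into a block become singleton blocks, so the blocks partition
    every chromosome.
    """
    d = np.asarray(dosage, dtype=np.float64)
    blocks: list[np.ndarray] = []
    for s, e in mmap.chrom_slices():
        sub = d[:, s:e]
        m = e - s
        if m == 1:
            blocks.append(np.array([s]))
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        r2 = np.nan_to_num(corr, nan=0.0) ** 2

        i = 0
        while i < m:
            if i + 1 < m and r2[i, i + 1] >= r2_threshold:
                block = [i, i + 1]
                outer = i + 1
                fails: list[int] = []
                j = i + 2
                while j < m:
                    if r2[j, outer] >= r2_threshold:
                        block.extend(fails)
                        fails = []
                        block.append(j)
                        outer = j
                    else:
                        fails.append(j)
                        if len(fails) > t:
                            break
                    j += 1
                blocks.append(np.array(sorted(block)) + s)
                i = outer + 1
            else:
                blocks.append(np.array([i + s]))
                i += 1
    return LDBlockSet(blocks=blocks, map=mmap, r2_threshold=r2_threshold, tolerance=t)


@dataclass
class RidgeModel:
    """RR-BLUP marker-effect model: y = mu + X u + e, u ~ N(0, s2_u I)."""

    intercept: float
    effects: np.ndarray  # shrinkage estimate per marker
    lam: float  # ridge parameter s2_e / s2_u
    sigma2_u: float
    sigma2_e: float
    marker_means: np.ndarray

    def predict(self, dosage: np.ndarray) -> np.ndarray:
        return self.intercept + (np.asarray(dosage, float) - self.marker_means) @ self.effects

    def genomic_values(self, dosage: np.ndarray) -> np.ndarray:
        """Total genomic value sum_j x_ij u_j on the raw dosage scale."""
        return np.asarray(dosage, float) @ self.effects


def fit_rrblup(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    lam: float | None = None,
) -> RidgeModel:
    """Estimate all marker effects simultaneously by ridge regression BLUP.

    With centered dosages Xc, u-hat = Xc' (Xc Xc' + lam I)^-1 (y - ybar)
    (dual form) which equals (Xc'Xc + lam I)^-1 Xc' (y - ybar) (primal);
    the cheaper of the two is used.  Unless ``lam`` is supplied, the ridge
    parameter is s2_e / s2_u from REML on the equivalent one-component
    mixed model, computed on the spectral decomposition of Xc Xc'.
    """
    X = np.asarray(dosage, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = X.shape
    mu = float(y.mean())
    means = X.mean(axis=0)
    Xc = X - means
    yc = y - mu

    if lam is None:
        G = Xc @ Xc.T
        evals, evecs = np.linalg.eigh(G)
        evals = np.clip(evals, 0.0, None)
        fit = reml_diag(evecs.T @ y, evecs.T @ np.ones((n, 1)), evals)
        sigma2_u, sigma2_e = fit.sigma2_u, fit.sigma2_e
        lam = sigma2_e / max(sigma2_u, 1e-12)
    else:
        if lam <= 0:
            raise ValueError("ridge parameter must be positive")
        sigma2_u = sigma2_e = float("nan")

    if n <= m:  # dual (n-dimensional) normal equations
        u = Xc.T @ np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
    else:  # primal
        u = np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
    return RidgeModel(
        intercept=mu,
        effects=u,
        lam=float(lam),
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        marker_means=means,
    )


@dataclass
class LocalGEBVMatrix:
    """Per-line, per-block sums of estimated marker effects.

    local GEBV(i, b) = sum_{j in b} x_ij u_j on the raw dosage scale; rows
    over blocks sum exactly to the line's total genomic value.
    """

    values: np.ndarray  # (n_lines, n_blocks)
    blocks: LDBlockSet

    def total(self) -> np.ndarray:
        return self.values.sum(axis=1)


def local_gebv(model: RidgeModel, blocks: LDBlockSet, dosage: np.ndarray) -> LocalGEBVMatrix:
    """Sum predicted allelic effects within every LD block for every line."""
    d = np.asarray(dosage, dtype=np.float64)
    if d.shape[1] != blocks.map.n_markers:
        raise ValueError("dosage and block set refer to different marker sets")
    if len(model.effects) != blocks.map.n_markers:
        raise ValueError("model and block set refer to different marker sets")
    vals = np.empty((d.shape[0], len(blocks.blocks)))
    for b, idx in enumerate(blocks.blocks):
        vals[:, b] = d[:, idx] @ model.effects[idx]
    return LocalGEBVMatrix(values=vals, blocks=blocks)


@dataclass
class HaplotypeCatalog:
    """Distinct dosage-string haplotypes per block with frequency classes.

    Classes follow strict cut-offs on carrier counts: high when more than
    ``high_min`` lines carry the haplotype, medium when more than
    ``medium_min``, rare otherwise.
    """

    blocks: LDBlockSet
    line_haplotype: np.ndarray  # (n_lines, n_blocks) haplotype index per line
    haplotypes: list[list[tuple]]  # per block: dosage strings, index-aligned
    counts: list[np.ndarray]  # per block: carrier counts
    high_min: int = 70
    medium_min: int = 10

    def frequency_class(self, block: int, hap: int) -> str:
        c = self.counts[block][hap]
        if c > self.high_min:
            return "high"
        if c > self.medium_min:
            return "medium"
        return "rare"

    def to_frame(self, gebvs: LocalGEBVMatrix | None = None) -> pd.DataFrame:
        rows = []
        ids = self.blocks.block_ids
        for b, (haps, cnts) in enumerate(zip(self.haplotypes, self.counts)):
            for h, (hap, c) in enumerate(zip(haps, cnts)):
                row = {
                    "block_id": ids[b],
                    "haplotype": "".join(str(int(x)) for x in hap),
                    "count": int(c),
                    "frequency": float(c) / self.line_haplotype.shape[0],
                    "class": self.frequency_class(b, h),
                }
                rows.append(row)
        return pd.DataFrame(rows)


def catalog_haplotypes(
    blocks: LDBlockSet,
    dosage: np.ndarray,
    high_min: int = 70,
    medium_min: int = 10,
) -> HaplotypeCatalog:
    """Tally the exact dosage strings observed in each block."""
    d = np.asarray(dosage)
    n = d.shape[0]
    line_hap = np.empty((n, len(blocks.blocks)), dtype=np.int64)
    haplotypes, counts = [], []
    for b, idx in enumerate(blocks.blocks):
        sub = d[:, idx]
        uniq, inv, cnt = np.unique(sub, axis=0, return_inverse=True, return_counts=True)
        line_hap[:, b] = inv
        haplotypes.append([tuple(row) for row in uniq])
        counts.append(cnt)
    return HaplotypeCatalog(
        blocks=blocks,
        line_haplotype=line_hap,
        haplotypes=haplotypes,
        counts=counts,
        high_min=high_min,
        medium_min=medium_min,
    )


def haplotype_gebvs(model: RidgeModel, catalog: HaplotypeCatalog) -> list[np.ndarray]:
    """Local GEBV of every distinct haplotype in every block."""
    out = []
    for idx, haps in zip(catalog.blocks.blocks, catalog.haplotypes):
        eff = model.effects[idx]
        out.append(np.array([np.asarray(h, float) @ eff for h in haps]))
    return out


def block_variance(
    gebvs: LocalGEBVMatrix,
    catalog: HaplotypeCatalog,
    model: RidgeModel,
    weighted: bool = False,
) -> pd.DataFrame:
    """Variance of each block's haplotype local GEBVs, ranked descending.

    By default the variance is taken across the distinct haplotypes
    (unweighted, population variance); the frequency-weighted option
    weights each haplotype by its carrier count, which equals the variance
    of per-line local GEBVs.
    """
    hap_vals = haplotype_gebvs(model, catalog)
    frame = catalog.blocks.to_frame()
    variances = []
    for vals, cnts in zip(hap_vals, catalog.counts):
        if len(vals) < 2:
            variances.append(0.0)
        elif weighted:
            w = cnts / cnts.sum()
            mu = float(w @ vals)
            variances.append(float(w @ (vals - mu) ** 2))
        else:
            variances.append(float(np.var(vals)))
    frame["variance"] = variances
    frame["rank"] = (
        frame["variance"].rank(ascending=False, method="first").astype(int)
    )
    return frame.sort_values("rank").reset_index(drop=True)


def haplotype_anova(
    catalog: HaplotypeCatalog,
    block: int,
    phenotype: np.ndarray,
    min_carriers: int = 2,
) -> dict:
    """One-way linear-model F test of phenotype on haplotype identity.

    Haplotypes with fewer than ``min_carriers`` carriers are excluded from
    the test (but reported with their means).  A block with fewer than two
    testable haplotypes returns a flagged, test-free result.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    hap_of_line = catalog.line_haplotype[:, block]
    n_h = len(catalog.haplotypes[block])
    means = pd.Series(
        {h: float(y[hap_of_line == h].mean()) for h in range(n_h) if (hap_of_line == h).any()}
    )
    groups = [y[hap_of_line == h] for h in range(n_h) if (hap_of_line == h).sum() >= min_carriers]
    if len(groups) < 2:
        return {"means": means, "F": None, "p": None, "testable": False}
    F, p = stats.f_oneway(*groups)
    return {"means": means, "F": float(F), "p": float(p), "testable": True}


@dataclass
class StackingResult:
    """Counts of desirable haplotypes per line over the top-k blocks."""

    counts: np.ndarray  # per line, in [0, k]
    top_blocks: list[int]
    direction: str
    per_count: pd.DataFrame  # phenotype summaries per stack count
    slope: float | None
    slope_p: float | None

    @property
    def trend_defined(self) -> bool:
        return self.slope is not None


def stack_haplotypes(
    catalog: HaplotypeCatalog,
    variance_table: pd.DataFrame,
    model: RidgeModel,
    phenotype: np.ndarray,
    direction: str = "negative",
    top_k: int = 10,
) -> StackingResult:
    """In-silico stacking of desirable haplotypes at the top-variance blocks.

    A line carries a desirable haplotype at a block when its haplotype's
    local GEBV has the requested sign (negative for earlier flowering,
    positive for taller stature).  Lines are scored by how many of the
    ``top_k`` highest-variance blocks carry a desirable haplotype, and the
    linear trend of phenotype on stack count is reported; the trend is
    undefined when all lines share one count.
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    y = np.asarray(phenotype, dtype=np.float64)
    ids = catalog.blocks.block_ids
    id_to_idx = {bid: i for i, bid in enumerate(ids)}
    ranked = variance_table.sort_values("rank")["block_id"].tolist()
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} available blocks; truncating",
            stacklevel=2,
        )
        top_k = len(ranked)
    top_blocks = [id_to_idx[b] for b in ranked[:top_k]]

    hap_vals = haplotype_gebvs(model, catalog)
    sign = -1.0 if direction == "negative" else 1.0
    counts = np.zeros(catalog.line_haplotype.shape[0], dtype=np.int64)
    for b in top_blocks:
        desirable = sign * hap_vals[b] > 0
        counts += desirable[catalog.line_haplotype[:, b]]

    per_count = (
        pd.DataFrame({"count": counts, "value": y})
        .groupby("count")["value"]
        .agg(["size", "mean", "std"])
        .reset_index()
    )
    if len(np.unique(counts)) < 2:
        slope = slope_p = None
    else:
        res = stats.linregress(counts, y)
        slope, slope_p = float(res.slope), float(res.pvalue)
    return StackingResult(
        counts=counts,
        top_blocks=top_blocks,
        direction=direction,
        per_count=per_count,
        slope=slope,
        slope_p=slope_p,
    )
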