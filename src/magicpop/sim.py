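"""Simulation of eight-founder MAGIC populations.

A MAGIC (multi-parent advanced generation intercross) population is built by
intercrossing a set of founders in a structured funnel — two-way, four-way,
then eight-way crosses — followed by several generations of selfing under
single seed descent (SSD).  This module generates such populations in silico
with complete ground truth: phased genotypes, per-haplotype founder-origin
tracking, the crossing pedigree, quantitative-trait architectures, and an
augmented field trial with replicated founder checks.

The default configuration mirrors a chickpea MAGIC resource: 8 homozygous
founders, 28 two-way / 14 four-way / 7 eight-way crosses, 8 SSD generations,
1135 inbred lines, and ~4255 biallelic SNPs spread over 8 chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "FounderPanel",
    "PedigreeDesign",
    "SimulatedPopulation",
    "TraitArchitecture",
    "FieldDesign",
    "default_marker_map",
    "simulate_founders",
    "build_funnel",
    "meiosis",
    "simulate_population",
    "make_trait_architectures",
    "simulate_phenotypes",
]

# Physical chromosome sizes (bp) of the chickpea (desi/kabuli) reference,
# Ca1..Ca8, used as the default genome scaffold.
CHICKPEA_CHROM_BP = (
    48_360_000,
    36_630_000,
    39_990_000,
    49_190_000,
    48_170_000,
    59_460_000,
    48_960_000,
    16_480_000,
)

#: default uniform recombination rate, centiMorgan per megabase
DEFAULT_CM_PER_MB = 1.2


@dataclass(frozen=True)
class MarkerMap:
    """Genome coordinates for a set of biallelic SNP markers.

    Markers must be sorted by (chromosome, position_bp); physical positions
    are 1-based and strictly increasing within a chromosome, genetic
    positions (cM) non-decreasing.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    position_cM: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "position_bp", np.asarray(self.position_bp, dtype=np.int64))
        object.__setattr__(self, "position_cM", np.asarray(self.position_cM, dtype=np.float64))
        n = len(self.marker_id)
        if not (len(self.chromosome) == len(self.position_bp) == len(self.position_cM) == n):
            raise ValueError("MarkerMap fields must have equal length")
        if len(np.unique(self.marker_id)) != n:
            raise ValueError("marker ids must be unique")
        if np.any(np.diff(self.chromosome) < 0):
            raise ValueError("markers must be sorted by chromosome")
        if np.any(self.position_bp < 1):
            raise ValueError("position_bp is 1-based and must be >= 1")
        for s, e in self.chrom_slices():
            if np.any(np.diff(self.position_bp[s:e]) <= 0):
                raise ValueError("position_bp must be strictly increasing within a chromosome")
            if np.any(np.diff(self.position_cM[s:e]) < 0):
                raise ValueError("position_cM must be non-decreasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slices(self) -> list[tuple[int, int]]:
        """(start, end) index ranges of each chromosome, in map order."""
        cached = getattr(self, "_chrom_slices", None)
        if cached is None:
            bounds = np.flatnonzero(np.diff(self.chromosome)) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [len(self.chromosome)]])
            cached = list(zip(starts.tolist(), ends.tolist()))
            object.__setattr__(self, "_chrom_slices", cached)
        return cached

    def subset(self, idx) -> "MarkerMap":
        """A new map restricted to the given marker indices (map order)."""
        idx = np.asarray(idx)
        return MarkerMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.position_bp[idx],
            self.position_cM[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "position_cM": self.position_cM,
            }
        )


@dataclass(frozen=True)
class FounderPanel:
    """Fully homozygous founders: one haplotype per founder suffices."""

    founder_ids: tuple[str, ...]
    haplotypes: np.ndarray  # (n_founders, n_markers) alleles in {0,1}
    map: MarkerMap

    def __post_init__(self):
        haps = np.asarray(self.haplotypes, dtype=np.uint8)
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "founder_ids", tuple(self.founder_ids))
        if haps.shape != (len(self.founder_ids), self.map.n_markers):
            raise ValueError("haplotypes must be (n_founders, n_markers)")
        if not np.isin(haps, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def polymorphic(self) -> np.ndarray:
        """Boolean mask of markers segregating among the founders."""
        return self.haplotypes.min(axis=0) != self.haplotypes.max(axis=0)


@dataclass(frozen=True)
class PedigreeDesign:
    """Funnel crossing design: two-way -> four-way -> eight-way.

    ``four_way`` holds index pairs into ``two_way``; ``eight_way`` index
    pairs into ``four_way``.  For fewer than eight founders the deepest
    non-empty tier is the terminal cross.
    """

    founder_ids: tuple[str, ...]
    two_way: tuple[tuple[int, int], ...]
    four_way: tuple[tuple[int, int], ...]
    eight_way: tuple[tuple[int, int], ...]
    ssd_generations: int = 8

    def terminal_crosses(self) -> list[frozenset[int]]:
        """Founder index sets of each terminal (deepest-tier) cross."""
        out = []
        if self.eight_way:
            for fw_a, fw_b in self.eight_way:
                out.append(self._fourway_founders(fw_a) | self._fourway_founders(fw_b))
        elif self.four_way:
            for fw in range(len(self.four_way)):
                out.append(self._fourway_founders(fw))
        else:
            out = [frozenset(p) for p in self.two_way]
        return [frozenset(s) for s in out]

    def _fourway_founders(self, i: int) -> set[int]:
        a, b = self.four_way[i]
        return set(self.two_way[a]) | set(self.two_way[b])

    @property
    def n_funnels(self) -> int:
        return len(self.terminal_crosses())


def build_funnel(founder_ids, rng: np.random.Generator | None = None) -> PedigreeDesign:
    """Construct the funnel crossing design by 1-factorization of K_n.

    The round-robin (circle) method partitions the n(n-1)/2 founder pairs
    into n-1 perfect matchings.  Each matching's disjoint pairs become
    two-way crosses; consecutive pairs within a matching are combined into
    four-way crosses, and (for n = 8) the matching's two four-ways into one
    eight-way.  For n = 8 this yields exactly 28 two-way, 14 four-way and
    7 eight-way crosses, every founder pair crossed once, and every funnel
    containing all eight founders.
    """
    founder_ids = tuple(str(f) for f in founder_ids)
    n = len(founder_ids)
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(
            f"number of founders must be a power of two >= 2, got {n}: "
            "the funnel pairs crosses at every tier"
        )
    order = np.arange(n)
    if rng is not None:
        order = rng.permutation(n)
    if n == 2:
        return PedigreeDesign(founder_ids, ((int(order[0]), int(order[1])),), (), ())

    # circle method: fix one vertex, rotate the rest
    circle = list(range(n))
    two_way: list[tuple[int, int]] = []
    four_way: list[tuple[int, int]] = []
    eight_way: list[tuple[int, int]] = []
    for _ in range(n - 1):
        matching = [(circle[i], circle[n - 1 - i]) for i in range(n // 2)]
        pair_ids = []
        for a, b in matching:
            two_way.append((int(order[a]), int(order[b])))
            pair_ids.append(len(two_way) - 1)
        fw_ids = []
        for i in range(0, len(pair_ids) - 1, 2):
            four_way.append((pair_ids[i], pair_ids[i + 1]))
            fw_ids.append(len(four_way) - 1)
        for i in range(0, len(fw_ids) - 1, 2):
            eight_way.append((fw_ids[i], fw_ids[i + 1]))
        circle = [circle[0]] + [circle[-1]] + circle[1:-1]
    return PedigreeDesign(founder_ids, tuple(two_way), tuple(four_way), tuple(eight_way))


def default_marker_map(
    n_markers: int = 4255,
    rng: np.random.Generator | None = None,
    chrom_bp=CHICKPEA_CHROM_BP,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> MarkerMap:
    """Random marker placement across chromosomes, proportional to length."""
    rng = np.random.default_rng() if rng is None else rng
    chrom_bp = np.asarray(chrom_bp, dtype=np.int64)
    probs = chrom_bp / chrom_bp.sum()
    counts = rng.multinomial(n_markers, probs)
    counts = np.maximum(counts, 2)  # every chromosome carries markers
    chroms, bps = [], []
    for c, (k, L) in enumerate(zip(counts, chrom_bp), start=1):
        # draw-with-top-up instead of permuting the full 1..L range
        pos = np.unique(rng.integers(1, L + 1, size=k))
        while len(pos) < k:
            extra = rng.integers(1, L + 1, size=k - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(k, c))
        bps.append(pos)
    chromosome = np.concatenate(chroms)
    position_bp = np.concatenate(bps)
    position_cM = position_bp / 1e6 * cm_per_mb
    ids = np.array(
        [f"M{c}.{p}" for c, p in zip(chromosome, position_bp)], dtype=object
    )
    return MarkerMap(ids, chromosome, position_bp, position_cM)


def simulate_founders(
    mmap: MarkerMap,
    rng: np.random.Generator,
    founder_ids=None,
    n_founders: int = 8,
    beta_a: float = 1.0,
    beta_b: float = 1.0,
    ld_length_bp: float = 1_000_000.0,
) -> FounderPanel:
    """Draw homozygous founder haplotypes with local haplotype sharing.

    Each marker gets a founder-level allele frequency p ~ Beta(a, b) and the
    founders draw alleles Bernoulli(p), producing a realistic frequency
    spectrum with conserved (even monomorphic) regions; monomorphic markers
    are meant to be removed downstream by QC.

    Real founder panels carry linkage disequilibrium of their own — related
    germplasm shares chromosome segments — without which even completely
    linked markers would be nearly uncorrelated in the derived population
    (eight independent haplotypes cap r-squared near 1/7).  This is
    emulated by a copy-down process along each chromosome: a founder reuses
    its previous allele with probability exp(-distance / ld_length_bp),
    otherwise draws afresh.  Set ``ld_length_bp`` to 0 for independent
    markers.
    """
    if founder_ids is None:
        founder_ids = tuple(f"F{i + 1}" for i in range(n_founders))
    n = len(founder_ids)
    p = rng.beta(beta_a, beta_b, size=mmap.n_markers)
    fresh = (rng.random((n, mmap.n_markers)) < p).astype(np.uint8)
    if ld_length_bp <= 0:
        return FounderPanel(tuple(founder_ids), fresh, mmap)
    haps = np.empty_like(fresh)
    for s, e in mmap.chrom_slices():
        haps[:, s] = fresh[:, s]
        bp = mmap.position_bp[s:e]
        for j in range(s + 1, e):
            keep = rng.random(n) < np.exp(-(bp[j - s] - bp[j - s - 1]) / ld_length_bp)
            haps[:, j] = np.where(keep, haps[:, j - 1], fresh[:, j])
    return FounderPanel(tuple(founder_ids), haps, mmap)


def meiosis(
    alleles: np.ndarray,
    origin: np.ndarray,
    mmap: MarkerMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete from a phased parent under the Haldane model.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome's genetic length in Morgans, crossover positions uniform on
    the genetic map, no interference; the starting haplotype is chosen with
    probability 1/2 per chromosome.  Founder-origin labels travel with the
    alleles.

    Parameters
    ----------
    alleles, origin : (2, n_markers) arrays
        The parent's two haplotypes and their founder-origin labels.
    """
    slices = mmap.chrom_slices()
    cm = mmap.position_cM
    # work in a global coordinate where chromosomes are far apart so a single
    # searchsorted handles the whole genome
    phase = np.empty(mmap.n_markers, dtype=np.int64)
    xo_all = []
    offset = 0.0
    gcoord = np.empty(mmap.n_markers)
    starts = rng.integers(0, 2, size=len(slices))
    for (s, e), st in zip(slices, starts):
        lo, hi = cm[s], cm[e - 1]
        length_morgan = (hi - lo) / 100.0
        k = rng.poisson(length_morgan) if length_morgan > 0 else 0
        gcoord[s:e] = cm[s:e] - lo + offset
        if k:
            xo_all.append(rng.uniform(0.0, hi - lo, size=k) + offset)
        phase[s:e] = st
        offset += (hi - lo) + 1e9  # gap >> any chromosome length
    xo = np.sort(np.concatenate(xo_all)) if xo_all else np.empty(0)
    phase = (phase + np.searchsorted(xo, gcoord, side="left")) % 2
    idx = np.arange(mmap.n_markers)
    return alleles[phase, idx], origin[phase, idx]


@dataclass
class SimulatedPopulation:
    """A simulated cohort of MAGIC lines with full founder-origin truth."""

    line_ids: list[str]
    dosage: np.ndarray  # (n_lines, n_markers) in {0,1,2}
    origin: np.ndarray  # (n_lines, 2, n_markers) founder index per haplotype
    haplotypes: np.ndarray  # (n_lines, 2, n_markers) alleles in {0,1}
    pedigree_id: list[int]  # terminal-cross (funnel) index per line
    map: MarkerMap
    founders: FounderPanel
    missing: np.ndarray | None = None  # optional (n_lines, n_markers) bool mask

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def founder_contributions(self) -> np.ndarray:
        """(n_lines, n_founders) fraction of each line's genome per founder.

        Computed from the origin labels over both haplotypes; rows sum to 1.
        """
        n_f = self.founders.n_founders
        flat = self.origin.reshape(self.n_lines, -1)
        counts = np.stack([(flat == f).sum(axis=1) for f in range(n_f)], axis=1)
        return counts / flat.shape[1]

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of heterozygous markers."""
        return (self.dosage == 1).mean(axis=1)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids, columns=self.map.marker_id)


def _founder_individual(panel: FounderPanel, f: int):
    al = np.broadcast_to(panel.haplotypes[f], (2, panel.map.n_markers)).copy()
    orig = np.full((2, panel.map.n_markers), f, dtype=np.uint8)
    return al, orig


def _cross(parent_a, parent_b, mmap, rng):
    al_a, or_a = meiosis(*parent_a, mmap, rng)
    al_b, or_b = meiosis(*parent_b, mmap, rng)
    return np.stack([al_a, al_b]), np.stack([or_a, or_b])


def simulate_population(
    founders: FounderPanel,
    design: PedigreeDesign,
    n_lines: int = 1135,
    rng: np.random.Generator | None = None,
    missing_rate: float = 0.0,
    mean_depth: float | None = None,
) -> SimulatedPopulation | tuple[SimulatedPopulation, np.ndarray]:
    """Simulate inbred lines descending through the funnel and SSD selfing.

    Two-way F1s are deterministic (both parents homozygous); below that
    tier every line descends through independent meioses — its own four-way
    F1 plants, its own terminal-cross F1, and ``design.ssd_generations``
    rounds of selfing — so lines are independent draws from the funnel and
    the per-founder genome share has expectation 1/8.  Lines are
    distributed across funnels as evenly as possible.  Optionally a missing mask (rate ``missing_rate``) and a
    per-genotype Poisson read-depth matrix (``mean_depth``) are generated so
    depth/missingness QC filters can be exercised.

    Returns the population, plus the depth matrix when ``mean_depth`` is set.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    mmap = founders.map
    import warnings

    terminals = design.terminal_crosses()
    n_fun = len(terminals)
    if n_lines < n_fun:
        warnings.warn(
            f"n_lines={n_lines} < {n_fun} funnels; only the first {n_lines} "
            "funnels contribute lines",
            stacklevel=2,
        )

    # one F1 individual per two-way and four-way cross
    two_f1 = []
    for a, b in design.two_way:
        al = np.stack([founders.haplotypes[a], founders.haplotypes[b]])
        orig = np.stack(
            [
                np.full(mmap.n_markers, a, dtype=np.uint8),
                np.full(mmap.n_markers, b, dtype=np.uint8),
            ]
        )
        two_f1.append((al, orig))
    def _terminal_f1(fun: int):
        """Fresh meioses down the funnel: one terminal-cross F1 individual."""
        if design.eight_way:
            fw_a, fw_b = design.eight_way[fun]
            pa = _cross(two_f1[design.four_way[fw_a][0]], two_f1[design.four_way[fw_a][1]], mmap, rng)
            pb = _cross(two_f1[design.four_way[fw_b][0]], two_f1[design.four_way[fw_b][1]], mmap, rng)
        elif design.four_way:
            pa, pb = (two_f1[j] for j in design.four_way[fun])
        else:
            a, b = design.two_way[fun]
            pa, pb = _founder_individual(founders, a), _founder_individual(founders, b)
        return _cross(pa, pb, mmap, rng)

    n_m = mmap.n_markers
    dosage = np.empty((n_lines, n_m), dtype=np.uint8)
    origin = np.empty((n_lines, 2, n_m), dtype=np.uint8)
    haps = np.empty((n_lines, 2, n_m), dtype=np.uint8)
    pedigree = []
    for i in range(n_lines):
        fun = i % n_fun
        pedigree.append(fun)
        ind = _terminal_f1(fun)
        for _ in range(design.ssd_generations):
            ind = _cross(ind, ind, mmap, rng)
        al, orig = ind
        haps[i] = al
        origin[i] = orig
        dosage[i] = al.sum(axis=0)

    line_ids = [f"MAGIC{i + 1:04d}" for i in range(n_lines)]
    missing = None
    if missing_rate > 0:
        missing = rng.random((n_lines, n_m)) < missing_rate
    pop = SimulatedPopulation(
        line_ids, dosage, origin, haps, pedigree, mmap, founders, missing
    )
    if mean_depth is not None:
        depth = rng.poisson(mean_depth, size=(n_lines, n_m))
        return pop, depth
    return pop


@dataclass
class TraitArchitecture:
    """Additive QTL architecture for one quantitative trait.

    Effects are in real trait units (days for flowering time, cm for plant
    height); ``pleiotropic`` flags QTL shared with the companion trait.
    """

    trait: str
    qtl_indices: np.ndarray
    effects: np.ndarray
    heritability: float
    grand_mean: float
    pleiotropic: np.ndarray = field(default=None)

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.pleiotropic is None:
            self.pleiotropic = np.zeros(len(self.qtl_indices), dtype=bool)
        self.pleiotropic = np.asarray(self.pleiotropic, dtype=bool)
        if not 0 < self.heritability <= 1:
            raise ValueError("heritability must be in (0, 1]")
        if len(self.effects) != len(self.qtl_indices):
            raise ValueError("one effect per QTL required")

    def genetic_values(self, dosage: np.ndarray) -> np.ndarray:
        return dosage[:, self.qtl_indices] @ self.effects

    def to_frame(self, mmap: MarkerMap) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait,
                "marker_id": mmap.marker_id[self.qtl_indices],
                "chromosome": mmap.chromosome[self.qtl_indices],
                "position_bp": mmap.position_bp[self.qtl_indices],
                "effect": self.effects,
                "pleiotropic": self.pleiotropic,
            }
        )


def make_trait_architectures(
    pop: SimulatedPopulation,
    rng: np.random.Generator,
    n_qtl: int = 10,
    n_shared: int = 4,
    h2_dtf: float = 0.5,
    h2_pht: float = 0.5,
    mean_dtf: float = 52.0,
    mean_pht: float = 35.0,
    sd_dtf: float = 2.3,
    sd_pht: float = 3.0,
) -> tuple[TraitArchitecture, TraitArchitecture]:
    """Two correlated trait architectures: days to flowering and plant height.

    ``n_shared`` QTL are pleiotropic with same-sign effects on both traits
    (inducing a positive genetic correlation); each trait additionally has
    one large-effect QTL among its private ones.  Effect sizes are scaled so
    the realized genetic standard deviation among the simulated lines equals
    the requested trait SD.
    """
    poly = np.flatnonzero(pop.founders.polymorphic())
    maf = np.minimum(pop.dosage[:, poly].mean(axis=0) / 2, 1 - pop.dosage[:, poly].mean(axis=0) / 2)
    usable = poly[maf > 0.05]
    total = 2 * n_qtl - n_shared
    chosen = rng.choice(usable, size=total, replace=False)
    shared = chosen[:n_shared]
    private_dtf = chosen[n_shared:n_qtl]
    private_pht = chosen[n_qtl:]

    def _effects(k, large_at=0):
        mag = rng.gamma(1.0, 1.0, size=k)
        mag[large_at] = mag.sum()  # one major QTL
        signs = rng.choice([-1.0, 1.0], size=k)
        return mag * signs

    eff_shared = np.abs(rng.gamma(1.0, 1.0, size=n_shared)) * rng.choice([-1.0, 1.0], size=n_shared)
    arch = {}
    for trait, private, h2, gm, sd in (
        ("DTF", private_dtf, h2_dtf, mean_dtf, sd_dtf),
        ("PHT", private_pht, h2_pht, mean_pht, sd_pht),
    ):
        idx = np.concatenate([shared, private])
        eff = np.concatenate([eff_shared, _effects(len(private))])
        g = pop.dosage[:, idx] @ eff
        scale = sd / g.std(ddof=1) if g.std(ddof=1) > 0 else 1.0
        arch[trait] = TraitArchitecture(
            trait=trait,
            qtl_indices=idx,
            effects=eff * scale,
            heritability=h2,
            grand_mean=gm,
            pleiotropic=np.concatenate(
                [np.ones(n_shared, dtype=bool), np.zeros(len(private), dtype=bool)]
            ),
        )
    return arch["DTF"], arch["PHT"]


@dataclass
class FieldDesign:
    """Augmented field design: unreplicated lines plus replicated checks."""

    n_blocks: int = 8
    block_effects: np.ndarray | None = None
    check_replicates: int = 8
    error_variance: float | None = None  # per trait; None -> derived from h2

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.block_effects is not None:
            self.block_effects = np.asarray(self.block_effects, dtype=np.float64)
            if len(self.block_effects) != self.n_blocks:
                raise ValueError("one effect per block required")

    def effects(self) -> np.ndarray:
        if self.block_effects is None:
            return np.zeros(self.n_blocks)
        return self.block_effects


def simulate_phenotypes(
    pop: SimulatedPopulation,
    architectures,
    field: FieldDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate an augmented field trial for one or more traits.

    Each MAGIC line is grown in exactly one block (round-robin assignment);
    every founder check is replicated ``field.check_replicates`` times,
    spread across blocks.  A record's value is

        grand mean + sum_j dosage_ij * a_j + block effect + e,   e ~ N(0, s2)

    where the residual variance is either ``field.error_variance`` or chosen
    so that the realized narrow-sense heritability among line means matches
    the architecture's target: s2 = var(g) * (1 - h2) / h2.

    Returns a tidy frame with columns line_id, trait, block, value, is_check.
    """
    if isinstance(architectures, TraitArchitecture):
        architectures = [architectures]
    blocks_lines = np.arange(pop.n_lines) % field.n_blocks + 1
    beff = field.effects()
    founders = pop.founders
    founder_dosage = 2 * founders.haplotypes.astype(np.float64)

    rows = []
    for arch in architectures:
        g = pop.dosage @ _effect_vector(arch, pop.map.n_markers)
        var_g = g.var(ddof=1)
        if field.error_variance is not None:
            s2 = field.error_variance
        else:
            s2 = var_g * (1 - arch.heritability) / arch.heritability
        sd = np.sqrt(s2)
        vals = arch.grand_mean + g + beff[blocks_lines - 1] + rng.normal(0, sd, pop.n_lines)
        for lid, b, v in zip(pop.line_ids, blocks_lines, vals):
            rows.append((lid, arch.trait, int(b), float(v), False))
        g_f = founder_dosage @ _effect_vector(arch, pop.map.n_markers)
        for f, fid in enumerate(founders.founder_ids):
            for r in range(field.check_replicates):
                b = r % field.n_blocks + 1
                v = (
                    arch.grand_mean
                    + g_f[f]
                    + beff[b - 1]
                    + rng.normal(0, sd)
                )
                rows.append((fid, arch.trait, int(b), float(v), True))
    return pd.DataFrame(rows, columns=["line_id", "trait", "block", "value", "is_check"])


def _effect_vector(arch: TraitArchitecture, n_markers: int) -> np.ndarray:
    a = np.zeros(n_markers)
    a[arch.qtl_indices] = arch.effects
    return a
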