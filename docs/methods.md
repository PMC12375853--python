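# Methods

This note documents the models implemented in `magicpop`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Population simulation

**Funnel construction.** For n founders (n a power of two; the flagship
case is n = 8) the crossing design is built from the round-robin
1-factorization of the complete graph Kₙ: the n(n−1)/2 founder pairs are
partitioned into n−1 perfect matchings.  Each matching's disjoint pairs
become two-way crosses; consecutive pairs within a matching combine into
four-way crosses and, for n = 8, the matching's two four-ways into one
eight-way cross.  This is the unique construction (up to relabelling)
consistent with the printed tier counts 28 / 14 / 7, uses every founder
pair exactly once, and gives every terminal cross all eight founders.

**Meiosis.** Recombination follows the Haldane model: crossover counts per
chromosome are Poisson with mean equal to the genetic length in Morgans,
crossover positions are uniform on the genetic map, and there is no
interference.  The starting haplotype is chosen with probability ½ per
chromosome.  Interference would slightly reduce double crossovers but has
no bearing on any quantity this package reports (founder shares,
heterozygosity decay, LD structure at the simulated marker density), so the
simplest defensible model is used.  Founder-origin labels travel with the
alleles, giving every line a complete ancestry mosaic.

**Descent.** Two-way F1s are deterministic because founders are fully
homozygous.  Below that tier every line descends through its own
independent meioses — its own four-way F1 plants, its own eight-way F1, and
then `ssd_generations` (default 8) rounds of selfing by single seed
descent.  Real programs advance multiple plants per cross; modelling lines
as independent draws from the funnel reflects that and makes the
per-founder genome share an i.i.d. average with expectation exactly 1/8.
Residual heterozygosity halves each selfing generation, so RILs retain
about (1/2)⁸ ≈ 0.4% of the F1 heterozygosity.

**Genome scaffold.** Eight chromosomes with the physical lengths of the
chickpea reference (≈348 Mbp total) and a uniform 1.2 cM/Mbp recombination
rate (≈ 860 cM genome, typical of chickpea consensus maps).  Markers are
placed uniformly at random, proportional to chromosome length; the default
density is 4255 markers.

**Founder haplotypes.** Each marker receives a founder-panel allele
frequency p ~ Beta(1, 1) and founders draw alleles Bernoulli(p).  Drawn
independently per marker this produces a realistic MAF spectrum
(mean MAF ≈ 0.29 after monomorphic removal) but *no* LD among the founder
haplotypes — and with only eight independent haplotypes, even completely
linked markers would show r² of about 1/7 in the derived population, far
below what real panels show.  Founder haplotypes are therefore generated
with local haplotype sharing: scanning along a chromosome, a founder reuses
its previous allele with probability exp(−Δbp / L) and redraws otherwise.
The length scale L defaults to 1 Mbp, chosen once so that the simulated
population reproduces the LD regime reported for eight-founder MAGIC
material: short-range r² well above 0.5 and a smoothed decay to r² = 0.2
within roughly 1–1.5 Mbp.  This also produces the conserved founder
segments and multi-marker LD blocks on which the haplotype machinery
operates.

**Traits.** Two quantitative traits mimic days to 50% flowering (DTF,
grand mean 52 d, genetic SD 2.3 d) and plant height (PHT, 35 cm, 3 cm),
each with 10 additive QTL by default of which 4 are pleiotropic with
same-sign effects — inducing the positive DTF–PHT correlation seen in such
populations.  Effect magnitudes are Gamma-distributed with one major QTL
per trait; effects are rescaled so the realized genetic SD among simulated
lines matches the target.  Narrow-sense heritability defaults to 0.5 per
trait; the residual variance is set to var(g)·(1−h²)/h² so the realized h²
among line means matches the target.

**Field trial.** The augmented design grows each RIL once and every
founder as a replicated check (8 replicates, spread across 8 blocks).
Block effects default to N(0, 1) draws.  A record is
grand mean + Σⱼ xᵢⱼaⱼ + block + ε.  The simulator models a single trial;
multi-season structure can only be emulated by treating season as an extra
block dimension.

## Marker curation

Filters run in a fixed order: genotypes with read depth < 5 are set
missing; samples missing > 50% are dropped; then MAF and marker
missingness are recomputed and markers are removed for MAF ≤ 0.01
(boundary inclusive), missingness > 50%, or monomorphism.  Ordering sample
removal before the marker rules means removing a bad sample can never
resurrect an already-failed marker, and makes the filter idempotent.
Redundancy pruning is a greedy left-to-right scan in map order dropping any
marker whose Pearson correlation with an already-kept marker on the same
chromosome exceeds 0.99; the restriction to within-chromosome pairs bounds
cost and reflects that cross-chromosome r > 0.99 at these sample sizes is
artifactual.  Missing genotypes are imputed with the marker's modal dosage
(ties toward the lower class) — a deliberate, transparent stand-in where a
real analysis would use reference-panel phasing/imputation.

## Structure and LD

Rogers distance between individuals is the per-locus Euclidean distance of
genotype-implied allele frequencies averaged over loci; for biallelic
dosages this reduces exactly to mean(|dᵢ−dⱼ|)/2 and is a metric on [0, 1].
Classical MDS double-centers the squared distance matrix; axis variance
percentages are eigenvalues over the positive-eigenvalue sum.  Cluster
number is chosen by maximizing the mean silhouette over a k range
(k-means, 25 restarts, fixed seed) — a single deterministic criterion in
place of multi-index ensembles; a complete-linkage tree provides heatmap
ordering.  Pairwise LD is the squared Pearson correlation of dosage
vectors for all within-chromosome pairs separated by at most 50 Mbp (more
distant pairs are treated as unlinked); "pairs" means all pairs within the
window, not only adjacent ones, since the decay curve needs the full
distance range.  Because lines are inbred, dosage correlation and
composite LD are essentially identical here.  The decay curve is a LOESS
fit (span 0.3 by default; on tables above 5000 pairs a 0.5% interpolation
delta keeps the smoother linear-time) evaluated on a 1000-point grid, and
the decay distance is the first grid crossing of the threshold (default
r² = 0.2) located by linear interpolation; if the fitted curve never
crosses, the result is flagged undefined rather than extrapolated.

## Augmented-design adjustment

The model is y = Xβ + Pw + Zg + ε with blocks β (sum-to-zero coded) and
founder checks w fixed and RIL effects g ~ N(0, σ²g I) random.  Because
every RIL is observed once, V is diagonal given the ratio γ = σ²g/σ²ₑ, and
the restricted likelihood profiles to a one-dimensional function of γ;
σ²ₑ then has a closed form.  The profile is minimized over log₁₀γ ∈
[−8, 8] with scipy's bounded scalar minimizer (tolerance 1e−6).  Adjusted
values are μ̂ + BLUP by default; the BLUE option (lines fixed) estimates
blocks and checks from check records only and subtracts the block effect,
which with noiseless data recovers genetic value + grand mean exactly.
BLUPs shrink toward the mean by γ/(1+γ), so BLUP-adjusted values never
have larger variance than BLUE ones.  Block significance is reported by a
Wald χ² test on the GLS coefficients.  Outliers are records whose
conditional residual exceeds 3 standard deviations (the conventional
cut-off); one refit pass follows removal.  Row effects are supported as an
optional second fixed factor, off by default.  Whether downstream mapping
should use BLUPs or BLUEs is a judgment call; both are exposed and BLUP is
the default.

## GWAS

The scan is a per-marker linear model with the leading genotype principal
components (default 4) as covariates, vectorized through a weighted QR
projection; the optional kinship mode uses the VanRaden genomic
relationship built from centered dosages, estimates the two variance
components once on the null model in the kinship eigenbasis, and reuses
them for every marker (the P3D shortcut).  Multi-locus iterative methods
(e.g. pseudo-QTN selection) are intentionally not re-implemented: the
reproducible surface — the fixed −log10(p) ≥ 4.0 threshold, LD-based
merging, QTL recovery — does not depend on them, and any external result
table with the same columns can be fed into the calling/merging steps.
Constant markers are flagged untestable rather than dropped silently.
Significant markers on one chromosome are merged into QTL regions by
single-linkage connected components over edges with r² ≥ `r2_link`; the
lead marker maximizes −log10(p) with ties broken toward the smaller
position.  `r2_link` has no default in pipeline runs: 0.5 (a conservative
methods convention) and 0.1 (a permissive results convention) are both in
circulation, and the choice materially changes region counts, so it must
be stated.  Raising `r2_link` can only split regions, never merge them.

## Haplotype-block mapping

**Block scan.** Per chromosome, left to right: a block is seeded when an
adjacent marker pair reaches r² ≥ 0.5; it extends while candidate flanking
markers reach the threshold against the block's current outer (rightmost
passing) member.  A failing flanker is tolerated — kept in the block — if
a passing marker occurs within the next t = 3 candidates; after more than
t consecutive failures the block closes at its last passing member, and
trailing failures are re-scanned.  Unabsorbed markers become singleton
blocks, so blocks exhaustively partition each chromosome and are
contiguous in map order.  The tolerance semantics ("t consecutive
candidates beyond the failing marker") is one defensible reading of a
tolerance parameter; both t and the threshold are exposed, and t = 0
degenerates to plain threshold scanning.

**RR-BLUP.** Marker effects are estimated simultaneously as
û = (XᵀcXc + λI)⁻¹Xᵀc(y − ȳ) with λ = σ̂²ₑ/σ̂²ᵤ from REML on the
equivalent one-variance-component mixed model, computed on the spectral
decomposition of XcXᵀc.  When n ≤ m the identical dual (n-dimensional)
form is solved instead; primal/dual agreement is tested to 1e−8.  A fixed
λ can be supplied; REML selection is the default because no single
canonical λ rule exists.

**Local GEBVs and block variance.** The local GEBV of line i at block b is
Σ_{j∈b} xᵢⱼûⱼ on the raw dosage scale, so block values sum exactly to the
line's total genomic value (blocks partition markers).  Haplotypes are
exact dosage strings over a block's markers — lines are ≥ 99.5%
homozygous after 8 SSD generations, so dosage strings stand in for phased
haplotypes, with residual heterozygous strings forming their own (rare)
classes.  Block variance is, by default, the population variance of the
*distinct* haplotypes' local GEBVs (each haplotype counted once); a
frequency-weighted option (equivalently, the variance over lines) is
exposed because either reading is defensible.  Blocks are ranked by
descending variance; high-variance blocks flag trait-associated regions.

**Haplotype classes, tests, stacking.** Frequency classes use strict
cut-offs on carrier counts: high > 70 lines, medium > 10, rare otherwise.
Haplotype phenotype effects are tested by a one-way linear-model F test;
haplotypes with fewer than 2 carriers are excluded from the test but kept
in the catalogue (both behaviors selectable).  Stacking scores each line
by how many of the top-k (default 10) variance blocks carry a haplotype
whose local GEBV has the desired sign — negative for earlier flowering,
positive for taller plants — and reports per-count phenotype summaries and
the linear trend slope with its p-value; the trend is flagged undefined
when all lines share one count.

## Pipeline

One master seed spawns independent per-stage substreams
(`numpy.random.SeedSequence.spawn`), so toggling stages does not perturb
the streams of the stages that run.  Identical config + seed gives
byte-identical result tables, recorded as SHA-256 checksums in the run
manifest.  Coordinates are 1-based inclusive bp throughout (VCF
convention); chromosome labels such as "Ca1" map to integers on input.
Genetic-map positions are carried through VCF via an INFO `CM` tag
(falling back to 1.2 cM/Mbp when absent) so write∘read is lossless.

## Verification scales and what passing shows

The test suite verifies the chain on synthetic populations sized to run on
one CPU in minutes; these sizes are the package's chosen verification
conditions:

- founder contribution: the full 1135 lines (2000 markers in tests, 4255
  in the acceptance script);
- heterozygosity decay: 600 lines × 1000 markers at 0 vs 8 selfings;
- GWAS power: 100 replicates at n = 1135 with a 5%-variance QTL;
  null calibration at n = 1135 × 2000 independent markers;
- high-variance block recovery: 100 replicates of 250 lines × 500 markers
  with a planted QTL carrying ≥ 10% of genetic variance (detected in the
  top-10 blocks in ≥ 90% of replicates);
- stacking trend: 100 replicates of 200 lines × 300 markers (negative
  DTF slope in ≥ 95%);
- LD decay: 400 lines × 1200 markers on two 48-Mbp chromosomes.

The generator reproduces the design combinatorics, inbreeding dynamics,
founder-share expectations, MAF spectrum and LD regime of a real
eight-founder MAGIC population, but not genotyping error, segregation
distortion, selection during SSD, epistasis, genotype-by-environment
interaction, or imputation artifacts.  Passing tests therefore demonstrate
that the algorithms are implemented correctly and behave as designed under
the stated generative model — not that any particular real dataset would
yield the same marker counts, QTL lists or block catalogues.

## Known limitations

- Mode imputation is a placeholder; real low-depth data needs proper
  phasing/imputation upstream.
- The GWAS engine is single-locus (with PC/kinship control); closely
  linked QTL in repulsion can mask each other.
- Block variance ranking inherits RR-BLUP shrinkage: very rare haplotypes
  have noisy local GEBVs, which the unweighted variance amplifies.
- The simulator draws founder LD from a stationary copy-down process;
  real panels have heterogeneous relatedness and recombination landscapes.
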