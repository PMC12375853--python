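# magicpop

Simulation and trait-mapping tools for eight-founder MAGIC (multi-parent
advanced generation intercross) populations in selfing crops such as
chickpea.

MAGIC populations intercross a set of diverse founders through a structured
funnel — for eight founders, 28 two-way crosses combined into 14 four-way
and then 7 eight-way crosses — followed by several generations of selfing
under single seed descent (SSD) to fix recombinant inbred lines (RILs).
The design reshuffles founder genomes so thoroughly that each founder is
expected to contribute 1/8 (12.5%) of every line's genome, population
structure is minimal, and linkage disequilibrium (LD) decays within about a
megabase — properties that make these populations powerful for mapping
quantitative trait loci (QTL).

`magicpop` implements the full analysis chain for such a population, either
on user-supplied data (VCF genotypes + phenotype TSV) or on synthetic
populations generated by its simulator with complete ground truth:

1. **Simulation** (`magicpop.sim`) — funnel construction by 1-factorization
   of K₈, Haldane-model meiosis with founder-origin tracking, SSD
   inbreeding, correlated additive trait architectures (days to 50%
   flowering, DTF; plant height, PHT), and an augmented field trial with
   replicated founder checks.
2. **Marker curation** (`magicpop.qc`) — depth, missingness, minor allele
   frequency (MAF ≤ 0.01, boundary inclusive) and monomorphism filters,
   modal imputation, and redundancy pruning of markers correlated > 0.99.
3. **Structure & LD** (`magicpop.structure`) — Rogers genetic distance,
   classical multidimensional scaling, silhouette-selected k-means with
   complete-linkage ordering, pairwise r² tables (50 Mbp cap), LOESS LD
   decay with the r² = 0.2 crossing distance, MAF/heterozygosity summaries.
4. **Phenotype adjustment** (`magicpop.adjust`) — REML fit of the augmented
   design model y = Xβ + Pw + Zg + ε (blocks and checks fixed, lines
   random), BLUP or BLUE adjusted values, Wald block tests, outlier removal.
5. **GWAS** (`magicpop.gwas`) — PC-covariate linear scan with optional
   kinship mixed model (VanRaden relationship, P3D variance components),
   significance at −log10(p) ≥ 4.0, and merging of significant markers into
   QTL regions by single-linkage LD connectivity at an explicit r²
   threshold.
6. **Haplotype-block mapping** (`magicpop.haplo`) — LD-block construction
   (r² = 0.5, marker tolerance t = 3), RR-BLUP marker effects
   û = (XᵀX + λI)⁻¹Xᵀy with REML-chosen λ = σ̂²ₑ/σ̂²ᵤ, per-block "local"
   genomic estimated breeding values (local GEBVs), block-variance ranking,
   haplotype catalogues with frequency classes (> 70 lines high, > 10
   medium, else rare), haplotype effect tests, and in-silico stacking of
   desirable haplotypes at the top-10 variance blocks.
7. **Pipeline & CLI** (`magicpop.pipeline`, `magicpop` command) — VCF/TSV
   I/O, config-driven end-to-end runs with per-stage seed substreams and a
   checksummed run manifest.

## Worked example

```python
import numpy as np
from magicpop import *

rng = np.random.default_rng(7)
mmap = default_marker_map(1000, rng)
founders = simulate_founders(mmap, rng)
design = build_funnel(founders.founder_ids)
pop = simulate_population(founders, design, 400, rng)

print(pop.heterozygosity().mean())              # 0.0024  (~ (1/2)^8 of F1 level)
print(100 * pop.founder_contributions().mean(0))  # [12.88 12.71 ... 12.15]

arch_dtf, arch_pht = make_trait_architectures(pop, rng)
field = FieldDesign(n_blocks=8, block_effects=rng.normal(0, 1, 8))
records = simulate_phenotypes(pop, [arch_dtf, arch_pht], field, rng)
model = fit_augmented(records, trait="DTF")      # blocks+checks fixed, lines random
y = model.adjusted.reindex(pop.line_ids).to_numpy()

from magicpop.qc import filter_markers
d, rep = filter_markers(pop.dosage.astype(float))  # 35 monomorphic markers removed
mmap_qc = mmap.subset(rep.surviving_markers)
```

Scanning the adjusted DTF values and mapping haplotype blocks:

```python
res = gwas_scan(d, y, mmap_qc, n_pcs=4)
sig = call_significant(res, 4.0)                  # 34 significant markers
regions = merge_qtl(sig, r2_link=0.5, dosage=d, mmap=mmap_qc, trait="DTF")
len(regions)                                      # 12 QTL regions

rr = fit_rrblup(d, y)
blocks = build_ld_blocks(d, mmap_qc)              # 355 LD blocks
catalog = catalog_haplotypes(blocks, d)
gebvs = local_gebv(rr, blocks, d)
vt = block_variance(gebvs, catalog, rr)
vt.iloc[0][["block_id", "chromosome"]]            # b000122 on chromosome 3,
                                                  # contains a true planted QTL
st = stack_haplotypes(catalog, vt, rr, y, direction="negative", top_k=10)
st.slope                                          # -0.52 days per stacked
                                                  # early-flowering haplotype
```

The negative slope reproduces the rationale of haplotype stacking: lines
carrying more negative-effect (early-flowering) haplotypes at high-variance
blocks flower measurably earlier.

An end-to-end run with all artifacts and a manifest:

```sh
magicpop run-all --seed 1 --r2-link 0.5 --out runs/demo
```

(`--r2-link` is deliberately required: both 0.5 and 0.1 are defensible LD
thresholds for declaring significant markers part of one QTL, and the
choice changes the region count.)

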