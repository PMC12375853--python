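"""Config-driven end-to-end pipeline and run manifests.

Stages: simulate -> qc -> structure -> adjust -> gwas -> haploblocks ->
stack.  A single master seed spawns independent per-stage substreams so a
stage's stream does not depend on which other stages ran.  Every stage
writes TSV artifacts into the output directory and a JSON manifest records
the config hash, seed, artifact checksums and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adjust, gwas, haplo, qc, sim, structure, vcfio

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "qc", "structure", "adjust", "gwas", "haploblocks", "stack")


@dataclass
class PipelineConfig:
    """All pipeline parameters, with field-standard defaults.

    ``r2_link`` — the LD threshold for merging significant markers into QTL
    — has no default and must be set explicitly for any run that reaches
    the GWAS stage (0.5 and 0.1 are the two defensible conventions; see the
    methods note).
    """

    seed: int = 0
    # simulate
    n_founders: int = 8
    n_lines: int = 1135
    n_markers: int = 4255
    ssd_generations: int = 8
    n_qtl: int = 10
    n_shared_qtl: int = 4
    h2_dtf: float = 0.5
    h2_pht: float = 0.5
    n_blocks: int = 8
    check_replicates: int = 8
    block_effect_sd: float = 1.0
    missing_rate: float = 0.0
    # qc
    maf_max_remove: float = 0.01
    depth_min: int = 5
    snp_missing_max: float = 0.5
    sample_missing_max: float = 0.5
    corr_prune: float = 0.99
    # structure
    mds_axes: int = 4
    ld_max_dist: int = 50_000_000
    decay_threshold: float = 0.2
    loess_span: float = 0.3
    # adjust
    adjust_method: str = "blup"
    outlier_sd: float = 3.0
    # gwas
    gwas_threshold: float = 4.0
    n_pcs: int = 4
    use_kinship: bool = False
    r2_link: float | None = None
    # haploblocks
    block_r2: float = 0.5
    block_tolerance: int = 3
    top_k: int = 10
    hap_high_min: int = 70
    hap_medium_min: int = 10
    variance_weighted: bool = False
    # stages
    stages: tuple[str, ...] = STAGES

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Parse a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``).  A stage
    whose upstream artifact is missing fails fast, naming the dependency.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    artifacts: dict[str, Path] = {}
    state: dict = {}

    def _write(name: str, df: pd.DataFrame):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        artifacts[name] = p

    def _need(key: str, stage: str, produced_by: str):
        if key not in state:
            raise RuntimeError(
                f"stage '{stage}' requires output of stage '{produced_by}', which did not run"
            )
        return state[key]

    if "simulate" in enabled:
        rng = streams["simulate"]
        mmap = sim.default_marker_map(config.n_markers, rng)
        founders = sim.simulate_founders(mmap, rng, n_founders=config.n_founders)
        design = sim.build_funnel(founders.founder_ids, rng)
        design = dataclasses.replace(design, ssd_generations=config.ssd_generations)
        pop = sim.simulate_population(
            founders, design, config.n_lines, rng, missing_rate=config.missing_rate
        )
        arch_dtf, arch_pht = sim.make_trait_architectures(
            pop,
            rng,
            n_qtl=config.n_qtl,
            n_shared=config.n_shared_qtl,
            h2_dtf=config.h2_dtf,
            h2_pht=config.h2_pht,
        )
        fielddef = sim.FieldDesign(
            n_blocks=config.n_blocks,
            block_effects=rng.normal(0, config.block_effect_sd, config.n_blocks),
            check_replicates=config.check_replicates,
        )
        records = sim.simulate_phenotypes(pop, [arch_dtf, arch_pht], fielddef, rng)
        state.update(pop=pop, records=records, archs=(arch_dtf, arch_pht))
        vcfio.write_population_vcf(outdir / "genotypes.vcf", pop)
        artifacts["genotypes"] = outdir / "genotypes.vcf"
        _write("phenotypes", records)
        _write("truth_qtl", pd.concat([a.to_frame(mmap) for a in (arch_dtf, arch_pht)]))
        contrib = pop.founder_contributions()
        _write(
            "truth_founder_contribution",
            pd.DataFrame(
                {"founder": founders.founder_ids, "mean_share": contrib.mean(axis=0)}
            ),
        )

    if "qc" in enabled:
        pop = _need("pop", "qc", "simulate")
        dosage = pop.dosage.astype(float)
        if pop.missing is not None:
            dosage[pop.missing] = np.nan
        cfg = qc.QCConfig(
            maf_max_remove=config.maf_max_remove,
            depth_min=config.depth_min,
            snp_missing_max=config.snp_missing_max,
            sample_missing_max=config.sample_missing_max,
            corr_prune=config.corr_prune,
        )
        filtered, report = qc.filter_markers(dosage, config=cfg)
        filtered = qc.impute_simple(filtered)
        keep1 = report.surviving_markers
        mmap1 = _subset_map(pop.map, keep1)
        pruned, kept2, _ = qc.prune_correlated(filtered, mmap1, threshold=cfg.corr_prune)
        keep = keep1[kept2]
        state["qc_dosage"] = pruned
        state["qc_map"] = _subset_map(pop.map, keep)
        state["qc_report"] = report
        state["qc_line_ids"] = [pop.line_ids[i] for i in report.surviving_samples]
        _write("qc_report", pd.DataFrame([report.summary()]))
        _write("qc_map", state["qc_map"].to_frame())

    if "structure" in enabled:
        d = _need("qc_dosage", "structure", "qc")
        mmap_q = state["qc_map"]
        dist = structure.rogers_distance(d)
        mds = structure.classical_mds(dist, k=config.mds_axes)
        ld = structure.pairwise_ld(d, mmap_q, max_dist=config.ld_max_dist)
        decay = structure.ld_decay(
            ld, loess_span=config.loess_span, threshold=config.decay_threshold
        )
        summ = structure.maf_het_summary(d)
        state.update(ld_table=ld, decay=decay, mds=mds)
        _write(
            "mds",
            pd.DataFrame(
                mds.coordinates,
                columns=[f"PC{i + 1}" for i in range(mds.coordinates.shape[1])],
            ).assign(line_id=state["pop"].line_ids if "pop" in state else range(len(dist))),
        )
        _write("ld_table", ld)
        _write(
            "ld_decay",
            pd.DataFrame(
                [
                    {
                        "decay_distance_bp": decay.decay_distance,
                        "threshold": decay.threshold,
                        "crossed": decay.crossed,
                        "mean_maf": summ["mean_maf"],
                        "mean_het": summ["mean_het"],
                    }
                ]
            ),
        )

    if "adjust" in enabled:
        records = _need("records", "adjust", "simulate")
        adjusted = {}
        models = {}
        for trait in records["trait"].unique():
            model = adjust.fit_augmented(records, trait=trait, method=config.adjust_method)
            _, model = adjust.detect_outliers(model, sd_threshold=config.outlier_sd)
            models[trait] = model
            adjusted[trait] = model.adjusted
        state["adjusted"] = adjusted
        state["adjust_models"] = models
        out = pd.DataFrame(adjusted)
        out.index.name = "line_id"
        _write("adjusted_phenotypes", out.reset_index())

    if "gwas" in enabled:
        if config.r2_link is None:
            raise ValueError(
                "r2_link must be set explicitly for the gwas stage (e.g. 0.5 or 0.1)"
            )
        d = _need("qc_dosage", "gwas", "qc")
        mmap_q = state["qc_map"]
        adjusted = _need("adjusted", "gwas", "adjust")
        line_ids = state.get("qc_line_ids")
        scans, all_regions = {}, []
        for trait, vals in adjusted.items():
            y = vals.reindex(line_ids).to_numpy() if line_ids is not None else vals.to_numpy()
            res = gwas.gwas_scan(
                d, y, mmap_q, n_pcs=config.n_pcs, use_kinship=config.use_kinship
            )
            scans[trait] = res
            sig = gwas.call_significant(res, threshold=config.gwas_threshold)
            regions = gwas.merge_qtl(
                sig,
                r2_link=config.r2_link,
                ld_table=state.get("ld_table"),
                dosage=d,
                mmap=mmap_q,
                trait=trait,
            )
            all_regions.extend(regions)
            _write(f"gwas_{trait.lower()}", res)
        state["qtl_regions"] = all_regions
        _write(
            "qtl_regions",
            pd.DataFrame([r.to_row() for r in all_regions])
            if all_regions
            else pd.DataFrame(
                columns=[
                    "trait", "chromosome", "n_markers", "lead_marker",
                    "lead_position_bp", "lead_minus_log10_p", "start_bp",
                    "end_bp", "members",
                ]
            ),
        )

    if "haploblocks" in enabled:
        d = _need("qc_dosage", "haploblocks", "qc")
        mmap_q = state["qc_map"]
        adjusted = _need("adjusted", "haploblocks", "adjust")
        line_ids = state.get("qc_line_ids")
        blocks = haplo.build_ld_blocks(
            d, mmap_q, r2_threshold=config.block_r2, t=config.block_tolerance
        )
        catalog = haplo.catalog_haplotypes(
            blocks, d, high_min=config.hap_high_min, medium_min=config.hap_medium_min
        )
        state["blocks"] = blocks
        state["catalog"] = catalog
        _write("ld_blocks", blocks.to_frame())
        models, tables = {}, {}
        for trait, vals in adjusted.items():
            y = vals.reindex(line_ids).to_numpy() if line_ids is not None else vals.to_numpy()
            model = haplo.fit_rrblup(d, y)
            gebvs = haplo.local_gebv(model, blocks, d)
            vt = haplo.block_variance(
                gebvs, catalog, model, weighted=config.variance_weighted
            )
            models[trait] = (model, gebvs, y)
            tables[trait] = vt
            _write(f"block_variance_{trait.lower()}", vt)
        state["rrblup"] = models
        state["variance_tables"] = tables
        _write("haplotype_catalog", catalog.to_frame())

    if "stack" in enabled:
        catalog = _need("catalog", "stack", "haploblocks")
        models = _need("rrblup", "stack", "haploblocks")
        tables = state["variance_tables"]
        directions = {"DTF": "negative", "PHT": "positive"}
        rows = []
        for trait, (model, gebvs, y) in models.items():
            direction = directions.get(trait, "negative")
            res = haplo.stack_haplotypes(
                catalog, tables[trait], model, y, direction=direction, top_k=config.top_k
            )
            for _, r in res.per_count.iterrows():
                rows.append(
                    {
                        "trait": trait,
                        "direction": direction,
                        "stack_count": int(r["count"]),
                        "n_lines": int(r["size"]),
                        "mean_value": r["mean"],
                        "sd_value": r["std"],
                        "trend_slope": res.slope,
                        "trend_p": res.slope_p,
                    }
                )
        _write("stacking", pd.DataFrame(rows))

    (outdir / "config.yaml").write_text(config.to_yaml())
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _subset_map(mmap: sim.MarkerMap, idx: np.ndarray) -> sim.MarkerMap:
    return mmap.subset(idx)
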