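"""File formats: VCF genotypes, TSV phenotype and truth tables.

Genotypes travel as biallelic SNP VCF (GT field only; ``./.`` for missing;
1-based POS).  Genetic-map positions, which plain VCF cannot carry in its
fixed columns, are written to an INFO ``CM`` tag and recovered on read;
when absent, a uniform 1.2 cM/Mb map is assumed.  Chromosome labels like
``Ca1`` are mapped to integers on input.  Reading uses cyvcf2.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sim import DEFAULT_CM_PER_MB, MarkerMap, SimulatedPopulation

__all__ = ["read_vcf", "write_vcf", "write_phenotypes", "read_phenotypes"]

_CHROM_RE = re.compile(r"^(?:Ca|chr|Chr)?0*(\d+)$")


def _chrom_to_int(label: str) -> int:
    m = _CHROM_RE.match(str(label))
    if not m:
        raise ValueError(f"cannot interpret chromosome label {label!r}")
    return int(m.group(1))


def write_vcf(
    path,
    dosage: np.ndarray,
    mmap: MarkerMap,
    sample_ids,
    chrom_prefix: str = "Ca",
) -> None:
    """Write a dosage matrix as a biallelic SNP VCF (GT only).

    Missing genotypes (NaN) become ``./.``; dosage 0/1/2 become
    ``0/0``, ``0/1``, ``1/1``.  REF/ALT are placeholders (A/T) since only
    the genotype configuration is modelled.
    """
    d = np.asarray(dosage, dtype=np.float64)
    sample_ids = list(sample_ids)
    if d.shape != (len(sample_ids), mmap.n_markers):
        raise ValueError("dosage must be (n_samples, n_markers)")
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in mmap.chromosomes:
            fh.write(f"##contig=<ID={chrom_prefix}{c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(mmap.n_markers):
            gts = "\t".join(
                "./." if np.isnan(d[i, j]) else gt_code[d[i, j]]
                for i in range(len(sample_ids))
            )
            fh.write(
                f"{chrom_prefix}{mmap.chromosome[j]}\t{mmap.position_bp[j]}\t"
                f"{mmap.marker_id[j]}\tA\tT\t.\t.\tCM={mmap.position_cM[j]:.6f}\tGT\t{gts}\n"
            )


def read_vcf(path, cm_per_mb: float = DEFAULT_CM_PER_MB):
    """Read a VCF into (dosage, MarkerMap, sample ids).

    Only biallelic SNP records are used; multi-allelic or indel records are
    skipped.  Returns ``(dosage, mmap, samples, n_skipped)``.  GT 0/0, 0/1,
    1/1, ./. map to 0, 1, 2, NaN.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, bps, ids, cms, rows = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        chroms.append(_chrom_to_int(rec.CHROM))
        bps.append(rec.POS)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"M{rec.CHROM}.{rec.POS}")
        cm = rec.INFO.get("CM")
        cms.append(float(cm) if cm is not None else rec.POS / 1e6 * cm_per_mb)
        # gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
        gt = rec.gt_types.astype(np.float64)
        gt[gt == 2.0] = np.nan
        gt[gt == 3.0] = 2.0
        rows.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    dosage = np.vstack(rows).T
    order = np.lexsort((bps, chroms))
    dosage = dosage[:, order]
    mmap = MarkerMap(
        np.asarray(ids, dtype=object)[order],
        np.asarray(chroms)[order],
        np.asarray(bps)[order],
        np.asarray(cms)[order],
    )
    return dosage, mmap, samples, n_skipped


def write_population_vcf(path, pop: SimulatedPopulation, include_founders: bool = True):
    """Write founders + simulated lines as one VCF."""
    dosage = pop.dosage.astype(np.float64)
    if pop.missing is not None:
        dosage = dosage.copy()
        dosage[pop.missing] = np.nan
    samples = list(pop.line_ids)
    if include_founders:
        fd = 2.0 * pop.founders.haplotypes.astype(np.float64)
        dosage = np.vstack([fd, dosage])
        samples = list(pop.founders.founder_ids) + samples
    write_vcf(path, dosage, pop.map, samples)


def write_phenotypes(path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "trait", "block", "value", "is_check"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df
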