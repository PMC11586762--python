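"""Readers and writers for the framework's tabular and VCF inputs.

The population database is a flat TSV (one row per variant per ancestry)
rather than a sites VCF, so every test input can be generated or inspected
as plain text.  Cohort genotypes come in as VCF v4.2/4.3 with GT:AD:DP:GQ.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .keys import VariantKey
from .types import (
    MISSING,
    AncestryLabel,
    CohortGenotypeMatrix,
    PopulationVariantStats,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_population_table",
    "write_population_table",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "read_loadings",
]

POPULATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "pop", "AC", "AN", "nhomalt",
    "qc_pass", "covered", "n_called",
]


class FormatError(ValueError):
    """Malformed input file."""


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "t", "1", "pass", "yes")


def read_population_table(path: str | Path) -> dict[VariantKey, PopulationVariantStats]:
    """Parse the ancestry-stratified allele-count table.

    Rows sharing (chrom, pos, ref, alt) are folded into one record with one
    ancestry entry per row.  AC > AN raises a validation error naming the
    variant; malformed rows raise with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"population table missing columns: {missing_cols}")
    records: dict[VariantKey, PopulationVariantStats] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
            pop = AncestryLabel(str(row.pop))
            ac, an, nhom = int(row.AC), int(row.AN), int(row.nhomalt)
        except (ValueError, KeyError) as exc:
            raise FormatError(f"malformed population-table row {row_no}: {exc}") from exc
        rec = records.get(key)
        if rec is None:
            rec = records[key] = PopulationVariantStats(
                key=key,
                qc_pass=_to_bool(row.qc_pass),
                covered=_to_bool(row.covered),
                n_called_individuals=int(row.n_called),
            )
        rec.ac[pop] = ac
        rec.an[pop] = an
        rec.hom_alt[pop] = nhom
        rec.validate()
    return records


def write_population_table(
    records: Mapping[VariantKey, PopulationVariantStats], path: str | Path
) -> None:
    rows = []
    for key in sorted(records):
        rec = records[key]
        for pop in rec.ac:
            rows.append(
                {
                    "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                    "pop": pop.value, "AC": rec.ac[pop], "AN": rec.an[pop],
                    "nhomalt": rec.hom_alt.get(pop, 0),
                    "qc_pass": rec.qc_pass, "covered": rec.covered,
                    "n_called": rec.n_called_individuals,
                }
            )
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_vcf(
    path: str | Path, ancestry_map: Mapping[str, AncestryLabel] | None = None
) -> CohortGenotypeMatrix:
    """Load a joint-genotyped VCF into a CohortGenotypeMatrix.

    Multiallelic records must be split upstream; encountering one raises.
    Samples absent from ``ancestry_map`` are labelled UNKNOWN.  Missing
    FORMAT fields leave the corresponding metric absent, never zero.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ancestry = dict(ancestry_map or {})
    keys: list[VariantKey] = []
    dosage_rows, dp_rows, gq_rows, ab_rows = [], [], [], []
    sor_vals, eh_vals = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {v.CHROM}:{v.POS}; split multiallelics "
                "(e.g. `bcftools norm -m-`) before loading"
            )
        keys.append(VariantKey(v.CHROM, v.POS, v.REF, v.ALT[0]))
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            dos[i] = sum(1 for a in alleles if a > 0)
        dosage_rows.append(dos)

        dp = v.format("DP")
        dp_rows.append(
            np.where(dp[:, 0] < 0, MISSING, dp[:, 0]).astype(np.int32)
            if dp is not None else np.full(len(samples), MISSING, dtype=np.int32)
        )
        gq = v.format("GQ")
        gq_rows.append(
            np.where(gq[:, 0] < 0, MISSING, gq[:, 0]).astype(np.int32)
            if gq is not None else np.full(len(samples), MISSING, dtype=np.int32)
        )
        ab = np.full(len(samples), np.nan)
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            ref_d = ad[:, 0].astype(float)
            alt_d = ad[:, 1].astype(float)
            tot = ref_d + alt_d
            het = dos == 1
            ok = het & (tot > 0) & (ref_d >= 0) & (alt_d >= 0)
            ab[ok] = alt_d[ok] / tot[ok]
        ab_rows.append(ab)

        sor = v.INFO.get("SOR")
        eh = v.INFO.get("ExcessHet")
        sor_vals.append(float(sor) if sor is not None else np.nan)
        eh_vals.append(float(eh) if eh is not None else np.nan)
    return CohortGenotypeMatrix(
        samples=samples,
        ancestry=ancestry,
        variants=keys,
        dosage=np.array(dosage_rows, dtype=np.int8).reshape(len(keys), len(samples)),
        dp=np.array(dp_rows, dtype=np.int32).reshape(len(keys), len(samples)),
        gq=np.array(gq_rows, dtype=np.int32).reshape(len(keys), len(samples)),
        ab=np.array(ab_rows, dtype=float).reshape(len(keys), len(samples)),
        sor=np.array(sor_vals, dtype=float),
        excess_het=np.array(eh_vals, dtype=float),
    )


def write_cohort_vcf(cohort: CohortGenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT:AD:DP:GQ) for the cohort."""
    order = np.argsort([k.packed for k in cohort.variants])
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">\n')
        fh.write('##INFO=<ID=ExcessHet,Number=1,Type=Float,Description="Phred-scaled excess heterozygosity">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        chroms = []
        for i in order:
            c = cohort.variants[i].chrom
            if c not in chroms:
                chroms.append(c)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples) + "\n")
        for i in order:
            key = cohort.variants[i]
            info = []
            if np.isfinite(cohort.sor[i]):
                info.append(f"SOR={cohort.sor[i]:g}")
            if np.isfinite(cohort.excess_het[i]):
                info.append(f"ExcessHet={cohort.excess_het[i]:g}")
            cols = [
                key.chrom, str(key.pos), ".", key.ref, key.alt, ".", ".",
                ";".join(info) or ".", "GT:AD:DP:GQ",
            ]
            for j in range(cohort.n_samples):
                d = int(cohort.dosage[i, j])
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(d, "./.")
                dp = int(cohort.dp[i, j])
                gq = int(cohort.gq[i, j])
                ab = cohort.ab[i, j]
                if d == MISSING or dp == MISSING:
                    ad = "."
                elif d == 1 and np.isfinite(ab):
                    alt_d = int(round(ab * dp))
                    ad = f"{dp - alt_d},{alt_d}"
                elif d == 2:
                    ad = f"0,{dp}"
                else:
                    ad = f"{dp},0"
                cols.append(
                    f"{gt}:{ad}:{dp if dp != MISSING else '.'}:{gq if gq != MISSING else '.'}"
                )
            fh.write("\t".join(cols) + "\n")


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "cadd_phred",
    "af_EUR", "af_AFR", "af_AMR", "af_SAS", "af_EAS", "domain",
]


def read_annotation_table(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"annotation table missing columns: {missing_cols}")
    out: dict[VariantKey, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        cadd = None if pd.isna(row.cadd_phred) else float(row.cadd_phred)
        af = {
            AncestryLabel(p): float(getattr(row, f"af_{p}"))
            for p in ("EUR", "AFR", "AMR", "SAS", "EAS")
            if not pd.isna(getattr(row, f"af_{p}"))
        }
        domain = None if pd.isna(row.domain) else str(row.domain)
        out[key] = VariantAnnotation(
            key=key, gene_id=str(row.gene), consequence=str(row.consequence),
            cadd_phred=cadd, af_pop=af, domain_id=domain,
        )
    return out


def write_annotation_table(
    annotations: Mapping[VariantKey, VariantAnnotation], path: str | Path
) -> None:
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        row = {
            "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
            "gene": a.gene_id, "consequence": a.consequence,
            "cadd_phred": a.cadd_phred if a.cadd_phred is not None else np.nan,
            "domain": a.domain_id if a.domain_id is not None else np.nan,
        }
        for p in ("EUR", "AFR", "AMR", "SAS", "EAS"):
            row[f"af_{p}"] = a.af_pop.get(AncestryLabel(p), np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_loadings(path: str | Path) -> pd.DataFrame:
    """Read projection loadings: chrom,pos,ref,alt,f,w_1..w_k (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    weight_cols = [c for c in df.columns if c.startswith("w_")]
    if not weight_cols or "f" not in df.columns:
        raise FormatError("loadings table needs columns f and w_1..w_k")
    df["key"] = [
        VariantKey(str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
    return df.set_index("key")[["f"] + weight_cols]
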