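"""Readers and writers for the standard formats the pipeline consumes.

Coordinates: SNP positions are 1-based internally (as in VCF); BED input
and output are 0-based half-open and converted at this boundary only.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger("haplopred")


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF 4.2 with phased GT fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplopred\n")
        for chrom in pd.unique(panel.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        haps = panel.haplotypes
        for j, row in panel.snp_map.iterrows():
            gts = "\t".join(
                f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}"
                for i in range(panel.n_individuals)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\tsnp{j}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path, strict: bool = True) -> GenotypePanel:
    """Read a phased VCF into a panel (biallelic SNPs only).

    Unphased or half-missing genotypes raise in strict mode; in lenient
    mode the offending site is dropped and counted in the log.  Duplicated
    positions on a chromosome are always an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_cols = []
    rows = []
    n_multi = 0
    n_dropped = 0
    seen: set[tuple] = set()
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        key = (v.CHROM, v.POS)
        if key in seen:
            raise ValueError(f"duplicated position {v.CHROM}:{v.POS}")
        seen.add(key)
        col = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0 or not phased:
                ok = False
                break
            col[2 * i] = a
            col[2 * i + 1] = b
        if not ok:
            if strict:
                raise ValueError(f"unphased or missing genotype at {v.CHROM}:{v.POS}")
            n_dropped += 1
            continue
        hap_cols.append(col)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_multi:
        logger.info("skipped %d non-biallelic-SNP sites", n_multi)
    if n_dropped:
        logger.info("dropped %d unphased/missing sites (lenient mode)", n_dropped)
    if not rows:
        raise ValueError("no usable phased biallelic SNPs in VCF")
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypePanel(
        haplotypes=np.column_stack(hap_cols), snp_map=snp_map, samples=samples
    )


def write_haplotype_tsv(panel: GenotypePanel, path) -> None:
    """Plain haplotype table: one row per phased chromosome, 0/1 alleles."""
    with Path(path).open("w") as fh:
        fh.write("hap_id\t" + "\t".join(f"snp{j}" for j in range(panel.n_snps)) + "\n")
        for i, sample in enumerate(panel.samples):
            for h in (0, 1):
                alleles = "\t".join(map(str, panel.haplotypes[2 * i + h]))
                fh.write(f"{sample}.h{h}\t{alleles}\n")


def read_bed(path) -> pd.DataFrame:
    """BED intervals with optional name and class columns (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "cls"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names) :])
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "cls" not in df.columns:
        df["cls"] = "gene"
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end", "name", "cls"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def gtf_to_bed(path) -> pd.DataFrame:
    """Minimal GTF gene extractor: gene features -> BED with coding class.

    Genes with ``gene_biotype``/``gene_type`` of ``protein_coding`` are
    classed ``coding``; everything else ``noncoding``.  Full GTF semantics
    are out of scope.
    """
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in parts[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            cls = "coding" if biotype == "protein_coding" else "noncoding"
            name = attrs.get("gene_id", f"gene{len(rows)}")
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), name, cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "cls"])


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate TSV with header; 'NA' is missing."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """TSV writer with optional commented provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_grm_text(grm: np.ndarray, ids: list, path) -> None:
    """Lower-triangle text GRM: id_i, id_j, value (i >= j)."""
    with Path(path).open("w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm[i, j]:.10g}\n")


def read_grm_text(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t")
    ids = list(pd.unique(df["id_i"]))
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    grm = np.zeros((n, n))
    for id_i, id_j, value in df.itertuples(index=False):
        i, j = index[id_i], index[id_j]
        grm[i, j] = grm[j, i] = value
    return grm, ids


def write_truth_json(truth, path) -> None:
    """Serialize a TruthRecord (arrays as lists) for provenance."""
    payload = {
        "fractions": truth.fractions,
        "additive_snps": truth.additive_snps.tolist(),
        "additive_effects": truth.additive_effects.tolist(),
        "dominance_snps": truth.dominance_snps.tolist(),
        "dominance_effects": truth.dominance_effects.tolist(),
        "epistasis_pairs": [list(p) for p in truth.epistasis_pairs],
        "fixed_coefficients": truth.fixed_coefficients,
        "boxcox_lambda_inverse": truth.boxcox_lambda_inverse,
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1)
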