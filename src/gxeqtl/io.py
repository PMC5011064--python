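"""Readers and writers for the pipeline's standard formats.

Genotypes travel as VCF 4.2 (GT:DS) or as a dosage TSV (one row per SNP:
``snp_id  chromosome  position  effect_allele  other_allele`` followed by one
column per sample, '.' for missing). Expression counts are TSV with
meta-exons as rows and samples as columns. Annotation is exchanged as GTF
(1-based inclusive, like the internal model) or BED (0-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    MetaExon,
    PlantedEffect,
    SampleMetadata,
    TruthTable,
)

DOSAGE_META_COLS = ["chromosome", "position", "effect_allele", "other_allele"]


# -- genotypes --------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.snp_info[DOSAGE_META_COLS].copy()
    df = pd.concat([df, geno.dosages.T], axis=1)
    df.to_csv(path, sep="\t", index_label="snp_id", na_rep=".")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id", na_values=".")
    snp_info = df[DOSAGE_META_COLS]
    dosages = df.drop(columns=DOSAGE_META_COLS).astype(float).T
    return GenotypeMatrix(dosages, snp_info)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS fields."""
    samples = list(geno.sample_ids)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        info = geno.snp_info
        dos = geno.dosages.to_numpy(dtype=float)
        for j, sid in enumerate(geno.snp_ids):
            row = info.loc[sid]
            fields = [str(row["chromosome"]), str(int(row["position"])), str(sid),
                      str(row["other_allele"]), str(row["effect_allele"]),
                      ".", "PASS", ".", "GT:DS"]
            for i in range(len(samples)):
                d = dos[i, j]
                fields.append(f"{gt_codes[int(round(d))]}:{d:.3f}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read VCF genotypes; DS preferred, else dosage = ALT allele count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_rows, dosage_cols = [], []
    for var in vcf:
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_rows.append((sid, var.CHROM, var.POS, var.ALT[0], var.REF))
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1)).astype(float)
        dosage_cols.append(ds)
    snp_info = pd.DataFrame(
        snp_rows, columns=["snp_id", "chromosome", "position", "effect_allele", "other_allele"]
    ).set_index("snp_id")
    dosages = pd.DataFrame(
        np.column_stack(dosage_cols), index=samples, columns=snp_info.index
    )
    return GenotypeMatrix(dosages, snp_info)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_dosage_tsv(path)


# -- expression -------------------------------------------------------------

def write_counts_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="meta_exon_id")


def read_counts_tsv(path: str | Path, state: str = "raw",
                    gene_ids: pd.Series | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="meta_exon_id")
    return ExpressionMatrix(df, state, gene_ids)


# -- metadata ---------------------------------------------------------------

def write_metadata_tsv(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path: str | Path, phenotype_columns: tuple[str, ...] = ("bmi",),
                      technical_columns: tuple[str, ...] = ("mean_gc", "insert_size_mode"),
                      ) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     dtype={"family": str, "zygosity": str,
                            "primer_index": str, "batch": str})
    return SampleMetadata(df, phenotype_columns, technical_columns)


# -- annotation -------------------------------------------------------------

def write_bed(annotation: list[MetaExon], path: str | Path) -> None:
    """0-based half-open BED6; name carries the gene ID."""
    with open(path, "w") as fh:
        for ex in annotation:
            fh.write(f"{ex.chromosome}\t{ex.start - 1}\t{ex.end}\t{ex.gene_id}\t0\t{ex.strand}\n")


def read_bed(path: str | Path) -> list[MetaExon]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            out.append(MetaExon(f[3], f[0], int(f[1]) + 1, int(f[2]), strand))
    return out


def write_gtf(annotation: list[MetaExon], path: str | Path) -> None:
    """Exon features, 1-based inclusive, gene_id attribute."""
    with open(path, "w") as fh:
        for ex in annotation:
            attrs = f'gene_id "{ex.gene_id}"; transcript_id "{ex.gene_id}.t1";'
            fh.write(
                f"{ex.chromosome}\tgxeqtl\texon\t{ex.start}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | Path) -> list[MetaExon]:
    """Exon intervals from a GTF, via pyranges."""
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    df = df[df["Feature"] == "exon"]
    out = []
    for row in df.itertuples(index=False):
        # pyranges coordinates are 0-based half-open
        out.append(MetaExon(row.gene_id, str(row.Chromosome), int(row.Start) + 1,
                            int(row.End), str(row.Strand)))
    return out


# -- truth table ------------------------------------------------------------

def write_truth_json(truth: TruthTable, path: str | Path) -> None:
    payload = {
        "effects": [e.__dict__ for e in truth.effects],
        "latent_scores": None if truth.latent_scores is None
        else truth.latent_scores.to_dict(orient="split"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path: str | Path) -> TruthTable:
    with open(path) as fh:
        payload = json.load(fh)
    effects = [PlantedEffect(**d) for d in payload["effects"]]
    scores = payload.get("latent_scores")
    latent = None
    if scores is not None:
        latent = pd.DataFrame(scores["data"], index=scores["index"], columns=scores["columns"])
    truth = TruthTable(latent_scores=latent)
    truth.effects = effects  # bypass conflict checks: these were validated at plant time
    return truth


def write_depths_tsv(depths: pd.Series, path: str | Path) -> None:
    depths.rename("well_mapped_reads").to_csv(path, sep="\t", index_label="sample_id")


def read_depths_tsv(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="sample_id")["well_mapped_reads"]
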