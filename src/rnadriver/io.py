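"""Readers and writers for the pipeline's on-disk formats.

Variant tables round-trip through minimal single-column VCF (all per-call
attributes in INFO), gene models through GTF, and matrices/fusion/junction
tables through headered TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pyranges as pr
import pysam

from .genes import GeneCatalog, GeneModel
from .matrix import CountMatrix
from .simulate import VARIANT_COLUMNS

_FLAGS = {
    "DBSNP": "in_dbsnp", "KG": "in_1000g", "CG": "in_cg",
    "NORMAL": "in_normal_panel", "THYMUS": "in_thymus", "COSMIC": "in_cosmic",
    "REPEAT": "in_repeat", "READEND": "read_end_only",
}


def _vcf_header(variants: pd.DataFrame,
                catalog: GeneCatalog | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if catalog is not None:
        for chrom in catalog.chromosomes:
            length = max(g.end for g in catalog.chromosome_genes(chrom)) + 10_000
            header.contigs.add(chrom, length=length)
    else:
        for chrom in dict.fromkeys(variants["chrom"]):
            length = int(variants.loc[variants["chrom"] == chrom, "pos"].max()) + 10_000
            header.contigs.add(chrom, length=length)
    header.info.add("SAMPLE", 1, "String", "Sample identifier")
    header.info.add("GENE", 1, "String", "Gene identifier")
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.info.add("AD", 1, "Integer", "Alternate-allele read depth")
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("ODP", 1, "Integer", "Depth in the companion assay")
    header.info.add("CSQ", ".", "String", "Consequence terms")
    header.info.add("HPCTX", 1, "String", "Homopolymer context around an INDEL")
    header.info.add("ANCHOR", 1, "Integer", "INDEL anchor offset within HPCTX")
    header.info.add("NOQC", 0, "Flag", "Upstream caller quality flag NOT passed")
    for flag, col in _FLAGS.items():
        header.info.add(flag, 0, "Flag", f"Membership flag for {col}")
    return header


def write_vcf(variants: pd.DataFrame, path,
              catalog: GeneCatalog | None = None) -> None:
    header = _vcf_header(variants, catalog)
    df = variants.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in df.iterrows():
            rec = out.new_record(contig=row["chrom"], start=int(row["pos"]) - 1,
                                 alleles=(row["ref"], row["alt"]))
            rec.info["SAMPLE"] = row["sample_id"]
            rec.info["GENE"] = row["gene_id"]
            rec.info["DP"] = int(row["depth"])
            rec.info["AD"] = int(row["alt_depth"])
            rec.info["VAF"] = float(row["vaf"])
            rec.info["ODP"] = int(row["other_depth"])
            rec.info["CSQ"] = tuple(str(row["consequence"]).split(","))
            if row["is_indel"]:
                rec.info["HPCTX"] = row["homopolymer_context"]
                rec.info["ANCHOR"] = int(row["anchor_offset"])
            if not row["caller_pass"]:
                rec.info["NOQC"] = True
            for flag, col in _FLAGS.items():
                if row[col]:
                    rec.info[flag] = True
            out.write(rec)


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            ref, alt = rec.ref, rec.alts[0]
            csq = info.get("CSQ", ())
            rows.append({
                "sample_id": info["SAMPLE"], "chrom": rec.chrom, "pos": rec.pos,
                "ref": ref, "alt": alt, "gene_id": info["GENE"],
                "depth": int(info["DP"]), "alt_depth": int(info["AD"]),
                "vaf": float(info["VAF"]), "is_indel": len(ref) != len(alt),
                "read_end_only": bool(info.get("READEND", False)),
                "consequence": ",".join(csq),
                "in_dbsnp": bool(info.get("DBSNP", False)),
                "in_1000g": bool(info.get("KG", False)),
                "in_cg": bool(info.get("CG", False)),
                "in_normal_panel": bool(info.get("NORMAL", False)),
                "in_thymus": bool(info.get("THYMUS", False)),
                "in_cosmic": bool(info.get("COSMIC", False)),
                "in_repeat": bool(info.get("REPEAT", False)),
                "caller_pass": not bool(info.get("NOQC", False)),
                "homopolymer_context": info.get("HPCTX", ""),
                "anchor_offset": int(info.get("ANCHOR", -1)),
                "other_depth": int(info.get("ODP", 0)),
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_gtf(catalog: GeneCatalog, path) -> None:
    """Gene models as GTF: one gene feature plus exon features per gene,
    flags and covariates carried in the attribute column."""
    with open(path, "w") as fh:
        for g in catalog:
            attrs = (
                f'gene_id "{g.gene_id}"; gc "{g.gc:.4f}"; '
                f'exonic_length "{g.length}"; gene_rank "{g.rank}"; '
                f'coding "{int(g.is_coding)}"; ribosomal "{int(g.is_ribosomal)}"; '
                f'mitochondrial "{int(g.is_chrm)}"; driver "{int(g.is_driver)}"; '
                f'tumor_suppressor "{int(g.is_tumor_suppressor)}"; '
                f'tf "{int(g.is_tf)}";'
            )
            fh.write(f"{g.chrom}\trnadriver\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for (es, ee) in g.exons:
                fh.write(f"{g.chrom}\trnadriver\texon\t{es}\t{ee}\t.\t"
                         f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")


def read_gtf(path) -> GeneCatalog:
    df = pr.read_gtf(str(path)).df
    genes = df[df["Feature"] == "gene"]
    exons = df[df["Feature"] == "exon"]
    models = []
    for _, row in genes.iterrows():
        gid = row["gene_id"]
        ex = exons[exons["gene_id"] == gid]
        exon_spans = tuple(sorted(
            (int(s) + 1, int(e)) for s, e in zip(ex["Start"], ex["End"])))
        models.append(GeneModel(
            gene_id=gid, chrom=str(row["Chromosome"]),
            start=int(row["Start"]) + 1, end=int(row["End"]),
            strand=str(row["Strand"]), exons=exon_spans,
            gc=float(row["gc"]), length=int(row["exonic_length"]),
            rank=int(row["gene_rank"]),
            is_coding=row["coding"] == "1", is_ribosomal=row["ribosomal"] == "1",
            is_chrm=row["mitochondrial"] == "1", is_driver=row["driver"] == "1",
            is_tumor_suppressor=row["tumor_suppressor"] == "1",
            is_tf=row["tf"] == "1",
        ))
    return GeneCatalog(models)


def write_counts(cm: CountMatrix, counts_path, sample_meta_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if sample_meta_path is not None:
        cm.sample_meta.to_csv(sample_meta_path, sep="\t", index=False)


def read_counts(counts_path, gene_meta: pd.DataFrame,
                sample_meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(sample_meta_path, sep="\t").set_index("sample_id", drop=False)
    return CountMatrix(counts, gene_meta, meta)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
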