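"""Readers and writers for the standard formats the pipeline touches.

External files use the community conventions (GFF3/GTF 1-based inclusive
coordinates, FASTA, TSV, a minimal VCF subset for genotypes); everything is
converted to 0-based half-open coordinates on the way in and back on the way
out, so the conversion is bijective and confined to this module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    AnnotationSet,
    ExpressionMatrix,
    Gene,
    GenotypeTable,
    LncRnaLocus,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# IUPAC ambiguity letters for heterozygous calls (Table-style single-letter
# genotype encodings) plus the unambiguous homozygote letters.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
MISSING_CALLS = {".", "-", "--", "..", "NN", "N", ""}


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


class ParseError(ValueError):
    pass


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
            if fields[2] in ("gene", "pseudogene", "transcript", "exon") and fields[6] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {fields[6]!r}")


def _gff_db(path: Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read reference gene models from a GFF3 (or GTF) file.

    Genes may carry exons either directly or via mRNA children; a gene with
    no exon features is treated as single-exon over its span.  Chromosome
    lengths are taken from ``##sequence-region`` pragmas when present,
    otherwise from the right-most feature per chromosome.
    """
    path = Path(path)
    _validate_gff_lines(path)
    db = _gff_db(path)

    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                chrom_lengths[chrom] = int(end)

    genes: dict[str, Gene] = {}
    for ftype in ("gene", "pseudogene"):
        for feat in db.features_of_type(ftype):
            start, end = to_internal(feat.start, feat.end)
            exons = sorted(
                to_internal(e.start, e.end)
                for e in db.children(feat, featuretype="exon")
            )
            if not exons:
                exons = [(start, end)]
            biotype = feat.attributes.get("biotype", [None])[0]
            if biotype is None:
                biotype = "pseudogene" if ftype == "pseudogene" else "protein_coding"
            genes[feat.id] = Gene(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                exons=exons,
                biotype=biotype,
            )
            chrom_lengths.setdefault(feat.seqid, 0)
            chrom_lengths[feat.seqid] = max(chrom_lengths[feat.seqid], end)
    return AnnotationSet(genes=genes, chrom_lengths=chrom_lengths)


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
        for gene in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.start)):
            start, end = to_external(gene.start, gene.end)
            ftype = "pseudogene" if gene.biotype == "pseudogene" else "gene"
            fh.write(
                f"{gene.chrom}\tpalmlnc\t{ftype}\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id};biotype={gene.biotype}\n"
            )
            for i, (es, ee) in enumerate(gene.exons, start=1):
                xs, xe = to_external(es, ee)
                fh.write(
                    f"{gene.chrom}\tpalmlnc\texon\t{xs}\t{xe}\t.\t{gene.strand}\t.\t"
                    f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read assembled transcript models from a GTF/GFF file.

    Per-transcript abundance is taken from an ``FPKM`` attribute when
    present (StringTie-style).
    """
    path = Path(path)
    _validate_gff_lines(path)
    db = _gff_db(path)
    transcripts = []
    for feat in db.features_of_type("transcript"):
        exons = sorted(
            to_internal(e.start, e.end)
            for e in db.children(feat, featuretype="exon")
        )
        if not exons:
            exons = [to_internal(feat.start, feat.end)]
        fpkm = feat.attributes.get("FPKM", [None])[0]
        transcripts.append(
            TranscriptModel(
                transcript_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=exons,
                fpkm=float(fpkm) if fpkm is not None else None,
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return transcripts


def write_transcripts(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            start, end = to_external(tx.start, tx.end)
            attrs = f'transcript_id "{tx.transcript_id}";'
            if tx.fpkm is not None:
                attrs += f' FPKM "{tx.fpkm!r}";'
            fh.write(
                f"{tx.chrom}\tpalmlnc\ttranscript\t{start}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for es, ee in tx.exons:
                xs, xe = to_external(es, ee)
                fh.write(
                    f"{tx.chrom}\tpalmlnc\texon\t{xs}\t{xe}\t.\t{tx.strand}\t.\t"
                    f'transcript_id "{tx.transcript_id}";\n'
                )


def read_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_expression(
    path: str | Path, required_samples: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Read a features x samples FPKM table (TSV, first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric expression value {bad.iloc[0]!r} in column {col!r}"
            )
    if required_samples is not None:
        missing = [s for s in required_samples if s not in df.columns]
        if missing:
            raise ParseError(f"missing sample column(s): {', '.join(missing)}")
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def normalize_call(call: str, allele_a: str, allele_b: str) -> int:
    """Normalize a genotype call to B-allele dosage (-1 = missing).

    Accepts two-letter allele pairs ("AG"), single homozygote letters ("G")
    and single IUPAC heterozygote letters ("R" = A/G).
    """
    call = call.strip().upper()
    if call in MISSING_CALLS:
        return GenotypeTable.MISSING
    if len(call) == 1:
        if call in "ACGT":
            pair = (call, call)
        elif call in IUPAC_HET:
            pair = IUPAC_HET[call]
        else:
            raise ParseError(f"unrecognized genotype call {call!r}")
    elif len(call) == 2 and set(call) <= set("ACGT"):
        pair = (call[0], call[1])
    elif "/" in call and len(call) == 3:
        pair = (call[0], call[2])
    else:
        raise ParseError(f"unrecognized genotype call {call!r}")
    alleles = {allele_a, allele_b}
    if not set(pair) <= alleles:
        raise ParseError(
            f"call {call!r} inconsistent with alleles {allele_a}/{allele_b}"
        )
    return sum(1 for a in pair if a == allele_b)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read genotypes from TSV (or a minimal VCF if the file ends in .vcf).

    TSV layout: columns ``snp_id  chrom  pos  alleles`` then one column per
    individual; ``pos`` is 1-based; ``alleles`` is "A/B".  Sites with more
    than two alleles are skipped with a warning.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["snp_id", "chrom", "pos", "alleles"]
    if list(df.columns[:4]) != fixed:
        raise ParseError(f"genotype TSV must start with columns {fixed}")
    individuals = list(df.columns[4:])
    rows, dosages = [], []
    for _, row in df.iterrows():
        alleles = row["alleles"].split("/")
        if len(alleles) != 2:
            logger.warning("skipping non-biallelic site %s (%s)", row["snp_id"], row["alleles"])
            continue
        a, b = alleles
        rows.append(
            {
                "snp_id": row["snp_id"],
                "chrom": row["chrom"],
                "pos": int(row["pos"]) - 1,
                "allele_a": a,
                "allele_b": b,
            }
        )
        dosages.append([normalize_call(row[ind], a, b) for ind in individuals])
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"])
    dosage = np.array(dosages, dtype=np.int8).reshape(len(rows), len(individuals))
    return GenotypeTable(snps, dosage, individuals)


def _read_vcf(path: Path) -> GenotypeTable:
    individuals: list[str] = []
    rows, dosages = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                logger.warning("skipping non-biallelic VCF site %s", snp_id)
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            calls = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    calls.append(GenotypeTable.MISSING)
                else:
                    calls.append(sum(int(a) for a in gt.split("/")))
            rows.append(
                {
                    "snp_id": snp_id if snp_id != "." else f"{chrom}:{pos}",
                    "chrom": chrom,
                    "pos": int(pos) - 1,
                    "allele_a": ref,
                    "allele_b": alt,
                }
            )
            dosages.append(calls)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"])
    dosage = np.array(dosages, dtype=np.int8).reshape(len(rows), len(individuals))
    return GenotypeTable(snps, dosage, individuals)


_DOSAGE_TO_CALL = {0: "{a}{a}", 1: "{a}{b}", 2: "{b}{b}", GenotypeTable.MISSING: "."}


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\talleles\t" + "\t".join(table.individuals) + "\n")
        for i, row in table.snps.iterrows():
            calls = [
                _DOSAGE_TO_CALL[int(d)].format(a=row["allele_a"], b=row["allele_b"])
                for d in table.dosage[i]
            ]
            fh.write(
                f"{row['snp_id']}\t{row['chrom']}\t{row['pos'] + 1}\t"
                f"{row['allele_a']}/{row['allele_b']}\t" + "\t".join(calls) + "\n"
            )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype table: first column individual id, remaining columns traits."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="individual")


def write_loci_gff3(loci: Iterable[LncRnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            start, end = to_external(locus.start, locus.end)
            attrs = (
                f"ID={locus.locus_id};lnc_class={locus.lnc_class};"
                f"members={','.join(locus.members)}"
            )
            if locus.nat_subtype:
                attrs += f";nat_subtype={locus.nat_subtype}"
            if locus.partner_gene:
                attrs += f";partner_gene={locus.partner_gene}"
            fh.write(
                f"{locus.chrom}\tpalmlnc\tlnc_RNA\t{start}\t{end}\t.\t{locus.strand}\t.\t{attrs}\n"
            )


def read_loci_gff3(path: str | Path) -> list[LncRnaLocus]:
    _validate_gff_lines(Path(path))
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            start, end = to_internal(int(fields[3]), int(fields[4]))
            loci.append(
                LncRnaLocus(
                    locus_id=attrs["ID"],
                    chrom=fields[0],
                    strand=fields[6],
                    start=start,
                    end=end,
                    members=attrs.get("members", "").split(",") if attrs.get("members") else [],
                    lnc_class=attrs["lnc_class"],
                    nat_subtype=attrs.get("nat_subtype"),
                    partner_gene=attrs.get("partner_gene"),
                )
            )
    return loci


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV, preserving column order."""
    records.to_csv(path, sep="\t", index=False)
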