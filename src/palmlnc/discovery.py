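"""lncRNA candidate filtering, positional classification and locus merging.

A transcript survives the candidate filters when its spliced length exceeds
200 nt, it has more than one exon, its abundance is at least 0.1 FPKM and
its longest ATG-initiated, stop-terminated open reading frame encodes at
most 50 amino acids.  Survivors are classified by their genomic relation to
the reference annotation into four classes -- lincRNA (intergenic), NAT
(antisense overlap or a 2-kb antisense flank), intronic (inside an intron of
a same-strand protein-coding gene) and sense (exonic overlap with a
same-strand pseudogene) -- and natural antisense transcripts are further
split into six geometric subtypes.  Finally same-strand overlapping
transcripts are merged into loci.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .containers import (
    AnnotationSet,
    ExpressionMatrix,
    FilterReport,
    Gene,
    Interval,
    LncRnaLocus,
    NAT_SUBTYPES,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

MIN_LENGTH_NT = 200       # spliced length must exceed this (strict)
MIN_FPKM = 0.1            # inclusive
MAX_ORF_AA = 50           # inclusive ("more than 50 aa" fails)
FLANK_WINDOW_NT = 2000    # antisense flank window for NAT subtypes V/VI

STOP_CODONS = ("TAA", "TAG", "TGA")

#: class codes: u intergenic, i intronic, o sense (pseudogene) overlap,
#: x antisense exonic overlap; transcripts with same-strand exonic overlap
#: of a protein-coding gene, or an otherwise ambiguous genic relation, are
#: excluded from the lncRNA set.
CLASS_CODES = ("u", "i", "o", "x", "coding_overlap_sense_exonic", "other_genic")

CODE_TO_CLASS = {"u": "lincRNA", "i": "intronic", "o": "sense", "x": "NAT"}

#: tie-break precedence for locus class conflicts after merging
CLASS_PRECEDENCE = ("NAT", "intronic", "sense", "lincRNA")


def max_orf_aa(sequence: str) -> int:
    """Length (aa) of the longest ATG-initiated, stop-terminated ORF.

    Scans the three forward frames of the given spliced sequence (the
    strand is known from the assembly, so reverse frames are not searched).
    The length counts Met through the last codon before the stop; a
    sequence with no complete ORF scores 0.
    """
    seq = sequence.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    best = max(best, (i - open_start) // 3)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    return best


def basic_filters(
    transcript: TranscriptModel,
    fpkm: float | None,
    spliced_sequence: str | None = None,
    orf_aa: int | None = None,
) -> FilterReport:
    """Apply the four candidate filters to one transcript.

    A missing abundance (or missing sequence, which leaves the ORF rule
    unevaluable) is recorded as indeterminate and the verdict is fail.
    """
    if orf_aa is None and spliced_sequence is not None:
        orf_aa = max_orf_aa(spliced_sequence)
    return FilterReport(
        transcript_id=transcript.transcript_id,
        length_pass=transcript.spliced_length > MIN_LENGTH_NT,
        exon_pass=len(transcript.exons) > 1,
        fpkm_pass=None if fpkm is None else fpkm >= MIN_FPKM,
        orf_pass=None if orf_aa is None else orf_aa <= MAX_ORF_AA,
        spliced_length=transcript.spliced_length,
        exon_count=len(transcript.exons),
        fpkm=fpkm,
        orf_aa=orf_aa,
    )


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _exonic_overlap(exons_a: list[Interval], exons_b: list[Interval]) -> int:
    return sum(_overlap(ea, eb) for ea in exons_a for eb in exons_b)


def classify_class_code(transcript: TranscriptModel, annotation: AnnotationSet) -> str:
    """Relate a transcript to the reference annotation by a class code.

    Precedence when several relations hold: same-strand exonic overlap of a
    protein-coding gene (exclusion) first, then x > o > i > u; a transcript
    overlapping a gene span without qualifying for any code is tagged
    ``other_genic`` and likewise excluded.
    """
    chrom_len = annotation.chrom_lengths.get(transcript.chrom)
    if chrom_len is not None and transcript.end > chrom_len:
        raise ValueError(
            f"transcript {transcript.transcript_id} beyond {transcript.chrom} bounds"
        )
    genes = annotation.genes_on(transcript.chrom)
    span = transcript.span

    for gene in genes:
        if (
            gene.biotype == "protein_coding"
            and gene.strand == transcript.strand
            and _exonic_overlap(transcript.exons, gene.exons) > 0
        ):
            return "coding_overlap_sense_exonic"
    for gene in genes:
        if gene.strand != transcript.strand and _exonic_overlap(transcript.exons, gene.exons) > 0:
            return "x"
    for gene in genes:
        if (
            gene.biotype == "pseudogene"
            and gene.strand == transcript.strand
            and _exonic_overlap(transcript.exons, gene.exons) > 0
        ):
            return "o"
    for gene in genes:
        if gene.biotype == "protein_coding" and gene.strand == transcript.strand:
            for intron in gene.introns():
                if intron[0] <= span[0] and span[1] <= intron[1]:
                    return "i"
    if all(_overlap(span, g.span) == 0 for g in genes):
        return "u"
    return "other_genic"


def classify_nat_subtype(
    lnc_span: Interval,
    lnc_strand: str,
    gene: Gene,
    window: int = FLANK_WINDOW_NT,
) -> str:
    """Assign one of the six NAT geometric subtypes.

    Genic-overlap cases: I = partial overlap at the lncRNA's 5' end
    (divergent, head-to-head), II = partial overlap at its 3' end
    (convergent, tail-to-tail), III = lncRNA wholly inside the gene span,
    IV = gene wholly inside the lncRNA span.  Flanking cases: V = gene
    within the 2-kb upstream (promoter-side) window, VI = within the 2-kb
    downstream window.  The partner must lie on the opposite strand.
    """
    if gene.strand == lnc_strand:
        raise ValueError(f"partner gene {gene.gene_id} is on the same strand")
    ls, le = lnc_span
    gs, ge = gene.span
    if _overlap(lnc_span, gene.span) > 0:
        if gs <= ls and le <= ge:
            return "III"
        if ls <= gs and ge <= le:
            return "IV"
        # partial overlap: decide which end of the lncRNA the gene crosses
        crosses_start = gs < ls
        if lnc_strand == "+":
            return "I" if crosses_start else "II"
        return "II" if crosses_start else "I"
    # no overlap: flanking relation
    if ge <= ls:
        distance, side = ls - ge, "left"
    else:
        distance, side = gs - le, "right"
    if distance > window:
        raise ValueError(
            f"gene {gene.gene_id} is {distance} nt away; not within the {window}-nt flank"
        )
    upstream = (side == "left") if lnc_strand == "+" else (side == "right")
    return "V" if upstream else "VI"


def _span_distance(a: Interval, b: Interval) -> int:
    if _overlap(a, b) > 0:
        return 0
    return b[0] - a[1] if b[0] >= a[1] else a[0] - b[1]


def choose_partner(
    transcript: TranscriptModel,
    candidates: list[Gene],
) -> Gene | None:
    """Deterministic partner-gene choice: largest exonic overlap, then
    largest span overlap, then smallest distance, then lexicographic id."""
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda g: (
            -_exonic_overlap(transcript.exons, g.exons),
            -_overlap(transcript.span, g.span),
            _span_distance(transcript.span, g.span),
            g.gene_id,
        ),
    )


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    class_code: str
    lnc_class: str | None
    nat_subtype: str | None = None
    partner_gene: str | None = None


def classify_transcript(
    transcript: TranscriptModel,
    annotation: AnnotationSet,
    window: int = FLANK_WINDOW_NT,
) -> ClassifiedTranscript:
    """Full class assignment for one filtered transcript.

    x -> NAT with a genic subtype; u -> NAT (subtype V/VI) when an
    opposite-strand gene lies within the flank window, else lincRNA;
    i -> intronic; o -> sense.  Excluded codes carry no class.
    """
    code = classify_class_code(transcript, annotation)
    if code in ("coding_overlap_sense_exonic", "other_genic"):
        return ClassifiedTranscript(transcript, code, None)
    genes = annotation.genes_on(transcript.chrom)
    if code == "x":
        partners = [
            g
            for g in genes
            if g.strand != transcript.strand
            and _exonic_overlap(transcript.exons, g.exons) > 0
        ]
        partner = choose_partner(transcript, partners)
        subtype = classify_nat_subtype(transcript.span, transcript.strand, partner, window)
        return ClassifiedTranscript(transcript, code, "NAT", subtype, partner.gene_id)
    if code == "u":
        flank = [
            g
            for g in genes
            if g.strand != transcript.strand
            and 0 < _span_distance(transcript.span, g.span) <= window
        ]
        partner = choose_partner(transcript, flank)
        if partner is not None:
            subtype = classify_nat_subtype(
                transcript.span, transcript.strand, partner, window
            )
            return ClassifiedTranscript(transcript, code, "NAT", subtype, partner.gene_id)
        return ClassifiedTranscript(transcript, code, "lincRNA")
    if code == "i":
        hosts = [
            g
            for g in genes
            if g.biotype == "protein_coding"
            and g.strand == transcript.strand
            and any(
                i[0] <= transcript.start and transcript.end <= i[1]
                for i in g.introns()
            )
        ]
        partner = choose_partner(transcript, hosts)
        return ClassifiedTranscript(
            transcript, code, "intronic", partner_gene=partner.gene_id if partner else None
        )
    # code == "o"
    partners = [
        g
        for g in genes
        if g.biotype == "pseudogene"
        and g.strand == transcript.strand
        and _exonic_overlap(transcript.exons, g.exons) > 0
    ]
    partner = choose_partner(transcript, partners)
    return ClassifiedTranscript(
        transcript, code, "sense", partner_gene=partner.gene_id if partner else None
    )


def _majority(values: list[str], precedence: tuple[str, ...]) -> str:
    counts = Counter(values)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    for p in precedence:
        if p in tied:
            return p
    return sorted(tied)[0]


def merge_transcripts_to_loci(
    classified: list[ClassifiedTranscript],
) -> list[LncRnaLocus]:
    """Merge same-chromosome, same-strand transcripts with overlapping spans.

    The result is independent of input order and idempotent.  A locus
    inherits the majority class of its members (ties broken by the
    precedence NAT > intronic > sense > lincRNA); the subtype and partner
    gene come from the majority among members of the winning class.
    """
    kept = [c for c in classified if c.lnc_class is not None]
    groups: dict[tuple[str, str], list[ClassifiedTranscript]] = {}
    for c in kept:
        groups.setdefault((c.transcript.chrom, c.transcript.strand), []).append(c)

    loci: list[LncRnaLocus] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda c: (c.transcript.start, c.transcript.transcript_id))
        cluster: list[ClassifiedTranscript] = []
        cur_end = -1
        for c in members:
            if cluster and c.transcript.start < cur_end:
                cluster.append(c)
                cur_end = max(cur_end, c.transcript.end)
            else:
                if cluster:
                    loci.append(_build_locus(chrom, strand, cluster))
                cluster = [c]
                cur_end = c.transcript.end
        if cluster:
            loci.append(_build_locus(chrom, strand, cluster))
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"LNC{i:05d}"
    return loci


def _build_locus(chrom: str, strand: str, members: list[ClassifiedTranscript]) -> LncRnaLocus:
    lnc_class = _majority([c.lnc_class for c in members], CLASS_PRECEDENCE)
    winning = [c for c in members if c.lnc_class == lnc_class]
    subtype = None
    if lnc_class == "NAT":
        subtype = _majority(
            [c.nat_subtype for c in winning if c.nat_subtype], NAT_SUBTYPES
        )
    partners = sorted(c.partner_gene for c in winning if c.partner_gene)
    partner = Counter(partners).most_common(1)[0][0] if partners else None
    return LncRnaLocus(
        locus_id="",
        chrom=chrom,
        strand=strand,
        start=min(c.transcript.start for c in members),
        end=max(c.transcript.end for c in members),
        members=sorted(c.transcript.transcript_id for c in members),
        lnc_class=lnc_class,
        nat_subtype=subtype,
        partner_gene=partner,
    )


def class_count_table(
    counts: pd.DataFrame, chromosomes: list[str] | None = None
) -> pd.DataFrame:
    """Build the per-chromosome class count table with totals.

    ``counts`` is indexed by chromosome with one column per lncRNA class;
    chromosomes not in ``chromosomes`` are pooled into an "others" row.  A
    "Total" column and row are appended; row totals are the sum of the four
    class counts by construction.
    """
    classes = ["lincRNA", "NAT", "intronic", "sense"]
    counts = counts.reindex(columns=classes, fill_value=0)
    if chromosomes is None:
        chromosomes = [c for c in counts.index]
    main = counts.reindex(chromosomes, fill_value=0)
    others = counts.loc[[c for c in counts.index if c not in chromosomes]]
    table = main.copy()
    if len(others):
        table.loc["others"] = others.sum()
    elif "others" not in table.index:
        table.loc["others"] = 0
    table["Total"] = table[classes].sum(axis=1)
    table.loc["Total"] = table.sum()
    return table.astype(int)


@dataclass
class DiscoveryResult:
    loci: list[LncRnaLocus]
    filter_reports: list[FilterReport]
    classified: list[ClassifiedTranscript]
    class_table: pd.DataFrame

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "spliced_length": r.spliced_length,
                    "exon_count": r.exon_count,
                    "fpkm": r.fpkm,
                    "orf_aa": r.orf_aa,
                    "length_pass": r.length_pass,
                    "exon_pass": r.exon_pass,
                    "fpkm_pass": r.fpkm_pass,
                    "orf_pass": r.orf_pass,
                    "verdict": r.verdict,
                }
                for r in self.filter_reports
            ]
        )


def discover_lncrnas(
    transcripts: list[TranscriptModel],
    annotation: AnnotationSet,
    expression: ExpressionMatrix | None = None,
    genome: dict[str, str] | None = None,
    chromosomes: list[str] | None = None,
) -> DiscoveryResult:
    """End-to-end discovery: filter, classify, merge, tabulate.

    Abundance for the FPKM filter is the transcript's maximum FPKM across
    the samples of ``expression`` when given, else the transcript's own
    assembly FPKM.  The ORF rule needs ``genome`` for spliced sequences.
    """
    reports: list[FilterReport] = []
    survivors: list[TranscriptModel] = []
    fpkm_max = expression.fpkm_max() if expression is not None else None
    for tx in transcripts:
        if fpkm_max is not None and tx.transcript_id in fpkm_max.index:
            fpkm = float(fpkm_max[tx.transcript_id])
        else:
            fpkm = tx.fpkm
        seq = tx.spliced_sequence(genome) if genome is not None else None
        report = basic_filters(tx, fpkm, spliced_sequence=seq)
        reports.append(report)
        if report.verdict:
            survivors.append(tx)

    classified = [classify_transcript(tx, annotation) for tx in survivors]
    excluded = [c for c in classified if c.lnc_class is None]
    if excluded:
        logger.info("excluded %d transcripts with coding/ambiguous overlap", len(excluded))
    loci = merge_transcripts_to_loci(classified)

    counts = (
        pd.DataFrame(
            [(l.chrom, l.lnc_class) for l in loci], columns=["chrom", "lnc_class"]
        )
        .groupby(["chrom", "lnc_class"])
        .size()
        .unstack(fill_value=0)
        if loci
        else pd.DataFrame(columns=["lincRNA", "NAT", "intronic", "sense"])
    )
    if chromosomes is None:
        chromosomes = sorted(annotation.chrom_lengths)
    table = class_count_table(counts, chromosomes)
    return DiscoveryResult(loci, reports, classified, table)
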