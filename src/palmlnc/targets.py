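"""Cis and trans target-gene prediction for lncRNA loci.

Cis targets are protein-coding genes whose span overlaps a locus or lies
within a 2-kb flank on either side (inclusive at exactly 2000 nt).  Trans
targets are scored by sliding one spliced sequence over the reverse of the
other and summing nearest-neighbour stacking free energies over contiguous
complementary stretches (Watson-Crick pairs plus G:U wobble); the minimum
total energy normalised by the shorter sequence length (ndG, in
kcal/mol/nt) calls a target when it falls at or below a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    Gene,
    Interval,
    LncRnaLocus,
    TranscriptModel,
)
from .discovery import _exonic_overlap, _overlap, _span_distance

logger = logging.getLogger(__name__)

CIS_WINDOW_NT = 2000
NDG_CUTOFF = -0.1  # kcal/mol/nt; pair called a trans target when ndG <= cutoff


@dataclass
class TargetPair:
    """One (lncRNA locus, gene) candidate with its mechanism."""

    locus_id: str
    gene_id: str
    mechanism: str  # cis_overlap | cis_flank | trans_duplex
    overlap: int = 0          # span overlap, nt (cis_overlap)
    distance: int | None = None  # span-to-span distance, nt (cis_flank)
    antisense: bool = False
    transcript_overlap: bool = False  # exon-level overlap of members vs gene exons
    ndg: float | None = None  # kcal/mol/nt (trans_duplex)


def cis_targets(
    locus: LncRnaLocus,
    annotation: AnnotationSet,
    transcripts: dict[str, TranscriptModel] | None = None,
    window: int = CIS_WINDOW_NT,
) -> list[TargetPair]:
    """Protein-coding genes overlapping the locus or within ``window`` nt.

    Overlapping genes are tagged ``cis_overlap`` (with ``antisense`` set for
    opposite-strand partners) and flanking genes ``cis_flank``; the
    ``transcript_overlap`` flag records whether any member transcript's
    exons overlap the gene's exons.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    pairs: list[TargetPair] = []
    member_exons: list[Interval] = []
    if transcripts is not None:
        for tid in locus.members:
            if tid in transcripts:
                member_exons.extend(transcripts[tid].exons)
    for gene in sorted(annotation.genes_on(locus.chrom), key=lambda g: g.gene_id):
        if gene.biotype != "protein_coding":
            continue
        ov = _overlap(locus.span, gene.span)
        if ov > 0:
            pairs.append(
                TargetPair(
                    locus_id=locus.locus_id,
                    gene_id=gene.gene_id,
                    mechanism="cis_overlap",
                    overlap=ov,
                    antisense=gene.strand != locus.strand,
                    transcript_overlap=_exonic_overlap(member_exons, gene.exons) > 0,
                )
            )
        else:
            dist = _span_distance(locus.span, gene.span)
            if dist <= window:
                pairs.append(
                    TargetPair(
                        locus_id=locus.locus_id,
                        gene_id=gene.gene_id,
                        mechanism="cis_flank",
                        distance=dist,
                        antisense=gene.strand != locus.strand,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# trans duplex energy

# Nearest-neighbour stacking free energies (kcal/mol, 37 C) for
# Watson-Crick / Watson-Crick stacks, keyed "XY/ZW" = 5'-XY-3' paired with
# 3'-ZW-5'.  Any stack involving a G:U wobble pair scores WOBBLE_STACK.
_WC_STACKS = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}
WOBBLE_STACK = -0.5

_BASES = "ACGU"
_INDEX = {b: i for i, b in enumerate(_BASES)}
_INDEX["N"] = 4

# pairing matrix over A,C,G,U,N (N never pairs)
_PAIRS = np.zeros((5, 5), dtype=bool)
for x, y in [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]:
    _PAIRS[_INDEX[x], _INDEX[y]] = True
_WOBBLE = {("G", "U"), ("U", "G")}


def _stack_energy_table() -> np.ndarray:
    """4-D lookup E[x1, x2, z1, z2] for the stack 5'-x1 x2-3' / 3'-z1 z2-5'.

    Built from the Watson-Crick table (inserted in both physical reading
    orientations, E(XY/ZW) = E(WZ/YX)) with the wobble constant for stacks
    containing a G:U pair; non-paired combinations score 0.
    """
    table = np.zeros((5, 5, 5, 5))
    energies: dict[str, float] = {}
    for key, e in _WC_STACKS.items():
        top, bottom = key.split("/")
        energies[key] = e
        energies[f"{bottom[::-1]}/{top[::-1]}"] = e
    for x1 in _BASES:
        for x2 in _BASES:
            for z1 in _BASES:
                for z2 in _BASES:
                    if not (_PAIRS[_INDEX[x1], _INDEX[z1]] and _PAIRS[_INDEX[x2], _INDEX[z2]]):
                        continue
                    if (x1, z1) in _WOBBLE or (x2, z2) in _WOBBLE:
                        e = WOBBLE_STACK
                    else:
                        e = energies[f"{x1}{x2}/{z1}{z2}"]
                    table[_INDEX[x1], _INDEX[x2], _INDEX[z1], _INDEX[z2]] = e
    return table


_STACKS = _stack_energy_table()


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return np.fromiter((_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def trans_duplex_ndG(seq_a: str, seq_b: str, min_length: int = 50) -> float:
    """Normalised duplex free energy (kcal/mol/nt) between two sequences.

    The shorter sequence is slid over the reverse of the longer (all
    antiparallel alignments, overhangs allowed); within each offset,
    adjacent complementary positions contribute their stacking energy and
    mismatches break stacks.  The minimum total over offsets is divided by
    the shorter sequence length.  Symmetric in argument order.
    """
    if len(seq_a) < min_length or len(seq_b) < min_length:
        raise ValueError(f"both sequences must be at least {min_length} nt")
    short, long_ = sorted((seq_a, seq_b), key=len)
    s = _encode(short)
    l_rev = _encode(long_)[::-1].copy()
    m, n = len(s), len(l_rev)
    best = 0.0
    # offset o: s[i] aligned with l_rev[o + i]
    for o in range(-(m - 1), n):
        i0 = max(0, -o)
        i1 = min(m, n - o)
        if i1 - i0 < 2:
            continue
        ss = s[i0:i1]
        ll = l_rev[i0 + o : i1 + o]
        paired = _PAIRS[ss, ll]
        both = paired[:-1] & paired[1:]
        if not both.any():
            continue
        e = _STACKS[ss[:-1], ss[1:], ll[:-1], ll[1:]][both].sum()
        best = min(best, e)
    return best / m


def trans_targets(
    locus_sequences: dict[str, str],
    mrna_sequences: dict[str, str],
    cutoff: float = NDG_CUTOFF,
) -> list[TargetPair]:
    """Score every (locus, mRNA) candidate pair; keep those with ndG <= cutoff."""
    pairs = []
    for locus_id, lnc_seq in locus_sequences.items():
        for gene_id, mrna_seq in mrna_sequences.items():
            ndg = trans_duplex_ndG(lnc_seq, mrna_seq)
            if ndg <= cutoff:
                pairs.append(
                    TargetPair(
                        locus_id=locus_id,
                        gene_id=gene_id,
                        mechanism="trans_duplex",
                        ndg=ndg,
                    )
                )
    return pairs


def pairs_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": p.locus_id,
                "gene_id": p.gene_id,
                "mechanism": p.mechanism,
                "overlap": p.overlap,
                "distance": p.distance,
                "antisense": p.antisense,
                "transcript_overlap": p.transcript_overlap,
                "ndg": p.ndg,
            }
            for p in pairs
        ],
        columns=[
            "locus_id",
            "gene_id",
            "mechanism",
            "overlap",
            "distance",
            "antisense",
            "transcript_overlap",
            "ndg",
        ],
    )


@dataclass
class TargetPredictionResult:
    pairs: pd.DataFrame           # de-duplicated per (locus, gene, mechanism)
    class_summary: pd.DataFrame   # unique targets per lncRNA class

    @property
    def unique_targets(self) -> int:
        return self.pairs["gene_id"].nunique()


def predict_targets(
    loci: list[LncRnaLocus],
    annotation: AnnotationSet,
    transcripts: dict[str, TranscriptModel] | None = None,
    genome: dict[str, str] | None = None,
    window: int = CIS_WINDOW_NT,
    ndg_cutoff: float = NDG_CUTOFF,
    trans_candidates: dict[str, list[str]] | None = None,
) -> TargetPredictionResult:
    """Union of cis and trans target records for a set of loci.

    When a genome is supplied, loci with no cis target (or the explicit
    ``trans_candidates`` locus -> gene lists) are scanned for trans duplex
    targets against spliced mRNA sequences.
    """
    records: list[TargetPair] = []
    cisless: list[LncRnaLocus] = []
    for locus in loci:
        hits = cis_targets(locus, annotation, transcripts, window)
        records.extend(hits)
        if not hits:
            cisless.append(locus)

    if genome is not None:
        locus_by_id = {l.locus_id: l for l in loci}
        if trans_candidates is None:
            trans_candidates = {
                l.locus_id: [g.gene_id for g in annotation.protein_coding()]
                for l in cisless
            }
        for locus_id, gene_ids in trans_candidates.items():
            locus = locus_by_id[locus_id]
            lnc_seq = _locus_sequence(locus, transcripts, genome)
            mrnas = {
                gid: _gene_sequence(annotation.genes[gid], genome) for gid in gene_ids
            }
            records.extend(trans_targets({locus_id: lnc_seq}, mrnas, ndg_cutoff))

    frame = pairs_frame(records).drop_duplicates(
        subset=["locus_id", "gene_id", "mechanism"]
    )
    class_by_locus = {l.locus_id: l.lnc_class for l in loci}
    if len(frame):
        summary = (
            frame.assign(lnc_class=frame["locus_id"].map(class_by_locus))
            .groupby("lnc_class")["gene_id"]
            .nunique()
            .rename("unique_targets")
            .to_frame()
        )
    else:
        summary = pd.DataFrame(columns=["unique_targets"])
    return TargetPredictionResult(frame.reset_index(drop=True), summary)


def _locus_sequence(
    locus: LncRnaLocus,
    transcripts: dict[str, TranscriptModel] | None,
    genome: dict[str, str],
) -> str:
    if transcripts:
        member = next((transcripts[t] for t in locus.members if t in transcripts), None)
        if member is not None:
            return member.spliced_sequence(genome)
    tmp = TranscriptModel(locus.locus_id, locus.chrom, locus.strand, [locus.span])
    return tmp.spliced_sequence(genome)


def _gene_sequence(gene: Gene, genome: dict[str, str]) -> str:
    tmp = TranscriptModel(gene.gene_id, gene.chrom, gene.strand, list(gene.exons))
    return tmp.spliced_sequence(genome)
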