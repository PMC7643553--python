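"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates held by these containers are 0-based, half-open
``[start, end)``.  Conversion from the 1-based inclusive convention of
GFF3/GTF happens only at the I/O boundary (:mod:`palmlnc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

VALID_STRANDS = ("+", "-")

#: the four lncRNA positional classes
LNC_CLASSES = ("lincRNA", "NAT", "intronic", "sense")

#: NAT subtypes: I/II partial antisense overlap at the lncRNA 5'/3' end,
#: III lncRNA inside the gene, IV gene inside the lncRNA, V/VI gene in the
#: 2-kb upstream/downstream flank on the opposite strand.
NAT_SUBTYPES = ("I", "II", "III", "IV", "V", "VI")


def _check_intervals(exons: Sequence[Interval]) -> None:
    if not exons:
        raise ValueError("at least one exon is required")
    prev_end = -1
    for start, end in exons:
        if not (0 <= start < end):
            raise ValueError(f"invalid exon interval [{start}, {end})")
        if start < prev_end:
            raise ValueError("exons must be sorted and non-overlapping")
        prev_end = end


@dataclass
class Gene:
    """A reference gene model: span plus ordered, disjoint exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        _check_intervals(self.exons)
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise ValueError(f"exons outside gene span for {self.gene_id}")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class AnnotationSet:
    """Reference annotation: gene models and chromosome lengths."""

    genes: dict[str, Gene]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            length = self.chrom_lengths.get(gene.chrom)
            if length is not None and gene.end > length:
                raise ValueError(
                    f"gene {gene.gene_id} extends beyond {gene.chrom} length {length}"
                )

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def protein_coding(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]


@dataclass
class TranscriptModel:
    """An assembled transcript with optional assembly-level abundance."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"unknown strand {self.strand!r} for transcript {self.transcript_id}"
            )
        _check_intervals(self.exons)
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError("FPKM must be non-negative")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Exonic sequence 5'->3' on the transcript's own strand."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LncRnaLocus:
    """A merged lncRNA locus with its positional class."""

    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    members: list[str]
    lnc_class: str
    nat_subtype: str | None = None
    partner_gene: str | None = None

    def __post_init__(self) -> None:
        if self.lnc_class not in LNC_CLASSES:
            raise ValueError(f"unknown lncRNA class {self.lnc_class!r}")
        if (self.lnc_class == "NAT") != (self.nat_subtype is not None):
            raise ValueError("NAT subtype set iff class is NAT")
        if self.nat_subtype is not None and self.nat_subtype not in NAT_SUBTYPES:
            raise ValueError(f"unknown NAT subtype {self.nat_subtype!r}")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class FilterReport:
    """Per-transcript outcome of the lncRNA candidate filters.

    Each rule field is True (pass), False (fail) or None (indeterminate,
    e.g. no abundance value supplied); the verdict is pass only when every
    rule affirmatively passes.
    """

    transcript_id: str
    length_pass: bool
    exon_pass: bool
    fpkm_pass: bool | None
    orf_pass: bool | None
    spliced_length: int
    exon_count: int
    fpkm: float | None
    orf_aa: int | None

    @property
    def verdict(self) -> bool:
        return bool(
            self.length_pass
            and self.exon_pass
            and self.fpkm_pass is True
            and self.orf_pass is True
        )


class GenotypeTable:
    """Biallelic SNP calls for a panel of individuals.

    Calls are stored as the dosage of the B allele: 0 (AA), 1 (AB), 2 (BB),
    -1 for missing.
    """

    MISSING = -1

    def __init__(
        self,
        snps: pd.DataFrame,
        dosage: np.ndarray,
        individuals: Sequence[str],
    ) -> None:
        required = {"snp_id", "chrom", "pos", "allele_a", "allele_b"}
        if not required.issubset(snps.columns):
            raise ValueError(f"snps frame must have columns {sorted(required)}")
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(snps), len(individuals)):
            raise ValueError("dosage shape must be (n_snps, n_individuals)")
        if dosage.max(initial=0) > 2 or dosage.min(initial=0) < -1:
            raise ValueError("dosage entries must be in {-1, 0, 1, 2}")
        self.snps = snps.reset_index(drop=True)
        self.dosage = dosage
        self.individuals = list(individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def call_rate(self) -> np.ndarray:
        return (self.dosage != self.MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing calls."""
        observed = self.dosage != self.MISSING
        n_called = observed.sum(axis=1)
        with np.errstate(invalid="ignore"):
            b_freq = np.where(
                n_called > 0,
                np.where(self.dosage == self.MISSING, 0, self.dosage).sum(axis=1)
                / (2.0 * np.maximum(n_called, 1)),
                np.nan,
            )
        return np.minimum(b_freq, 1.0 - b_freq)

    def heterozygosity(self) -> np.ndarray:
        """Observed heterozygosity per SNP over non-missing calls."""
        observed = self.dosage != self.MISSING
        n_called = observed.sum(axis=1)
        if (n_called == 0).any():
            raise ValueError("SNP with no non-missing calls")
        return (self.dosage == 1).sum(axis=1) / n_called

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.snps.loc[mask].reset_index(drop=True),
            self.dosage[mask],
            self.individuals,
        )

    def imputed_dosage(self) -> np.ndarray:
        """Float dosage matrix with missing calls mean-imputed per SNP."""
        d = self.dosage.astype(float)
        d[d == self.MISSING] = np.nan
        means = np.nanmean(d, axis=1)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[0]]
        return d


class ExpressionMatrix:
    """FPKM values, features x samples."""

    def __init__(self, values: pd.DataFrame) -> None:
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.values = values.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def fpkm_max(self) -> pd.Series:
        """Per-feature maximum FPKM across samples (FPKM_max)."""
        return self.values.max(axis=1)

    def row(self, feature: str) -> np.ndarray:
        return self.values.loc[feature].to_numpy()

    def __contains__(self, feature: str) -> bool:
        return feature in self.values.index
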