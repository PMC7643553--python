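"""Synthetic data with the geometric and statistical structure the
pipeline assumes, carrying ground-truth labels for every planted feature.

The generator emulates the study design the pipeline targets: a small
plant genome with strand-annotated gene models; planted lncRNAs of all
four positional classes and all six NAT subtypes plus decoy transcripts
violating each candidate filter; log-normal FPKM matrices over 18 samples
with planted correlated lncRNA/target pairs and a configurable
low-expression fraction; structured genotypes for 200 individuals (five
admixed subpopulations, Balding-Nichols divergence, missing calls); and
phenotypes generated under the same Q+K mixed model the association stage
fits, with planted SNP effects in phenotype-standard-deviation units.

A single integer seed drives one documented generator stream; every stage
derives its own substream deterministically, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .association import kinship_matrix
from .containers import (
    AnnotationSet,
    ExpressionMatrix,
    Gene,
    GenotypeTable,
    Interval,
    TranscriptModel,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_STAGE_ANNOTATION = 0
_STAGE_EXPRESSION = 1
_STAGE_GENOTYPES = 2
_STAGE_PHENOTYPES = 3

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline emulates: 18 expression
    samples, 200 genotyped individuals in five admixed subpopulations, SNPs
    with minor-allele frequencies above 0.05, ~10% missing calls, a
    majority (~80%) of features at low (<1 FPKM) expression, planted
    coexpressed pairs at r* = 0.9 and a trait heritability of 0.4.
    """

    seed: int = 0
    # genome and annotation
    n_chromosomes: int = 3
    chromosome_length: int = 200_000
    n_background_genes: int = 12
    intergenic_spacing: int = 4000
    # planted lncRNAs per class / NAT subtype, plus one decoy per filter
    n_lincrna: int = 6
    nat_per_subtype: int = 2
    n_intronic: int = 3
    n_sense: int = 3
    plant_decoys: bool = True
    # expression
    n_samples: int = 18
    log_fpkm_mean: float = 0.0
    log_fpkm_sigma: float = 2.0
    low_expression_fraction: float = 0.8
    r_star: float = 0.9
    pair_log_sigma: float = 0.5
    n_coexpressed_pairs: int = 4
    # genotypes
    n_individuals: int = 200
    n_snps: int = 2000
    n_subpops: int = 5
    fst: float = 0.1
    admixture_alpha: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.1
    # phenotypes
    h2: float = 0.4
    n_causal: int = 2
    causal_beta: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not -1.0 < self.r_star < 1.0:
            raise ValueError("r_star must be in (-1, 1)")
        if self.n_samples < 4:
            raise ValueError("at least 4 samples required")
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_samples",
            "n_individuals",
            "n_snps",
            "n_subpops",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]
        )


# ---------------------------------------------------------------------------
# annotation, transcripts, genome

_LNC_EXONS: list[Interval] = [(0, 300), (500, 800)]  # spliced 600 nt
_LNC_WIDTH = 800
_GENE_EXONS: list[Interval] = [(0, 400), (700, 1100), (1400, 1800)]
_GENE_WIDTH = 1800


def _nat_gene_offset(subtype: str, lnc_strand: str) -> Interval:
    """Partner-gene span relative to a lncRNA at local [0, 800)."""
    mirror = lnc_strand == "-"
    if subtype == "III":
        return (-500, 1400)
    if subtype == "IV":
        return (200, 600)
    if subtype == "I":
        return (500, 2000) if mirror else (-1200, 300)
    if subtype == "II":
        return (-1200, 300) if mirror else (500, 2000)
    if subtype == "V":
        return (1300, 2800) if mirror else (-2000, -500)
    if subtype == "VI":
        return (-2000, -500) if mirror else (1300, 2800)
    raise ValueError(f"unknown NAT subtype {subtype}")


@dataclass
class SimulatedGenome:
    annotation: AnnotationSet
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    truth: pd.DataFrame  # transcript_id, lnc_class, nat_subtype, partner_gene, expected_fail


def simulate_annotation_and_transcripts(config: SimulationConfig) -> SimulatedGenome:
    """Plant genes, lncRNAs of every class/subtype and filter decoys.

    Units are laid out left to right with at least ``intergenic_spacing``
    nt between their bounding boxes, so the 2-kb cis window is unambiguous
    except where a unit plants proximity deliberately.
    """
    rng = config.rng(_STAGE_ANNOTATION)
    genes: dict[str, Gene] = {}
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    orf_decoy_ids: list[str] = []

    chroms = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}
    cursor = {c: 1000 for c in chroms}
    chrom_cycle = 0

    def place(width: int) -> tuple[str, int]:
        nonlocal chrom_cycle
        for _ in range(len(chroms)):
            chrom = chroms[chrom_cycle % len(chroms)]
            chrom_cycle += 1
            start = cursor[chrom] + config.intergenic_spacing
            if start + width < config.chromosome_length - 1000:
                cursor[chrom] = start + width
                return chrom, start
        raise ValueError(
            "infeasible packing: increase chromosome_length or n_chromosomes"
        )

    gene_counter = tx_counter = 0

    def add_gene(chrom: str, origin: int, span: Interval, exons: list[Interval], strand: str, biotype: str) -> str:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"GENE{gene_counter:04d}"
        genes[gid] = Gene(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            start=origin + span[0],
            end=origin + span[1],
            exons=[(origin + s, origin + e) for s, e in exons],
            biotype=biotype,
        )
        return gid

    def add_transcript(chrom: str, origin: int, exons: list[Interval], strand: str) -> TranscriptModel:
        nonlocal tx_counter
        tx_counter += 1
        tx = TranscriptModel(
            transcript_id=f"TX{tx_counter:04d}",
            chrom=chrom,
            strand=strand,
            exons=[(origin + s, origin + e) for s, e in exons],
        )
        transcripts.append(tx)
        return tx

    def record(tx: TranscriptModel, lnc_class=None, subtype=None, partner=None, expected_fail=None):
        truth_rows.append(
            {
                "transcript_id": tx.transcript_id,
                "lnc_class": lnc_class,
                "nat_subtype": subtype,
                "partner_gene": partner,
                "expected_fail": expected_fail,
            }
        )

    strands = ("+", "-")

    for _ in range(config.n_background_genes):
        chrom, origin = place(_GENE_WIDTH)
        add_gene(chrom, origin, (0, _GENE_WIDTH), _GENE_EXONS, rng.choice(strands), "protein_coding")

    for _ in range(config.n_lincrna):
        chrom, origin = place(_LNC_WIDTH)
        tx = add_transcript(chrom, origin, _LNC_EXONS, rng.choice(strands))
        record(tx, "lincRNA")

    for subtype in ("I", "II", "III", "IV", "V", "VI"):
        for _ in range(config.nat_per_subtype):
            lnc_strand = rng.choice(strands)
            gene_strand = "-" if lnc_strand == "+" else "+"
            gs, ge = _nat_gene_offset(subtype, lnc_strand)
            shift = -min(0, gs)
            width = max(_LNC_WIDTH, ge) + shift
            chrom, origin = place(width)
            gid = add_gene(
                chrom, origin, (gs + shift, ge + shift), [(gs + shift, ge + shift)],
                gene_strand, "protein_coding",
            )
            lnc_exons = [(s + shift, e + shift) for s, e in _LNC_EXONS]
            tx = add_transcript(chrom, origin, lnc_exons, lnc_strand)
            record(tx, "NAT", subtype, gid)

    for _ in range(config.n_intronic):
        strand = rng.choice(strands)
        chrom, origin = place(1800)
        gid = add_gene(chrom, origin, (0, 1800), [(0, 400), (1400, 1800)], strand, "protein_coding")
        tx = add_transcript(chrom, origin, [(500, 800), (1000, 1300)], strand)
        record(tx, "intronic", partner=gid)

    for _ in range(config.n_sense):
        strand = rng.choice(strands)
        chrom, origin = place(900)
        gid = add_gene(chrom, origin, (0, 900), [(0, 900)], strand, "pseudogene")
        tx = add_transcript(chrom, origin, [(100, 400), (500, 800)], strand)
        record(tx, "sense", partner=gid)

    if config.plant_decoys:
        chrom, origin = place(299)
        tx = add_transcript(chrom, origin, [(0, 100), (200, 299)], rng.choice(strands))
        record(tx, expected_fail="length")  # spliced 199 nt

        chrom, origin = place(500)
        tx = add_transcript(chrom, origin, [(0, 500)], rng.choice(strands))
        record(tx, expected_fail="exon")

        chrom, origin = place(_LNC_WIDTH)
        tx = add_transcript(chrom, origin, _LNC_EXONS, rng.choice(strands))
        record(tx, expected_fail="fpkm")

        chrom, origin = place(_LNC_WIDTH)
        tx = add_transcript(chrom, origin, _LNC_EXONS, "+")
        record(tx, expected_fail="orf")
        orf_decoy_ids.append(tx.transcript_id)

    annotation = AnnotationSet(genes=genes, chrom_lengths=chrom_lengths)
    genome = _simulate_sequences(config, rng, annotation, transcripts, truth_rows, orf_decoy_ids)
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "lnc_class", "nat_subtype", "partner_gene", "expected_fail"],
    )
    return SimulatedGenome(annotation, transcripts, genome, truth)


def _simulate_sequences(
    config: SimulationConfig,
    rng: np.random.Generator,
    annotation: AnnotationSet,
    transcripts: list[TranscriptModel],
    truth_rows: list[dict],
    orf_decoy_ids: list[str],
) -> dict[str, str]:
    """Random genome; lncRNAs meant to pass get ORF <= 50 aa by resampling
    their exonic sequence; the ORF decoy gets an embedded 61-aa ORF."""
    bases = np.array(list("ACGT"))
    genome = {
        chrom: rng.choice(bases, size=length)
        for chrom, length in annotation.chrom_lengths.items()
    }
    by_id = {t.transcript_id: t for t in transcripts}
    for row in truth_rows:
        tx = by_id[row["transcript_id"]]
        arr = genome[tx.chrom]
        if row["transcript_id"] in orf_decoy_ids:
            # 61-aa ORF (fails the <= 50 aa rule): ATG + 60 non-stop codons + TAA
            codons = ["ATG"]
            while len(codons) < 61:
                c = "".join(rng.choice(bases, size=3))
                if c not in STOP_CODONS and c != "ATG":
                    codons.append(c)
            orf = "".join(codons) + "TAA"
            s = tx.exons[0][0]
            arr[s : s + len(orf)] = list(orf)
            continue
        if row["expected_fail"] is None:
            from .discovery import max_orf_aa

            for _ in range(200):
                spliced = "".join("".join(arr[s:e]) for s, e in tx.exons)
                if tx.strand == "-":
                    spliced = reverse_complement(spliced)
                if max_orf_aa(spliced) <= 50:
                    break
                for s, e in tx.exons:
                    arr[s:e] = rng.choice(bases, size=e - s)
            else:
                raise RuntimeError("could not sample an ORF-free lncRNA sequence")
    return {chrom: "".join(arr) for chrom, arr in genome.items()}


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    features: list[str],
    pairs: list[tuple[str, str]] | None = None,
    zero_features: list[str] | None = None,
    min_fpkm_features: dict[str, float] | None = None,
    max_fpkm_features: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-normal FPKM matrix with planted correlated pairs.

    Baseline log-FPKM is i.i.d. Normal(mu, sigma); members of each planted
    pair are drawn from a bivariate normal with correlation ``r_star``.  A
    ``low_expression_fraction`` of the remaining features is rescaled so
    their FPKM_max falls below 1.  ``min_fpkm_features`` /
    ``max_fpkm_features`` rescale named rows so their FPKM_max is at least
    / at most the given value (used to make truth labels hold exactly);
    ``zero_features`` are all-zero rows.
    """
    if rng is None:
        rng = config.rng(_STAGE_EXPRESSION)
    pairs = pairs or []
    zero_features = set(zero_features or [])
    t = config.n_samples
    mu, sigma = config.log_fpkm_mean, config.log_fpkm_sigma

    values = pd.DataFrame(
        np.exp(rng.normal(mu, sigma, size=(len(features), t))),
        index=pd.Index(features, name="feature_id"),
        columns=[f"S{i + 1:02d}" for i in range(t)],
    )
    paired_features: set[str] = set()
    # planted pairs use a moderate log-scale spread so the planted
    # correlation survives the exp transform to the FPKM scale
    ps = config.pair_log_sigma
    cov = ps**2 * np.array([[1.0, config.r_star], [config.r_star, 1.0]])
    for a, b in pairs:
        z = rng.multivariate_normal([mu, mu], cov, size=t)
        values.loc[a] = np.exp(z[:, 0])
        values.loc[b] = np.exp(z[:, 1])
        paired_features.update((a, b))

    eligible = [
        f for f in features if f not in paired_features and f not in zero_features
    ]
    n_low = int(np.floor(config.low_expression_fraction * len(eligible)))
    low = rng.choice(len(eligible), size=n_low, replace=False) if n_low else []
    for idx in low:
        f = eligible[idx]
        target = rng.uniform(0.15, 0.95)
        row_max = values.loc[f].max()
        if row_max > 0:
            values.loc[f] *= target / row_max

    for f in zero_features:
        values.loc[f] = 0.0
    for f, floor_val in (min_fpkm_features or {}).items():
        row_max = values.loc[f].max()
        if 0 < row_max < floor_val:
            values.loc[f] *= floor_val / row_max
    for f, cap in (max_fpkm_features or {}).items():
        row_max = values.loc[f].max()
        if row_max > cap:
            values.loc[f] *= cap / row_max
    return ExpressionMatrix(values)


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class SimulatedGenotypes:
    table: GenotypeTable
    q_matrix: pd.DataFrame  # individuals x subpopulations, rows sum to 1
    subpop_freqs: np.ndarray  # (n_snps, n_subpops)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenotypes:
    """Admixed genotypes under the Balding-Nichols model.

    Ancestral allele frequencies are uniform on ``maf_range``; each
    subpopulation's frequency is Beta-distributed around the ancestral one
    with divergence ``fst``; individuals carry Dirichlet admixture
    proportions and genotypes are Hardy-Weinberg draws at the individual's
    expected frequency.  Calls go missing completely at random.
    """
    if rng is None:
        rng = config.rng(_STAGE_GENOTYPES)
    n, m, k = config.n_individuals, config.n_snps, config.n_subpops
    lo, hi = config.maf_range
    f = config.fst

    p_anc = rng.uniform(lo, hi, size=m)
    if f > 0:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        subpop_freqs = np.clip(rng.beta(a[:, None], b[:, None], size=(m, k)), 0.01, 0.99)
    else:
        subpop_freqs = np.repeat(p_anc[:, None], k, axis=1)

    if k == 1:
        q = np.ones((n, 1))
    else:
        q = rng.dirichlet(np.full(k, config.admixture_alpha), size=n)
    expected = subpop_freqs @ q.T  # (m, n)
    dosage = rng.binomial(2, expected).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(size=dosage.shape) < config.missing_rate
        dosage[mask] = GenotypeTable.MISSING

    allele_pairs = np.array([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")])
    chosen = allele_pairs[rng.integers(0, len(allele_pairs), size=m)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"SNP{i + 1:06d}" for i in range(m)],
            "chrom": "Chr1",
            "pos": np.arange(1, m + 1) * 50,
            "allele_a": chosen[:, 0],
            "allele_b": chosen[:, 1],
        }
    )
    table = GenotypeTable(snps, dosage, [f"IND{i + 1:04d}" for i in range(n)])
    q_matrix = pd.DataFrame(
        q, index=table.individuals, columns=[f"Q{j + 1}" for j in range(k)]
    )
    return SimulatedGenotypes(table, q_matrix, subpop_freqs)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class SimulatedPhenotype:
    y: pd.Series
    causal: dict[str, float]          # snp_id -> effect (phenotype-sd units)
    sigma_g2: float
    sigma_e2: float
    k_true: np.ndarray
    subpop_effects: np.ndarray | None


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: GenotypeTable,
    q_matrix: pd.DataFrame | np.ndarray,
    causal: dict[str, float] | None = None,
    subpop_effects: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    trait: str = "trait",
) -> SimulatedPhenotype:
    """Phenotypes under y = mu + sum_s x_s beta_s + Q v + g + e.

    The polygenic term g is multivariate normal with covariance
    sigma_g^2 K_true where K_true is the VanRaden kinship of the generating
    genotypes; sigma_g^2 = h2 and sigma_e^2 = 1 - h2, so the genetic
    fraction of variance matches h2 in expectation and planted effects are
    in phenotype-standard-deviation units (applied to standardised
    dosages).
    """
    if rng is None:
        rng = config.rng(_STAGE_PHENOTYPES)
    n = genotypes.n_individuals
    q = np.asarray(q_matrix, dtype=float)

    if causal is None:
        maf = genotypes.maf()
        candidates = np.flatnonzero(maf >= 0.2)
        if len(candidates) < config.n_causal:
            candidates = np.argsort(-maf)[: config.n_causal]
        chosen = rng.choice(candidates, size=config.n_causal, replace=False)
        causal = {
            genotypes.snps.loc[int(i), "snp_id"]: config.causal_beta for i in chosen
        }

    sigma_g2 = config.h2
    sigma_e2 = 1.0 - config.h2
    k_true = kinship_matrix(genotypes)
    evals, evecs = np.linalg.eigh(k_true)
    evals = np.clip(evals, 0.0, None)
    g = evecs @ (np.sqrt(sigma_g2 * evals) * rng.standard_normal(n))
    e = np.sqrt(sigma_e2) * rng.standard_normal(n)

    y = g + e
    dosage = genotypes.imputed_dosage()
    id_to_row = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    for snp_id, beta in causal.items():
        x = dosage[id_to_row[snp_id]]
        sd = x.std()
        if sd == 0:
            raise ValueError(f"causal SNP {snp_id} is monomorphic")
        y = y + beta * (x - x.mean()) / sd
    if subpop_effects is not None:
        y = y + q @ np.asarray(subpop_effects, dtype=float)

    series = pd.Series(y, index=genotypes.individuals, name=trait)
    return SimulatedPhenotype(series, causal, sigma_g2, sigma_e2, k_true, subpop_effects)


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimulationBundle:
    config: SimulationConfig
    annotation: AnnotationSet
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    truth: pd.DataFrame
    expression: ExpressionMatrix
    coexpressed_pairs: list[tuple[str, str]]
    genotypes: GenotypeTable
    q_matrix: pd.DataFrame
    phenotype: SimulatedPhenotype


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimulationBundle:
    """Run every generator stage and optionally write the standard files."""
    sim = simulate_annotation_and_transcripts(config)
    truth = sim.truth

    # abundance features: all transcripts plus all protein-coding genes
    gene_ids = sorted(g.gene_id for g in sim.annotation.protein_coding())
    tx_ids = [t.transcript_id for t in sim.transcripts]
    features = tx_ids + gene_ids

    nat_rows = truth[(truth["lnc_class"] == "NAT") & truth["partner_gene"].notna()]
    pairs = [
        (r["transcript_id"], r["partner_gene"])
        for _, r in nat_rows.head(config.n_coexpressed_pairs).iterrows()
    ]
    must_pass = truth.loc[truth["expected_fail"].isna(), "transcript_id"].tolist()
    fpkm_decoys = truth.loc[truth["expected_fail"] == "fpkm", "transcript_id"].tolist()
    expression = simulate_expression(
        config,
        features,
        pairs=pairs,
        min_fpkm_features={f: 0.5 for f in must_pass}
        | {a: 2.0 for pair in pairs for a in pair},
        max_fpkm_features={f: 0.05 for f in fpkm_decoys},
    )

    genos = simulate_genotypes(config)
    phenotype = simulate_phenotypes(config, genos.table, genos.q_matrix)

    bundle = SimulationBundle(
        config=config,
        annotation=sim.annotation,
        transcripts=sim.transcripts,
        genome=sim.genome,
        truth=truth,
        expression=expression,
        coexpressed_pairs=pairs,
        genotypes=genos.table,
        q_matrix=genos.q_matrix,
        phenotype=phenotype,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def write_bundle(bundle: SimulationBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_annotation(bundle.annotation, outdir / "annotation.gff3")
    pio.write_transcripts(bundle.transcripts, outdir / "transcripts.gtf")
    pio.write_genome(bundle.genome, outdir / "genome.fa")
    pio.write_expression(bundle.expression, outdir / "expression.tsv")
    pio.write_genotypes(bundle.genotypes, outdir / "genotypes.tsv")
    bundle.q_matrix.to_csv(outdir / "q_matrix.tsv", sep="\t", index_label="individual")
    pio.write_phenotypes(bundle.phenotype.y.to_frame(), outdir / "phenotypes.tsv")
    bundle.truth.to_csv(outdir / "truth_transcripts.tsv", sep="\t", index=False)
    pd.DataFrame(bundle.coexpressed_pairs, columns=["lnc_id", "target_id"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"snp_id": s, "beta": b} for s, b in bundle.phenotype.causal.items()]
    ).to_csv(outdir / "truth_causal_snps.tsv", sep="\t", index=False)
    logger.info("simulation written to %s (seed=%d)", outdir, bundle.config.seed)
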