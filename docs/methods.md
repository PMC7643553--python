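# Methods

This note documents the models, conventions and design choices behind
`palmlnc`, in the spirit of the methods documentation of statistical
genetics packages: what is computed, under which assumptions, with which
defaults, and what the synthetic-data validation does and does not show.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3/GTF's 1-based
inclusive convention is converted exactly at the I/O boundary, so interval
arithmetic (overlaps, containment, distances) is uniform everywhere.
Genotype calls are accepted as two-letter allele pairs, single homozygote
letters, or single IUPAC ambiguity letters for heterozygotes (R=A/G,
Y=C/T, S=C/G, W=A/T, K=G/T, M=A/C), and normalised to B-allele dosage
0/1/2 with −1 for missing. A minimal VCF subset (biallelic, GT only) is
read through the same path. Sites with more than two alleles are skipped
with a logged warning rather than failing the run.

## Candidate filters

A transcript survives iff

* spliced length (sum of exon lengths) **strictly exceeds 200 nt**;
* exon count **> 1**;
* FPKM **≥ 0.1** (inclusive);
* longest ORF **≤ 50 aa** (strictly more than 50 fails).

Boundary inclusivity follows the literal wording of the criteria the
filters implement ("more than 200 bp", "FPKM ≥ 0.1", "more than 50 amino
acids"). The ORF is ATG-initiated and stop-terminated, scanned in the
three forward frames only — assembled transcripts are stranded, so
reverse frames would test the wrong molecule. Amino-acid length counts
Met through the last codon before the stop; an ORF without an in-frame
stop does not count. `N` codons match neither start nor stop but may sit
inside an ORF. Whether the original length filter used spliced or genomic
length is not documented anywhere we know of; spliced length is the
biologically meaningful choice and is what we use. A missing abundance
value leaves the FPKM rule indeterminate and the verdict is fail (the
transcript cannot be shown to qualify).

## Classification

Class codes are assigned with the precedence

1. same-strand **exonic** overlap with a protein-coding gene →
   `coding_overlap_sense_exonic`, excluded (likely a coding fragment);
2. `x`: any exon overlaps an exon of an opposite-strand gene;
3. `o`: exonic overlap with a same-strand pseudogene;
4. `i`: wholly inside one intron of a same-strand protein-coding gene;
5. `u`: the span overlaps no gene span on either strand;
6. anything else (e.g. inside an intron of an opposite-strand gene, or a
   same-strand span overlap without exonic overlap) → `other_genic`,
   excluded.

Step 1 outranks `x` because a transcript sharing exonic sequence with a
sense coding gene is removed from the lncRNA set regardless of any
antisense relation; steps 2–5 follow the conventional x > o > i > u
order. Classes then follow: `x` → NAT, `i` → intronic, `o` → sense, and
`u` → NAT (subtype V/VI) when an opposite-strand gene lies within 2 kb,
else lincRNA.

**NAT subtypes.** With the partner gene on the opposite strand: III =
lncRNA span inside the gene span, IV = gene inside the lncRNA (checked
first, so identical spans are III); partial overlap is I when the gene
crosses the lncRNA's 5′ end (head-to-head/divergent) and II when it
crosses the 3′ end (tail-to-tail/convergent); without overlap, V = gene
within the 2-kb upstream (promoter-side) window and VI = within the 2-kb
downstream window, boundary inclusive at exactly 2000 nt. The I/II
orientation assignment is a documented convention of this package: the
geometric taxonomy it implements is usually given as a figure, not as
text, so divergent-at-5′ = I was fixed once and is enforced against a
brute-force geometry oracle in the tests. The "promoter region" for
class V is 2 kb, the same constant as the cis window, to avoid a second
arbitrary length.

When several genes qualify as partner, the choice is deterministic:
largest exonic overlap, then largest span overlap, then smallest
distance, then lexicographic gene id.

**Locus merging.** Same-chromosome, same-strand transcripts with
overlapping spans (≥ 1 bp; abutting intervals do not merge) form one
locus — a single sorted sweep, verified against a union-find oracle, and
by construction order-invariant and idempotent. A locus inherits the
majority class of its members, ties broken NAT > intronic > sense >
lincRNA (antisense relations are the analysis's focus); subtype and
partner come from the majority among winning-class members.

## Target prediction

Cis: every protein-coding gene whose span overlaps the locus
(`cis_overlap`, with an antisense flag and the exact overlap length) or
lies within 2 kb of either end (`cis_flank`, distance span-to-span,
inclusive at 2000). Whether member-transcript exons overlap the gene's
exons is recorded separately, since coexpression screening excludes
exon-overlapping pairs.

Trans: the score slides the shorter spliced sequence over the reverse of
the longer (all antiparallel alignments, overhangs allowed). Paired
positions are Watson–Crick or G:U wobble; each adjacent paired pair of
positions contributes a nearest-neighbour stacking free energy
(kcal/mol, 37 °C) from the standard ten-parameter Watson–Crick table,
entered in both physical reading orientations so the score is exactly
symmetric in argument order; any stack containing a wobble pair scores a
flat −0.5 kcal/mol. Mismatches break stacks; isolated pairs contribute
nothing; no loop, bulge or initiation terms are modelled. ndG is the
minimum total energy divided by the shorter length, and a pair is called
a trans target at ndG ≤ −0.1 kcal·mol⁻¹·nt⁻¹ (the published default of
the normalised-dG tool family this emulates). This is a deliberately
simple, fully shipped duplex model — a screening heuristic, not a folding
algorithm. By default only loci with no cis target are scanned, against
caller-supplied candidate mRNA lists, to bound cost.

## Expression and coexpression

FPKM = fragments × 10⁹ / (length × total fragments); gene FPKM is the sum
over isoforms; FPKM_max is the per-feature maximum across samples. Bins:
low [0,1), medium [1,15], high (15,100], very high (100,∞) — the interior
boundaries follow the usual 1/15/100 break points, with ties assigned to
the lower bin.

The screen excludes pairs with FPKM_max < 1 on either member, then
computes Pearson r over all samples and compares it to
r\* = t(1−α/2, df) / √(t² + df) with **df = n_samples − 2**. The published
threshold 0.468 quoted alongside "n = 16" for 18 samples is exactly the
critical r at df = 16, so "16" is read as degrees of freedom — this is
the one place the package takes a documented interpretive position.
Negative coexpression uses the symmetric threshold −r\*. A zero-variance
vector leaves r undefined; the pair is reported `not_significant` with an
explicit flag (never NaN), since constant rows arise naturally after
low-expression filtering.

## Association

* **SNP filters:** MAF > 0.05 and call rate > 0.80, both strict, MAF on
  non-missing calls only.
* **SNPs in loci:** a SNP annotates every locus whose span contains it
  (overlapping loci yield multiple records); context is exon iff the
  position falls in a member transcript's exon.
* **Kinship:** VanRaden centred cross-product Z Zᵀ / (2Σp(1−p)) with
  per-SNP mean imputation of missing calls. This is a deliberate,
  documented estimator choice; pedigree-style estimators used by other
  toolchains will differ by a scale/shift but give equivalent scans.
* **REML:** with K = U D Uᵀ, the model is rotated so the covariance is
  diagonal in λ = σ²_g/σ²_e; the restricted likelihood is profiled over a
  41-point log-spaced λ grid on [10⁻⁵, 10⁵] and refined by bounded scalar
  search in the bracketing interval — deterministic, no starting-point
  sensitivity. At the lower boundary σ²_g is reported as exactly 0. With
  K = I, λ is unidentified and only σ²_g + σ²_e (the sample variance) is
  meaningful.
* **Scan:** variance components are estimated once under the null and
  reused for every SNP (the EMMAX approximation; exact per-SNP REML
  changes little at these scales and costs an eigen-solve per SNP). Each
  SNP enters as a mean-imputed 0/1/2 dosage; the Wald t statistic uses
  n − p degrees of freedom, so with σ²_g = 0 the p-values reduce exactly
  to ordinary regression. The last admixture column of Q is dropped
  against the intercept. The significance cutoff is a raw p < 10⁻³ with
  no multiple-testing correction, matching the convention of the analysis
  this reproduces; users wanting FDR control can apply it to the output
  table.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture.
Its defaults are the study conditions the pipeline emulates: 18
expression samples; 200 individuals in 5 admixed subpopulations; MAF
drawn uniformly on (0.05, 0.5]; 10% missing calls; ~80% of features at
low (< 1 FPKM) expression; planted coexpressed pairs at r\* = 0.9;
heritability 0.4.

* **Geometry:** planted units (background multi-exon genes, lncRNAs of
  each class, one NAT pair per subtype layout, decoys violating each
  filter) are placed left-to-right with ≥ 4 kb between bounding boxes, so
  the 2-kb window is unambiguous unless a layout plants proximity
  deliberately. NAT partner genes are single-exon so that span overlap
  guarantees the exonic antisense overlap the class requires.
  Infeasible packing raises an error suggesting longer chromosomes.
* **Sequences:** random uniform nucleotides; transcripts meant to pass
  have their exonic sequence resampled until the longest ORF is ≤ 50 aa;
  the ORF decoy gets an embedded 61-codon ORF. Sequence content is
  otherwise unrealistic by design (no codon bias, GC structure or
  repeats).
* **Expression:** baseline log-FPKM i.i.d. Normal(μ=0, σ=2) — the heavy
  right tail of FPKM data, with ~80% of features rescaled below 1 FPKM.
  Planted pairs are bivariate normal on the log scale with correlation
  r\* and a moderate spread (σ = 0.5): with a large σ the exp transform
  attenuates Pearson correlation on the FPKM scale, which would decouple
  the planted parameter from what the screen measures.
* **Genotypes:** Balding–Nichols subpopulation frequencies around a
  common ancestral frequency (divergence F_ST = 0.1), Dirichlet(0.3)
  admixture proportions, Hardy–Weinberg draws at each individual's
  admixed frequency, missing completely at random. No linkage
  disequilibrium beyond the shared structure.
* **Phenotypes:** y = Σβ·x_std + Qv + g + e with g ~ N(0, h²·K_true),
  e ~ N(0, 1−h²), K_true from the generating genotypes; effects β are in
  phenotype-standard-deviation units applied to standardised dosages.
* **Determinism:** one integer seed; every stage draws from a substream
  spawned deterministically from it, so equal seeds give bit-identical
  outputs.

Because the generator satisfies the model assumptions exactly (no LD, no
assembly errors, clean geometry, Gaussian traits), passing tests show the
*implementation* is correct and well-calibrated under those assumptions;
they do not show robustness to real-data pathologies such as misassembled
transcripts, LD between causal and tested SNPs, or non-Gaussian traits.

## Validation scales

The test suite and acceptance script size their simulations for a desk
machine: oracle suites use 1000 random layouts; heritability recovery
uses n = 500 with 50 replicates per h²; the null error rate uses 2000 SNP
tests with kinship from a disjoint SNP set (avoiding proximal
contamination); power uses 100 replicates at N = 200; the end-to-end run
plants ~28 transcripts on a 3 × 200-kb genome. These sizes were chosen as
the smallest at which the Monte-Carlo standard errors are comfortably
inside the asserted tolerances.

## Known limitations

* The duplex model ignores loop/bulge energetics and initiation; ndG is
  comparable between pairs scored by this package only.
* The geometric NAT I/II orientation is a convention (see above).
* Kinship is VanRaden, not an identity-by-descent estimator.
* P3D/compression variants of the mixed model are not implemented; the
  single null-model estimation is the only approximation mode.
* The coexpression screen assumes bivariate normality well enough for the
  t-based threshold; heavy-tailed FPKM rows make the positive call rate
  under the null slightly anticonservative (observed ~0.03–0.04 against a
  nominal 0.025 one-sided rate at the default generator settings).
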