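"""Published summary tables from the oil palm lncRNA catalogue the
pipeline models, used for internal-consistency checks.

These are printed study-level values (per-chromosome locus counts by
class; the 28 trait-associated SNPs inside lncRNA loci with their observed
heterozygosities), not outputs of this package; the pipeline's tabulation
and summary code is run over them to confirm it reproduces the published
totals and summaries.
"""

from __future__ import annotations

import io as _io

import pandas as pd

# Per-chromosome lncRNA locus counts by class across the 16 oil palm
# chromosomes plus unanchored scaffolds ("others").
_LOCUS_COUNTS_TSV = """\
chrom	lincRNA	NAT	intronic	sense
Chr1	61	59	4	5
Chr2	44	47	2	3
Chr3	46	46	1	2
Chr4	38	41	1	4
Chr5	26	45	1	3
Chr6	24	31	1	2
Chr7	21	23	0	4
Chr8	22	30	1	1
Chr9	13	33	0	2
Chr10	11	19	0	1
Chr11	19	15	0	1
Chr12	13	28	1	2
Chr13	19	13	0	0
Chr14	24	13	0	1
Chr15	11	16	2	1
Chr16	12	20	1	0
others	299	102	17	15
"""

# The 28 SNPs inside lncRNA loci significantly associated with fatty-acid
# or oil content (trait, association p-value, exon/intron context and
# observed heterozygosity across the 200-individual panel).
_SNP_ASSOCIATIONS_TSV = """\
locus	chrom	pos	context	trait	p_value	het
MSTRG.2123	Chr1	26348240	intron	palmitic_acid	0.000794231	0.2301
MSTRG.2168	Chr1	27359487	intron	stearic_acid	0.000671054	0.318
MSTRG.2168	Chr1	27366210	exon	stearic_acid	0.000667117	0.2188
MSTRG.4816	Chr2	10805479	intron	oil_content	0.000916663	0.4067
MSTRG.7396	Chr2	56802941	intron	palmitic_acid	0.00038596	0.1968
MSTRG.7396	Chr2	56803122	intron	palmitic_acid	0.000874185	0.208
MSTRG.7396	Chr2	56767445	exon	oil_content	0.000732102	0.1425
MSTRG.7397	Chr2	56767445	intron	oil_content	0.000732102	0.2518
MSTRG.10380	Chr3	37185131	intron	linoleic_acid	1.49E-09	0.375
MSTRG.11378	Chr4	4103682	intron	oil_content	0.000223078	0.1605
MSTRG.11378	Chr4	4103761	intron	oil_content	0.000414367	0.1565
MSTRG.13525	Chr4	50679685	intron	oil_content	0.000982483	0.4258
MSTRG.15295	Chr5	25374494	exon	linoleic_acid	0.000862608	0.4562
MSTRG.15330	Chr5	27273554	intron	oil_content	0.000838241	0.3712
MSTRG.16341	Chr5	46800615	intron	palmitic_acid	0.000916155	0.495
MSTRG.16341	Chr5	46773860	intron	linoleic_acid	0.000914323	0.375
MSTRG.16342	Chr5	46773860	intron	linoleic_acid	0.000914323	0.3871
MSTRG.16344	Chr5	46800615	intron	palmitic_acid	0.000916155	0.495
MSTRG.16345	Chr5	46800615	intron	palmitic_acid	0.000916155	0.3432
MSTRG.17117	Chr6	5087561	intron	oil_content	0.000433608	0.4061
MSTRG.17118	Chr6	5087561	intron	oil_content	0.000433608	0.4283
MSTRG.17644	Chr6	21539684	intron	oil_content	0.000343467	0.4793
MSTRG.17644	Chr6	21539697	intron	oil_content	0.000776114	0.4851
MSTRG.28271	Chr11	28838549	intron	oil_content	0.000973214	0.4968
MSTRG.28993	Chr12	15680141	intron	linoleic_acid	0.000661354	0.475
MSTRG.28993	Chr12	15680161	intron	linoleic_acid	0.000820421	0.4729
MSTRG.29406	Chr12	21510854	intron	stearic_acid	0.000778935	0.1147
MSTRG.30615	Chr13	13106882	intron	oil_content	0.000815972	0.1888
"""

#: published headline counts used in ratio consistency checks
SUMMARY_COUNTS = {
    "nat_target_genes": 712,
    "nat_genic_overlap_targets": 514,  # NAT targets with genic antisense overlap (I-IV)
    "coexpression_pairs_tested": 205,
    "coexpression_pairs_positive": 21,
    "top_snp_p_value": 5.01e-08,
}

CHROMOSOMES = [f"Chr{i}" for i in range(1, 17)]


def published_locus_counts() -> pd.DataFrame:
    """Per-chromosome lncRNA class counts (no totals)."""
    return pd.read_csv(_io.StringIO(_LOCUS_COUNTS_TSV), sep="\t", index_col=0)


def published_snp_associations() -> pd.DataFrame:
    """The 28 trait-associated SNPs in lncRNA loci."""
    return pd.read_csv(_io.StringIO(_SNP_ASSOCIATIONS_TSV), sep="\t")
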