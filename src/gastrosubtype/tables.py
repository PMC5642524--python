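"""Published study tables used as machine-readable fixtures and defaults.

The cohort is the 107-patient Korean gastric-cancer series profiled with a
43-gene tumor/normal panel, five-marker MSI PCR, EBV qPCR and a SNP array.
These constants transcribe its printed summary tables:

* cohort marginals (EBV status, MSI status),
* the 30 germline variants in hereditary-cancer genes,
* location-specific recurrent somatic variants,
* gene-by-molecular-subtype somatic mutation counts, and
* clinical covariates cross-tabulated by subtype.

They parameterize the synthetic cohort generator and serve as ground truth
in tests; nothing here is computed.
"""

from __future__ import annotations

import io

import pandas as pd

SUBTYPES = ("EBV", "MSI", "CIN", "GS")

#: Number of cases per molecular subtype (cohort n = 107).
SUBTYPE_SIZES = {"EBV": 7, "MSI": 19, "CIN": 46, "GS": 35}

COHORT_N = 107

#: Cohort-level assay marginals.
EBV_COUNTS = {"Negative": 100, "Positive": 7}
MSI_STATUS_COUNTS = {"MSS": 88, "MSI-L": 4, "MSI-H": 15}

#: Five mononucleotide microsatellite markers of the pentaplex PCR assay.
MSI_MARKERS = ("BAT-25", "BAT-26", "NR-21", "NR-24", "NR-27")

#: Cases with >=1 somatic mutation per gene, by subtype (EBV, MSI, CIN, GS).
GENE_SUBTYPE_COUNTS = {
    "TP53": (0, 5, 26, 10),
    "ACVR1B": (0, 1, 1, 0),
    "ALK": (0, 3, 2, 1),
    "APC": (2, 1, 8, 1),
    "ARID1A": (4, 14, 12, 9),
    "BCOR": (1, 9, 2, 0),
    "BRAF": (0, 3, 0, 0),
    "CBWD1": (0, 0, 1, 1),
    "CCND1": (0, 3, 2, 2),
    "CD274": (1, 0, 0, 0),
    "CDH1": (3, 1, 3, 4),
    "CIC": (0, 5, 3, 2),
    "CR1": (0, 5, 2, 8),
    "CTNNB1": (1, 2, 0, 2),
    "EGFR": (0, 4, 0, 1),
    "ERBB2": (0, 5, 2, 1),
    "ERBB3": (0, 5, 2, 2),
    "FBXW7": (0, 3, 3, 1),
    "FGFR2": (0, 2, 0, 0),
    "HLA-B": (0, 3, 2, 0),
    "IRF2": (0, 2, 1, 1),
    "JAK2": (0, 1, 1, 0),
    "KDR": (0, 3, 1, 0),
    "KRAS": (0, 5, 1, 0),
    "LARP4B": (0, 3, 1, 0),
    "MDM2": (0, 1, 0, 0),
    "MEDAG": (0, 2, 0, 0),
    "MLH1": (0, 2, 0, 0),
    "MSH2": (0, 4, 1, 0),
    "MTOR": (0, 3, 3, 0),
    "MVK": (0, 4, 0, 0),
    "MYC": (1, 0, 0, 0),
    "PGM5": (1, 4, 0, 0),
    "PIK3CA": (2, 7, 1, 0),
    "PTEN": (0, 2, 0, 1),
    "RHOA": (2, 1, 2, 4),
    "SMAD4": (0, 1, 1, 0),
    "STK11": (0, 1, 1, 0),
    "ZBTB20": (0, 5, 0, 0),
}

#: The full 43-gene panel: the 39 genes above plus four in which no somatic
#: variant was observed in the cohort.
GENE_PANEL = tuple(sorted(GENE_SUBTYPE_COUNTS)) + (
    "C16orf74",
    "CCNE1",
    "MET",
    "PDCD1LG2",
)

#: Gene-level copy-number events observed in the cohort (all amplifications
#: except the PTEN deletion), with event counts.
CNA_EVENT_COUNTS = {
    "BCOR": ("duplication", 1),
    "CCND1": ("duplication", 2),
    "CCNE1": ("duplication", 3),
    "ERBB2": ("duplication", 5),
    "FGFR2": ("duplication", 1),
    "KRAS": ("duplication", 6),
    "MYC": ("duplication", 1),
    "PIK3CA": ("duplication", 1),
    "PTEN": ("deletion", 1),
    "JAK2": ("duplication", 1),
}

#: Pathway gene sets used for the therapeutic-implication summary.
RTK_GENES = frozenset({"ERBB2", "EGFR", "FGFR2", "KDR"})
RAS_PI3K_GENES = frozenset({"KRAS", "BRAF", "PIK3CA", "PTEN", "MTOR"})

#: Germline variants in hereditary cancer-predisposition genes (30 records).
#: VAF(1) is the tumor sample, VAF(2) the matched non-tumor sample.
GERMLINE_TABLE_TSV = """\
case_id	chrom	pos	ref	alt	gene_symbol	transcript_id	protein_change	total_depth	vaf_tumor	vaf_normal	significance
YMC 54	2	29449820	G	A	ALK	NM_004304.4	p.T1012M	637	48.51%	60.36%	Benign
YMC 7	2	29449820	G	A	ALK	NM_004304.4	p.T1012M	208	55.77%	43.83%	Benign
YMC 70	2	29449820	G	A	ALK	NM_004304.4	p.T1012M	755	52.58%	57.85%	Benign
SKW 18	2	29519923	G	A	ALK	NM_004304.4	p.L550F	155	38.06%	55.39%	VUS
YMC 13	5	112177778	A	C	APC	NM_001127511.2	p.K2145Q	151	52.32%	33.74%	Benign
YMC 24	5	112178865	G	A	APC	NM_001127511.2	p.R2507H	1142	47.90%	49.52%	VUS
SKW 38	5	112176548	G	C	APC	NM_001127511.2	p.A1735P	628	45.86%	47.30%	VUS
SKW 21	5	112173895	A	C	APC	NM_001127511.2	p.E850D	147	55.78%	50.93%	Benign
YMC 29	16	68867247	G	A	CDH1	NM_004360.4	p.V832M	1337	52.21%	49.75%	Likely pathogenic
YMC 37	16	68867247	G	A	CDH1	NM_004360.4	p.V832M	1498	50.73%	46.41%	Likely pathogenic
SKW 16	16	68856080	C	G	CDH1	NM_004360.4	p.L630V	928	43.74%	40.61%	Benign
SKW 15	16	68856080	C	G	CDH1	NM_004360.4	p.L630V	827	49.33%	71.46%	Benign
YMC 53	3	37053562	C	T	MLH1	NM_000249.3	p.R217C	1397	46.96%	50.40%	VUS
YMC 55	3	37042521	T	G	MLH1	NM_000249.3	p.S95A	233	39.06%	30.52%	VUS
YMC 6	3	37067240	T	A	MLH1	NM_000249.3	p.V384D	578	48.79%	44.85%	Benign
YMC 70	3	37067240	T	A	MLH1	NM_000249.3	p.V384D	547	51.55%	47.99%	Benign
YMC 14	3	37053562	C	T	MLH1	NM_000249.3	p.R217C	1409	45.71%	51.65%	VUS
YMC 22	3	37067240	T	A	MLH1	NM_000249.3	p.V384D	862	99.54%	100%	Benign
YMC 3	3	37090506	C	A	MLH1	NM_000249.3	p.Q701K	369	51.49%	41.29%	Benign
YMC 4	3	37089022	C	G	MLH1	NM_000249.3	p.L582V	364	48.63%	57.47%	VUS
YMC 37	3	37053562	C	T	MLH1	NM_000249.3	p.R217C	1315	49.20%	49.76%	VUS
YMC 48	3	37067240	T	A	MLH1	NM_000249.3	p.V384D	899	43.38%	44.61%	Benign
SKW 31	3	37053562	C	T	MLH1	NM_000249.3	p.R217C	294	55.78%	39.71%	VUS
YMC 66	2	47656972	C	T	MSH2	NM_000251.2	p.L390F	197	56.85%	52.78%	Benign
YMC 15	2	47656972	C	T	MSH2	NM_000251.2	p.L390F	1281	46.68%	79.62%	Benign
YMC 28	2	47630344	C	A	MSH2	NM_000251.2	p.P5Q	231	53.25%	86.79%	VUS
YMC 5	2	47637371	A	G	MSH2	NM_000251.2	p.I169V	711	51.34%	45.12%	Likely benign
YMC 48	2	47656972	C	T	MSH2	NM_000251.2	p.L390F	692	51.30%	53.31%	Benign
SKW 41	2	47703564	G	A	MSH2	NM_000251.2	p.M688I	993	52.57%	50.83%	VUS
SKW 40	17	7578209	G	A	TP53	NM_000546.5	p.H214Y	168	39.29%	59.58%	VUS
"""

#: Recurrent somatic variants (>=2 mutated samples) with sample counts.
RECURRENT_VARIANTS = [
    ("APC", "p.Glu1464ValfsTer8", 2),
    ("ARID1A", "p.Asp1850ThrfsTer33", 5),
    ("ARID1A", "p.Gln1334del/dup", 23),
    ("ARID1A", "p.Gly87del", 2),
    ("BCOR", "p.Gln1174ThrfsTer8", 3),
    ("BRAF", "p.Pro403LeufsTer8", 2),
    ("CCND1", "p.Glu280del", 7),
    ("CDH1", "p.Leu15del", 5),
    ("CR1", "p.Arg2194Ter", 10),
    ("ERBB2", "p.Arg678Gln", 4),
    ("ERBB2", "p.Ser310Phe", 2),
    ("ERBB2", "p.Val842Ile", 2),
    ("ERBB3", "p.Val104Met", 2),
    ("FBXW7", "p.Arg385His", 3),
    ("HLA-B", "p.Glu69Val", 2),
    ("KRAS", "p.Gly13Asp", 5),
    ("LARP4B", "p.Thr163HisfsTer47", 2),
    ("MVK", "p.Ala141ArgfsTer18", 2),
    ("PIK3CA", "p.His1047Arg", 4),
    ("PGM5", "p.Ile98Val", 3),
    ("RHOA", "p.Arg5Gln/Trp", 3),
    ("RHOA", "p.Thr37Ala/Ile", 2),
    ("RHOA", "p.Tyr42Cys", 2),
    ("TP53", "p.Arg248Trp", 2),
    ("TP53", "p.Arg342Ter", 2),
    ("TP53", "p.Cys275Tyr", 2),
    ("TP53", "p.Val173Leu", 2),
    ("ZBTB20", "p.Pro619LeufsTer43", 5),
]

#: Clinical covariates cross-tabulated by molecular subtype; each category
#: maps to per-subtype case counts in (EBV, MSI, CIN, GS) order.
CLINICAL_SUBTYPE_COUNTS = {
    "age_band": {
        "<=50": (0, 1, 3, 6),
        "51-60": (2, 1, 9, 6),
        "61-70": (1, 3, 13, 8),
        "71-80": (3, 12, 16, 13),
        ">80": (1, 2, 5, 2),
    },
    "sex": {
        "Female": (1, 8, 16, 11),
        "Male": (6, 11, 30, 24),
    },
    "lauren_class": {
        "Diffuse": (3, 2, 9, 14),
        "Intestinal": (2, 15, 26, 15),
        "Mixed": (2, 2, 11, 6),
    },
    "who_class": {
        "Tubular": (2, 17, 32, 18),
        "Mucinous": (0, 0, 2, 1),
        "Poorly cohesive": (0, 0, 5, 9),
        "Mixed": (1, 1, 7, 7),
        "Uncommon": (4, 1, 0, 0),
    },
    "ajcc_stage_group": {
        "I": (3, 4, 11, 11),
        "II": (1, 9, 13, 3),
        "III": (2, 6, 19, 20),
        "IV": (1, 0, 3, 1),
    },
    "anatomical_region": {
        "Antrum": (1, 15, 25, 13),
        "Antrum_Body": (1, 0, 2, 2),
        "Fundus_Body": (4, 4, 10, 18),
        "GEJ_Cardia": (1, 0, 7, 0),
        "Diffuse": (0, 0, 0, 1),
        "Pylorus": (0, 0, 2, 1),
    },
    "lymphatic_invasion": {
        "Positive": (4, 17, 34, 21),
        "Negative": (3, 2, 12, 13),
        "Missing": (0, 0, 0, 1),
    },
    "venous_invasion": {
        "Positive": (2, 1, 7, 5),
        "Negative": (5, 18, 39, 29),
        "Missing": (0, 0, 0, 1),
    },
    "perineural_invasion": {
        "Positive": (4, 6, 25, 17),
        "Negative": (3, 13, 21, 17),
        "Missing": (0, 0, 0, 1),
    },
    "h_pylori": {
        "Negative": (3, 8, 21, 9),
        "Positive": (4, 11, 25, 26),
    },
}

#: AJCC 7th-edition gastric staging: stage group -> compatible (pT, pN, M)
#: category combinations.
AJCC_STAGE_COMBOS = {
    "I": [("T1", "N0", "M0"), ("T1", "N1", "M0"), ("T2", "N0", "M0")],
    "II": [
        ("T1", "N2", "M0"), ("T2", "N1", "M0"), ("T3", "N0", "M0"),
        ("T1", "N3", "M0"), ("T2", "N2", "M0"), ("T3", "N1", "M0"),
        ("T4a", "N0", "M0"),
    ],
    "III": [
        ("T2", "N3", "M0"), ("T3", "N2", "M0"), ("T4a", "N1", "M0"),
        ("T3", "N3", "M0"), ("T4a", "N2", "M0"), ("T4b", "N0", "M0"),
        ("T4b", "N1", "M0"), ("T4a", "N3", "M0"), ("T4b", "N2", "M0"),
        ("T4b", "N3", "M0"),
    ],
    "IV": [("T3", "N1", "M1"), ("T4a", "N2", "M1"), ("T2", "N0", "M1")],
}

#: Per-gene locus catalog used by the synthetic generator: chromosome, a
#: representative coding start position, and a canonical somatic protein
#: change (recurrent hotspots where the study reported one).
GENE_CATALOG = {
    "TP53": ("17", 7578000, "p.Arg248Trp"),
    "ARID1A": ("1", 27100000, "p.Gln1334dup"),
    "CR1": ("1", 207670000, "p.Arg2194Ter"),
    "APC": ("5", 112170000, "p.Glu1464ValfsTer8"),
    "BCOR": ("X", 39910000, "p.Gln1174ThrfsTer8"),
    "CDH1": ("16", 68770000, "p.Leu15del"),
    "CIC": ("19", 42780000, "p.Arg215Trp"),
    "PIK3CA": ("3", 178936000, "p.His1047Arg"),
    "ERBB3": ("12", 56480000, "p.Val104Met"),
    "RHOA": ("3", 49400000, "p.Tyr42Cys"),
    "ERBB2": ("17", 37880000, "p.Arg678Gln"),
    "CCND1": ("11", 69455000, "p.Glu280del"),
    "FBXW7": ("4", 153245000, "p.Arg385His"),
    "ALK": ("2", 29440000, "p.Phe1174Leu"),
    "KRAS": ("12", 25398000, "p.Gly13Asp"),
    "MTOR": ("1", 11180000, "p.Ser2215Tyr"),
    "CTNNB1": ("3", 41265000, "p.Ser45Phe"),
    "EGFR": ("7", 55240000, "p.Leu858Arg"),
    "HLA-B": ("6", 31320000, "p.Glu69Val"),
    "MSH2": ("2", 47630000, "p.Arg524Pro"),
    "PGM5": ("9", 70970000, "p.Ile98Val"),
    "ZBTB20": ("3", 114060000, "p.Pro619LeufsTer43"),
    "IRF2": ("4", 185310000, "p.Arg110Cys"),
    "KDR": ("4", 55950000, "p.Arg1032Gln"),
    "LARP4B": ("10", 855000, "p.Thr163HisfsTer47"),
    "MVK": ("12", 110010000, "p.Ala141ArgfsTer18"),
    "BRAF": ("7", 140450000, "p.Pro403LeufsTer8"),
    "PTEN": ("10", 89620000, "p.Arg130Gln"),
    "ACVR1B": ("12", 52345000, "p.Arg478His"),
    "CBWD1": ("9", 115000, "p.Ala202Thr"),
    "FGFR2": ("10", 123240000, "p.Ser252Trp"),
    "JAK2": ("9", 5020000, "p.Val617Phe"),
    "MEDAG": ("13", 31480000, "p.Gly140Ser"),
    "MLH1": ("3", 37035000, "p.Val384Asp"),
    "SMAD4": ("18", 48570000, "p.Arg361His"),
    "STK11": ("19", 1205000, "p.Phe354Leu"),
    "CD274": ("9", 5450000, "p.Ala121Thr"),
    "MDM2": ("12", 69200000, "p.Ser186Arg"),
    "MYC": ("8", 128748000, "p.Ser62Pro"),
    "C16orf74": ("16", 85740000, "p.Ala30Val"),
    "CCNE1": ("19", 30300000, "p.Arg95His"),
    "PDCD1LG2": ("9", 5510000, "p.Ala52Thr"),
    "MET": ("7", 116310000, "p.Tyr1253Asp"),
}

#: Modal germline (non-tumor) allele length per MSI marker, in bp.
MSI_MARKER_MODAL_LENGTHS = {
    "BAT-25": 124,
    "BAT-26": 120,
    "NR-21": 103,
    "NR-24": 132,
    "NR-27": 87,
}


def germline_table() -> pd.DataFrame:
    """Return the published germline-variant table as a DataFrame."""
    return pd.read_csv(io.StringIO(GERMLINE_TABLE_TSV), sep="\t")


def gene_subtype_count_frame() -> pd.DataFrame:
    """Gene-by-subtype mutated-case counts as a DataFrame (genes x 4)."""
    return pd.DataFrame.from_dict(
        GENE_SUBTYPE_COUNTS, orient="index", columns=list(SUBTYPES)
    )
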