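"""Bundled reference table of protein-altering exome-array variants.

Genotype counts (minor-allele homozygotes and heterozygotes) for the 46
directly genotyped loss-of-function and missense variants with at least ten
minor-allele homozygotes among 2,378 unrelated adults of European descent in
a population cohort. This is the screening input of the worked
genotype-based recall example: the focal variant is the PPARG Pro12Ala
substitution rs1801282 (31 minor-allele homozygotes, 561 heterozygotes).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

N_UNRELATED_EUROPEAN = 2378

_TABLE_TSV = """\
rsID	chromosome	position	minor_allele	major_allele	n_minor_hom	n_het	locus	consequence
rs1137101	1	66058513	A	G	531	1090	LEPR	missense
rs1935	10	64927823	G	C	528	1113	JMJD1C	missense
rs492594	2	169764176	C	G	474	1038	G6PC2	missense
rs13928	7	44153780	G	A	451	1112	AEBP1	missense
rs3784634	15	62259637	C	T	445	1055	VPS13C	missense
rs10851704	15	62202482	C	T	421	1064	VPS13C	missense
rs1208	8	18258316	G	A	377	1074	NAT2	missense
rs5215	11	17408630	C	T	367	1034	KCNJ11	missense
rs5219	11	17409572	T	C	366	1035	KCNJ11	missense
rs12529	10	5136651	G	C	303	1014	AKR1C3	missense
rs9938550	16	30999142	A	G	276	1021	HSD3B7	missense
rs1260326	2	27730940	T	C	261	980	GCKR	missense
rs11057401	12	124427306	A	T	240	981	CCDC92	missense
rs13266634	8	118184783	T	C	221	937	SLC30A8	missense
rs1169288	12	121416650	C	A	216	1011	HNF1A	missense
rs9814557	3	135720540	G	A	215	964	PPP2R3A	missense
rs17197552	3	135722264	G	A	215	965	PPP2R3A	missense
rs56200889	11	72408055	C	G	197	890	ARAP1	missense
rs61748245	2	165476253	A	T	179	876	GRB14	missense
rs2464196	12	121435427	A	G	177	935	HNF1A	missense
rs1799930	8	18258103	A	G	172	931	NAT2	missense
rs1137100	1	66036441	G	A	171	952	LEPR	missense
rs6779903	3	135720851	T	G	153	847	PPP2R3A	missense
rs321776	5	55407542	T	C	151	861	ANKRD55	missense
rs17570	19	33878837	A	G	141	847	PEPD	missense
rs1800437	19	46181392	C	G	104	779	GIPR	missense
rs10761725	10	64974537	A	T	84	716	JMJD1C	missense
rs17244632	2	165551404	A	G	75	670	COBLL1	missense
rs17185413	11	61730553	C	T	71	675	BEST1	missense
rs479661	2	169721377	G	A	65	590	NOSTRIN	missense
rs7657817	4	89668859	T	C	60	615	FAM13A	missense
rs9898682	17	41738823	A	G	52	445	MEOX1	missense
rs12453522	17	41931375	G	A	49	555	CD300LG	missense
rs10445686	2	135893372	G	A	45	477	RAB3GAP1	missense
rs7607980	2	165551201	C	T	40	490	COBLL1	missense
rs12440118	15	42744094	G	A	39	513	ZFP106	missense
rs8940	7	116146074	G	C	35	514	CAV2	missense
rs1801282	3	12393125	G	C	31	561	PPARG	missense
rs7130656	11	45832509	G	A	30	477	SLC35C1	missense
rs12702	15	44093927	C	T	24	315	C15orf63	missense
rs328	8	19819724	G	C	17	372	LPL	LOF
rs12907567	15	62214607	T	C	13	284	VPS13C	missense
rs11629598	15	62243197	C	T	13	284	VPS13C	missense
rs2303405	15	62253791	C	T	13	281	VPS13C	missense
rs10488698	11	116633947	A	G	13	285	BUD13	missense
rs74459242	2	165578602	T	C	10	252	COBLL1	missense
"""

FOCAL_VARIANT = "rs1801282"


def protein_altering_variants() -> pd.DataFrame:
    """The bundled 46-variant screen table, indexed by rsID.

    Columns: chromosome, position (GRCh37, 1-based), minor/major allele,
    n_minor_hom, n_het, n_major_hom (derived from the 2,378-sample total),
    maf, locus, consequence.
    """
    df = pd.read_csv(StringIO(_TABLE_TSV), sep="\t").set_index("rsID")
    df["n_major_hom"] = N_UNRELATED_EUROPEAN - df["n_minor_hom"] - df["n_het"]
    df["maf"] = (2 * df["n_minor_hom"] + df["n_het"]) / (2.0 * N_UNRELATED_EUROPEAN)
    return df
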