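"""Bundled example data: published black-rice anthocyanin candidate sets.

Two small tables from a black-rice vs white-rice screen serve as worked
examples and fixtures: the 18 sweep-candidate genes called from SNP variation
(gene coordinates on the rice RAP-DB assembly, strand, in-gene SNP count and
region ZHp) and the nine transcripts that passed the all-time-points twofold
FPKM screen with their regulation calls and high/none expression ratios.
"""

from __future__ import annotations

import io as _io

import pandas as pd

# gene_id, chrom, start (1-based), end (inclusive), strand, n_snp, zhp, description
_SWEEP_GENES_TSV = """\
gene_id	chrom	start	end	strand	n_snp	zhp	description
Os04g0175600	chr4	5161947	5167404	+	22	-1.57	Similar to 0-methyltransferase
Os04g0175900	chr4	5178491	5186485	+	36	-1.59	Winged helix repressor domain
Os04g0176200	chr4	5189974	5194492	-	3	-1.57	Similar to N-methyltransferase
Os04g0176300	chr4	5210111	5216557	+	48	-1.57	Hypothetical protein
Os04g0176400	chr4	5210122	5216551	-	2	-1.57	Similar to serine carboxypeptidase 1
Os05g0338933	chr5	15866499	15866891	+	26	-1.58	Proton-dependent oligopeptide transport
Os05g0339000	chr5	15873838	15880419	-	8	-1.58	VHS domain-containing protein
Os05g0340000	chr5	15931964	15933657	-	4	-1.49	Conserved hypothetical protein
Os10g0162856	chr10	4226902	4229142	+	30	-1.52	Chalcone and stilbene synthases
Os10g0174751	chr10	5198971	5204584	+	2	-1.57	Hypothetical protein
Os10g0175500	chr10	5236268	5237084	+	43	-1.59	Hypothetical gene
Os10g0175700	chr10	5237690	5245182	-	17	-1.57	Hypothetical protein
Os10g0175800	chr10	5247357	5248013	+	10	-1.57	Similar to nodulin protein
Os10g0188100	chr10	6079970	6087844	-	2	-1.55	Conserved hypothetical protein
Os10g0188275	chr10	6103102	6109882	-	3	-1.56	Hypothetical protein
Os10g0188300	chr10	6104501	6110244	+	5	-1.56	Similar to JHL05D22.13 protein
Os10g0188400	chr10	6111498	6115269	+	10	-1.56	Similar to ACI13
Os10g0188900	chr10	6144589	6150509	+	43	-1.65	Conserved hypothetical protein
"""

# transcript, chrom, regulation, published high/none expression ratio
_DEG_TSV = """\
transcript_id	chrom	regulation	ratio
Os01t0372500	chr1	up	25.2
Os01t0633500	chr1	up	18.1
Os04t0662600	chr4	up	36.0
Os06t0192100	chr6	up	17.6
Os07t0217600	chr7	down	0.01
Os09t0343200	chr9	down	0.01
Os10t0395400	chr10	up	27.7
Os11t0233201	chr11	down	0.01
Os12t0222650	chr12	up	25.3
"""

# printed transition/transversion tallies of the same screen's SNP set
TSTV_COUNTS = (557_573, 232_492)


def sweep_candidate_genes() -> pd.DataFrame:
    """The 18 published sweep-candidate genes (1-based inclusive coordinates)."""
    return pd.read_csv(_io.StringIO(_SWEEP_GENES_TSV), sep="\t")


def sweep_candidate_genes_internal() -> pd.DataFrame:
    """Same genes converted to the internal 0-based half-open convention."""
    df = sweep_candidate_genes().copy()
    df["start"] -= 1
    return df


def deg_candidates() -> pd.DataFrame:
    """The nine published all-time-points DEGs with regulation and ratio."""
    return pd.read_csv(_io.StringIO(_DEG_TSV), sep="\t")


def deg_ratio_profiles(n_timepoints: int = 3) -> pd.DataFrame:
    """Ratio table shaped for the staged screen, one constant ratio per time point."""
    df = deg_candidates()
    out = pd.DataFrame({"transcript_id": df["transcript_id"]})
    for t in range(1, n_timepoints + 1):
        out[f"ratio_t{t}"] = df["ratio"]
    return out
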