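"""Readers and writers for the formats the pipeline touches.

Conventions: VCF and GFF3 are 1-based on disk and converted to the internal
0-based half-open coordinates on read; BED output is 0-based half-open; TSV
reports print 1-based inclusive coordinates to match published gene tables,
and every report header comment states its convention.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, read_group_table
from .qc import filter_biallelic
from .sweep import CandidateGene, Region

_GT_CODE = {0: 0, 1: 1, 3: 2, 2: -1}  # cyvcf2 gt_types -> alt dosage
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def read_vcf(path, groups: Mapping[str, str] | str | os.PathLike,
             biallelic_only: bool = True) -> tuple[GenotypeMatrix, dict]:
    """Load a VCF into a :class:`GenotypeMatrix` with its two-group sample map.

    ``groups`` is either a mapping or the path of the sample/group sidecar
    TSV. Non-bi-allelic records are dropped (and counted in the returned
    summary dict) unless ``biallelic_only`` is False, in which case they
    raise. Samples present in the VCF but absent from the group map are an
    error, as are group entries naming unknown samples.
    """
    from cyvcf2 import VCF

    if not isinstance(groups, Mapping):
        groups = read_group_table(groups)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"VCF samples missing from group table: {missing}")
    # the group table may cover additional assays (e.g. RNA-seq accessions)
    groups = {s: groups[s] for s in samples}

    counter: dict = {}
    chroms, pos, ref, alt, geno = [], [], [], [], []
    stream = filter_biallelic(vcf, counter) if biallelic_only else iter(vcf)
    for rec in stream:
        if not biallelic_only and (len(rec.ALT) != 1 or len(rec.REF) != 1):
            raise ValueError(f"non-bi-allelic record at {rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS - 1)  # VCF 1-based -> internal 0-based
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        geno.append([_GT_CODE[t] for t in rec.gt_types])
    vcf.close()

    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(geno, dtype=np.int8) if geno else np.empty((0, len(samples)), np.int8),
        samples=samples,
        groups=dict(groups),
    ).sort()
    return gm, counter


def read_vcf_header_lines(path) -> list[str]:
    """Return the raw ``##`` meta lines of a VCF (for sidecar truth metadata)."""
    lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            lines.append(line.rstrip("\n"))
    return lines


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths: Mapping[str, int] | None = None,
              extra_header_lines: Sequence[str] = ()) -> None:
    """Write a minimal deterministic VCF 4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscreen\n")
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        if chrom_lengths is None:
            chrom_lengths = {c: int(gm.pos[idx].max()) + 1 for c, idx in gm.by_chrom()}
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.genotypes[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_gff(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a frame (gene_id, chrom, start, end, strand, description) with
    0-based half-open coordinates, stably sorted by (chrom, start).
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    cols = ["gene_id", "chrom", "start", "end", "strand", "description"]
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
    except EmptyInputError:
        return pd.DataFrame(columns=cols)
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise ValueError(f"gene with end < start: {feat.id} at {feat.seqid}:{feat.start}")
        gid = feat.attributes.get("ID", [feat.id])[0]
        desc = feat.attributes.get("description", [""])[0]
        rows.append((gid, feat.seqid, feat.start - 1, feat.end, feat.strand, desc))
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gff(genes: pd.DataFrame, path) -> None:
    """Write the gene-model frame (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            attrs = f"ID={g.gene_id}"
            desc = getattr(g, "description", "")
            if desc:
                attrs += f";description={desc}"
            fh.write(f"{g.chrom}\tsweepscreen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def read_fpkm(path) -> pd.DataFrame:
    """Read the long-format FPKM TSV (transcript_id, sample_id, timepoint, fpkm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "sample_id", "timepoint", "fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_fpkm(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_terms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_window_stats(stats: pd.DataFrame, path) -> None:
    """Per-window statistics TSV (0-based half-open window coordinates)."""
    with open(path, "w") as fh:
        fh.write("# windows are 0-based half-open [start, end)\n")
        stats.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """Merged candidate regions as BED (0-based half-open), score = min ZHp."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tsweep\t{r.zhp_min:.4g}\n")


def write_gene_report(genes: Sequence[CandidateGene], path) -> None:
    """Candidate-gene TSV mirroring published sweep-gene tables (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tn_snp\tzhp\tdescription\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\t"
                     f"{g.n_snps_in_gene}\t{g.zhp_of_region:.4g}\t{g.description}\n")


def write_tracks(track: pd.DataFrame, outdir, prefix: str = "track") -> list[str]:
    """Write one (chrom, start, end, value) track file per statistic column."""
    paths = []
    for col in track.columns:
        if col in ("chrom", "start", "end", "n_snps"):
            continue
        path = os.path.join(outdir, f"{prefix}_{col}.tsv")
        sub = track[["chrom", "start", "end", col]].dropna(subset=[col])
        sub.to_csv(path, sep="\t", index=False, header=["chrom", "start", "end", "value"],
                   float_format="%.6g")
        paths.append(path)
    return paths


def write_deg_report(final: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# high/none FPKM ratios per time point; geometric mean across time points\n")
        final.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_enrichment(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)
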