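"""Synthetic genotype, annotation and expression data with planted signal.

The generator emulates the study design the screen assumes: two diploid
accession groups genotyped at independent bi-allelic SNPs on a multi-chromosome
genome, with *planted sweep regions* in which the high-anthocyanin group's
minor-allele frequencies are scaled down by a diversity-reduction factor, and
an FPKM expression matrix over three post-heading time points with planted
up/down regulated transcripts. No linkage, recombination or demography is
modelled: sites are independent, and genotypes are drawn under Hardy-Weinberg
proportions at each group's site frequency.

Every entry point takes an explicit seed; there is no global random state, and
identical seeds reproduce outputs byte-for-byte through the writers in
:mod:`sweepscreen.io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GROUP_HIGH, GROUP_NONE

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ["C", "T"], "G": ["C", "T"], "C": ["A", "G"], "T": ["A", "G"]}


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SweepRegion:
    """A planted low-diversity interval (0-based half-open) in the high group."""

    chrom: str
    start: int
    end: int
    diversity_reduction: float

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ConfigError(f"invalid sweep region {self}")
        if not 0.0 <= self.diversity_reduction <= 1.0:
            raise ConfigError(
                f"diversity_reduction must be in [0, 1], got {self.diversity_reduction} ({self})"
            )


@dataclass
class SimGenomeConfig:
    """Parameters of the two-group genotype simulation.

    ``maf_low``/``maf_high`` bound the uniform distribution the per-site
    minor-allele frequency is drawn from (the alternate allele is the minor
    allele at draw time). ``ts_fraction`` sets the transition share of
    substitutions so Ts/Tv summaries land near the ~2 expected of real SNP
    sets. Defaults give per-bp nucleotide diversity near 0.004 outside sweeps,
    matching the scale at which the candidate rule "pi <= 0.005" operates.
    """

    seed: int
    n_chrom: int = 3
    chrom_length: int = 2_000_000
    n_high: int = 8
    n_none: int = 9
    n_snps_per_chrom: int = 20_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ts_fraction: float = 0.7
    sweep_regions: list[SweepRegion] = field(default_factory=list)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def validate(self) -> None:
        if self.n_high < 2 or self.n_none < 2:
            raise ConfigError("need at least 2 samples per group")
        if not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ConfigError(f"MAF bounds must satisfy 0 <= low <= high <= 0.5")
        if self.n_snps_per_chrom > self.chrom_length:
            raise ConfigError("more SNPs requested than positions available")
        names = set(self.chrom_names())
        by_chrom: dict[str, list[SweepRegion]] = {}
        for r in self.sweep_regions:
            if r.chrom not in names:
                raise ConfigError(f"sweep region on unknown chromosome: {r}")
            if r.end > self.chrom_length:
                raise ConfigError(f"sweep region extends past chromosome end: {r}")
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regions in by_chrom.items():
            regions = sorted(regions, key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if b.start < a.end:
                    raise ConfigError(f"overlapping sweep regions on {chrom}: {a} / {b}")


@dataclass
class GenotypeTruth:
    """Ground truth emitted alongside simulated genotypes."""

    sweep_regions: list[SweepRegion]
    freq_high: dict[str, np.ndarray]
    freq_none: dict[str, np.ndarray]

    def to_json_dict(self) -> dict:
        return {
            "sweep_regions": [asdict(r) for r in self.sweep_regions],
        }


@dataclass
class ExpressionTruth:
    """Planted differential-expression truth."""

    de_transcripts: dict[str, tuple[str, float]]  # id -> (direction, fold)

    def to_json_dict(self) -> dict:
        return {
            "de_transcripts": {
                t: {"direction": d, "fold": f} for t, (d, f) in self.de_transcripts.items()
            }
        }


def default_sample_names(n_high: int, n_none: int) -> tuple[list[str], dict[str, str]]:
    samples = [f"A{i + 1}" for i in range(n_high)] + [f"N{i + 1}" for i in range(n_none)]
    groups = {s: (GROUP_HIGH if s.startswith("A") else GROUP_NONE) for s in samples}
    return samples, groups


def simulate_genotypes(config: SimGenomeConfig) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Draw a two-group diploid genotype matrix with planted sweeps.

    Outside sweep regions both groups share each site's allele frequency, so
    the reduction-of-diversity contrast is null there. Inside a sweep region
    the high group's frequency is multiplied by ``1 - diversity_reduction``;
    a reduction of 1 leaves the high group homozygous reference throughout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples, groups = default_sample_names(config.n_high, config.n_none)

    chroms, positions, refs, alts, geno_blocks = [], [], [], [], []
    freq_high: dict[str, np.ndarray] = {}
    freq_none: dict[str, np.ndarray] = {}
    regions_by_chrom: dict[str, list[SweepRegion]] = {}
    for r in config.sweep_regions:
        regions_by_chrom.setdefault(r.chrom, []).append(r)

    for chrom in config.chrom_names():
        m = config.n_snps_per_chrom
        pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False))
        p_none = rng.uniform(config.maf_low, config.maf_high, size=m)
        p_high = p_none.copy()
        for region in regions_by_chrom.get(chrom, []):
            inside = (pos >= region.start) & (pos < region.end)
            p_high[inside] *= 1.0 - region.diversity_reduction

        ref = rng.choice(_BASES, size=m)
        is_ts = rng.random(m) < config.ts_fraction
        alt = np.array([
            _TRANSITION[r] if ts else _TRANSVERSIONS[r][tv]
            for r, ts, tv in zip(ref, is_ts, rng.integers(0, 2, size=m))
        ], dtype=object)

        g_high = rng.binomial(2, p_high[:, None], size=(m, config.n_high))
        g_none = rng.binomial(2, p_none[:, None], size=(m, config.n_none))

        chroms.append(np.full(m, chrom, dtype=object))
        positions.append(pos)
        refs.append(ref.astype(object))
        alts.append(alt)
        geno_blocks.append(np.hstack([g_high, g_none]).astype(np.int8))
        freq_high[chrom] = p_high
        freq_none[chrom] = p_none

    gm = GenotypeMatrix(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        genotypes=np.vstack(geno_blocks),
        samples=samples,
        groups=groups,
    )
    return gm, GenotypeTruth(list(config.sweep_regions), freq_high, freq_none)


def simulate_gff(config: SimGenomeConfig, n_genes: int, seed: int,
                 gene_length: tuple[int, int] = (2_000, 8_000)) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping gene intervals on the genome.

    At least one gene is forced inside each planted sweep region so the
    sweep-to-gene overlap step always has a recoverable target. Returns a
    frame with 0-based half-open coordinates (columns gene_id, chrom, start,
    end, strand, description); :func:`sweepscreen.io.write_gff` converts to
    GFF3 1-based on disk.
    """
    config.validate()
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if n_genes < len(config.sweep_regions):
        raise ConfigError("need at least one gene per sweep region")
    rng = np.random.default_rng(seed)
    lo, hi = gene_length
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names()}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in placed[chrom])

    records = []

    def add(chrom: str, start: int, end: int) -> None:
        placed[chrom].append((start, end))
        gid = f"GENE{len(records) + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((gid, chrom, start, end, strand, "simulated gene"))

    for region in config.sweep_regions:
        span = region.end - region.start
        length = int(min(rng.integers(lo, hi + 1), span))
        start = region.start + int(rng.integers(0, span - length + 1))
        add(region.chrom, start, start + length)

    attempts = 0
    while len(records) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise ConfigError(f"genome too small to place {n_genes} non-overlapping genes")
        chrom = config.chrom_names()[int(rng.integers(0, config.n_chrom))]
        length = int(rng.integers(lo, hi + 1))
        if length >= config.chrom_length:
            continue
        start = int(rng.integers(0, config.chrom_length - length))
        if not overlaps(chrom, start, start + length):
            add(chrom, start, start + length)

    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand", "description"])
    chrom_order = {c: i for i, c in enumerate(config.chrom_names())}
    return df.sort_values(["chrom", "start"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
                          ).reset_index(drop=True)


def simulate_expression(
    n_transcripts: int,
    de_fraction: float,
    fold_range: tuple[float, float] = (4.0, 8.0),
    n_timepoints: int = 3,
    noise_cv: float = 0.2,
    seed: int = 0,
    n_high: int = 8,
    n_none: int = 2,
    baseline_mean_log: float = 2.5,
    baseline_sd_log: float = 1.0,
    fpkm_floor: float = 1e-3,
    transcript_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate a long-format FPKM table with planted fold changes.

    Each transcript has a lognormal baseline shared by both groups; planted DE
    transcripts multiply (up) or divide (down) the high group by a fold drawn
    from ``fold_range`` at every time point. Per-observation noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``
    (mean-one). Group sizes default to the 8 high / 2 none layout of the
    three-time-point RNA-seq design this emulates. Values are floored at
    ``fpkm_floor`` so expressed transcripts never carry exact zeros.
    """
    if not 0.0 <= de_fraction < 1.0:
        raise ConfigError(f"de_fraction must be in [0, 1), got {de_fraction}")
    if fold_range[0] < 2.0:
        raise ConfigError("planted folds must be >= 2 (the screen's threshold)")
    if fold_range[1] < fold_range[0]:
        raise ConfigError("fold_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    if transcript_ids is None:
        transcript_ids = [f"TR{i + 1:06d}" for i in range(n_transcripts)]
    elif len(transcript_ids) != n_transcripts:
        raise ConfigError("transcript_ids length must equal n_transcripts")

    samples = [f"AR{i + 1}" for i in range(n_high)] + [f"NR{i + 1}" for i in range(n_none)]
    sample_group = {s: (GROUP_HIGH if s.startswith("AR") else GROUP_NONE) for s in samples}

    n_de = int(round(de_fraction * n_transcripts))
    de_idx = rng.choice(n_transcripts, size=n_de, replace=False)
    directions = rng.random(n_de) < 0.5
    folds = rng.uniform(fold_range[0], fold_range[1], size=n_de)
    de_truth = {
        transcript_ids[i]: ("up" if up else "down", float(f))
        for i, up, f in zip(de_idx, directions, folds)
    }

    baseline = np.exp(rng.normal(baseline_mean_log, baseline_sd_log, size=n_transcripts))
    high_factor = np.ones(n_transcripts)
    for i, up, f in zip(de_idx, directions, folds):
        high_factor[i] = f if up else 1.0 / f

    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -sigma**2 / 2.0  # mean-one lognormal noise
    rows = []
    for t in range(1, n_timepoints + 1):
        for s in samples:
            mean = baseline * (high_factor if sample_group[s] == GROUP_HIGH else 1.0)
            if noise_cv > 0:
                vals = mean * np.exp(rng.normal(mu, sigma, size=n_transcripts))
            else:
                vals = mean
            rows.append(pd.DataFrame({
                "transcript_id": transcript_ids,
                "sample_id": s,
                "timepoint": t,
                "fpkm": np.maximum(vals, fpkm_floor),
            }))
    table = pd.concat(rows, ignore_index=True)
    return table, ExpressionTruth(de_truth)


def simulate_term_table(
    transcript_ids: list[str],
    de_ids: list[str],
    n_terms: int = 20,
    seed: int = 0,
    enriched_terms: int = 1,
) -> pd.DataFrame:
    """Random gene -> term memberships, with optional DE-enriched terms.

    Background terms sample uniformly from all transcripts; each enriched term
    takes most of its members from the planted DE set, giving the Fisher /
    permutation-FDR stage a recoverable signal.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(transcript_ids, dtype=object)
    rows = []
    for t in range(n_terms):
        term = f"TERM{t + 1:04d}"
        size = int(rng.integers(5, max(6, len(ids) // 10)))
        if t < enriched_terms and de_ids:
            n_from_de = min(len(de_ids), max(1, int(0.8 * size)))
            members = list(rng.choice(np.asarray(de_ids, dtype=object), size=n_from_de, replace=False))
            rest = int(max(0, size - n_from_de))
            members += list(rng.choice(ids, size=rest, replace=False))
        else:
            members = list(rng.choice(ids, size=min(size, len(ids)), replace=False))
        rows.extend((m, term) for m in dict.fromkeys(members))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def truth_headers(truth: GenotypeTruth) -> list[str]:
    """VCF meta lines making the planted sweep regions recoverable from the file."""
    return [
        f"##sweep_region=<chrom={r.chrom},start={r.start},end={r.end},"
        f"diversity_reduction={r.diversity_reduction:g}>"
        for r in truth.sweep_regions
    ]


def parse_truth_headers(header_lines: list[str]) -> list[SweepRegion]:
    """Inverse of :func:`truth_headers`."""
    regions = []
    for line in header_lines:
        if not line.startswith("##sweep_region=<"):
            continue
        body = line[len("##sweep_region=<"):].rstrip(">")
        kv = dict(item.split("=", 1) for item in body.split(","))
        regions.append(SweepRegion(kv["chrom"], int(kv["start"]), int(kv["end"]),
                                   float(kv["diversity_reduction"])))
    return regions


def write_truth_json(path, *parts) -> None:
    merged: dict = {}
    for part in parts:
        merged.update(part.to_json_dict())
    with open(path, "w") as fh:
        json.dump(merged, fh, indent=2, sort_keys=True)
        fh.write("\n")
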