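"""Windowed selective-sweep scan over two accession groups.

Statistics per genomic window (fixed tiles or 100-kb sliding windows with a
20-kb step, the defaults of the screen this implements):

* per-group nucleotide diversity ``pi`` — sum over in-window SNPs of the
  unbiased per-site average pairwise difference 2 p (1-p) n/(n-1), divided by
  the window span in bp;
* ``ROD = 1 - pi_high / pi_none`` — reduction of diversity of the selected
  ("high") group relative to the control ("none") group; near 1 where the
  high group has lost essentially all diversity, undefined where the control
  is monomorphic;
* pooled heterozygosity ``Hp = 2 S_maj S_min / (S_maj + S_min)^2`` over the
  summed major/minor allele counts of the window's SNPs, and its genome-wide
  z-score ``ZHp``;
* Hudson's FST, combined over SNPs as a ratio of sums.

Candidate regions are windows that fall below the ZHp threshold (default
-1.5) or sit in the upper tail of the empirical ROD distribution (default
p <= 0.01) while keeping high-group diversity below the candidate ceiling
(default pi <= 0.005/bp); overlapping or adjacent hit windows merge, and genes
overlapping a merged region by at least 1 bp are reported with their in-gene
SNP count and the region's minimum ZHp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass(frozen=True)
class GenomeWindow:
    """Half-open 0-based genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: {self}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class SweepCallConfig:
    """Window scheme and thresholds for candidate-region calling."""

    window_size: int = 100_000
    step: int = 20_000
    min_snps_per_window: int = 30
    zhp_threshold: float = -1.5
    rod_quantile_alpha: float = 0.01
    pi_max_for_candidate: float = 0.005
    exclude_terminal_windows: bool = False
    zhp_on_pooled: bool = False

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 < self.step <= self.window_size:
            raise ValueError(f"step must be in (0, window_size], got {self.step}")
        if not 0 < self.rod_quantile_alpha < 1:
            raise ValueError("rod_quantile_alpha must be in (0, 1)")


@dataclass
class Region:
    """A merged candidate sweep region."""

    chrom: str
    start: int
    end: int
    zhp_min: float
    n_windows: int


@dataclass
class CandidateGene:
    """A gene overlapping a called sweep region (report row)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_snps_in_gene: int
    zhp_of_region: float
    description: str = ""


def make_windows(chrom_lengths: dict[str, int], size: int, step: int | None = None
                 ) -> list[GenomeWindow]:
    """Tile (step == size) or slide (step < size) windows over each chromosome.

    A window is emitted for every start 0, step, 2*step, ... strictly below
    the chromosome length; its end is clipped at the chromosome end, so the
    terminal window may be short.
    """
    if step is None:
        step = size
    if size <= 0:
        raise ValueError("window size must be positive")
    if not 0 < step <= size:
        raise ValueError(f"step must be in (0, size], got step={step} size={size}")
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, step):
            windows.append(GenomeWindow(chrom, start, min(start + size, length)))
    return windows


def site_pi(alt_allele_count: int, n_alleles: int) -> float:
    """Unbiased per-site diversity: mean pairwise difference among n alleles.

    Equals 2 p (1-p) n/(n-1) with p the alternate-allele frequency — the
    proportion of the n(n-1)/2 allele pairs that differ.
    """
    if n_alleles < 2:
        raise ValueError("need at least two alleles")
    if not 0 <= alt_allele_count <= n_alleles:
        raise ValueError("alt allele count must be in [0, n_alleles]")
    p = alt_allele_count / n_alleles
    return 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1)


def _site_pi_vec(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_pi`; sites with n < 2 contribute 0."""
    out = np.zeros(len(alt))
    ok = n >= 2
    p = np.where(ok, alt / np.maximum(n, 1), 0.0)
    out[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * n[ok] / (n[ok] - 1)
    return out


def window_pi(site_pis: np.ndarray, window: GenomeWindow) -> float:
    """Sum of per-site diversities over the window, per bp of window span."""
    return float(np.sum(site_pis)) / window.span


def rod(pi_high: float, pi_none: float) -> float:
    """Reduction of diversity 1 - pi_high/pi_none; NaN when pi_none == 0."""
    if pi_high < 0 or pi_none < 0:
        raise ValueError("diversities must be non-negative")
    if pi_none == 0:
        return float("nan")
    return 1.0 - pi_high / pi_none


def window_hp(major_counts: np.ndarray, minor_counts: np.ndarray) -> float:
    """Pooled heterozygosity 2 S_maj S_min / (S_maj + S_min)^2 over a window's SNPs."""
    if len(major_counts) == 0:
        return float("nan")
    s_maj = float(np.sum(major_counts))
    s_min = float(np.sum(minor_counts))
    total = s_maj + s_min
    if total == 0:
        return float("nan")
    return 2.0 * s_maj * s_min / total**2


def zhp(hp_values: np.ndarray) -> np.ndarray:
    """Z-transform Hp across scored windows (genome-wide mean 0, sd 1).

    NaN entries (unscored windows) are excluded from the moments and stay NaN.
    """
    hp_values = np.asarray(hp_values, dtype=float)
    scored = hp_values[~np.isnan(hp_values)]
    if len(scored) < 2:
        raise ValueError("need at least two scored windows to z-transform")
    mean = scored.mean()
    sd = scored.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate scan: all windows have identical Hp")
    return (hp_values - mean) / sd


def hudson_fst_components(p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of Hudson's two-population FST estimator."""
    num = (p1 - p2) ** 2 \
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1) \
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(alt1: np.ndarray, n1: np.ndarray, alt2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson's FST over a window's SNPs, averaged as a ratio of sums.

    Sites where either group has fewer than two called alleles are skipped;
    with no scorable site (or zero pooled denominator) the window is NaN.
    """
    ok = (n1 >= 2) & (n2 >= 2)
    if not np.any(ok):
        return float("nan")
    p1 = alt1[ok] / n1[ok]
    p2 = alt2[ok] / n2[ok]
    num, den = hudson_fst_components(p1, n1[ok], p2, n2[ok])
    den_sum = float(den.sum())
    if den_sum == 0:
        return float("nan")
    return float(num.sum()) / den_sum


def compute_window_stats(gm: GenotypeMatrix, cfg: SweepCallConfig,
                         chrom_lengths: dict[str, int] | None = None,
                         windows: list[GenomeWindow] | None = None,
                         strict_zhp: bool = True) -> pd.DataFrame:
    """Score every window: n_snps, per-group pi, ROD, Hp, ZHp, FST.

    Windows with fewer than ``cfg.min_snps_per_window`` SNPs are retained in
    the output but flagged unscored (``scored`` column False); their Hp is
    excluded from the ZHp moments and they never become hits. When
    ``chrom_lengths`` is omitted, each chromosome extends to its last SNP + 1.
    """
    if windows is None:
        if chrom_lengths is None:
            chrom_lengths = {c: int(gm.pos[idx].max()) + 1 for c, idx in gm.by_chrom()}
        windows = make_windows(chrom_lengths, cfg.window_size, cfg.step)

    alt_h, n_h = gm.allele_counts("high")
    alt_n, n_n = gm.allele_counts("none")
    pi_site_h = _site_pi_vec(alt_h, n_h)
    pi_site_n = _site_pi_vec(alt_n, n_n)
    maj_h = np.maximum(alt_h, n_h - alt_h)
    min_h = n_h - maj_h
    if cfg.zhp_on_pooled:
        alt_p, n_p = gm.allele_counts()
        maj_hp_src = np.maximum(alt_p, n_p - alt_p)
        min_hp_src = n_p - maj_hp_src
    else:
        maj_hp_src, min_hp_src = maj_h, min_h

    pos_by_chrom = {c: (idx, gm.pos[idx]) for c, idx in gm.by_chrom()}

    rows = []
    for w in windows:
        if w.chrom in pos_by_chrom:
            idx, pos = pos_by_chrom[w.chrom]
            lo, hi = np.searchsorted(pos, [w.start, w.end])
            sel = idx[lo:hi]
        else:
            sel = np.array([], dtype=np.intp)
        n_snps = len(sel)
        pi_high = window_pi(pi_site_h[sel], w)
        pi_none = window_pi(pi_site_n[sel], w)
        rows.append({
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "n_snps": n_snps,
            "pi_high": pi_high,
            "pi_none": pi_none,
            "rod": rod(pi_high, pi_none),
            "hp_high": window_hp(maj_hp_src[sel], min_hp_src[sel]),
            "fst": window_fst(alt_h[sel], n_h[sel], alt_n[sel], n_n[sel]),
            "terminal": w.span < cfg.window_size,
        })
    stats = pd.DataFrame(rows)
    stats["scored"] = stats["n_snps"] >= cfg.min_snps_per_window
    if cfg.exclude_terminal_windows:
        stats["scored"] &= ~stats["terminal"]
    hp_for_z = np.where(stats["scored"], stats["hp_high"], np.nan)
    try:
        stats["zhp_high"] = zhp(hp_for_z)
    except ValueError:
        if strict_zhp:
            raise
        stats["zhp_high"] = np.nan
    return stats


def call_sweep_regions(stats: pd.DataFrame, cfg: SweepCallConfig) -> list[Region]:
    """Call and merge candidate sweep regions from window statistics.

    A scored window is a hit when its ZHp falls at or below the threshold, or
    when its ROD reaches the empirical (1 - alpha) quantile of defined ROD
    values while staying positive with high-group diversity at or below the
    candidate ceiling. Overlapping or bookended hit windows on a chromosome
    merge; each region carries the minimum ZHp over its member windows.
    """
    if len(stats) == 0:
        return []
    scored = stats[stats["scored"]]
    if len(scored) == 0:
        return []
    rod_vals = scored["rod"].to_numpy(dtype=float)
    defined = rod_vals[~np.isnan(rod_vals)]
    rod_cut = np.quantile(defined, 1.0 - cfg.rod_quantile_alpha) if len(defined) else np.inf

    zhp_hit = scored["zhp_high"] <= cfg.zhp_threshold
    rod_hit = (
        (scored["rod"] >= rod_cut)
        & (scored["rod"] > 0)
        & (scored["pi_high"] <= cfg.pi_max_for_candidate)
    )
    hits = scored[zhp_hit | rod_hit.fillna(False)]

    regions: list[Region] = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples():
            if cur is not None and row.start <= cur.end:
                cur.end = max(cur.end, row.end)
                cur.zhp_min = min(cur.zhp_min, row.zhp_high)
                cur.n_windows += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = Region(chrom, row.start, row.end, float(row.zhp_high), 1)
        if cur is not None:
            regions.append(cur)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def genes_in_regions(regions: list[Region], genes: pd.DataFrame,
                     gm: GenotypeMatrix | None = None) -> list[CandidateGene]:
    """Report genes overlapping any called region by >= 1 bp.

    ``genes`` is the gene-model frame (gene_id, chrom, start, end, strand,
    description; 0-based half-open). Each reported gene carries its in-gene
    SNP count (0 when no genotype matrix is supplied) and the minimum ZHp of
    the regions it overlaps. Output is ordered by (chrom, start).
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    if gm is not None:
        pos_by_chrom = {c: np.sort(gm.pos[idx]) for c, idx in gm.by_chrom()}

    out: list[CandidateGene] = []
    for g in genes.itertuples():
        overlapping = [r for r in regions
                       if r.chrom == g.chrom and g.start < r.end and r.start < g.end]
        if not overlapping:
            continue
        if g.chrom in pos_by_chrom:
            pos = pos_by_chrom[g.chrom]
            n_snps = int(np.searchsorted(pos, g.end) - np.searchsorted(pos, g.start))
        else:
            n_snps = 0
        out.append(CandidateGene(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=int(g.start),
            end=int(g.end),
            strand=g.strand,
            n_snps_in_gene=n_snps,
            zhp_of_region=min(r.zhp_min for r in overlapping),
            description=getattr(g, "description", "") or "",
        ))
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def track_windows(gm: GenotypeMatrix, chrom_lengths: dict[str, int] | None = None,
                  size: int = 5_000) -> pd.DataFrame:
    """Fixed-tile track values (chrom, start, end, rod, pi_high, pi_none, fst).

    Defaults to 5-kb tiles, the resolution used for circular genome-plot
    tracks; no minimum SNP count is applied, so sparse tiles carry NaNs.
    """
    cfg = SweepCallConfig(window_size=size, step=size, min_snps_per_window=1)
    stats = compute_window_stats(gm, cfg, chrom_lengths=chrom_lengths, strict_zhp=False)
    return stats[["chrom", "start", "end", "n_snps", "pi_high", "pi_none", "rod", "fst"]]
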