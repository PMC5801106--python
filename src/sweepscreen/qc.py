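"""SNP quality control: bi-allelic screen, HWE test, MAF filter, Ts/Tv.

The filter stack mirrors the staged reduction used in two-group resequencing
panels: keep bi-allelic single-nucleotide sites, drop sites out of
Hardy-Weinberg equilibrium at a stringent alpha (default 0.001, pooled across
both groups), then drop rare sites below a minor-allele-frequency floor
(default 0.1). Retention is non-strict at both boundaries: a site is kept when
HWE p >= alpha and MAF >= maf_min.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

_VALID_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


@dataclass
class QcConfig:
    """Thresholds for the SNP filter stack.

    hwe_alpha : sites with HWE goodness-of-fit p below this are dropped.
    maf_min : minor-allele-frequency floor (kept when MAF >= maf_min).
    max_missing : drop sites where more than this fraction of genotypes is missing.
    hwe_exact : use the exact conditional HWE test instead of the 1-df chi-square.
    hwe_per_group : test HWE within each group separately (drop if either fails)
        instead of pooled across groups.
    """

    hwe_alpha: float = 0.001
    maf_min: float = 0.1
    max_missing: float = 0.5
    hwe_exact: bool = False
    hwe_per_group: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError(f"hwe_alpha must be in (0, 1), got {self.hwe_alpha}")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")


def is_biallelic_snp(ref: str, alts: Iterable[str]) -> bool:
    """True when the record is a single-nucleotide site with exactly one ALT."""
    alts = list(alts)
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _VALID_BASES
        and alts[0].upper() in _VALID_BASES
        and ref.upper() != alts[0].upper()
    )


def filter_biallelic(sites: Iterable, counter: dict | None = None) -> Iterator:
    """Pass through bi-allelic SNP records, counting what was dropped.

    Works on any record with ``.REF`` and ``.ALT`` attributes (cyvcf2
    variants). ``counter`` accumulates ``n_in``/``n_out``/``n_dropped``.
    """
    if counter is None:
        counter = {}
    counter.setdefault("n_in", 0)
    counter.setdefault("n_out", 0)
    for rec in sites:
        counter["n_in"] += 1
        if is_biallelic_snp(rec.REF, rec.ALT):
            counter["n_out"] += 1
            yield rec
    counter["n_dropped"] = counter["n_in"] - counter["n_out"]


def hwe_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """One-degree-of-freedom chi-square HWE goodness-of-fit p-value.

    Observed genotype counts are compared with Hardy-Weinberg expectations at
    the sample allele frequency. Monomorphic sites fit trivially (p = 1).
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_homalt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_homref, n_het, n_homalt], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional HWE test (sum of probabilities <= the observed one).

    Enumerates every heterozygote count compatible with the observed allele
    counts; each configuration's probability under HWE conditional on allele
    counts is n! 2^het / (homref! het! homalt!) * na! nb! / (2n)!, computed
    here with exact integer weights.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_homref + n_het  # rarer-or-not does not matter: symmetric
    n_b = 2 * n_homalt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    het_min = (n_a * n_b) % 2  # parity fixed by allele counts
    weights = {}
    for het in range(het_min, min(n_a, n_b) + 1, 2):
        homref = (n_a - het) // 2
        homalt = (n_b - het) // 2
        weights[het] = (
            comb(n, homref) * comb(n - homref, het) * (1 << het)
        )
    total = sum(weights.values())
    obs_w = weights[n_het]
    return sum(w for w in weights.values() if w <= obs_w) / total


def hwe_pvalues(gm: GenotypeMatrix, cfg: QcConfig) -> np.ndarray:
    """Per-site HWE p-values under the configured test and stratification."""
    test = hwe_exact_test if cfg.hwe_exact else hwe_test

    def _pvals(counts: np.ndarray) -> np.ndarray:
        return np.array([
            test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
            for a, b, c in counts[:, :3]
        ])

    if cfg.hwe_per_group:
        p_high = _pvals(gm.genotype_counts("high"))
        p_none = _pvals(gm.genotype_counts("none"))
        return np.minimum(p_high, p_none)
    return _pvals(gm.genotype_counts())


def apply_qc(gm: GenotypeMatrix, cfg: QcConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run the missingness -> HWE -> MAF filter stack on a genotype matrix.

    Returns the retained sites and a per-stage summary frame with columns
    (stage, n_in, n_out, n_dropped). The retained set is order-independent
    across the HWE and MAF stages (each is evaluated on the input counts); the
    summary reports them in the order applied.
    """
    counts = gm.genotype_counts()
    n_total = counts[:, :4].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        missing_frac = np.where(n_total > 0, counts[:, 3] / np.maximum(n_total, 1), 1.0)
    keep_missing = missing_frac <= cfg.max_missing

    pvals = hwe_pvalues(gm, cfg)
    keep_hwe = pvals >= cfg.hwe_alpha
    maf = gm.maf()
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min

    stages = []
    mask = np.ones(gm.n_sites, dtype=bool)
    for name, keep in (("missingness", keep_missing), ("hwe", keep_hwe), ("maf", keep_maf)):
        n_in = int(mask.sum())
        mask &= keep
        n_out = int(mask.sum())
        stages.append((name, n_in, n_out, n_in - n_out))
    summary = pd.DataFrame(stages, columns=["stage", "n_in", "n_out", "n_dropped"])
    return gm.subset(mask), summary


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a substitution as ``"transition"`` (A<->G, C<->T) or ``"transversion"``."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _VALID_BASES or alt not in _VALID_BASES:
        raise ValueError(f"bases must be one of ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref} -> {alt}")
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


def tstv_ratio(n_ts: int, n_tv: int) -> float:
    """Transition/transversion ratio; NaN when there are no transversions."""
    if n_ts < 0 or n_tv < 0:
        raise ValueError("counts must be non-negative")
    if n_tv == 0:
        return float("nan")
    return n_ts / n_tv


def tstv_from_sites(gm: GenotypeMatrix) -> tuple[int, int, float]:
    """Tally transitions and transversions over all sites and return the ratio."""
    n_ts = 0
    for r, a in zip(gm.ref, gm.alt):
        if classify_substitution(r, a) == "transition":
            n_ts += 1
    n_tv = gm.n_sites - n_ts
    return n_ts, n_tv, tstv_ratio(n_ts, n_tv)
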