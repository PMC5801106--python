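"""In-memory genotype container shared by the QC and sweep-scan stages.

A :class:`GenotypeMatrix` holds one diploid genotype per sample per bi-allelic
site, encoded as the alternate-allele dosage (0, 1, 2; -1 for missing), plus a
two-group partition of the samples ("high" vs "none" anthocyanin accessions in
the motivating screen). All positions are internal 0-based; file boundaries
(VCF, GFF3) convert on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

GROUP_HIGH = "high"
GROUP_NONE = "none"
VALID_GROUPS = frozenset({GROUP_HIGH, GROUP_NONE})

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Bi-allelic sites x samples dosage matrix with a two-group sample map.

    Parameters
    ----------
    chrom : array of str, one per site
    pos : array of int, 0-based positions, sorted within chromosome
    ref, alt : arrays of single bases
    genotypes : int8 array of shape (n_sites, n_samples); alt dosage, -1 missing
    samples : ordered sample names matching genotype columns
    groups : mapping sample -> "high" | "none"
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    groups: dict[str, str]
    _group_idx: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        unknown = [s for s in self.samples if s not in self.groups]
        if unknown:
            raise ValueError(f"samples missing a group assignment: {unknown}")
        bad = {s: g for s, g in self.groups.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"invalid group labels (want high/none): {bad}")
        self._group_idx = {
            g: np.array([i for i, s in enumerate(self.samples) if self.groups[s] == g],
                        dtype=np.intp)
            for g in VALID_GROUPS
        }

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_samples(self, group: str) -> list[str]:
        return [self.samples[i] for i in self.group_indices(group)]

    def group_indices(self, group: str) -> np.ndarray:
        if group not in VALID_GROUPS:
            raise KeyError(f"unknown group {group!r}; expected one of {sorted(VALID_GROUPS)}")
        return self._group_idx[group]

    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    # -- per-site summaries --------------------------------------------------

    def allele_counts(self, group: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called allele count) per site.

        ``group=None`` pools both groups. Missing genotypes contribute neither
        alleles nor calls.
        """
        g = self.genotypes if group is None else self.genotypes[:, self.group_indices(group)]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1, dtype=np.int64)
        n_alleles = 2 * called.sum(axis=1, dtype=np.int64)
        return alt, n_alleles

    def genotype_counts(self, group: str | None = None) -> np.ndarray:
        """Per-site (n_homref, n_het, n_homalt, n_missing) as an (n_sites, 4) array."""
        g = self.genotypes if group is None else self.genotypes[:, self.group_indices(group)]
        out = np.empty((g.shape[0], 4), dtype=np.int64)
        out[:, 0] = (g == 0).sum(axis=1)
        out[:, 1] = (g == 1).sum(axis=1)
        out[:, 2] = (g == 2).sum(axis=1)
        out[:, 3] = (g == MISSING).sum(axis=1)
        return out

    def maf(self, group: str | None = None) -> np.ndarray:
        """Pooled minor-allele frequency per site (NaN where no alleles called)."""
        alt, n = self.allele_counts(group)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    # -- structural ops ------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
            groups=dict(self.groups),
        )

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chrom, site index array) in first-seen chromosome order."""
        for name in self.chrom_names():
            yield name, np.flatnonzero(self.chrom == name)

    def sort(self) -> "GenotypeMatrix":
        """Stable sort by (chromosome first-seen order, position)."""
        order = np.concatenate(
            [idx[np.argsort(self.pos[idx], kind="stable")] for _, idx in self.by_chrom()]
        ) if self.n_sites else np.array([], dtype=np.intp)
        return self.subset(order)


def read_group_table(path) -> dict[str, str]:
    """Read the two-column sample/group sidecar TSV (sample_id, group)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns, got {len(parts)}")
            sample, group = parts
            if sample == "sample_id" and group == "group":
                continue  # header
            if group not in VALID_GROUPS:
                raise ValueError(f"{path}:{ln}: group {group!r} not in {sorted(VALID_GROUPS)}")
            groups[sample] = group
    return groups


def write_group_table(groups: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")
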