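import numpy as np
import pytest

from sweepscreen.genotypes import GenotypeMatrix


def make_gm(genotypes, pos=None, chrom="chr1", n_high=None, ref=None, alt=None):
    """Build a tiny GenotypeMatrix from a (sites x samples) dosage list.

    The first ``n_high`` columns are the "high" group (default: half).
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if n_high is None:
        n_high = n_samples // 2
    samples = [f"A{i}" for i in range(n_high)] + [f"N{i}" for i in range(n_samples - n_high)]
    groups = {s: ("high" if s.startswith("A") else "none") for s in samples}
    if pos is None:
        pos = np.arange(n_sites) * 10
    chroms = np.full(n_sites, chrom, dtype=object) if isinstance(chrom, str) \
        else np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        chrom=chroms,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object),
        genotypes=g,
        samples=samples,
        groups=groups,
    )


@pytest.fixture
def tiny_gm():
    """5 sites x 4 samples (2 high / 2 none) with a mix of dosages."""
    return make_gm(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 0],
            [2, 2, 0, 0],
            [0, 0, 0, 1],
            [1, 2, 1, 2],
        ],
        pos=[5, 100, 250, 400, 900],
    )
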