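import numpy as np
import pandas as pd
import pytest

from dcmscan.io import MAP_COLUMNS, HaplotypeMatrix


def make_matrix(alleles, chrom="1", pos=None, subpop=None, spacing=1000):
    """Build a HaplotypeMatrix from a nested list / array of haplotype rows.

    ``chrom`` may be a single name or a per-locus list; positions default
    to ``spacing``-spaced within each chromosome.
    """
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_loci = alleles.shape
    assert n_hap % 2 == 0
    chroms = [chrom] * n_loci if isinstance(chrom, str) else list(chrom)
    if pos is None:
        pos, counters = [], {}
        for c in chroms:
            counters[c] = counters.get(c, 0) + 1
            pos.append(counters[c] * spacing)
    vmap = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "id": [f"snp{i}" for i in range(n_loci)],
            "ref": "A",
            "alt": "G",
        }
    )[MAP_COLUMNS]
    sample_ids = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(alleles, vmap, sample_ids, subpop)


def random_matrix(rng, n_samples=5, n_loci=8, chrom="1", maf_range=(0.1, 0.9),
                  spacing=1000):
    freqs = rng.uniform(*maf_range, size=n_loci)
    alleles = (rng.random((2 * n_samples, n_loci)) < freqs).astype(np.int8)
    return make_matrix(alleles, chrom=chrom, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
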