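import numpy as np
import pytest

from miniscan.genomics_io import GenomicInterval, GenotypeMatrix, VariantSite


def make_matrix(sample_ids, chrom_positions, calls):
    """Build a GenotypeMatrix from {chrom: [positions]} and a calls array."""
    variants = []
    for chrom in chrom_positions:
        for pos in chrom_positions[chrom]:
            variants.append(VariantSite(chrom, int(pos), "A", "G", qual=99.0))
    return GenotypeMatrix(sample_ids, variants, np.asarray(calls, dtype=np.int8))


def bitmap_cover(intervals, chrom, length):
    """Boolean per-base coverage of a toy chromosome (1-based positions
    1..length) — the brute-force oracle for interval arithmetic."""
    cover = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chromosome == chrom:
            cover[iv.start - 1 : iv.end] = True
    return cover


def intervals_from_bitmap(cover, chrom):
    """Inverse of bitmap_cover: maximal covered runs as intervals."""
    out = []
    n = len(cover)
    i = 0
    while i < n:
        if not cover[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cover[j + 1]:
            j += 1
        out.append(GenomicInterval(chrom, i + 1, j + 1))
        i = j + 1
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20180625)
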