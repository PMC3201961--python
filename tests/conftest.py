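import numpy as np
import pytest

from tetracomb.markers_io import Tetrad


def make_tetrad(chrom_data):
    """Build a Tetrad from {chrom: [(pos, (g1, g2, g3, g4)), ...]}."""
    tetrad = Tetrad()
    for chrom, rows in chrom_data.items():
        pos = np.array([p for p, _ in rows], dtype=np.int64)
        geno = np.array([g for _, g in rows], dtype=np.int8)
        tetrad.set_chromosome(chrom, pos, geno)
    return tetrad


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_parental_tetrad():
    """All-2:2 parental seg on two chromosomes: no recombination anywhere."""
    rows = [(p, (0, 1, 1, 0)) for p in range(1000, 20001, 1000)]
    return make_tetrad({1: rows, 2: rows})
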