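import numpy as np
import pandas as pd
import pytest

from rilqtl import simdata
from rilqtl.geno import GenotypeMatrix


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 100 cM each, 200 markers, 1 cM ~ 1 Mbp."""
    return simdata.GeneticMap.uniform([100, 100], 200)


@pytest.fixture(scope="session")
def ril_geno(small_map):
    """118 S7 RILs on the small two-chromosome map."""
    return simdata.simulate_ril_genomes(small_map, 118, 7, seed=42)


def make_geno(calls, chrom=None, pos=None, lines=None):
    """Build a GenotypeMatrix from an int array of coded calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    markers = pd.DataFrame(
        {
            "marker": [f"S{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
        }
    )
    lines = [f"L{i:03d}" for i in range(n)] if lines is None else lines
    return GenotypeMatrix(lines=lines, markers=markers, calls=calls)


@pytest.fixture
def toy_geno():
    """10 lines x 4 markers with known allele counts."""
    calls = np.array(
        [
            # marker0: 3 B, 7 A -> MAF 0.3 ; marker1: monomorphic A
            # marker2: balanced  ; marker3: 25% missing
            [2, 0, 0, -1],
            [2, 0, 0, -1],
            [2, 0, 0, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 2],
            [0, 0, 2, 2],
            [0, 0, 2, 2],
            [0, 0, 2, 0],
            [0, 0, 2, 0],
            [0, 0, 2, -1],
        ],
        dtype=np.int8,
    )
    return make_geno(calls)
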