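import numpy as np
import pandas as pd
import pytest

from fermqtl.genotyping import GenotypeMatrix
from fermqtl.synthetic_data import GenomeModel, default_genome, simulate_cross, simulate_parents


@pytest.fixture(scope="session")
def small_genome():
    return GenomeModel(chromosomes=(("chrA", 400_000), ("chrB", 300_000)), cm_per_kb=0.4)


@pytest.fixture(scope="session")
def yeast_genome():
    return default_genome()


@pytest.fixture(scope="session")
def study_cross(yeast_genome):
    """A default-scale cross: 1071 markers, 117 segregants, seed 11."""
    parents = simulate_parents(yeast_genome, 1071, seed=11)
    cross = simulate_cross(parents, 117, yeast_genome, seed=11)
    return parents, cross


def one_marker_gm(n_p1: int, n_p2: int) -> GenotypeMatrix:
    """A single-marker genotype matrix with the first n_p1 segregants P1."""
    calls = np.array([[0]] * n_p1 + [[1]] * n_p2, dtype=np.int8)
    segs = [f"s{i}" for i in range(n_p1 + n_p2)]
    markers = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]})
    return GenotypeMatrix(calls=calls, segregants=segs, markers=markers)
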