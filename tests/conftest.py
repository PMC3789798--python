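import numpy as np
import pytest

from linkmap.distances import DistanceConfig, pair_distance
from linkmap.io_formats import Chromosome, Gene, GenomeAnnotation


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two chromosomes with a handful of genes at known midpoints."""
    genes = [
        Gene("gA1", "chrA", 99_500, 100_500),    # midpoint 100 kb
        Gene("gA2", "chrA", 139_500, 140_500),   # midpoint 140 kb
        Gene("gA3", "chrA", 159_500, 160_500),   # midpoint 160 kb
        Gene("gA4", "chrA", 249_500, 250_500),   # midpoint 250 kb
        Gene("gB1", "chrB", 49_500, 50_500),
        Gene("gB2", "chrB", 449_500, 450_500),
    ]
    return GenomeAnnotation(
        chromosomes=[
            Chromosome("chrA", 300_000, 150_000),
            Chromosome("chrB", 900_000, 200_000),
        ],
        genes=genes,
    )


@pytest.fixture
def dcfg() -> DistanceConfig:
    return DistanceConfig()


def make_pair(query, array, sga, R=0.1):
    """PairDistance with a forced sga_gd (for matrix-construction tests)."""
    p = pair_distance(query, array, R)
    p.sga_gd = float(sga)
    return p


@pytest.fixture
def pair_factory():
    return make_pair
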