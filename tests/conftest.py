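import numpy as np
import pytest

from haploshare.formats_io import ALLELE_CODES, GeneticMap


def geno(strings):
    """'AB' -> [[0,1]], '--' -> [[-1,-1]] etc.; one 2-char string per marker."""
    return np.array(
        [[ALLELE_CODES[s[0]], ALLELE_CODES[s[1]]] for s in strings], dtype=np.int8
    )


@pytest.fixture
def make_geno():
    return geno


@pytest.fixture
def six_marker_map():
    """One chromosome, markers every 10 cM from 0 to 50."""
    return GeneticMap(
        tuple(f"m{i}" for i in range(1, 7)),
        tuple("1" * 6),
        np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0]),
    )


@pytest.fixture
def two_chrom_map():
    return GeneticMap(
        ("a1", "a2", "a3", "b1", "b2"),
        ("1", "1", "1", "2", "2"),
        np.array([0.0, 25.0, 50.0, 0.0, 30.0]),
    )


@pytest.fixture(scope="session")
def mixed_population():
    """Error-free cherry-scale simulated population with all pair classes."""
    from haploshare.pedsim import SimDesign, simulate_population

    design = SimDesign(
        templates={"FSIB": 8, "HSIB": 8, "GPGC": 8, "HAAM": 8, "OSGP": 8, "NKCR": 8},
        n_markers=800,
        seed=11,
    )
    return simulate_population(design)
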