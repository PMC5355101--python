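import numpy as np
import pytest

from psekit import (
    BioSequence,
    Molecule,
    PropertyIndex,
    PropertyTable,
    default_property_index,
    standardize_properties,
)
from psekit.sequence_io import ALPHABETS


def random_sequence(rng, molecule, length, seq_id="s"):
    alphabet = ALPHABETS[molecule]
    residues = "".join(
        np.array(list(alphabet))[rng.integers(0, len(alphabet), length)]
    )
    return BioSequence(seq_id, residues, molecule)


@pytest.fixture(scope="session")
def dna_index():
    return default_property_index(Molecule.DNA)


@pytest.fixture(scope="session")
def rna_index():
    return default_property_index(Molecule.RNA)


@pytest.fixture(scope="session")
def protein_index():
    return default_property_index(Molecule.PROTEIN)


@pytest.fixture(scope="session")
def toy_residue_index():
    """Single property over DNA residues standardizing to A,T=-1 and C,G=+1.

    Raw values {A:0, C:2, G:2, T:0} have mean 1 and population SD 1, so the
    standardized values are exactly ±1 — convenient for hand-computed
    correlation factors.
    """
    table = PropertyTable(
        Molecule.DNA,
        "residue",
        ("toy",),
        {"toy": {"A": 0.0, "C": 2.0, "G": 2.0, "T": 0.0}},
        set_name="toy",
    )
    return standardize_properties(table)


#: Reduced grid used by the slower end-to-end checks: a 16-candidate subset
#: of the package defaults that resolves the planted-motif benchmark.
REDUCED_GRID = dict(
    ks=(4, 5),
    lams=(1, 2),
    ws=(0.1,),
    Cs=(2.0**0, 2.0**4),
    gammas=(2.0**2, 2.0**6),
)
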