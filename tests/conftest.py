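import numpy as np
import pytest

import ifacevol as iv


@pytest.fixture(scope="session")
def toy_complex():
    """Toy complex with planted residue classes (default study geometry)."""
    cx, truth = iv.make_toy_complex(seed=7)
    return cx, truth


@pytest.fixture(scope="session")
def toy_labels(toy_complex):
    cx, _ = toy_complex
    return iv.classify_complex(cx, with_heme=True)


@pytest.fixture(scope="session")
def small_tree():
    return iv.simulate_tree(6, 0.2, seed=11)


@pytest.fixture(scope="session")
def small_alignment(small_tree):
    aln, truth = iv.simulate_codon_alignment(
        small_tree,
        {"slow": 0.1, "fast": 0.6},
        kappa=3.0,
        columns_per_partition={"slow": 40, "fast": 40},
        seed=13,
    )
    return aln, truth


@pytest.fixture()
def pdb_fixture(tmp_path):
    """Hand-written PDB exercising altlocs, hydrogens, waters and a heme."""
    lines = [
        # chain A, residue 1: two altlocs on CA (B has the higher occupancy)
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C",
        "ATOM      3  CA BALA A   1       1.500   0.000   0.000  0.60  0.00           C",
        "ATOM      4  H   ALA A   1       9.000   9.000   9.000  1.00  0.00           H",
        "ATOM      5  N   GLY A   2       3.000   0.000   0.000  1.00  0.00           N",
        "ATOM      6  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C",
        "TER",
        "ATOM      7  N   SER B   1       0.000   8.000   0.000  1.00  0.00           N",
        "ATOM      8  CA  SER B   1       1.000   8.000   0.000  1.00  0.00           C",
        "ATOM      9  OG  SER B   1       2.000   8.000   0.000  1.00  0.00           O",
        "TER",
        "HETATM   10 FE   HEM A 901      20.000  20.000  20.000  1.00  0.00          FE",
        "HETATM   11  O   HOH A 902      30.000  30.000  30.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


@pytest.fixture()
def fasta_writer():
    return write_fasta
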