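"""Shared fixtures: tiny hand-written PDB files and built peptides."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from snnkit.structure import read_structure
from snnkit.synth import PeptideBuildSpec, ResidueTorsions, build_peptide

# a single-residue, three-atom fixture written by hand (fixed-column PDB)
THREE_ATOM_PDB = textwrap.dedent(
    """\
    ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
    ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
    END
    """
)

# altloc fixture: CA has two conformers, B with the higher occupancy
ALTLOC_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
    ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40  0.00           C
    ATOM      3  CA BALA A   1       1.458   0.100   0.000  0.60  0.00           C
    ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
    END
    """
)


@pytest.fixture
def three_atom_structure(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return read_structure(path)


@pytest.fixture
def altloc_path(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def extended_strand():
    """A 9-residue all-extended peptide (φ = −135°, ψ = 135°)."""
    return build_peptide(PeptideBuildSpec("AAAAAAAAA"))


@pytest.fixture
def alpha_helix():
    """A 9-residue ideal α-helix (φ = −57°, ψ = −47°)."""
    tors = [ResidueTorsions(phi=-57.0, psi=-47.0) for _ in range(9)]
    return build_peptide(PeptideBuildSpec("AAAAAAAAA", tors))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
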