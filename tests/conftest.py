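import textwrap

import numpy as np
import pandas as pd
import pytest

from conformer_ddg.variant_io import DdgMatrix, SasRecord


def pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ",
             element=None, record="ATOM"):
    if element is None:
        element = name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Nine-atom, two-residue single chain: resolved positions {1, 2}."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0, element="C"),
        pdb_line(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, element="C"),
        pdb_line(4, "O", "ALA", "A", 1, 1.5, 2.5, 0.0, element="O"),
        pdb_line(5, "N", "GLY", "A", 2, 3.3, 1.3, 0.0, element="N"),
        pdb_line(6, "CA", "GLY", "A", 2, 4.2, 2.4, 0.0, element="C"),
        pdb_line(7, "C", "GLY", "A", 2, 5.6, 1.9, 0.0, element="C"),
        pdb_line(8, "O", "GLY", "A", 2, 6.0, 0.8, 0.0, element="O"),
        pdb_line(9, "CB", "ALA", "A", 1, 1.9, -1.3, 0.0, element="C"),
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("".join(lines) + "END\n")
    return path


def make_ddg_matrix(rows):
    """rows: iterable of (protein, pos, wt, mut, conformer, ddg)."""
    return DdgMatrix(
        pd.DataFrame(
            rows,
            columns=[
                "protein_id", "position", "wt_aa", "mut_aa",
                "conformer_id", "ddg_kcal_mol",
            ],
        )
    )


def make_labels(entries):
    """entries: iterable of (protein, pos, wt, mut, label)."""
    return [
        SasRecord(protein_id=p, position=pos, wt_aa=wt, mut_aa=mut, label=label)
        for p, pos, wt, mut, label in entries
    ]


@pytest.fixture
def toy_matrix_and_labels():
    """Two proteins, 3 substitutions x 2 conformers, hand-checkable values."""
    matrix = make_ddg_matrix(
        [
            ("P1", 10, "A", "D", "c1", 3.0),
            ("P1", 10, "A", "D", "c2", 1.0),
            ("P1", 20, "G", "R", "c1", 0.5),
            ("P1", 20, "G", "R", "c2", 0.2),
            ("P2", 5, "L", "P", "d1", 2.5),
            ("P2", 5, "L", "P", "d2", 4.5),
        ]
    )
    labels = make_labels(
        [
            ("P1", 10, "A", "D", "disease"),
            ("P1", 20, "G", "R", "neutral"),
            ("P2", 5, "L", "P", "disease"),
        ]
    )
    return matrix, labels
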