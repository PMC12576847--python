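"""Shared fixtures: tiny hand-constructed PDB files and small ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from modeltriage.structio import CATrace, ResidueKey
from modeltriage.cluster import SolutionRecord


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.00,
    altloc: str = " ",
    element: str = "C",
    record: str = "ATOM",
    icode: str = " ",
) -> str:
    """One fixed-width coordinate record (standard PDB columns)."""
    padded = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {padded}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three alanines in chain A, backbone N/CA/C each."""
    lines = []
    serial = 1
    for i in range(3):
        z = 3.8 * i
        for atom, dx, el in (("N", -1.0, "N"), ("CA", 0.0, "C"), ("C", 1.0, "C")):
            lines.append(pdb_atom_line(serial, atom, "ALA", "A", i + 1, dx, 0.0, z, element=el))
            serial += 1
    return write_pdb(tmp_path / "three.pdb", lines)


def make_trace(coords, chain="A", start=1) -> CATrace:
    coords = np.asarray(coords, dtype=float)
    keys = [ResidueKey(chain, start + i) for i in range(len(coords))]
    return CATrace(keys=keys, coords=coords)


def make_solution(solution_id: str, score: float, coords) -> SolutionRecord:
    return SolutionRecord(solution_id=solution_id, score=score, trace=make_trace(coords))


def random_trace_coords(rng, n=12, scale=10.0):
    return rng.uniform(-scale, scale, size=(n, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
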