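"""Coordinate I/O: read PDB/mmCIF models, extract CA traces, pair residues.

Models are reduced to plain dataclasses so that downstream distance code
never touches the parser. Residue identity is (chain, number, insertion
code); the residue *name* is deliberately ignored when pairing, so that a
register shift (same position, different residue type) still pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyModelError, InputError, PairingError

__all__ = [
    "ResidueKey",
    "Atom",
    "Residue",
    "Model",
    "CATrace",
    "read_model",
    "write_model",
    "extract_ca_trace",
    "match_residues",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain id, sequence number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # compact form used in error messages
        return f"{self.chain_id}{self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Model:
    """All polymer atoms of one coordinate file, in file order."""

    residues: list[Residue]
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CATrace:
    """Ordered CA coordinates of one model, keyed by residue identity."""

    keys: list[ResidueKey]
    coords: np.ndarray  # (L, 3) float64, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"CA coordinates must be (L, 3), got {self.coords.shape}")
        if len(self.keys) != self.coords.shape[0]:
            raise InputError(
                f"key/coordinate length mismatch: {len(self.keys)} keys, "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if len(self.keys) < 1:
            raise InputError("CA trace must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("CA coordinates contain non-finite values")

    def __len__(self) -> int:
        return len(self.keys)


def _select_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to altloc 'A', then first seen."""
    best = atoms[0]
    for atom in atoms[1:]:
        if atom.occ > best.occ + 1e-9:
            best = atom
        elif abs(atom.occ - best.occ) <= 1e-9 and atom.altloc == "A" != best.altloc:
            best = atom
    return best


def read_model(path: str | Path, chains: Iterable[str] | None = None) -> Model:
    """Read all polymer atoms from a PDB (or mmCIF) file.

    Alternate locations are collapsed to the highest-occupancy conformer.
    Waters and hetero compounds without a CA atom are excluded; hetero
    residues embedded in the chain that do carry a CA (e.g. MSE) are kept.
    Hydrogens are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"coordinate file not found: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    structure.remove_hydrogens()
    if len(structure) == 0:
        raise EmptyModelError(f"no coordinate model in {path}")
    wanted = set(chains) if chains is not None else None

    residues: list[Residue] = []
    for chain in structure[0]:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            if res.is_water():
                continue
            is_het = res.het_flag == "H"
            if is_het and res.find_atom("CA", "*") is None:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in by_name:
                a = _select_altloc(by_name[name])
                atoms.append(
                    Atom(
                        name=name,
                        element=a.element.name,
                        pos=(a.pos.x, a.pos.y, a.pos.z),
                        occupancy=a.occ,
                        altloc=a.altloc,
                    )
                )
            key = ResidueKey(chain.name, res.seqid.num, res.seqid.icode.strip())
            residues.append(Residue(key=key, name=res.name, atoms=atoms))
    if not residues:
        raise EmptyModelError(f"empty model: no polymer ATOM records in {path}")
    return Model(residues=residues, source=str(path))


def write_model(model: Model, path: str | Path) -> None:
    """Write a model back to PDB via gemmi (fixed-width, 3-decimal coords)."""
    structure = gemmi.Structure()
    structure.name = Path(path).stem
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        cid = res.key.chain_id
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.key.residue_number, res.key.insertion_code or " ")
        for atom in res.atoms:
            gatom = gemmi.Atom()
            gatom.name = atom.name
            gatom.element = gemmi.Element(atom.element)
            gatom.pos = gemmi.Position(*atom.pos)
            gatom.occ = atom.occupancy
            gres.add_atom(gatom)
        chains[cid].add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


def extract_ca_trace(model: Model, chains: Iterable[str] | None = None) -> CATrace:
    """One entry per residue possessing a CA atom, in model order.

    Residues lacking a CA are skipped; their count is reported in a warning.
    """
    if not model.residues:
        raise EmptyModelError("cannot extract CA trace from an empty model")
    wanted = set(chains) if chains is not None else None
    if wanted is not None:
        present = {r.key.chain_id for r in model.residues}
        if not wanted & present:
            raise InputError(
                f"chain filter {sorted(wanted)} matches no chain; present: {sorted(present)}"
            )
    keys: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    skipped = 0
    for res in model.residues:
        if wanted is not None and res.key.chain_id not in wanted:
            continue
        ca = res.get_atom("CA")
        if ca is None:
            skipped += 1
            continue
        keys.append(res.key)
        coords.append(ca.pos)
    if skipped:
        warnings.warn(f"{skipped} residue(s) lack a CA atom and were skipped", stacklevel=2)
    if not keys:
        raise EmptyModelError("no residue possesses a CA atom")
    return CATrace(keys=keys, coords=np.array(coords, dtype=np.float64))


def match_residues(
    a: CATrace, b: CATrace, mode: str = "strict"
) -> tuple[np.ndarray, np.ndarray]:
    """Pair residues between two traces by residue key.

    strict    — key sets must be identical; returns the full pairing.
    intersect — pairing over shared keys only, preserving a's order.
    """
    if mode not in ("strict", "intersect"):
        raise InputError(f"unknown match mode: {mode!r}")
    if len(a) == 0 or len(b) == 0:
        raise PairingError("cannot match empty traces")
    index_b = {key: i for i, key in enumerate(b.keys)}
    if mode == "strict":
        set_a, set_b = set(a.keys), set(b.keys)
        if set_a != set_b:
            mismatches = sorted(set_a ^ set_b)[:5]
            raise PairingError(
                "strict residue match failed; first mismatched keys: "
                + ", ".join(str(k) for k in mismatches)
            )
        ia = np.arange(len(a), dtype=np.intp)
        ib = np.array([index_b[key] for key in a.keys], dtype=np.intp)
        return ia, ib
    ia_list, ib_list = [], []
    for i, key in enumerate(a.keys):
        j = index_b.get(key)
        if j is not None:
            ia_list.append(i)
            ib_list.append(j)
    if not ia_list:
        raise PairingError("residue key intersection is empty")
    return np.array(ia_list, dtype=np.intp), np.array(ib_list, dtype=np.intp)
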