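"""Lightweight protein-structure container and PDB input/output.

Only what the residue filters need is kept: chains of residues, each
residue holding its heavy-atom coordinates.  Hydrogens, waters and
heteroatoms are dropped on read; for alternate locations the
highest-occupancy conformer is kept; only the first model of a multi-model
entry is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = ["Residue", "Structure", "read_pdb", "write_pdb"]

#: residue identity within a structure: (chain id, residue number, insertion code)
ResidueId = tuple[str, int, str]


@dataclass
class Residue:
    chain: str
    number: int
    icode: str  # insertion code, "" when absent
    name: str  # three-letter, upper case
    atom_names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    elements: list[str] = field(default_factory=list)

    @property
    def id(self) -> ResidueId:
        return (self.chain, self.number, self.icode)

    @property
    def ca(self) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index("CA")]
        except ValueError:
            return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain}:{self.name}{self.number}{self.icode}>"


class Structure:
    """Ordered chains of residues with heavy-atom coordinates."""

    def __init__(self, residues: Iterable[Residue], name: str = ""):
        self.name = name
        self.chains: dict[str, list[Residue]] = {}
        for res in residues:
            self.chains.setdefault(res.chain, []).append(res)
        for chain_id, chain in self.chains.items():
            seen: set[ResidueId] = set()
            for res in chain:
                if res.id in seen:
                    raise ValueError(f"duplicate residue {res.id} in chain {chain_id}")
                seen.add(res.id)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chains: Iterable[str] | None = None) -> list[Residue]:
        ids = list(chains) if chains is not None else self.chain_ids
        out: list[Residue] = []
        for cid in ids:
            if cid not in self.chains:
                raise KeyError(f"no chain {cid!r} in structure {self.name!r}")
            out.extend(self.chains[cid])
        return out

    def subset(self, chains: Iterable[str]) -> "Structure":
        return Structure(self.residues(chains), name=self.name)

    def atom_coords(self, chains: Iterable[str] | None = None) -> np.ndarray:
        residues = self.residues(chains)
        if not residues:
            return np.empty((0, 3))
        return np.vstack([r.coords for r in residues])

    def ca_coords(self, chains: Iterable[str] | None = None) -> np.ndarray:
        cas = [r.ca for r in self.residues(chains) if r.ca is not None]
        return np.vstack(cas) if cas else np.empty((0, 3))

    def sequence(self, chain: str) -> str:
        """One-letter sequence of a chain (X for unknown residue names)."""
        return "".join(
            protein_letters_3to1.get(r.name, "X") for r in self.chains[chain]
        )

    def find(self, chain: str, number: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain, []):
            if res.number == number and res.icode == icode:
                return res
        return None

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path, name: str | None = None) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    ATOM records only; hydrogens/deuteriums dropped; waters and HETATM
    dropped; highest-occupancy alternate location kept.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        entry = parser.get_structure(name or Path(path).stem, str(path))
        models = list(entry)
        if not models:
            raise ValueError(f"no protein residues found in {path}")
        model = models[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip() or res.resname.strip() in _WATER_NAMES:
                continue
            # name -> (occupancy, coord, element); highest occupancy wins
            picked: dict[str, tuple[float, np.ndarray, str]] = {}
            for atom in res.get_unpacked_list():
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                occ = atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                key = atom.get_name()
                if key not in picked or occ > picked[key][0]:
                    picked[key] = (occ, atom.coord.astype(float), element or key[0])
            if not picked:
                continue
            atom_names = list(picked)
            coords = [picked[k][1] for k in atom_names]
            elements = [picked[k][2] for k in atom_names]
            residues.append(
                Residue(
                    chain=chain.id,
                    number=resseq,
                    icode=icode.strip(),
                    name=res.resname.strip().upper(),
                    atom_names=atom_names,
                    coords=np.asarray(coords),
                    elements=elements,
                )
            )
    if not residues:
        raise ValueError(f"no protein residues found in {path}")
    return Structure(residues, name=name or Path(path).stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal, valid PDB file (ATOM records + TER/END)."""
    lines: list[str] = []
    serial = 1
    for chain_id, chain in structure.chains.items():
        for res in chain:
            for atom_name, xyz, element in zip(res.atom_names, res.coords, res.elements):
                name_field = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field:<4s} {res.name:<3s} {chain_id}"
                    f"{res.number:4d}{res.icode or ' '}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain[-1].name:<3s} {chain_id}{chain[-1].number:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
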