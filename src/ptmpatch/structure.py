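"""Core structure model: atoms, residues, chains, models.

Positions are held in nanometres throughout the library; conversion to and
from the ångström scale of PDB files happens only in :mod:`ptmpatch.pdb_io`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

CANONICAL_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


@dataclass
class AtomRecord:
    """One coordinate record (ATOM or HETATM)."""

    record_kind: str  # "ATOM" | "HETATM"
    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    position: np.ndarray  # shape (3,), nm
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")
        if not self.name.strip():
            raise ValueError("atom name must be non-blank")

    def copy(self) -> "AtomRecord":
        new = copy.copy(self)
        new.position = self.position.copy()
        return new


@dataclass
class Residue:
    name: str
    chain_id: str
    res_seq: int
    i_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    non_canonical: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    number: int
    chains: list[Chain] = field(default_factory=list)
    het_records: list[AtomRecord] = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self.residues():
            yield from res.atoms

    def find_residue(self, chain_id: str, res_seq: int, i_code: str = "") -> Residue | None:
        for chain in self.chains:
            if chain.chain_id != chain_id:
                continue
            for res in chain.residues:
                if res.res_seq == res_seq and res.i_code == i_code:
                    return res
        return None


@dataclass
class Structure:
    """Parsed structure plus pass-through metadata.

    ``models[0]`` is always the modification target; extra models are
    retained for bookkeeping but only model 1 is ever written back out.
    """

    models: list[Model] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)
    ter_chain_ids: list[str] = field(default_factory=list)
    multi_model: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def first_model(self) -> Model:
        if not self.models:
            raise ValueError("structure has no models")
        return self.models[0]

    def atom_count(self, include_het: bool = True) -> int:
        n = sum(1 for _ in self.first_model.atoms())
        if include_het:
            n += len(self.first_model.het_records)
        return n

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def positions(self, include_het: bool = False) -> np.ndarray:
        """Stack model-1 ATOM positions into an (N, 3) array, nm."""
        recs = list(self.first_model.atoms())
        if include_het:
            recs += self.first_model.het_records
        return np.array([a.position for a in recs], dtype=float)

    def set_positions(self, pos: np.ndarray, include_het: bool = False) -> None:
        recs = list(self.first_model.atoms())
        if include_het:
            recs += self.first_model.het_records
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (len(recs), 3):
            raise ValueError(f"expected positions of shape ({len(recs)}, 3)")
        for rec, p in zip(recs, pos):
            rec.position = p.copy()
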