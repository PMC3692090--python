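"""Synthetic peptide fixtures built by sequential internal-coordinate
placement, so every pipeline stage is testable without any download.

The backbone N/CA/C triad of each residue is placed from the preceding
residue (or from scratch for the first); all remaining atoms come from the
residue block's zmatrix.  An optional seeded uniform perturbation makes
reproducible "experimental-quality" inputs for minimization tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import renumber_inplace
from .errors import ValidationError
from .geometry import place_atom
from .registry import Registry, default_registry
from .structure import AtomRecord, Chain, Model, Residue, Structure

def make_stiff_chain(n: int = 32, k_stiff: float = 1e8, k_soft: float = 50.0,
                     b0: float = 0.15, stretch: float = 0.6):
    """Deterministic ill-conditioned harmonic chain that steepest descent
    cannot relax below the default force threshold within the step cap.

    Alternating very stiff and soft bonds give the energy surface a huge
    condition number: the stiff bonds cap the stable step size while the
    soft bonds hold residual force.  Returns ``(topology, positions)``.
    """
    from .forcefield import Topology  # local import avoids a cycle

    bonds = np.array([[i, i + 1] for i in range(n - 1)], dtype=int)
    kb = np.array([k_stiff if i % 2 == 0 else k_soft for i in range(n - 1)])
    topo = Topology(
        atom_names=[f"C{i}" for i in range(n)],
        type_labels=["CH2"] * n,
        charges=np.zeros(n),
        masses=np.full(n, 14.027),
        sigmas=np.zeros(n),
        epsilons=np.zeros(n),
        bonds=bonds,
        bond_b0=np.full(n - 1, b0),
        bond_kb=kb,
        angles=np.zeros((0, 3), int),
        angle_theta0=np.zeros(0),
        angle_k=np.zeros(0),
        dihedrals=np.zeros((0, 4), int),
        dihedral_phis=np.zeros(0),
        dihedral_n=np.zeros(0, int),
        dihedral_k=np.zeros(0),
        exclusions={frozenset((int(i), int(j))) for i, j in bonds},
        residue_labels=[(1, "XXX")] * n,
    )
    x = np.zeros((n, 3))
    x[:, 0] = np.arange(n) * b0 * (1.0 + stretch)
    return topo, x


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

CONFORMATIONS = {
    "extended": (-120.0, 120.0),  # phi, psi
    "helical": (-57.0, -47.0),
}


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str | tuple[str, ...]
    conformation: str = "extended"
    perturbation: float = 0.0  # nm, uniform amplitude per coordinate
    seed: int = 0
    chain_id: str = "A"

    def residue_names(self) -> list[str]:
        if isinstance(self.sequence, str):
            names = [ONE_TO_THREE.get(c) for c in self.sequence.upper()]
            if None in names:
                bad = self.sequence[names.index(None)]
                raise ValidationError(f"unknown one-letter residue code {bad!r}")
            return names  # type: ignore[return-value]
        return [n.upper() for n in self.sequence]


def make_peptide(spec: PeptideSpec, registry: Registry | None = None) -> Structure:
    """Build a united-atom peptide structure from a :class:`PeptideSpec`."""
    if registry is None:
        registry = default_registry()
    names = spec.residue_names()
    if not names:
        raise ValidationError("empty sequence")
    if spec.perturbation < 0:
        raise ValidationError("perturbation amplitude must be >= 0")
    if spec.conformation not in CONFORMATIONS:
        raise ValidationError(f"unknown conformation preset {spec.conformation!r}")
    phi, psi = CONFORMATIONS[spec.conformation]
    omega = 180.0
    blocks = registry.residue_blocks
    ff = registry.forcefield

    chain = Chain(chain_id=spec.chain_id)
    prev: dict[str, np.ndarray] | None = None  # previous residue backbone coords

    for seq_i, res_name in enumerate(names, start=1):
        block = blocks.get(res_name)
        if block is None or not block.zmatrix:
            raise ValidationError(
                f"residue {res_name!r} is not supported by the fixture builder"
            )
        coords: dict[str, np.ndarray] = {}
        if prev is None:
            coords["N"] = np.zeros(3)
            coords["CA"] = np.array([0.147, 0.0, 0.0])
            ang = np.deg2rad(180.0 - 109.5)
            coords["C"] = coords["CA"] + 0.153 * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            coords["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                     0.133, 120.0, psi)
            coords["CA"] = place_atom(prev["CA"], prev["C"], coords["N"],
                                      0.147, 120.0, omega)
            coords["C"] = place_atom(prev["C"], coords["N"], coords["CA"],
                                     0.153, 109.5, phi)
        for entry in block.zmatrix:
            name, rb, ra, rd, r, theta, phi_z = entry
            coords[name] = place_atom(coords[rd], coords[ra], coords[rb],
                                      float(r), float(theta), float(phi_z))

        residue = Residue(name=res_name, chain_id=spec.chain_id, res_seq=seq_i)
        for aname, atype, _charge in block.atoms:  # block order = output order
            residue.atoms.append(
                AtomRecord(
                    record_kind="ATOM",
                    serial=0,
                    name=aname,
                    alt_loc="",
                    res_name=res_name,
                    chain_id=spec.chain_id,
                    res_seq=seq_i,
                    i_code="",
                    position=coords[aname],
                    element=ff.element(atype),
                )
            )
        chain.residues.append(residue)
        prev = {k: coords[k] for k in ("N", "CA", "C")}

    structure = Structure(models=[Model(number=1, chains=[chain])])
    renumber_inplace(structure)

    if spec.perturbation > 0:
        rng = np.random.default_rng(spec.seed)
        pos = structure.positions()
        pos += rng.uniform(-spec.perturbation, spec.perturbation, size=pos.shape)
        structure.set_positions(pos)
    return structure
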