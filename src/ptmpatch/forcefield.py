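"""United-atom molecular-mechanics topology and in-vacuo energy/forces.

Functional forms (documented in the packaged parameter table): harmonic
bonds and angles, cosine proper dihedrals, 12-6 Lennard-Jones plus Coulomb
with plain cutoff truncation.  A nonbonded pair contributes iff its
separation is strictly below the cutoff; pairs at graph distance 1 or 2 on
the bond graph are excluded.  Forces are the exact analytic negative
gradient of the energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    IncompleteResidueError,
    SingularityError,
    TopologyError,
    UnknownResidueError,
)
from .registry import Registry
from .structure import Structure

DEFAULT_CUTOFF = 1.4  # nm


@dataclass
class Topology:
    """Bonded terms, nonbonded parameters and exclusions for one structure."""

    atom_names: list[str]
    type_labels: list[str]
    charges: np.ndarray          # (N,)
    masses: np.ndarray           # (N,)
    sigmas: np.ndarray           # (N,)
    epsilons: np.ndarray         # (N,)
    bonds: np.ndarray            # (nb, 2) int
    bond_b0: np.ndarray          # (nb,)
    bond_kb: np.ndarray          # (nb,)
    angles: np.ndarray           # (na, 3) int, centre is column 1
    angle_theta0: np.ndarray     # (na,) radians
    angle_k: np.ndarray          # (na,)
    dihedrals: np.ndarray        # (nd, 4) int
    dihedral_phis: np.ndarray    # (nd,) radians
    dihedral_n: np.ndarray       # (nd,)
    dihedral_k: np.ndarray       # (nd,)
    exclusions: set = field(default_factory=set)  # frozenset pairs {i, j}
    coulomb_constant: float = 138.935458
    residue_labels: list[tuple[int, str]] = field(default_factory=list)  # (res_seq, name) per atom

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def validate(self) -> None:
        n = self.n_atoms
        if n == 0:
            raise TopologyError("empty topology")
        for arr, width in ((self.bonds, 2), (self.angles, 3), (self.dihedrals, 4)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise TopologyError("bonded term references out-of-range atom index")
        if self.bonds.size and np.any(self.bonds[:, 0] == self.bonds[:, 1]):
            raise TopologyError("self-bond in topology")
        if not np.all(self.masses > 0):
            raise TopologyError("non-positive atom mass")


@dataclass
class EnergyForces:
    total: float
    terms: dict
    forces: np.ndarray  # (N, 3), kJ/mol/nm


def build_topology(structure: Structure, registry: Registry,
                   flavour: str = "54a7") -> Topology:
    """Topology for model 1 from the packaged building blocks.

    Both force-field flavours select the same packaged parameter table; the
    flavour string is recorded in output file headers only.
    """
    if flavour not in ("45a3", "54a7"):
        raise TopologyError(f"unknown force-field flavour {flavour!r}")
    ff = registry.forcefield
    blocks = registry.residue_blocks

    if structure.first_model.het_records:
        names = sorted({h.res_name for h in structure.first_model.het_records})
        raise UnknownResidueError(
            f"unparameterized ligand(s) present: {', '.join(names)}"
        )

    atom_names: list[str] = []
    type_labels: list[str] = []
    charges: list[float] = []
    residue_labels: list[tuple[int, str]] = []
    index: dict[tuple[int, str], int] = {}  # (residue object id, atom name) -> global idx
    bonds: list[tuple[int, int]] = []

    for chain in structure.first_model.chains:
        prev_c: int | None = None
        for res in chain.residues:
            block = blocks.get(res.name)
            if block is None:
                raise UnknownResidueError(
                    f"no building block for residue {res.name!r} "
                    f"({res.chain_id}:{res.res_seq})"
                )
            present = set(res.atom_names())
            expected = set(block.atom_names())
            missing = expected - present
            if missing:
                raise IncompleteResidueError(
                    f"residue {res.chain_id}:{res.res_seq} ({res.name}) is missing "
                    f"atom(s): {', '.join(sorted(missing))}"
                )
            extra = present - expected
            if extra:
                raise IncompleteResidueError(
                    f"residue {res.chain_id}:{res.res_seq} ({res.name}) has "
                    f"unexpected atom(s): {', '.join(sorted(extra))}"
                )
            for atom in res.atoms:  # structure order defines global indexing
                index[(id(res), atom.name)] = len(atom_names)
                atom_names.append(atom.name)
                type_labels.append(block.atom_type(atom.name))
                charges.append(block.atom_charge(atom.name))
                residue_labels.append((res.res_seq, res.name))
            for a, b in block.bonds:
                bonds.append((index[(id(res), a)], index[(id(res), b)]))
            if prev_c is not None:
                bonds.append((prev_c, index[(id(res), "N")]))
            prev_c = index[(id(res), "C")]

    n = len(atom_names)
    if n == 0:
        raise TopologyError("structure has no ATOM records")

    masses = np.array([ff.mass(t) for t in type_labels])
    sigmas = np.array([float(ff.types[t]["sigma"]) for t in type_labels])
    epsilons = np.array([float(ff.types[t]["epsilon"]) for t in type_labels])

    bond_idx = np.array(sorted({tuple(sorted(b)) for b in bonds}), dtype=int)
    b0 = np.empty(len(bond_idx))
    for k, (i, j) in enumerate(bond_idx):
        length = ff.bond_length(type_labels[i], type_labels[j])
        if length is None:
            raise TopologyError(
                f"no ideal length for bond type pair "
                f"({type_labels[i]}, {type_labels[j]}) "
                f"[atoms {atom_names[i]}-{atom_names[j]}]"
            )
        b0[k] = length
    bond_kb = np.full(len(bond_idx), ff.kb)

    # adjacency for angles / dihedrals / exclusions
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in bond_idx:
        neighbors[i].append(j)
        neighbors[j].append(i)
    for lst in neighbors:
        lst.sort()

    angles: list[tuple[int, int, int]] = []
    for j in range(n):
        nb = neighbors[j]
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    angle_idx = np.array(angles, dtype=int).reshape(-1, 3)
    theta0 = np.array([
        np.deg2rad(ff.angle_theta0[ff.types[type_labels[j]]["cls"]])
        for _, j, _ in angles
    ])
    angle_k = np.full(len(angles), ff.ktheta)

    dihedrals: list[tuple[int, int, int, int]] = []
    d_params: list[tuple[float, int, float]] = []  # (phi_s rad, n, k)
    for j, k in bond_idx:
        outer_j = [x for x in neighbors[j] if x != k]
        outer_k = [x for x in neighbors[k] if x != j]
        if not outer_j or not outer_k:
            continue
        i, l = outer_j[0], outer_k[0]
        cls_j = ff.types[type_labels[j]]["cls"]
        cls_k = ff.types[type_labels[k]]["cls"]
        if cls_j == "tri" and cls_k == "tri":
            rule = ff.dihedral_rules["conjugated"]
        elif cls_j in ("tet", "bent") and cls_k in ("tet", "bent"):
            rule = ff.dihedral_rules["aliphatic"]
        else:
            rule = ff.dihedral_rules["mixed"]
        dihedrals.append((i, j, k, l))
        d_params.append((np.deg2rad(rule["phi_s"]), int(rule["n"]), float(rule["k"])))
    dihedral_idx = np.array(dihedrals, dtype=int).reshape(-1, 4)

    exclusions: set = set()
    for i, j in bond_idx:
        exclusions.add(frozenset((int(i), int(j))))
    for i, j, k in angles:
        exclusions.add(frozenset((int(i), int(k))))

    topo = Topology(
        atom_names=atom_names,
        type_labels=type_labels,
        charges=np.array(charges),
        masses=masses,
        sigmas=sigmas,
        epsilons=epsilons,
        bonds=bond_idx,
        bond_b0=b0,
        bond_kb=bond_kb,
        angles=angle_idx,
        angle_theta0=theta0,
        angle_k=angle_k,
        dihedrals=dihedral_idx,
        dihedral_phis=np.array([p[0] for p in d_params]),
        dihedral_n=np.array([p[1] for p in d_params], dtype=int),
        dihedral_k=np.array([p[2] for p in d_params]),
        exclusions=exclusions,
        coulomb_constant=ff.coulomb,
        residue_labels=residue_labels,
    )
    topo.validate()
    return topo


def _bond_terms(x: np.ndarray, topo: Topology, forces: np.ndarray) -> float:
    if topo.bonds.size == 0:
        return 0.0
    i, j = topo.bonds[:, 0], topo.bonds[:, 1]
    d = x[j] - x[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-6):
        raise SingularityError("coincident bonded atoms (r < 1e-6 nm)")
    dr = r - topo.bond_b0
    e = 0.5 * topo.bond_kb * dr**2
    # F_i = kb (r - b0) * u_ij (pulls i towards j when stretched)
    fmag = (topo.bond_kb * dr / r)[:, None] * d
    np.add.at(forces, i, fmag)
    np.add.at(forces, j, -fmag)
    return float(e.sum())


def _angle_terms(x: np.ndarray, topo: Topology, forces: np.ndarray) -> float:
    if topo.angles.size == 0:
        return 0.0
    i, j, k = topo.angles[:, 0], topo.angles[:, 1], topo.angles[:, 2]
    rij = x[i] - x[j]
    rkj = x[k] - x[j]
    nij = np.linalg.norm(rij, axis=1)
    nkj = np.linalg.norm(rkj, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", rij, rkj) / (nij * nkj), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    dt = theta - topo.angle_theta0
    e = 0.5 * topo.angle_k * dt**2
    # dtheta/dri = (cos_t * uij - ukj) / (nij * sin_t); F = -k dt * dtheta/dx
    uij = rij / nij[:, None]
    ukj = rkj / nkj[:, None]
    coef = (-topo.angle_k * dt / sin_t)
    fi = coef[:, None] * (cos_t[:, None] * uij - ukj) / nij[:, None]
    fk = coef[:, None] * (cos_t[:, None] * ukj - uij) / nkj[:, None]
    np.add.at(forces, i, fi)
    np.add.at(forces, k, fk)
    np.add.at(forces, j, -(fi + fk))
    return float(e.sum())


def _dihedral_terms(x: np.ndarray, topo: Topology, forces: np.ndarray) -> float:
    if topo.dihedrals.size == 0:
        return 0.0
    i, j, k, l = (topo.dihedrals[:, c] for c in range(4))
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    sn1 = np.einsum("ij,ij->i", n1, n1)
    sn2 = np.einsum("ij,ij->i", n2, n2)
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(nb2, 1e-12),
        np.einsum("ij,ij->i", n1, n2),
    )
    mult = topo.dihedral_n
    e = topo.dihedral_k * (1.0 + np.cos(mult * phi - topo.dihedral_phis))
    dV = -topo.dihedral_k * mult * np.sin(mult * phi - topo.dihedral_phis)
    # standard analytic dihedral gradient (Blondel & Karplus form)
    dpi = (-nb2 / np.maximum(sn1, 1e-12))[:, None] * n1
    dpl = (nb2 / np.maximum(sn2, 1e-12))[:, None] * n2
    tj = (np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2**2, 1e-12))[:, None]
    tk = (np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2**2, 1e-12))[:, None]
    dpj = -(1.0 + tj) * dpi + tk * dpl
    dpk = tj * dpi - (1.0 + tk) * dpl
    np.add.at(forces, i, -dV[:, None] * dpi)
    np.add.at(forces, j, -dV[:, None] * dpj)
    np.add.at(forces, k, -dV[:, None] * dpk)
    np.add.at(forces, l, -dV[:, None] * dpl)
    return float(e.sum())


def _nonbonded_terms(x: np.ndarray, topo: Topology, cutoff: float,
                     forces: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if n < 2:
        return 0.0, 0.0
    iu, ju = np.triu_indices(n, k=1)
    if topo.exclusions:
        keep = np.array([
            frozenset((int(a), int(b))) not in topo.exclusions
            for a, b in zip(iu, ju)
        ])
        iu, ju = iu[keep], ju[keep]
    if iu.size == 0:
        return 0.0, 0.0
    d = x[ju] - x[iu]
    r = np.linalg.norm(d, axis=1)
    within = r < cutoff  # a pair contributes iff r < cutoff
    iu, ju, d, r = iu[within], ju[within], d[within], r[within]
    if iu.size == 0:
        return 0.0, 0.0
    if np.any(r < 1e-6):
        raise SingularityError("coincident nonbonded atoms (r < 1e-6 nm)")
    sig = 0.5 * (topo.sigmas[iu] + topo.sigmas[ju])
    eps = np.sqrt(topo.epsilons[iu] * topo.epsilons[ju])
    sr6 = (sig / r) ** 6
    src6 = (sig / cutoff) ** 6
    # potentials shifted to vanish continuously at the cutoff (forces are
    # unaffected); keeps the energy surface continuous for the minimizer
    e_lj = 4.0 * eps * ((sr6**2 - sr6) - (src6**2 - src6))
    qq = topo.coulomb_constant * topo.charges[iu] * topo.charges[ju]
    e_coul = qq * (1.0 / r - 1.0 / cutoff)
    # dE/dr terms
    dlj = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
    dcoul = -qq / r**2
    fmag = (-(dlj + dcoul) / r)[:, None] * d  # force on j along +d
    np.add.at(forces, ju, fmag)
    np.add.at(forces, iu, -fmag)
    return float(e_lj.sum()), float(e_coul.sum())


def energy_forces(positions: np.ndarray, topology: Topology,
                  cutoff: float = DEFAULT_CUTOFF) -> EnergyForces:
    """Total energy (kJ/mol) with per-term breakdown and analytic forces."""
    x = np.asarray(positions, dtype=float)
    if x.shape != (topology.n_atoms, 3):
        raise ValueError(f"positions must have shape ({topology.n_atoms}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite positions")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    forces = np.zeros_like(x)
    e_bond = _bond_terms(x, topology, forces)
    e_angle = _angle_terms(x, topology, forces)
    e_dih = _dihedral_terms(x, topology, forces)
    e_lj, e_coul = _nonbonded_terms(x, topology, cutoff, forces)
    terms = {
        "bond": e_bond,
        "angle": e_angle,
        "dihedral": e_dih,
        "lj": e_lj,
        "coulomb": e_coul,
    }
    return EnergyForces(total=float(sum(terms.values())), terms=terms, forces=forces)
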