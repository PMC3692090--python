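"""GROMACS-dialect writers: fixed-column .gro and directive-style .top.

One modern (>= 4.5.x) dialect is emitted.  Velocities are omitted and a
zero rectangular box is written, matching the in-vacuo semantics of the
minimization protocol.
"""

from __future__ import annotations

import numpy as np

from .errors import TopologyError
from .forcefield import Topology
from .structure import Structure

TOOL_VERSION = "ptmpatch 0.1.0"


def write_gro(structure: Structure, title: str = "modified protein") -> str:
    """Serialize model 1 in .gro fixed format (nm, 3 decimals, zero box)."""
    model = structure.first_model
    records = []
    for res in model.residues():
        for atom in res.atoms:
            records.append((res.res_seq, res.name, atom.name, atom.position))
    for het in model.het_records:
        records.append((het.res_seq, het.res_name, het.name, het.position))
    if not records:
        raise TopologyError("structure has no atoms")
    lines = [title.replace("\n", " "), f"{len(records):5d}"]
    for serial, (res_seq, res_name, atom_name, pos) in enumerate(records, start=1):
        if not np.all(np.isfinite(pos)):
            raise TopologyError(f"non-finite coordinates for atom {atom_name!r}")
        x, y, z = pos
        lines.append(
            f"{res_seq % 100000:5d}{res_name:<5s}{atom_name:>5s}"
            f"{serial % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    lines.append(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}")
    return "\n".join(lines) + "\n"


def write_top(topology: Topology, flavour: str = "54a7",
              title: str = "modified protein") -> str:
    """Serialize a topology in GROMACS .top directive syntax (standalone)."""
    topology.validate()
    lines = [
        f"; {title}",
        f"; generated by {TOOL_VERSION}; force-field flavour: {flavour}",
        "; single packaged united-atom parameter set (see data/forcefield.yaml)",
        "",
        "[ defaults ]",
        "; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ",
        "  1       2          no         1.0      1.0",
        "",
        "[ atomtypes ]",
        "; name  mass      charge  ptype  sigma    epsilon",
    ]
    seen = set()
    for t, m, s, e in zip(topology.type_labels, topology.masses,
                          topology.sigmas, topology.epsilons):
        if t in seen:
            continue
        seen.add(t)
        lines.append(f"  {t:<5s} {m:9.4f}  0.000   A      {s:.4f}   {e:.4f}")
    lines += [
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        "  protein  2",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for idx in range(topology.n_atoms):
        res_seq, res_name = topology.residue_labels[idx]
        lines.append(
            f"{idx + 1:5d}  {topology.type_labels[idx]:<5s}{res_seq:5d}  "
            f"{res_name:<5s}{topology.atom_names[idx]:<5s}{idx + 1:5d}"
            f"{topology.charges[idx]:9.3f}{topology.masses[idx]:10.4f}"
        )
    lines += ["", "[ bonds ]", ";  i    j  funct  b0       kb"]
    for (i, j), b0, kb in zip(topology.bonds, topology.bond_b0, topology.bond_kb):
        lines.append(f"{i + 1:5d}{j + 1:5d}  1  {b0:8.4f} {kb:11.1f}")
    lines += ["", "[ pairs ]", "; none: 1-4 pairs interact at full nonbonded strength"]
    lines += ["", "[ angles ]", ";  i    j    k  funct  theta0   ktheta"]
    for (i, j, k), t0, kt in zip(topology.angles, topology.angle_theta0,
                                 topology.angle_k):
        lines.append(
            f"{i + 1:5d}{j + 1:5d}{k + 1:5d}  1  {np.degrees(t0):8.2f} {kt:9.2f}"
        )
    lines += ["", "[ dihedrals ]", ";  i    j    k    l  funct  phi_s  k  mult"]
    for (i, j, k, l), ps, kd, n in zip(topology.dihedrals, topology.dihedral_phis,
                                       topology.dihedral_k, topology.dihedral_n):
        lines.append(
            f"{i + 1:5d}{j + 1:5d}{k + 1:5d}{l + 1:5d}  1  "
            f"{np.degrees(ps):7.1f} {kd:7.2f} {n:3d}"
        )
    lines += ["", "[ exclusions ]"]
    by_atom: dict[int, list[int]] = {}
    for pair in sorted(tuple(sorted(p)) for p in topology.exclusions):
        by_atom.setdefault(pair[0], []).append(pair[1])
    for i in sorted(by_atom):
        partners = " ".join(str(j + 1) for j in sorted(by_atom[i]))
        lines.append(f"{i + 1:5d} {partners}")
    lines += [
        "",
        "[ system ]",
        title,
        "",
        "[ molecules ]",
        "protein 1",
    ]
    return "\n".join(lines) + "\n"
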