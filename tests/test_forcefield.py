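from collections import deque

import numpy as np
import pytest

from ptmpatch import (
    PeptideSpec,
    apply_all,
    build_topology,
    energy_forces,
    make_peptide,
    parse_selection,
)
from ptmpatch.errors import (
    IncompleteResidueError,
    SingularityError,
    TopologyError,
    UnknownResidueError,
)
from ptmpatch.forcefield import Topology
from ptmpatch.structure import AtomRecord


def two_atom_bond(kb=1000.0, b0=0.15, charges=(0.0, 0.0), sig=0.0, eps=0.0):
    n = 2
    return Topology(
        atom_names=["A1", "A2"], type_labels=["CH2", "CH2"],
        charges=np.array(charges), masses=np.full(n, 14.0),
        sigmas=np.full(n, sig), epsilons=np.full(n, eps),
        bonds=np.array([[0, 1]]), bond_b0=np.array([b0]),
        bond_kb=np.array([kb]),
        angles=np.zeros((0, 3), int), angle_theta0=np.zeros(0),
        angle_k=np.zeros(0),
        dihedrals=np.zeros((0, 4), int), dihedral_phis=np.zeros(0),
        dihedral_n=np.zeros(0, int), dihedral_k=np.zeros(0),
        exclusions={frozenset((0, 1))},
        residue_labels=[(1, "XXX")] * n,
    )


def free_pair(charges=(0.3, -0.2), sig=0.3, eps=0.4):
    topo = two_atom_bond(charges=charges, sig=sig, eps=eps)
    topo.bonds = np.zeros((0, 2), int)
    topo.bond_b0 = np.zeros(0)
    topo.bond_kb = np.zeros(0)
    topo.exclusions = set()
    return topo


class TestBuildTopology:
    def test_single_residue_valid(self, registry):
        s = make_peptide(PeptideSpec("A"), registry)
        topo = build_topology(s, registry)
        topo.validate()
        assert topo.n_atoms == 6
        assert len(topo.bonds) == 5

    def test_tripeptide_peptide_bonds_generated(self, registry, ala_ser_ala):
        topo = build_topology(ala_ser_ala, registry)
        # 5 + 7 + 5 intra bonds + 2 peptide bonds
        assert len(topo.bonds) == 19

    def test_exclusions_equal_bruteforce_graph_distance(self, registry,
                                                        ala_ser_ala):
        topo = build_topology(ala_ser_ala, registry)
        adj = {i: set() for i in range(topo.n_atoms)}
        for i, j in topo.bonds:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        expected = set()
        for start in range(topo.n_atoms):
            seen = {start: 0}
            q = deque([start])
            while q:
                u = q.popleft()
                if seen[u] == 2:
                    continue
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        q.append(v)
            for v, d in seen.items():
                if v != start and d <= 2:
                    expected.add(frozenset((start, v)))
        assert topo.exclusions == expected

    def test_unknown_residue_raises(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        s.first_model.find_residue("A", 2).name = "XYZ"
        with pytest.raises(UnknownResidueError):
            build_topology(s, registry)

    def test_ligand_raises_unknown_residue(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        s.first_model.het_records.append(
            AtomRecord("HETATM", 1, "C1", "", "LIG", "A", 99, "",
                       np.zeros(3), element="C"))
        with pytest.raises(UnknownResidueError, match="ligand"):
            build_topology(s, registry)

    def test_missing_backbone_atom_raises(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        res = s.first_model.find_residue("A", 1)
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(IncompleteResidueError, match="CA"):
            build_topology(s, registry)

    def test_modified_residue_has_building_block(self, registry, ala_ser_ala):
        mod, _ = apply_all(ala_ser_ala,
                           [parse_selection("A:2:phosphorylation")], registry)
        topo = build_topology(mod, registry)
        assert "P" in topo.atom_names

    def test_bad_flavour_rejected(self, registry, ala_ser_ala):
        with pytest.raises(TopologyError):
            build_topology(ala_ser_ala, registry, flavour="99x9")


class TestEnergyForces:
    def test_harmonic_bond_closed_form(self):
        topo = two_atom_bond(kb=1000.0, b0=0.15)
        x = np.array([[0.0, 0, 0], [0.16, 0, 0]])
        ef = energy_forces(x, topo)
        assert abs(ef.total - 0.05) < 1e-12
        f = np.linalg.norm(ef.forces, axis=1)
        assert np.allclose(f, [10.0, 10.0])
        assert np.allclose(ef.forces[0], -ef.forces[1])
        # stretched bond pulls the atoms together
        assert ef.forces[0][0] > 0 and ef.forces[1][0] < 0

    def test_pair_beyond_cutoff_contributes_zero(self):
        topo = free_pair()
        x = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        ef = energy_forces(x, topo, cutoff=1.4)
        assert ef.terms["lj"] == 0.0
        assert ef.terms["coulomb"] == 0.0
        assert np.all(ef.forces == 0.0)

    def test_pair_within_cutoff_contributes(self):
        topo = free_pair()
        ef = energy_forces(np.array([[0.0, 0, 0], [1.0, 0, 0]]), topo)
        assert ef.terms["coulomb"] != 0.0

    def test_forces_match_finite_differences_on_random_configs(self, registry):
        s = make_peptide(PeptideSpec("ASA"), registry)
        topo = build_topology(s, registry)
        x0 = s.positions()
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(50):
            x = x0 + rng.uniform(-0.02, 0.02, size=x0.shape)
            ef = energy_forces(x, topo)
            # probe a handful of random components per configuration
            for _ in range(6):
                i = int(rng.integers(len(x)))
                d = int(rng.integers(3))
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                fd = -(energy_forces(xp, topo).total
                       - energy_forces(xm, topo).total) / (2 * h)
                denom = max(1.0, abs(fd))
                assert abs(fd - ef.forces[i, d]) / denom < 1e-4

    def test_translational_invariance(self, registry, ala_ser_ala):
        topo = build_topology(ala_ser_ala, registry)
        x = ala_ser_ala.positions()
        e1 = energy_forces(x, topo).total
        e2 = energy_forces(x + np.array([1.3, -0.7, 2.9]), topo).total
        assert abs(e1 - e2) < 1e-10 * max(1.0, abs(e1))

    def test_net_force_zero(self, registry, perturbed_tripeptide):
        topo = build_topology(perturbed_tripeptide, registry)
        ef = energy_forces(perturbed_tripeptide.positions(), topo)
        assert np.all(np.abs(ef.forces.sum(axis=0)) < 1e-8)

    def test_energy_decomposition_sums_to_total(self, registry,
                                                perturbed_tripeptide):
        topo = build_topology(perturbed_tripeptide, registry)
        ef = energy_forces(perturbed_tripeptide.positions(), topo)
        assert abs(sum(ef.terms.values()) - ef.total) < 1e-10

    def test_coincident_bonded_atoms_raise(self):
        topo = two_atom_bond()
        with pytest.raises(SingularityError):
            energy_forces(np.zeros((2, 3)), topo)

    def test_atom_order_permutation_preserves_energy(self, registry):
        s = make_peptide(PeptideSpec("AA"), registry)
        topo = build_topology(s, registry)
        x = s.positions()
        e1 = energy_forces(x, topo).total
        perm = np.random.default_rng(5).permutation(topo.n_atoms)
        inv = np.argsort(perm)
        topo2 = Topology(
            atom_names=[topo.atom_names[i] for i in perm],
            type_labels=[topo.type_labels[i] for i in perm],
            charges=topo.charges[perm], masses=topo.masses[perm],
            sigmas=topo.sigmas[perm], epsilons=topo.epsilons[perm],
            bonds=inv[topo.bonds], bond_b0=topo.bond_b0, bond_kb=topo.bond_kb,
            angles=inv[topo.angles], angle_theta0=topo.angle_theta0,
            angle_k=topo.angle_k, dihedrals=inv[topo.dihedrals],
            dihedral_phis=topo.dihedral_phis, dihedral_n=topo.dihedral_n,
            dihedral_k=topo.dihedral_k,
            exclusions={frozenset(int(inv[i]) for i in pair)
                        for pair in topo.exclusions},
            residue_labels=[topo.residue_labels[i] for i in perm],
        )
        e2 = energy_forces(x[perm], topo2).total
        assert abs(e1 - e2) < 1e-9 * max(1.0, abs(e1))

    def test_empty_topology_invalid(self):
        topo = two_atom_bond()
        topo.atom_names = []
        topo.type_labels = []
        with pytest.raises(TopologyError):
            topo.validate()
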