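# ptmpatch

Introduce post-translational modifications (PTMs) into protein PDB
structures, optionally energy-minimize the result in vacuo, and export
GROMACS-format structure/topology files — as a standalone library and CLI.

Given a structure and a set of (chain, residue, reaction) selections,
ptmpatch deletes the atoms a modification removes, renames the ones it
relabels, places new atoms from internal-coordinate templates
(bond / angle / dihedral against three reference atoms), renames the
residue to its 3-letter product code, renumbers everything, and emits:

1. a three-letter-code sequence of the modified protein (`.seq.txt`),
2. a modified PDB file (modified residues as `ATOM` records, original
   `HETATM` entries retained and renumbered) (`.pdb`),
3. GROMACS structure and topology files (`.gro`, `.top`) plus a settings
   echo (`.mdp`) — only when minimization/topology building succeeds,
4. a run log with the modification entries, eligibility report and
   minimization trace (`.log`).

Minimization is adaptive steepest descent with the protocol constants:
at most **1500 steps**, maximum per-atom force threshold
**1.0 kJ/mol/nm**, nonbonded cutoff **1.4 nm**, in vacuo. An eligibility
pre-check (unknown residues/ligands, missing atoms, formatting problems)
deactivates minimization without blocking the modified PDB output.

The packaged reaction registry has two layers: a names layer (the
catalogue) and an executable layer (entries with geometric templates),
covering phosphorylation (S/T/Y), acetylation (K, N-terminal),
mono/di/tri-methylation (K), methylation (R), hydroxylation (P),
carboxylation (E), nitration (Y), carbonylation (K/R/P/T), deamidation
(N/Q) and its reverse, and oxidation (M/C), plus chained entries
(e.g. successive lysine methylations). Force-field parameters are a
single documented placeholder set in GROMOS-like united-atom style;
parameter fidelity is a non-goal, gradient correctness is the tested
contract.

## CLI

```bash
# list available reactions
ptmpatch list --residue LYS

# modify + minimize (defaults), writing out.pdb/.seq.txt/.gro/.top/.mdp/.log
ptmpatch modify --input protein.pdb \
    --mod A:58:phosphorylation --mod A:12:carbonylation \
    --out-prefix out

# modification only (no GROMACS files)
ptmpatch modify --input protein.pdb --mod A:58:phosphorylation \
    --no-minimize --out-prefix out

# network access is opt-in; offline is the default
ptmpatch fetch 1N5U --out 1n5u.pdb
```

Selection syntax is `CHAIN:RESSEQ[ICODE]:REACTION_ID`. Multi-model (NMR)
inputs are legal: only the first model is modified and written, and the
log says so. Non-canonical residues are rendered as `!` in the sequence
and cannot be modified.

## Library

```python
import ptmpatch as p

reg = p.default_registry()
s = p.parse_pdb(open("protein.pdb").read())
mod, log = p.apply_all(s, [p.parse_selection("A:58:phosphorylation")], reg)
topo = p.build_topology(mod, reg)
result = p.steepest_descent(mod.positions(), topo)
mod.set_positions(result.positions)
open("out.pdb", "w").write(p.write_pdb(mod))
```

Synthetic peptide fixtures (`p.make_peptide(p.PeptideSpec("ASA",
perturbation=0.02, seed=42))`) make the whole pipeline testable offline.

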