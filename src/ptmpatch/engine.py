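"""Modification engine: apply plans to structures.

Edits are transactional: ``apply_all`` works on a private copy and either
returns a fully modified structure or raises without observable side
effects on the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    DuplicateSelectionError,
    NonCanonicalResidueError,
    SelectionError,
    StructuralIncompletenessError,
    ValidationError,
)
from .geometry import place_from_ic
from .registry import ModificationPlan, Registry
from .structure import AtomRecord, Residue, Structure


@dataclass(frozen=True)
class SelectionSpec:
    chain_id: str
    res_seq: int
    i_code: str = ""
    reaction_id: str = ""

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.res_seq}{self.i_code}:{self.reaction_id}"


def parse_selection(token: str) -> SelectionSpec:
    """Parse CHAIN:RESSEQ[ICODE]:REACTION_ID (e.g. ``A:58:phosphorylation``)."""
    parts = token.split(":")
    if len(parts) != 3:
        raise ValidationError(
            f"bad selection {token!r}: expected CHAIN:RESSEQ[ICODE]:REACTION_ID"
        )
    chain_id, seq_part, reaction_id = parts
    if len(chain_id) != 1:
        raise ValidationError(f"bad selection {token!r}: chain id must be one character")
    if not reaction_id:
        raise ValidationError(f"bad selection {token!r}: empty reaction id")
    i_code = ""
    if seq_part and seq_part[-1].isalpha():
        seq_part, i_code = seq_part[:-1], seq_part[-1]
    try:
        res_seq = int(seq_part)
    except ValueError:
        raise ValidationError(
            f"bad selection {token!r}: residue number {seq_part!r} is not an integer"
        ) from None
    return SelectionSpec(chain_id=chain_id, res_seq=res_seq,
                         i_code=i_code, reaction_id=reaction_id)


@dataclass
class LogEntry:
    site: str
    reaction_id: str
    product_code: str
    deleted: list[str]
    renamed: list[tuple[str, str]]
    added: list[str]


@dataclass
class ModificationLog:
    entries: list[LogEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _resolve_residue(structure: Structure, site: SelectionSpec) -> Residue:
    res = structure.first_model.find_residue(site.chain_id, site.res_seq, site.i_code)
    if res is None:
        raise SelectionError(
            f"no residue {site.chain_id}:{site.res_seq}{site.i_code} in model 1"
        )
    return res


def _apply_plan_inplace(structure: Structure, residue: Residue,
                        plan: ModificationPlan, registry: Registry) -> LogEntry:
    if residue.name != plan.target:
        raise SelectionError(
            f"residue {residue.chain_id}:{residue.res_seq} is {residue.name}, "
            f"plan targets {plan.target}"
        )
    if plan.terminus == "N":
        chain = next(c for c in structure.first_model.chains
                     if c.chain_id == residue.chain_id)
        if chain.residues[0] is not residue:
            raise SelectionError(
                f"reaction {plan.reaction_id!r} targets the N-terminus but "
                f"{residue.chain_id}:{residue.res_seq} is not the first residue"
            )

    for name in plan.deletions:
        atom = residue.atom(name)
        if atom is None:
            raise StructuralIncompletenessError(
                f"cannot delete atom {name!r}: missing from residue "
                f"{residue.chain_id}:{residue.res_seq} ({residue.name})"
            )
        residue.atoms.remove(atom)
    for old, new in plan.renames:
        atom = residue.atom(old)
        if atom is None:
            raise StructuralIncompletenessError(
                f"cannot rename atom {old!r}: missing from residue "
                f"{residue.chain_id}:{residue.res_seq} ({residue.name})"
            )
        atom.name = new

    ff = registry.forcefield
    for add in plan.additions:
        refs = []
        for ref_name in (add.ic.ref_dihedral, add.ic.ref_angle, add.ic.ref_bond):
            ref = residue.atom(ref_name)
            if ref is None:
                raise StructuralIncompletenessError(
                    f"placement of {add.name!r} needs reference atom {ref_name!r}, "
                    f"missing from residue {residue.chain_id}:{residue.res_seq}"
                )
            refs.append(ref.position)
        pos = place_from_ic(refs[0], refs[1], refs[2], add.ic)
        residue.atoms.append(
            AtomRecord(
                record_kind="ATOM",
                serial=0,
                name=add.name,
                alt_loc="",
                res_name=plan.product_code,
                chain_id=residue.chain_id,
                res_seq=residue.res_seq,
                i_code=residue.i_code,
                position=pos,
                occupancy=1.0,
                b_factor=0.0,
                element=ff.element(add.type_label),
            )
        )

    residue.name = plan.product_code
    residue.non_canonical = False
    for atom in residue.atoms:
        atom.res_name = plan.product_code
        atom.record_kind = "ATOM"
    return LogEntry(
        site=f"{residue.chain_id}:{residue.res_seq}{residue.i_code}",
        reaction_id=plan.reaction_id,
        product_code=plan.product_code,
        deleted=list(plan.deletions),
        renamed=list(plan.renames),
        added=[a.name for a in plan.additions],
    )


def apply_modification(structure: Structure, site: SelectionSpec,
                       plan: ModificationPlan, registry: Registry | None = None) -> Structure:
    """Apply a single plan; returns a new structure, input untouched."""
    if registry is None:
        from .registry import default_registry

        registry = default_registry()
    out = structure.copy()
    residue = _resolve_residue(out, site)
    if residue.non_canonical and residue.name != plan.target:
        raise NonCanonicalResidueError(
            f"residue {residue.name!r} at {site.chain_id}:{site.res_seq} is "
            "non-canonical and cannot be modified"
        )
    _apply_plan_inplace(out, residue, plan, registry)
    return out


def apply_all(structure: Structure, selections: list[SelectionSpec],
              registry: Registry) -> tuple[Structure, ModificationLog]:
    """Apply selections in input order, renumber once, return structure + log.

    Transactional: any failure raises before anything observable changes.
    """
    sites = [s.site for s in selections]
    for i, site in enumerate(sites):
        if site in sites[:i]:
            raise DuplicateSelectionError(
                f"duplicate selection for residue {site[0]}:{site[1]}{site[2]}"
            )
    out = structure.copy()
    log = ModificationLog(warnings=list(structure.warnings))
    for sel in selections:
        residue = _resolve_residue(out, sel)
        if residue.non_canonical:
            raise NonCanonicalResidueError(
                f"residue {residue.name!r} at {sel.chain_id}:{sel.res_seq} is "
                "non-canonical and cannot be modified"
            )
        plan = registry.lookup_reaction(residue.name, sel.reaction_id)
        entry = _apply_plan_inplace(out, residue, plan, registry)
        log.entries.append(entry)
    if selections:
        renumber_inplace(out)
    return out, log


def renumber_inplace(structure: Structure) -> None:
    """Serials 1..N over model-1 ATOM records (TER consumes a serial per
    chain), HETATM records continuing the sequence.  Idempotent."""
    serial = 0
    model = structure.first_model
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                atom.serial = serial
        if chain.residues:
            serial += 1  # TER record
    for het in model.het_records:
        serial += 1
        het.serial = serial


def renumber_structure(structure: Structure) -> Structure:
    out = structure.copy()
    renumber_inplace(out)
    return out


def render_sequence(structure: Structure) -> str:
    """Three-letter sequence of model 1, one line per chain; non-canonical
    unmodifiable residues are shown as '!'."""
    lines = []
    for chain in structure.first_model.chains:
        tokens = ["!" if r.non_canonical else r.name for r in chain.residues]
        cid = chain.chain_id if chain.chain_id.strip() else "_"
        lines.append(f"{cid}: " + " ".join(tokens))
    return "\n".join(lines) + "\n"
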