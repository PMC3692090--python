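"""PTM reaction catalogue: load, validate, and resolve modification plans.

The registry ships in two layers: a names layer (the full catalogue as
transcribed) and an executable layer (entries with a geometric template).
All invariants -- template/parent/product consistency, product code length,
entry uniqueness -- are checked at load time, so a successfully loaded
registry is guaranteed internally consistent.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import (
    NotExecutableError,
    ReactionNotFoundError,
    RegistryLoadError,
    TargetMismatchError,
)
from .geometry import InternalCoordinate
from .structure import CANONICAL_RESIDUES

_DATA_PACKAGE = "ptmpatch.data"


@dataclass(frozen=True)
class ReactionDef:
    reaction_id: str
    target: str                # residue (or product) 3-letter code
    terminus: str              # "-" | "N" | "C"
    product_code: str
    description: str
    template_id: str | None    # None for names-layer-only entries

    @property
    def executable(self) -> bool:
        return self.template_id is not None


@dataclass(frozen=True)
class AtomAddition:
    name: str
    ic: InternalCoordinate
    type_label: str
    charge: float
    mass: float


@dataclass(frozen=True)
class ModificationPlan:
    reaction_id: str
    target: str
    terminus: str
    product_code: str
    deletions: tuple[str, ...]
    renames: tuple[tuple[str, str], ...]
    additions: tuple[AtomAddition, ...]
    atom_params: dict  # product atom name -> (type_label, charge, mass)


@dataclass
class ResidueBlock:
    """Building block: atom parameters, intra-residue bonds, fixture zmatrix."""

    name: str
    atoms: list[tuple[str, str, float]]          # (name, type, charge)
    bonds: list[tuple[str, str]]
    zmatrix: list[tuple] = field(default_factory=list)

    def atom_names(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def atom_type(self, name: str) -> str:
        for aname, atype, _ in self.atoms:
            if aname == name:
                return atype
        raise KeyError(name)

    def atom_charge(self, name: str) -> float:
        for aname, _, q in self.atoms:
            if aname == name:
                return q
        raise KeyError(name)


class ForceFieldTable:
    """Parsed force-field parameter table (single packaged set)."""

    def __init__(self, raw: dict):
        self.types: dict[str, dict] = raw["types"]
        self.kb: float = raw["constants"]["kb"]
        self.ktheta: float = raw["constants"]["ktheta"]
        self.coulomb: float = raw["constants"]["coulomb"]
        self.charge_scale: float = float(raw["constants"].get("charge_scale", 1.0))
        self.default_cutoff: float = raw["constants"]["default_cutoff"]
        self.angle_theta0: dict[str, float] = raw["angle_theta0"]
        self.dihedral_rules: dict[str, dict] = raw["dihedral_rules"]
        self.bond_lengths: dict[frozenset, float] = {}
        for t1, t2, b0 in raw["bond_lengths"]:
            self.bond_lengths[frozenset((t1, t2))] = float(b0)

    def mass(self, type_label: str) -> float:
        return float(self.types[type_label]["mass"])

    def element(self, type_label: str) -> str:
        return self.types[type_label]["element"]

    def bond_length(self, t1: str, t2: str) -> float | None:
        return self.bond_lengths.get(frozenset((t1, t2)))


class Registry:
    def __init__(
        self,
        reactions: list[ReactionDef],
        templates: dict[str, dict],
        blocks: dict[str, ResidueBlock],
        forcefield: ForceFieldTable,
    ):
        self.reactions = reactions
        self._templates = templates
        self.residue_blocks = blocks
        self.forcefield = forcefield
        self._validate()

    # -- counts ----------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_products(self) -> int:
        return len({r.product_code for r in self.reactions})

    @property
    def n_targets(self) -> int:
        return len({r.target for r in self.reactions})

    # -- derived sets ----------------------------------------------------

    def product_codes(self) -> frozenset[str]:
        return frozenset(r.product_code for r in self.reactions)

    def known_residues(self) -> frozenset[str]:
        """Canonical 20 plus every registry product code."""
        return CANONICAL_RESIDUES | self.product_codes()

    # -- lookup ----------------------------------------------------------

    def lookup_reaction(self, residue: str, reaction_id: str) -> ModificationPlan:
        residue = residue.upper()
        matching = [r for r in self.reactions if r.reaction_id == reaction_id]
        if not matching:
            all_ids = sorted({r.reaction_id for r in self.reactions})
            near = tuple(difflib.get_close_matches(reaction_id, all_ids, n=3))
            raise ReactionNotFoundError(
                f"unknown reaction {reaction_id!r}", suggestions=near
            )
        for r in matching:
            if r.target == residue:
                if not r.executable:
                    raise NotExecutableError(
                        f"reaction {reaction_id!r} on {residue} is catalogued "
                        "name-only; no geometric template is packaged"
                    )
                return self._build_plan(r)
        targets = ", ".join(sorted({r.target for r in matching}))
        raise TargetMismatchError(
            f"reaction {reaction_id!r} is not defined for residue {residue}"
            f" (defined for: {targets})"
        )

    def list_reactions(self, residue: str = "all") -> list[ReactionDef]:
        if residue.lower() == "all":
            result = list(self.reactions)
        else:
            residue = residue.upper()
            if residue not in {r.target for r in self.reactions}:
                raise ReactionNotFoundError(
                    f"no reactions catalogued for residue {residue!r}"
                )
            result = [r for r in self.reactions if r.target == residue]
        return sorted(result, key=lambda r: (r.reaction_id, r.target))

    # -- internals -------------------------------------------------------

    def _build_plan(self, rdef: ReactionDef) -> ModificationPlan:
        tpl = self._templates[rdef.template_id]
        product_block = self.residue_blocks[rdef.product_code]
        ff = self.forcefield
        additions = []
        for name, rb, ra, rd, r, theta, phi in tpl["additions"]:
            type_label = product_block.atom_type(name)
            additions.append(
                AtomAddition(
                    name=name,
                    ic=InternalCoordinate(rb, ra, rd, float(r), float(theta), float(phi)),
                    type_label=type_label,
                    charge=product_block.atom_charge(name),
                    mass=ff.mass(type_label),
                )
            )
        atom_params = {
            aname: (atype, q, ff.mass(atype))
            for aname, atype, q in product_block.atoms
        }
        return ModificationPlan(
            reaction_id=rdef.reaction_id,
            target=rdef.target,
            terminus=rdef.terminus,
            product_code=rdef.product_code,
            deletions=tuple(tpl["deletions"]),
            renames=tuple((o, n) for o, n in tpl["renames"]),
            additions=tuple(additions),
            atom_params=atom_params,
        )

    def _validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for r in self.reactions:
            key = (r.reaction_id, r.target, r.terminus)
            if key in seen:
                raise RegistryLoadError(
                    f"duplicate reaction entry {r.reaction_id!r} for target {r.target!r}"
                )
            seen.add(key)
            if len(r.product_code) != 3:
                raise RegistryLoadError(
                    f"product code {r.product_code!r} of {r.reaction_id!r} "
                    "must have exactly 3 characters"
                )
            if r.executable and r.template_id not in self._templates:
                raise RegistryLoadError(
                    f"reaction {r.reaction_id!r}: template {r.template_id!r} not packaged"
                )
        for tid, tpl in self._templates.items():
            self._validate_template(tid, tpl)

    def _validate_template(self, tid: str, tpl: dict) -> None:
        parent = tpl["parent"]
        product = tpl["product"]
        if parent not in self.residue_blocks:
            raise RegistryLoadError(f"template {tid!r}: unknown parent block {parent!r}")
        if product not in self.residue_blocks:
            raise RegistryLoadError(f"template {tid!r}: unknown product block {product!r}")
        available = list(self.residue_blocks[parent].atom_names())
        for name in tpl["deletions"]:
            if name not in available:
                raise RegistryLoadError(
                    f"template {tid!r}: deletion {name!r} not in parent {parent}"
                )
            available.remove(name)
        for old, new in tpl["renames"]:
            if old not in available:
                raise RegistryLoadError(
                    f"template {tid!r}: rename source {old!r} not in parent {parent}"
                )
            available[available.index(old)] = new
        for entry in tpl["additions"]:
            name, rb, ra, rd = entry[0], entry[1], entry[2], entry[3]
            for ref in (rb, ra, rd):
                if ref not in available:
                    raise RegistryLoadError(
                        f"template {tid!r}: addition {name!r} references "
                        f"{ref!r} before it exists"
                    )
            if name in available:
                raise RegistryLoadError(
                    f"template {tid!r}: addition {name!r} duplicates an existing atom"
                )
            available.append(name)
        expected = self.residue_blocks[product].atom_names()
        if sorted(available) != sorted(expected):
            raise RegistryLoadError(
                f"template {tid!r}: applying the plan to {parent} yields atoms "
                f"{sorted(available)} but product block {product} declares "
                f"{sorted(expected)}"
            )


def _read_data_text(filename: str, data_dir: Path | None) -> str:
    if data_dir is not None:
        return (data_dir / filename).read_text()
    return resources.files(_DATA_PACKAGE).joinpath(filename).read_text()


def _parse_reactions_tsv(text: str) -> list[ReactionDef]:
    reactions = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise RegistryLoadError(f"malformed reaction row: {raw!r}")
        rid, target, terminus, product, template_id, desc = (p.strip() for p in parts)
        reactions.append(
            ReactionDef(
                reaction_id=rid,
                target=target.upper(),
                terminus=terminus.upper(),
                product_code=product,
                description=desc,
                template_id=None if template_id == "-" else template_id,
            )
        )
    return reactions


def _parse_blocks(raw: dict, charge_scale: float = 1.0) -> dict[str, ResidueBlock]:
    blocks = {}
    for name, spec in raw.items():
        blocks[name] = ResidueBlock(
            name=name,
            atoms=[(a[0], a[1], float(a[2]) * charge_scale) for a in spec["atoms"]],
            bonds=[(b[0], b[1]) for b in spec["bonds"]],
            zmatrix=[tuple(z) for z in spec.get("zmatrix", [])],
        )
    return blocks


def load_registry(data_dir: str | Path | None = None) -> Registry:
    """Load and validate the registry from packaged (or alternate) tables.

    Parameters
    ----------
    data_dir:
        Directory holding ``reactions.tsv``, ``templates.yaml``,
        ``residues.yaml`` and ``forcefield.yaml``.  Defaults to the tables
        packaged with ptmpatch.
    """
    data_dir = Path(data_dir) if data_dir is not None else None
    reactions = _parse_reactions_tsv(_read_data_text("reactions.tsv", data_dir))
    templates = yaml.safe_load(_read_data_text("templates.yaml", data_dir))
    ff = ForceFieldTable(yaml.safe_load(_read_data_text("forcefield.yaml", data_dir)))
    blocks = _parse_blocks(yaml.safe_load(_read_data_text("residues.yaml", data_dir)),
                           charge_scale=ff.charge_scale)
    return Registry(reactions, templates, blocks, ff)


_default_registry: Registry | None = None


def default_registry() -> Registry:
    """Packaged registry, loaded once per process."""
    global _default_registry
    if _default_registry is None:
        _default_registry = load_registry()
    return _default_registry
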