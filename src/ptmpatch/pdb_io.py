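"""PDB reading and writing.

Handling conventions: only coordinate records are interpreted; everything
before the first coordinate record is kept verbatim as pass-through header.
Multi-model files are parsed in full but model 1 is the modification target
and the only model ever written.  Internally all coordinates are in
nanometres; the file scale (ångströms) is converted at this boundary only.
"""

from __future__ import annotations

import re
import urllib.error
import urllib.request

from .errors import (
    EmptyStructureError,
    FetchError,
    PDBFormatError,
    PDBParseError,
    ValidationError,
)
from .structure import AtomRecord, Chain, Model, Residue, Structure

_ANGSTROM_PER_NM = 10.0
_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

MULTI_MODEL_WARNING = (
    "multi-model input: only the first model is modified and written to output"
)


def _parse_coord_line(line: str, lineno: int) -> AtomRecord:
    try:
        record_kind = line[:6].strip()
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16:17].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22] or " "
        res_seq = int(line[22:26])
        i_code = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparseable coordinate record: {exc}", lineno) from None
    occ_field = line[54:60].strip()
    b_field = line[60:66].strip()
    try:
        occupancy = float(occ_field) if occ_field else 1.0
        b_factor = float(b_field) if b_field else 0.0
    except ValueError:
        raise PDBParseError("unparseable occupancy/B-factor", lineno) from None
    element = line[76:78].strip()
    if not name:
        raise PDBParseError("blank atom name", lineno)
    try:
        return AtomRecord(
            record_kind=record_kind,
            serial=serial,
            name=name,
            alt_loc=alt_loc,
            res_name=res_name,
            chain_id=chain_id,
            res_seq=res_seq,
            i_code=i_code,
            position=(x / _ANGSTROM_PER_NM, y / _ANGSTROM_PER_NM, z / _ANGSTROM_PER_NM),
            occupancy=occupancy,
            b_factor=b_factor,
            element=element,
        )
    except ValueError as exc:
        raise PDBParseError(str(exc), lineno) from None


def parse_pdb(text: str, known_residues: frozenset[str] | None = None) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    ``known_residues`` defaults to the canonical 20 plus the packaged
    registry's product codes; residues outside that set are flagged
    non-canonical (rendered as "!" and not modifiable).
    """
    if not text.strip():
        raise EmptyStructureError("empty input")
    if known_residues is None:
        from .registry import default_registry

        known_residues = default_registry().known_residues()

    structure = Structure()
    current_model: Model | None = None
    explicit_models = False
    model_open = False
    seen_coords = False
    dropped_altloc = 0
    residue_keys_seen: dict[int, set] = {}

    def ensure_model() -> Model:
        nonlocal current_model
        if current_model is None:
            current_model = Model(number=len(structure.models) + 1)
            structure.models.append(current_model)
            residue_keys_seen[id(current_model)] = set()
        return current_model

    for lineno, raw in enumerate(text.splitlines(), start=1):
        tag = raw[:6].strip()
        if tag == "MODEL":
            if model_open:
                raise PDBParseError("MODEL record while a model is still open", lineno)
            explicit_models = True
            model_open = True
            seen_coords = True
            try:
                number = int(raw[10:14])
            except (ValueError, IndexError):
                number = len(structure.models) + 1
            current_model = Model(number=number)
            structure.models.append(current_model)
            residue_keys_seen[id(current_model)] = set()
        elif tag == "ENDMDL":
            if not model_open:
                raise PDBParseError("ENDMDL without matching MODEL", lineno)
            model_open = False
            current_model = None
        elif tag in ("ATOM", "HETATM"):
            if explicit_models and not model_open:
                raise PDBParseError("coordinate record outside MODEL/ENDMDL block", lineno)
            seen_coords = True
            rec = _parse_coord_line(raw, lineno)
            if rec.alt_loc not in ("", "A"):
                dropped_altloc += 1
                continue
            rec.alt_loc = ""
            model = ensure_model()
            if rec.record_kind == "HETATM":
                model.het_records.append(rec)
                continue
            _append_atom(model, rec, known_residues,
                         residue_keys_seen[id(model)], lineno)
        elif tag == "TER":
            if current_model is not None and current_model.chains:
                structure.ter_chain_ids.append(current_model.chains[-1].chain_id)
        elif not seen_coords:
            structure.header_lines.append(raw)
        # anything else after coordinates started is deliberately ignored

    if model_open:
        raise PDBParseError("MODEL block never closed by ENDMDL")
    if not any(m.chains or m.het_records for m in structure.models):
        raise EmptyStructureError("no ATOM/HETATM records found")
    if len(structure.models) > 1:
        structure.multi_model = True
        structure.warnings.append(MULTI_MODEL_WARNING)
    if dropped_altloc:
        structure.warnings.append(
            f"dropped {dropped_altloc} alternate-location record(s) "
            "(kept blank/'A' conformers)"
        )
    return structure


def _append_atom(model: Model, rec: AtomRecord, known_residues: frozenset[str],
                 keys_seen: set, lineno: int) -> None:
    if not model.chains or model.chains[-1].chain_id != rec.chain_id:
        model.chains.append(Chain(chain_id=rec.chain_id))
    chain = model.chains[-1]
    key = (rec.chain_id, rec.res_seq, rec.i_code)
    if chain.residues and chain.residues[-1].key == key:
        residue = chain.residues[-1]
        if residue.name != rec.res_name:
            raise PDBParseError(
                f"residue {key} has conflicting names "
                f"{residue.name!r}/{rec.res_name!r}", lineno)
    else:
        if key in keys_seen:
            raise PDBParseError(f"residue identity {key} occurs twice", lineno)
        keys_seen.add(key)
        residue = Residue(
            name=rec.res_name,
            chain_id=rec.chain_id,
            res_seq=rec.res_seq,
            i_code=rec.i_code,
            non_canonical=rec.res_name not in known_residues,
        )
        chain.residues.append(residue)
    if residue.atom(rec.name) is not None:
        return  # duplicate atom name within residue (altloc remnant): keep first
    residue.atoms.append(rec)


def _format_atom_name(name: str) -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} exceeds 4 characters")
    # standard convention: names shorter than 4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def _coord_fields(rec: AtomRecord) -> str:
    x, y, z = rec.position * _ANGSTROM_PER_NM
    return f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{rec.b_factor:6.2f}"


def _format_record(kind: str, serial: int, rec: AtomRecord) -> str:
    if serial > 99999:
        raise PDBFormatError("atom serial exceeds 99999; PDB format cannot express it")
    res_name = rec.res_name.strip()
    if kind == "ATOM" and len(res_name) != 3:
        raise PDBFormatError(
            f"residue name {res_name!r} must have exactly 3 characters in ATOM records"
        )
    return (
        f"{kind:<6s}{serial:5d} {_format_atom_name(rec.name)}"
        f"{rec.alt_loc or ' ':1s}{res_name:>3s} {rec.chain_id:1s}"
        f"{rec.res_seq:4d}{rec.i_code or ' ':1s}   "
        f"{_coord_fields(rec)}          {rec.element:>2s}"
    )


def write_pdb(structure: Structure, copy_header: bool = False) -> str:
    """Serialize model 1 in fixed-column PDB v3 layout.

    Serials are assigned sequentially at write time (ATOM records chain by
    chain, a TER per chain consuming a serial, then HETATM records), so the
    output is always properly renumbered.
    """
    lines: list[str] = []
    if copy_header:
        lines.extend(structure.header_lines)
    model = structure.first_model
    if structure.multi_model:
        lines.append(f"MODEL     {model.number:4d}")
    serial = 0
    for chain in model.chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_record("ATOM", serial, atom))
            last_res = res
        if last_res is not None:
            serial += 1
            if serial > 99999:
                raise PDBFormatError("atom serial exceeds 99999")
            lines.append(
                f"TER   {serial:5d}      {last_res.name:>3s} "
                f"{chain.chain_id:1s}{last_res.res_seq:4d}{last_res.i_code or ' ':1s}"
            )
    for het in model.het_records:
        serial += 1
        lines.append(_format_record("HETATM", serial, het))
    if structure.multi_model:
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def fetch_pdb(pdb_id: str, offline: bool = True, timeout: float = 30.0) -> str:
    """Download raw PDB text by 4-character id.

    Offline is the default; the caller must opt in to network access.
    Never invoked implicitly by other library functions.
    """
    if not _PDB_ID_RE.match(pdb_id or ""):
        raise ValidationError(
            f"invalid PDB id {pdb_id!r}: expected a digit followed by "
            "3 alphanumeric characters"
        )
    if offline:
        raise FetchError(
            f"offline mode: refusing to download {pdb_id!r} "
            "(pass offline=False / --fetch to allow network access)"
        )
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read().decode("utf-8", errors="replace")
    except urllib.error.HTTPError as exc:
        raise FetchError(f"server returned HTTP {exc.code} for {pdb_id!r}") from exc
    except urllib.error.URLError as exc:
        raise FetchError(f"network unavailable fetching {pdb_id!r}: {exc.reason}") from exc
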