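"""Exception hierarchy for ptmpatch.

Every failure mode raised by the library derives from :class:`PtmPatchError`
so callers (notably the CLI) can catch a single base class.
"""


class PtmPatchError(Exception):
    """Base class for all ptmpatch errors."""


# --- PDB I/O -------------------------------------------------------------

class PDBParseError(PtmPatchError):
    """Malformed PDB content; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(PDBParseError):
    """Input contained no ATOM/HETATM coordinate records."""


class PDBFormatError(PtmPatchError):
    """Structure cannot be serialized in fixed-column PDB format."""


class FetchError(PtmPatchError):
    """PDB download failed (network unavailable, offline mode, or 404)."""


class ValidationError(PtmPatchError):
    """Invalid user-facing input (ids, selection strings, config)."""


# --- Registry ------------------------------------------------------------

class RegistryLoadError(PtmPatchError):
    """Packaged registry/template tables failed validation at load time."""


class ReactionNotFoundError(PtmPatchError):
    """Unknown reaction id; may carry near-match suggestions."""

    def __init__(self, message: str, suggestions: tuple[str, ...] = ()):
        self.suggestions = suggestions
        if suggestions:
            message += f" (did you mean: {', '.join(suggestions)}?)"
        super().__init__(message)


class TargetMismatchError(PtmPatchError):
    """Reaction exists but is not defined for the requested residue."""


class NotExecutableError(PtmPatchError):
    """Reaction is catalogued name-only; no geometric template is packaged."""


# --- Geometry ------------------------------------------------------------

class DegenerateFrameError(PtmPatchError):
    """Reference points are coincident or collinear; no frame exists."""


# --- Engine --------------------------------------------------------------

class SelectionError(PtmPatchError):
    """A selection did not resolve to exactly one residue in model 1."""


class DuplicateSelectionError(PtmPatchError):
    """Two selections name the same residue site."""


class NonCanonicalResidueError(PtmPatchError):
    """The selected residue is non-canonical and cannot be modified."""


class StructuralIncompletenessError(PtmPatchError):
    """A reference atom required for placement is missing from the residue."""


# --- Force field / minimization ------------------------------------------

class UnknownResidueError(PtmPatchError):
    """No building block packaged for this residue name."""


class IncompleteResidueError(PtmPatchError):
    """Residue is missing atoms required by its building block."""


class SingularityError(PtmPatchError):
    """Coincident bonded atoms make the energy/force evaluation singular."""


class MinimizationInputError(PtmPatchError):
    """Non-finite energy at the starting configuration."""


class TopologyError(PtmPatchError):
    """Topology is empty or internally inconsistent."""
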