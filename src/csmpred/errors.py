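"""Exception hierarchy shared across the package."""


class CsmpredError(Exception):
    """Base class for all package errors."""


class PDBParseError(CsmpredError):
    """A PDB file could not be parsed."""


class EmptyStructureError(CsmpredError):
    """A parsed structure contained no protein atoms."""


class UnknownAtomError(CsmpredError):
    """An atom could not be assigned a pharmacophore class."""


class UnsupportedResidueError(CsmpredError):
    """A residue name outside the 20 standard amino acids was requested."""


class MutationParseError(CsmpredError):
    """A mutation code could not be parsed."""


class SilentMutationError(MutationParseError):
    """Wild-type and mutant residues are identical."""


class WildTypeMismatchError(CsmpredError):
    """The structure residue does not match the mutation's stated wild type."""


class DatasetError(CsmpredError):
    """Dataset loading or validation failed."""


class ProtocolError(CsmpredError):
    """A cross-validation protocol cannot be satisfied."""


class DegenerateMatrixError(CsmpredError):
    """Noise reduction removed every feature column."""


class UndefinedMetricError(CsmpredError):
    """A metric is undefined for the given inputs (e.g. zero-variance data)."""


class FixtureSpecError(CsmpredError):
    """Invalid synthetic-fixture specification."""
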