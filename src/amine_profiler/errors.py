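"""Exception types shared across the package."""


class AmineProfilerError(Exception):
    """Base class for all package errors."""


class UnknownResidue(AmineProfilerError):
    """Residue code not present in the chemistry tables."""


class NotAnAcceptor(AmineProfilerError):
    """Atom is not an H-bond acceptor for the given residue."""


class ParseError(AmineProfilerError):
    """Input file (structure or representative-set CSV) could not be parsed."""


class ModelNotFound(AmineProfilerError):
    """Requested model number absent from the structure."""


class GeometryError(AmineProfilerError):
    """Degenerate geometry (zero-length vector, coincident atoms)."""


class ContractViolation(AmineProfilerError):
    """An operation was called outside its contract."""


class FragmentIncomplete(AmineProfilerError):
    """Fragment extraction could not assemble the full 6x5 window."""


class NoValidCutoff(AmineProfilerError):
    """Cutoff scan range is empty (e.g. all-singleton clustering)."""


class InfeasibleScenario(AmineProfilerError):
    """Requested donation scenario cannot be constructed under the criteria."""


class EmptyStructure(AmineProfilerError):
    """Operation requires a non-empty structure."""
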