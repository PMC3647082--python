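"""Exception hierarchy for comigratlas."""


class ComigratlasError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ComigratlasError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ComigratlasError):
    """An input violated a domain invariant (duplicate accession, bad row...)."""


class UndefinedMassError(ComigratlasError):
    """Peptide mass is undefined (empty or nonstandard-residue sequence)."""


class UndefinedDenominatorError(ComigratlasError):
    """emPAI requested for a protein with observed peptides but zero
    observable peptides; flags an inconsistency between the identification
    table and the digestion parameters."""
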