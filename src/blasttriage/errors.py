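"""Exception hierarchy shared across the package."""


class BlastTriageError(Exception):
    """Base class for all package errors."""


class ParseError(BlastTriageError):
    """Malformed or unsupported input file."""


class UnsupportedProgramError(ParseError):
    """BLAST flavour the pipeline does not handle (tblastx)."""


class MultiQueryError(ParseError):
    """Report contains more than one query; run one query per report."""


class IntegrityError(BlastTriageError):
    """Internal data violates a structural invariant."""


class SelectionError(BlastTriageError):
    """Invalid selection parameters (thresholds, intervals, labels)."""


class TaxonomyError(BlastTriageError):
    """Taxonomy table integrity or lookup failure."""
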