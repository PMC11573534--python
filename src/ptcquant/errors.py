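"""Exception hierarchy.

``InputError`` marks malformed caller input (bad residue letters, invalid
charge, unknown variants); ``ValidationError`` marks inconsistent domain
objects (a declared stop site whose codon is not a stop, duplicate FASTA ids).
Both derive from ``PtcQuantError`` so callers can catch package errors
wholesale.
"""


class PtcQuantError(Exception):
    """Base class for all errors raised by ptcquant."""


class InputError(PtcQuantError):
    """Malformed input supplied by the caller."""


class ValidationError(PtcQuantError):
    """A domain object failed its internal consistency checks."""
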