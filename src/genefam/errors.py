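"""Exception hierarchy.

``GenefamError`` is the base for everything the library raises on bad
input; the CLI maps it to exit code 2 (data error).
"""


class GenefamError(Exception):
    """Base class for data/contract errors raised by genefam."""


class FormatError(GenefamError):
    """Malformed input file (FASTA/GFF3/TSV)."""


class ValidationError(GenefamError):
    """Arguments violate an operation's preconditions."""
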