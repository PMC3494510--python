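"""Exception types shared across the package."""


class XenoscreenError(Exception):
    """Base class for all package errors."""


class FormatError(XenoscreenError):
    """An external file (FASTA, Newick, config, table) is malformed."""


class DataError(XenoscreenError):
    """Inputs are well-formed but inconsistent (missing ids, bad values)."""
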