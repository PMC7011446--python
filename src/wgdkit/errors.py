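"""Exception hierarchy shared across the pipeline."""


class WgdkitError(Exception):
    """Base class for all wgdkit errors."""


class NewickParseError(WgdkitError):
    """Malformed newick input; message carries the approximate byte offset."""


class RootingError(WgdkitError):
    """A rooted tree was required but none could be resolved."""


class StructureError(WgdkitError):
    """A tree violates a structural requirement (e.g. non-pectinate species tree)."""


class BlastRowError(WgdkitError):
    """A BLAST tabular row could not be parsed; message carries the line number."""


class InsufficientDataError(WgdkitError):
    """Too few observations to carry out an estimate."""


class SaturationError(WgdkitError):
    """Synonymous divergence beyond the range of the distance correction."""
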