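"""Exception hierarchy shared across the package."""


class CladolinkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CladolinkError):
    """Malformed input file (duplicate ids, unparseable records, ...)."""


class AlignmentError(CladolinkError):
    """Sequences are not aligned: unequal lengths."""


class AlphabetError(CladolinkError):
    """A sequence contains a symbol outside the declared alphabet."""


class MetricError(CladolinkError):
    """Unknown or misused distance metric."""


class LabelingError(CladolinkError):
    """A tree node that needs a sequence label does not carry one."""


class SizeGuardError(CladolinkError):
    """An exhaustive computation was refused because the instance is too large."""
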