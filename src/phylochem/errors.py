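"""Exception types shared across the package."""


class PhylochemError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhylochemError):
    """Malformed Newick input; message carries the parser's position info."""


class DuplicateTipLabelError(PhylochemError):
    """Two or more tips share a label."""


class NotBifurcatingError(PhylochemError):
    """An operation that requires a strictly bifurcating tree met a polytomy."""


class MissingStateError(PhylochemError):
    """A tip has no trait state assigned."""


class NullsIndistinguishableError(PhylochemError):
    """Permutation and Brownian null means coincide; D is undefined."""


class LabelMismatchError(PhylochemError):
    """Two labelled objects do not share the same label set/order."""


class ZeroVarianceError(PhylochemError):
    """A correlation is undefined because one input has no variance."""


class VocabularyMismatchError(PhylochemError):
    """Chemical profiles are not defined over the same type vocabulary."""


class ReconciliationError(PhylochemError):
    """Tree and trait matrix share too few species to analyse."""
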