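"""Exception hierarchy.

``PhyloPredError`` is the base for every error this package raises on
user-facing data problems; the CLI maps it to exit code 1.
"""


class PhyloPredError(Exception):
    """Base class for phylopred data and model errors."""


class NewickParseError(PhyloPredError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips,
    missing or negative branch lengths)."""


class TreeError(PhyloPredError):
    """Invalid tree operation (unknown tip label, non-ultrametric input
    where an ultrametric tree is required, lambda outside [0, 1])."""


class DataError(PhyloPredError):
    """Invalid trait table content (duplicate species, non-numeric cells,
    log of non-positive values, empty tree/table intersection)."""


class FitError(PhyloPredError):
    """Degenerate model fit (constant trait, singular covariance,
    rank-deficient design, too few complete cases)."""
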