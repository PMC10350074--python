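"""Exception hierarchy for spaceanova.

All errors derive from :class:`SpaceanovaError` so callers can catch the
package's failures with a single ``except`` clause.  Estimation-level
"missing data" conditions (too few cells for a pair in an image) are
signalled with :class:`InsufficientCellsError` and are routinely caught by
the pipeline, which records the curve as missing rather than zero.
"""

from __future__ import annotations


class SpaceanovaError(Exception):
    """Base class for all spaceanova errors."""


class SchemaError(SpaceanovaError):
    """Input table is malformed: a required column is missing or empty."""


class ParseError(SpaceanovaError):
    """A cell-table value could not be parsed (e.g. non-numeric coordinate)."""


class ConsistencyError(SpaceanovaError):
    """The table violates the study hierarchy (image -> subject -> group)."""


class ConfigError(SpaceanovaError):
    """Invalid configuration value (nonpositive radius, bad grid, ...)."""


class DesignError(SpaceanovaError):
    """Study design cannot support the requested inference (e.g. G < 2)."""


class DegenerateVarianceError(SpaceanovaError):
    """Pointwise error variance vanishes on a set of positive measure.

    The beta-chi-square approximation is meaningless here; the permutation
    p-value remains available and the error message says so.
    """


class InsufficientCellsError(SpaceanovaError):
    """An image has too few cells of a requested type to estimate a curve.

    Carries the pair and image id so pipelines can record which curve is
    missing.  A missing curve is *not* a zero curve.
    """

    def __init__(self, pair: tuple[str, str], image_id: str, message: str | None = None):
        self.pair = pair
        self.image_id = image_id
        super().__init__(
            message
            or f"image {image_id!r}: too few cells to estimate pair {pair!r}"
        )
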