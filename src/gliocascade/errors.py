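"""Exception hierarchy.

All errors derive from :class:`GliocascadeError` so callers can catch the
package's failures with one clause; most also derive from the matching
built-in (``ValueError``, ``FileNotFoundError``) so generic handling keeps
working.
"""


class GliocascadeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GliocascadeError, ValueError):
    """Invalid configuration value (shape, threshold, epochs, fraction...)."""


class ShapeError(GliocascadeError, ValueError):
    """Array arguments have incompatible shapes."""


class DataError(GliocascadeError, ValueError):
    """Training/evaluation data violate a precondition (empty set, one class)."""


class MissingSequenceError(GliocascadeError, FileNotFoundError):
    """One or more of the four required MR sequences is absent."""


class GeometryMismatchError(GliocascadeError, ValueError):
    """Volumes that must share shape/spacing do not."""


class FormatError(GliocascadeError, ValueError):
    """File exists but is not a readable volume of a supported format."""


class LabelDomainError(GliocascadeError, ValueError):
    """Label volume contains values outside {0,1,2,3,4}."""


class RegionNameError(GliocascadeError, KeyError):
    """Unknown tumor-region name."""


class GeometryError(GliocascadeError, ValueError):
    """Phantom geometry does not fit inside the volume."""
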