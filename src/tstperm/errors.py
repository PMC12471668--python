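"""Exception hierarchy for tstperm.

All exceptions derive from :class:`TstpermError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from malformed input files.
"""


class TstpermError(Exception):
    """Base class for all tstperm errors."""


class FormatError(TstpermError):
    """A topology/trajectory file is malformed or inconsistent
    (e.g. atom-count mismatch between topology and trajectory)."""


class TruncationError(TstpermError):
    """A trajectory frame could not be read; carries the index of the
    last frame that was read successfully."""

    def __init__(self, message: str, last_good_frame: int):
        super().__init__(message)
        self.last_good_frame = last_good_frame


class ConfigurationError(TstpermError):
    """A user-supplied configuration value is invalid (empty atom
    selection, unknown residue group, out-of-range plane position...)."""


class GeometryError(TstpermError):
    """A geometric construction is degenerate (e.g. zero-length channel
    axis)."""


class DataError(TstpermError):
    """Input data violate a structural invariant (non-monotonic times,
    zero frames...)."""


class TopologyError(TstpermError):
    """A required atom is missing from the topology (e.g. a hydrogen-bond
    donor without resolvable hydrogens)."""


class DomainError(TstpermError, ValueError):
    """A numeric argument is outside its physical domain (kappa not in
    [0, 1], equal temperatures in an Arrhenius fit...)."""
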