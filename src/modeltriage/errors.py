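"""Exception hierarchy.

Every error carries an ``exit_code`` so the CLI can map error classes to
distinct process exit statuses.
"""


class TriageError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(TriageError):
    """Malformed, missing or inconsistent input data."""

    exit_code = 2


class EmptyModelError(InputError):
    """Coordinate file contains no usable polymer atoms."""

    exit_code = 2


class PairingError(InputError):
    """Residue correspondence between two traces could not be established."""

    exit_code = 2


class IncompleteMetricsError(InputError):
    """A metrics record lacks fields required by the requested rule."""

    exit_code = 2


class NoAcceptableModelError(TriageError):
    """Every candidate was rejected by the picker rules."""

    exit_code = 3


class DegenerateGeometryError(TriageError):
    """Point set too degenerate (collinear/coincident) for superposition."""

    exit_code = 4
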