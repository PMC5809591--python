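"""Exception hierarchy.

``DataError`` covers malformed or inconsistent inputs (missing files, bad
dimensionality, empty masks); ``ConvergenceError`` covers iterative
procedures that fail to reach their tolerance (field inversion, demons
registration, Cox fitting).  The CLI maps these to distinct exit codes.
"""


class VentridispError(Exception):
    """Base class for all package-specific errors."""


class DataError(VentridispError):
    """Invalid, inconsistent, or missing input data."""


class ConvergenceError(VentridispError):
    """An iterative numerical procedure failed to converge."""
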