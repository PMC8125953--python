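"""Exception hierarchy with CLI exit codes.

Exit-code convention: 2 input error, 3 degenerate geometry, 4 configuration
error (0 is success).
"""


class OildropError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(OildropError):
    """A structure file could not be parsed."""

    exit_code = 2


class EmptyModelError(OildropError):
    """A structure contains no standard amino-acid residues."""

    exit_code = 2


class SelectionError(OildropError):
    """A unit selector did not resolve to a valid residue subset."""

    exit_code = 2


class DegenerateGeometryError(OildropError):
    """Effective atoms are coincident or otherwise unusable for fitting."""

    exit_code = 3


class ConfigurationError(OildropError):
    """A scale, cutoff or other configuration value is invalid."""

    exit_code = 4


class GenerationError(OildropError):
    """The synthetic generator could not satisfy its packing constraints."""

    exit_code = 2
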