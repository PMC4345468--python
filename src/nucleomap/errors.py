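"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, DataError (and subclasses) to 3.
"""


class NucleomapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NucleomapError):
    """Invalid configuration: bad key, out-of-range channel, bad parameter."""


class DataError(NucleomapError):
    """Input data cannot be processed (format, degeneracy, inconsistency)."""


class GenerationError(NucleomapError):
    """Synthetic-data generation produced an invalid object (e.g. non-convex)."""
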