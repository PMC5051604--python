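"""Exception hierarchy.

``ConfigurationError`` covers invalid study/DGP configuration (bad
correlation matrix, unknown DGP id, invalid truncation levels);
``EstimationError`` covers data-dependent failures (one-class treatment,
empty arms, non-convergent fluctuations).  Plain ``ValueError`` is reserved
for malformed arguments to low-level numerical helpers.
"""


class DrbenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DrbenchError, ValueError):
    """A configuration object or file is invalid."""


class EstimationError(DrbenchError, RuntimeError):
    """An estimator or nuisance fit failed on the given data."""
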