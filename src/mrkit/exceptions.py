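"""Exception hierarchy.

All mrkit errors derive from :class:`MrkitError` so callers can catch the
package's failures with a single except clause; subclasses distinguish
configuration problems from data problems (the CLI maps them to distinct
exit codes).
"""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MrkitError):
    """Invalid configuration (bad parameter values, non-PSD matrices, ...)."""


class DataError(MrkitError):
    """Invalid or insufficient input data."""


class EmptyTableError(DataError):
    """A summary-statistics table contained no valid rows."""


class EmptyIntersectionError(DataError):
    """No SNPs shared between tables to be harmonized."""


class InsufficientInstrumentsError(DataError):
    """Fewer instruments than the estimator requires."""


class MissingMetadataError(DataError):
    """A required column (sample size, chrom/pos, ...) is absent."""


class CollinearityError(DataError):
    """Rank-deficient exposure matrix in multivariable MR."""

    def __init__(self, exposures):
        self.exposures = list(exposures)
        super().__init__(
            "exposure effect columns are collinear: " + ", ".join(self.exposures)
        )


class DegenerateInstrumentError(DataError):
    """A SNP with zero exposure effect reached a ratio-based estimator."""
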