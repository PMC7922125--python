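"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter is outside its admissible domain (e.g. p1 not in (0,1))."""


class DegenerateDesignError(ValueError):
    """A regression design has no residual degrees of freedom."""


class UndefinedLDError(ValueError):
    """LD r^2 is undefined because at least one genotype vector is constant."""


class FeasibilityError(ValueError):
    """Requested LD is unattainable for the given allele frequencies."""


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


class DataError(ValueError):
    """Input data files are malformed or cannot be joined."""
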