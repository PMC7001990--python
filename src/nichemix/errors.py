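"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or run configuration violates its invariants."""


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


class DegenerateDataError(ValueError):
    """A computation is undefined on the given data (zero denominator etc.)."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics indicate the sampler may not have converged."""


class DataQualityWarning(UserWarning):
    """Input is usable but degenerate (e.g. n=1 source groups, singleton whiskers)."""
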