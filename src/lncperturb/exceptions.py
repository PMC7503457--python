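"""Exception hierarchy shared by all lncperturb modules."""


class LncPerturbError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LncPerturbError, ValueError):
    """A configuration value violates its documented range or invariant."""


class DataError(LncPerturbError, ValueError):
    """Input tables are inconsistent (missing samples, empty intersections...)."""


class DomainError(LncPerturbError, ValueError):
    """A statistical routine was called outside its mathematical domain."""


class FitError(LncPerturbError, RuntimeError):
    """A model fit failed to converge or was otherwise unusable."""
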