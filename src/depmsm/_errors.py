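"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A spec/config object is internally inconsistent (bad rates, shapes, grids)."""


class DataError(ValueError):
    """Input data violate a structural contract (forbidden transition, empty risk set)."""


class ExclusionError(ValueError):
    """A subject or column falls under a study exclusion rule (symptomatic baseline,
    missing-rate cap) and must be removed upstream rather than analysed."""
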