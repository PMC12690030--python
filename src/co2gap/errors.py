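"""Exception and warning types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the physiologically plausible range."""


class MissingDataError(ValueError):
    """A required field is absent (NaN/None); the message names the field."""


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateLeverageError(ValueError):
    """A leverage of 1 makes the HC3 residual inflation undefined."""


class SampleSizeError(ValueError):
    """Too few complete observations for the requested model."""


class PlausibilityWarning(UserWarning):
    """Physiologically suspicious but not fatal input (e.g. inverted CO2 gradient)."""
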