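"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input specification or configuration file is invalid."""


class CalibrationError(RuntimeError):
    """A calibration target cannot be reached within the multiplier bounds."""
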