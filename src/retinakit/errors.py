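"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument is outside the domain an operation is defined on."""


class ConfigError(ValueError):
    """A pipeline configuration is internally inconsistent."""


class NoSpikesError(RuntimeError):
    """No usable spikes remain after windowing; the cell should be flagged,
    not crash the pipeline."""


class CalibrationError(RuntimeError):
    """An intensity-response calibration did not reproduce its anchor points."""
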