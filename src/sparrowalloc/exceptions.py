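"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Optimizer or problem configuration is internally inconsistent."""


class EvaluationError(RuntimeError):
    """An objective returned a non-finite value."""


class InfeasibleProblemError(ValueError):
    """The allocation constraint set is empty (e.g. variance cap below 1/n)."""
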