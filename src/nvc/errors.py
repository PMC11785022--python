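"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument is outside its documented domain (bad band, bad matrix, ...)."""


class AlignmentError(ValueError):
    """Two traces that must share a time base do not."""


class MeasurementError(RuntimeError):
    """A per-frame measurement could not be made (no FWHM crossing, empty
    connected component, ...). Frame-level code catches this and flags the
    frame invalid rather than aborting a whole trace."""


class ConditioningWarning(UserWarning):
    """A linear system was ill-conditioned and a stabilizer was applied."""
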