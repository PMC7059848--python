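"""Exception and warning types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but analytically empty
    (all-zero audio, signal shorter than one analysis window, ...)."""


class AudioIOError(IOError):
    """Raised when an audio file cannot be read or decoded; the message
    always names the offending path."""


class IntegrityError(ValueError):
    """Raised when the participant table violates the dyadic design
    (duplicate ids, pairs without exactly two same-sex members, ...)."""


class FitError(RuntimeError):
    """Raised when the mixed model cannot be estimated (singular design,
    non-convergence)."""


class BandRangeError(ValueError):
    """Raised when a requested modulation band lies outside the grid."""


class ComparabilityWarning(UserWarning):
    """Emitted when pixel areas from different recordings are on different
    modulation grids and therefore not comparable."""
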