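"""Exception hierarchy for beam-physics error conditions."""


class RSBeamError(Exception):
    """Base class for all package-specific errors."""


class StoppedBeamError(RSBeamError):
    """The beam does not exit the medium (requested depth exceeds the residual range)."""


class NonPhysicalPhaseSpaceError(RSBeamError):
    """A phase-space operation produced a negative position variance.

    This can only happen when the covariance determinant A*C - B**2 is
    negative, i.e. the phase space does not describe a physical beam.
    The core transport never repairs such a state silently; emulation of
    treatment-planning-system behaviour that does is opt-in and explicit.
    """


class GeometryError(RSBeamError):
    """Inconsistent beam-line geometry (e.g. a range shifter crossing isocenter)."""


class DegenerateDataError(RSBeamError):
    """Input data cannot constrain the requested fit."""
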