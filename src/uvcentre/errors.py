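"""Exception hierarchy for the centring pipeline."""


class UVCentreError(Exception):
    """Base class for centring-pipeline errors."""


class NoObjectError(UVCentreError):
    """No sample holder (foreground) detected in a frame: empty mount."""


class NoCrystalError(UVCentreError):
    """A holder was present but no fluorescing crystal could be segmented."""


class OutOfFrameError(UVCentreError):
    """Requested scene geometry projects outside the camera frame."""

    def __init__(self, omega_deg: float, message: str | None = None):
        self.omega_deg = omega_deg
        super().__init__(
            message or f"crystal projects outside the frame at omega={omega_deg:g} deg"
        )


class InsufficientAnglesError(UVCentreError):
    """The rotation-angle set cannot determine a 3D position (need >=2 angles
    distinct modulo 180 degrees)."""
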