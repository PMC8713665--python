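"""Exception and warning types shared across the pipeline."""


class OxymapError(Exception):
    """Base class for all package errors."""


class DomainCoverageError(OxymapError):
    """A wavelength grid does not cover a filter passband."""


class DegenerateFilterError(OxymapError):
    """A filter has zero total transmission weight on the given grid."""


class StructuralError(OxymapError):
    """Shape or band-order mismatch between cubes."""


class CalibrationError(OxymapError):
    """Unusable calibration frames (e.g. fully-zero white reference)."""


class FitError(OxymapError):
    """The unmixing design matrix is rank deficient."""


class RegistrationError(OxymapError):
    """Registration cannot be estimated (e.g. constant image)."""


class ProfileError(OxymapError):
    """Invalid profile geometry or out-of-range decision position."""


class IllConditionedBankWarning(UserWarning):
    """The filter bank yields a rank-deficient or near-singular design matrix."""


class EmptyMaskWarning(UserWarning):
    """A tissue mask came out empty."""
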