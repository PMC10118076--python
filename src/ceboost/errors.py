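"""Exception hierarchy for the ceboost toolkit."""


class CeboostError(Exception):
    """Base class for all ceboost errors."""


class GeometryError(CeboostError):
    """Volumes or probes disagree on shape, spacing or orientation."""


class VolumeIOError(CeboostError):
    """A file could not be read or written as a CT volume."""


class PhantomSpecError(CeboostError):
    """A phantom specification violates its invariants."""


class ConfigError(CeboostError):
    """An unknown or invalid processing parameter."""


class RegistrationError(CeboostError):
    """Rigid registration failed (e.g. non-overlapping fields of view)."""


class MeasurementError(CeboostError):
    """An ROI or line probe cannot be measured on the given volume."""


class FWHMUndefinedError(MeasurementError):
    """The attenuation profile has no measurable full width at half maximum."""


class DegenerateInputError(CeboostError):
    """A statistical routine received input with no usable variation."""
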