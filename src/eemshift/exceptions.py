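"""Exception hierarchy for EEM processing errors."""


class EEMError(Exception):
    """Base class for all eemshift errors."""


class FormatError(EEMError, ValueError):
    """A file does not conform to the declared CSV dialect."""


class GridMismatchError(EEMError, ValueError):
    """Two objects that must share a wavelength grid do not."""


class UnitError(EEMError, ValueError):
    """Quantities with incompatible acquisition units were combined."""


class RangeError(EEMError, ValueError):
    """A requested wavelength or range falls outside the available grid."""


class WindowError(EEMError, ValueError):
    """A smoothing window contains too few points for the local fit."""
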