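"""Exception hierarchy shared across the analysis stages."""


class BeadStressError(Exception):
    """Base class for all analysis errors."""


class ConstantRegionError(BeadStressError):
    """A region of interest contains a single intensity value; no threshold exists."""


class NoObjectError(BeadStressError):
    """Thresholding produced an empty foreground."""


class OutOfRangeError(BeadStressError):
    """A pressure or strain lies outside the calibrated constitutive range."""


class NonMonotoneFitError(BeadStressError):
    """A fitted stress-strain polynomial is not strictly increasing on its range."""


class DivergentCoreError(BeadStressError):
    """Radial stress requested at r=0 where the power law diverges (beta<0)."""


class NoBeadsError(BeadStressError):
    """No bead passed quality control; the profile stages have no input."""


class PlacementError(BeadStressError):
    """Random object placement failed after the allowed number of attempts."""
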