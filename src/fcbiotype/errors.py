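"""Exception hierarchy shared across the package."""


class FCBiotypeError(Exception):
    """Base class for all package-specific errors."""


class AtlasError(FCBiotypeError):
    """Invalid atlas: bad ROI ids, unknown network label, too few regions."""


class FormatError(FCBiotypeError):
    """A file failed to parse; the message names the file and, where
    possible, the offending line or column."""


class DimensionError(FCBiotypeError):
    """Shapes of atlas, matrices, cohort or maps are inconsistent."""


class DesignError(FCBiotypeError):
    """A simulation design is infeasible (bad proportions, |rho| > 1, ...)."""
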