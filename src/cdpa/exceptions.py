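"""Exception and warning types shared across the package."""


class CDPAError(Exception):
    """Base class for all package errors."""


class ParseError(CDPAError):
    """Raised when a structure file cannot be parsed into atom records."""


class LigandNotFoundError(CDPAError):
    """Raised when a ligand selector matches no hetero atoms."""


class AmbiguousLigandError(CDPAError):
    """Raised when a selector matches more than one ligand instance."""


class DegenerateSiteError(CDPAError):
    """Raised for sites too small or too degenerate for a 3-D covariance."""


class SingularModelError(CDPAError):
    """Raised when a group covariance cannot be inverted (no ridge requested)."""


class OverfitRiskError(CDPAError):
    """Raised when a logistic fit is requested with parameters >= n/1.25."""


class DegenerateFrameWarning(UserWarning):
    """Near-equal coordinate-covariance eigenvalues: axes are convention-dependent."""


class SmallGroupWarning(UserWarning):
    """Group too small for a full-rank 6x6 covariance; ridge applied."""
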