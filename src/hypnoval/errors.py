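"""Exception hierarchy for hypnogram validation."""


class HypnovalError(Exception):
    """Base class for all package errors."""


class HypnogramError(HypnovalError):
    """Invalid hypnogram contents (bad label, empty sequence, bad duration)."""


class AlignmentError(HypnovalError):
    """Two hypnograms cannot be placed on a common epoch grid."""


class NoSleepError(HypnovalError):
    """The hypnogram contains no sleep epoch; sleep features are undefined."""


class UndefinedRateError(HypnovalError):
    """Transition rates requested on an empty transition set."""


class UndefinedKappaError(HypnovalError):
    """Fleiss' kappa is undefined (chance agreement is 1 without total agreement)."""
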