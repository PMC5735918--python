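"""Exception hierarchy shared across the package."""


class NmsgenError(Exception):
    """Base class for all package errors."""


class MoleculeError(NmsgenError):
    """Invalid molecular data (unknown element, shape mismatch, coincident atoms)."""


class HessianError(NmsgenError):
    """Malformed Hessian input (wrong size, asymmetric)."""


class ImaginaryModeError(NmsgenError):
    """A vibrational force constant came out non-positive."""


class ScheduleError(NmsgenError):
    """Requested molecule size missing from the sampling schedule."""


class CalculatorError(NmsgenError):
    """A calculator cannot handle the requested species at all."""


class SinglePointFailure(NmsgenError):
    """Typed signal: one single-point energy evaluation did not converge.

    Mirrors an SCF non-convergence — the conformer is recorded as failed and
    excluded from exported arrays; it never aborts a sampling run.
    """


class CurationError(NmsgenError):
    """Invalid curation input (empty conformer set, inconsistent counts)."""


class AniFormatError(NmsgenError):
    """ANI-style HDF5 file violates the expected record layout."""


class StatsError(NmsgenError):
    """A coverage statistic has nothing to tally (no matching pairs/triples)."""
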