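"""Exception hierarchy for intercoev."""


class IntercoevError(Exception):
    """Base class for all intercoev errors."""


class AlignmentError(IntercoevError):
    """Malformed or inconsistent multiple sequence alignment."""


class PairingError(IntercoevError):
    """Rows of two alignments cannot be paired."""


class SamplingError(IntercoevError):
    """Invalid subsampling request."""


class CorrectionError(IntercoevError):
    """Average product correction is undefined for this matrix."""


class CouplingError(IntercoevError):
    """Mean-field coupling estimation failed (singular covariance)."""


class ConvergenceError(IntercoevError):
    """Iterative two-site marginal matching did not converge."""


class NullModelError(IntercoevError):
    """Null-model P-value transform is undefined for these scores."""


class MappingError(IntercoevError):
    """Alignment column to structure residue mapping failed."""


class TreeError(IntercoevError):
    """Invalid phylogenetic tree or leaf subset."""


class EvaluationError(IntercoevError):
    """Benchmark metric undefined for the given labels."""


class SimulationError(IntercoevError):
    """Invalid synthetic-data configuration."""
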