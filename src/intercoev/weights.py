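"""Identity-based sequence reweighting and effective sequence counts.

Redundant sequences inflate apparent evidence for coevolution.  The
standard remedy weights each sequence by the inverse of the number of
sequences within a fractional-identity threshold ``theta`` of it (itself
included), giving the effective number of sequences

    N_eff = sum_s w_s,   w_s = 1 / |{t : pid(s, t) >= theta}|.

Percent identity ``pid`` is computed over columns where at least one of
the two sequences has a non-gap symbol; positions where both are gaps are
excluded from the denominator so that shared gap blocks do not inflate
identity.

Two conventional defaults are exposed: ``THETA_NEFF = 0.62`` (the
PSICOV-style redundancy threshold used for the N_eff statistic) and
``THETA_DCA = 0.8`` (the mean-field DCA convention used for weighted
frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import GAP_CODE
from .errors import AlignmentError
from .msa import Msa, PairedAlignment, concatenate

THETA_NEFF = 0.62
THETA_DCA = 0.8

_CHUNK = 64


@dataclass
class WeightVector:
    """Per-sequence weights at a given identity threshold."""

    weights: np.ndarray
    theta: float

    @property
    def n_eff(self) -> float:
        """Effective number of sequences (sum of weights)."""
        return float(self.weights.sum())


def pairwise_identity(msa: Msa | np.ndarray) -> np.ndarray:
    """Fraction-identity matrix between all rows of an alignment.

    The denominator for a pair of rows is the number of columns where at
    least one row is a non-gap; matching gap-gap positions are ignored.
    Pairs with an empty denominator get identity 0.
    """
    codes = msa.codes() if isinstance(msa, Msa) else np.asarray(msa)
    n = codes.shape[0]
    is_gap = codes == GAP_CODE
    pid = np.empty((n, n), dtype=float)
    for start in range(0, n, _CHUNK):
        block = codes[start : start + _CHUNK]
        bg = is_gap[start : start + _CHUNK]
        eq = block[:, None, :] == codes[None, :, :]
        both_gap = bg[:, None, :] & is_gap[None, :, :]
        match = (eq & ~both_gap).sum(axis=2)
        denom = (~both_gap).sum(axis=2)
        with np.errstate(invalid="ignore"):
            pid[start : start + _CHUNK] = np.where(denom > 0, match / np.maximum(denom, 1), 0.0)
    return pid


def identity_weights(msa: Msa | np.ndarray, theta: float = THETA_NEFF) -> WeightVector:
    """Inverse-neighborhood-size weights at identity threshold ``theta``."""
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    codes = msa.codes() if isinstance(msa, Msa) else np.asarray(msa)
    if codes.size == 0:
        raise AlignmentError("cannot weight an empty alignment")
    pid = pairwise_identity(codes)
    neighbors = (pid >= theta).sum(axis=1)  # includes self (pid(s,s)=1)
    return WeightVector(1.0 / neighbors, theta)


def neff_over_L(weights: WeightVector, paired: PairedAlignment) -> float:
    """N_eff divided by the total number of columns in both alignments."""
    return weights.n_eff / paired.length


def neff_over_L_from_paired(paired: PairedAlignment, theta: float = THETA_NEFF) -> float:
    """Convenience: weight the concatenated alignment, then N_eff / L."""
    return neff_over_L(identity_weights(concatenate(paired), theta), paired)
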