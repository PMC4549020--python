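"""Column entropies, information-based coevolution statistics, and APC.

For a pair of alignment columns the joint symbol distribution (optionally
sequence-weighted) yields, in bits:

    MI      = H(A) + H(B) - H(A,B)            (mutual information)
    VI      = H(A,B) - MI                     (variation of information)
    MI_j    = MI / H(A,B)                     (joint-entropy normalized)
    MI_Hmin = MI / min(H(A), H(B))            (min-entropy normalized)
    MI_w    = MI computed on weighted counts  (identity-reweighted MI)

VI is a distance: *lower* means stronger coevolution.  Its score
orientation is recorded on the matrix so that ranking code and null
models treat all statistics uniformly.

Gap policy: by default each column pair is evaluated on the rows where
neither column carries a gap or an unknown symbol ("pairwise-complete");
the alternative ``gap-as-state`` keeps gaps as a 21st symbol (unknowns are
still dropped).  Normalized statistics with a zero denominator are masked
rather than forced to 0 — a constant column carries no coevolution
evidence either way.

The average product correction (APC) removes the background row/column
bias of a score matrix:

    corrected(i, j) = S(i, j) - rowmean_i * colmean_j / overallmean,

computed over the inter-protein rectangle only (masked cells excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import GAP_CODE, N_SYMBOLS, UNKNOWN_CODE, encode
from .errors import CorrectionError
from .msa import PairedAlignment
from .weights import WeightVector, identity_weights, THETA_DCA
from .msa import concatenate

GAP_POLICIES = ("pairwise-complete", "gap-as-state")
INFO_METHODS = ("MI", "VI", "MI_j", "MI_Hmin", "MI_w")

#: Ranking orientation per method: does a larger value mean more coevolution?
HIGHER_IS_STRONGER = {
    "MI": True,
    "VI": False,
    "MI_j": True,
    "MI_Hmin": True,
    "MI_w": True,
    "DI": True,
}


@dataclass
class ScoreMatrix:
    """L_A x L_B inter-protein coevolution scores for one method.

    ``values`` holds NaN at masked cells; ``mask`` is True where a cell is
    excluded (degenerate column pair).  ``metadata`` records the gap
    policy, weighting threshold and log base used.
    """

    method: str
    values: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def higher_is_stronger(self) -> bool:
        return HIGHER_IS_STRONGER.get(self.method, True)

    def oriented(self) -> np.ndarray:
        """Values negated if needed so that larger always means stronger."""
        return self.values if self.higher_is_stronger else -self.values

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with 1-based filtered-alignment coordinates."""
        la, lb = self.shape
        i, j = np.meshgrid(np.arange(1, la + 1), np.arange(1, lb + 1), indexing="ij")
        return pd.DataFrame(
            {
                "pos_A": i.ravel(),
                "pos_B": j.ravel(),
                self.method: self.values.ravel(),
                "masked": self.mask.ravel().astype(int),
            }
        )


def _as_codes(column) -> np.ndarray:
    col = np.asarray(column)
    if col.dtype.kind in ("U", "S"):
        col = encode(col.reshape(1, -1)).ravel()
    return col.astype(np.int64)  # int64: the joint index a*q+b must not overflow


def _usable(codes: np.ndarray, gap_policy: str) -> np.ndarray:
    if gap_policy == "pairwise-complete":
        return codes < GAP_CODE
    if gap_policy == "gap-as-state":
        return codes != UNKNOWN_CODE
    raise ValueError(f"unknown gap policy {gap_policy!r}")


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def marginal_entropy(
    column,
    weights: np.ndarray | WeightVector | None = None,
    gap_policy: str = "pairwise-complete",
) -> float:
    """Shannon entropy of one column in bits; NaN if no usable rows."""
    codes = _as_codes(column)
    w = _weight_array(weights, codes.shape[0])
    use = _usable(codes, gap_policy)
    if not use.any():
        return float("nan")
    counts = np.bincount(codes[use], weights=w[use], minlength=N_SYMBOLS)
    return _entropy_from_counts(counts)


def _weight_array(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    if isinstance(weights, WeightVector):
        return weights.weights
    return np.asarray(weights, dtype=float)


def _pair_entropies(
    colA, colB, weights=None, gap_policy: str = "pairwise-complete"
) -> tuple[float, float, float] | None:
    """(H_A, H_B, H_AB) on the shared usable rows, or None if < 2 rows."""
    a = _as_codes(colA)
    b = _as_codes(colB)
    w = _weight_array(weights, a.shape[0])
    use = _usable(a, gap_policy) & _usable(b, gap_policy)
    if use.sum() < 2:
        return None
    a, b, w = a[use], b[use], w[use]
    joint = np.bincount(a * N_SYMBOLS + b, weights=w, minlength=N_SYMBOLS * N_SYMBOLS)
    joint = joint.reshape(N_SYMBOLS, N_SYMBOLS)
    h_a = _entropy_from_counts(joint.sum(axis=1))
    h_b = _entropy_from_counts(joint.sum(axis=0))
    h_ab = _entropy_from_counts(joint.ravel())
    return h_a, h_b, h_ab


def mi(colA, colB, weights=None, gap_policy: str = "pairwise-complete") -> float:
    """Mutual information in bits; NaN if fewer than 2 usable rows."""
    ent = _pair_entropies(colA, colB, weights, gap_policy)
    if ent is None:
        return float("nan")
    h_a, h_b, h_ab = ent
    return max(h_a + h_b - h_ab, 0.0)


def vi(colA, colB, weights=None, gap_policy: str = "pairwise-complete") -> float:
    """Variation of information in bits (lower = stronger coevolution)."""
    ent = _pair_entropies(colA, colB, weights, gap_policy)
    if ent is None:
        return float("nan")
    h_a, h_b, h_ab = ent
    return max(2.0 * h_ab - h_a - h_b, 0.0)


def mi_joint_norm(colA, colB, weights=None, gap_policy: str = "pairwise-complete") -> float:
    """MI / H(A,B) in [0, 1]; NaN when the joint entropy is zero."""
    ent = _pair_entropies(colA, colB, weights, gap_policy)
    if ent is None:
        return float("nan")
    h_a, h_b, h_ab = ent
    if h_ab <= 0.0:
        return float("nan")
    return max(h_a + h_b - h_ab, 0.0) / h_ab


def mi_hmin_norm(colA, colB, weights=None, gap_policy: str = "pairwise-complete") -> float:
    """MI / min(H(A), H(B)) in [0, 1]; NaN when either column is constant."""
    ent = _pair_entropies(colA, colB, weights, gap_policy)
    if ent is None:
        return float("nan")
    h_a, h_b, h_ab = ent
    h_min = min(h_a, h_b)
    if h_min <= 0.0:
        return float("nan")
    return max(h_a + h_b - h_ab, 0.0) / h_min


_STAT_FN = {
    "MI": mi,
    "VI": vi,
    "MI_j": mi_joint_norm,
    "MI_Hmin": mi_hmin_norm,
}


def score_all_pairs(
    paired: PairedAlignment,
    method: str = "MI",
    weights: WeightVector | np.ndarray | None = None,
    gap_policy: str = "pairwise-complete",
    theta_w: float = THETA_DCA,
) -> ScoreMatrix:
    """Score every inter-protein column pair with one statistic.

    ``MI_w`` is MI on identity-reweighted counts; if no weights are given
    they are computed on the concatenated alignment at ``theta_w``.
    Intra-protein pairs are never included.
    """
    if method not in INFO_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {INFO_METHODS}")
    if method == "MI_w":
        if weights is None:
            weights = identity_weights(concatenate(paired), theta_w)
        fn = mi
    else:
        fn = _STAT_FN[method]
    codesA = paired.msaA.codes()
    codesB = paired.msaB.codes()
    la, lb = codesA.shape[1], codesB.shape[1]
    values = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            values[i, j] = fn(codesA[:, i], codesB[:, j], weights, gap_policy)
    mask = np.isnan(values)
    meta = {"gap_policy": gap_policy, "log_base": 2}
    if isinstance(weights, WeightVector):
        meta["theta"] = weights.theta
    return ScoreMatrix(method, values, mask, meta)


def apc_correct(scores: ScoreMatrix) -> ScoreMatrix:
    """Average product correction on the inter-protein rectangle.

    Masked cells are excluded from the row, column and overall means and
    stay masked in the output.
    """
    v = np.ma.masked_array(scores.values, mask=scores.mask)
    overall = v.mean()
    if overall is np.ma.masked or overall == 0:
        raise CorrectionError("overall mean of unmasked scores is zero or undefined")
    row = v.mean(axis=1)
    col = v.mean(axis=0)
    corrected = v - np.ma.outer(row, col) / overall
    out = corrected.filled(np.nan)
    meta = dict(scores.metadata, apc=True)
    return ScoreMatrix(scores.method, out, scores.mask.copy(), meta)


def scores_to_table(matrices: Sequence[ScoreMatrix]) -> pd.DataFrame:
    """Merge several score matrices into one long table (pos_A major)."""
    if not matrices:
        raise ValueError("no score matrices given")
    base = matrices[0].to_frame()[["pos_A", "pos_B"]]
    for m in matrices:
        base[m.method] = m.values.ravel()
    base["masked"] = np.any([m.mask.ravel() for m in matrices], axis=0).astype(int)
    return base
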