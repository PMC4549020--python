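"""Null models converting coevolution scores to per-pair P-values.

Two desk-ready nulls are provided:

* ``empirical`` — the P-value of a score S is the proportion of unmasked
  scores in the matrix that are more extreme (strictly stronger) than S.
  An optional add-one variant, (#{S' > S} + 1) / (M + 1), never returns 0.
* ``normal`` — scores are standardized to Z-scores over the unmasked
  inter-protein cells and compared to the upper tail of the standard
  normal distribution.

Scores are first oriented so that larger always means stronger
coevolution (VI is negated), giving a single monotone contract: P-values
are non-increasing in the oriented score, and tied scores receive tied
P-values.  The null name ``simulated`` is reserved for a future
parametric-bootstrap null and currently rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NullModelError
from .evaluation import ConfusionTable
from .infostats import ScoreMatrix

NULL_MODELS = ("empirical", "normal")


@dataclass
class PValueMatrix:
    """Per-column-pair P-values under a named null model."""

    null: str
    values: np.ndarray
    mask: np.ndarray
    method: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]


def p_empirical(scores: ScoreMatrix, add_one: bool = False) -> PValueMatrix:
    """Empirical-rank P-values: proportion of scores more extreme than S."""
    oriented = scores.oriented()
    flat = oriented[~scores.mask]
    m = flat.size
    if m < 2:
        raise NullModelError("need at least 2 unmasked scores for the empirical null")
    sorted_flat = np.sort(flat)
    values = np.full(scores.values.shape, np.nan)
    obs = oriented[~scores.mask]
    greater = m - np.searchsorted(sorted_flat, obs, side="right")
    if add_one:
        p = (greater + 1.0) / (m + 1.0)
    else:
        p = greater / float(m)
    values[~scores.mask] = p
    return PValueMatrix(
        "empirical", values, scores.mask.copy(), scores.method, {"add_one": add_one, "m": m}
    )


def p_normal(scores: ScoreMatrix) -> PValueMatrix:
    """Upper-tail standard-normal P-values of matrix-wide Z-scores."""
    oriented = scores.oriented()
    flat = oriented[~scores.mask]
    if flat.size < 2:
        raise NullModelError("need at least 2 unmasked scores for the normal null")
    sd = flat.std(ddof=1)
    if sd == 0:
        raise NullModelError("zero variance across unmasked scores")
    z = (oriented - flat.mean()) / sd
    values = np.where(scores.mask, np.nan, stats.norm.sf(z))
    return PValueMatrix("normal", values, scores.mask.copy(), scores.method, {"sd": float(sd)})


def summarize_residue_pvalues(pmatrix: PValueMatrix, axis: str = "A") -> np.ndarray:
    """Most significant (minimum) P per residue along one protein.

    ``axis="A"`` summarizes rows (protein A residues), ``axis="B"``
    columns.  Fully masked residues get NaN.
    """
    if axis not in ("A", "B"):
        raise ValueError("axis must be 'A' or 'B'")
    v = np.ma.masked_array(pmatrix.values, mask=pmatrix.mask)
    summary = v.min(axis=1 if axis == "A" else 0)
    return summary.filled(np.nan)


def threshold_max_precision(
    pvalues: np.ndarray, labels: np.ndarray
) -> tuple[float, ConfusionTable]:
    """P-value cutoff maximizing precision on known positives.

    Predicts positive iff P <= alpha; among cutoffs achieving the maximal
    PPV the one with the most predictions is returned, with its confusion
    table.
    """
    p = np.asarray(pvalues, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = ~np.isnan(p)
    p, y = p[ok], y[ok]
    if not y.any():
        raise NullModelError("no positive labels; precision is undefined")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, p.size + 1)
    # only evaluate at block boundaries (ties predicted together)
    is_boundary = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    idx = np.nonzero(is_boundary)[0]
    ppv = cum_tp[idx] / n_pred[idx]
    best_ppv = ppv.max()
    # ties toward more predictions: last boundary achieving the max
    k = idx[np.nonzero(np.isclose(ppv, best_ppv))[0][-1]]
    alpha = float(p_sorted[k])
    tp = int(cum_tp[k])
    fp = int(n_pred[k] - tp)
    fn = int(y.sum() - tp)
    tn = int(p.size - tp - fp - fn)
    return alpha, ConfusionTable(tp, fp, tn, fn)
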