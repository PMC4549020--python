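"""Mean-field direct coupling analysis over a concatenated paired alignment.

The alignment is modelled with a 21-state Potts model (20 amino acids plus
gap; unknown symbols are treated as gaps).  Sequences are reweighted at an
identity threshold ``theta`` and frequencies regularized with a pseudocount
of weight ``lambda`` (default: equal to the effective sequence count, i.e.
a 50/50 mixture with the uniform distribution):

    f_i(a)     = (lambda/q   + c_i(a))    / (lambda + N_eff)
    f_ij(a,b)  = (lambda/q^2 + c_ij(a,b)) / (lambda + N_eff)   (i != j)

The couplings are the mean-field (naive inverse-Ising) estimate

    e_ij(a,b) = -(C^{-1})_ij(a,b),   C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b)

with the covariance restricted to the first q-1 = 20 states (the gap state
is the gauge reference).  Direct information for a pair of sites is the
mutual information of the re-estimated two-site distribution

    P_dir(a,b) ~ exp(e_ij(a,b)) h_i(a) h_j(b)

whose auxiliary fields h are iterated (damped fixed point) until the
marginals of P_dir match f_i and f_j.  DI is reported in bits and, by
convention for direct methods, with the average product correction applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP_CODE, UNKNOWN_CODE
from .errors import ConvergenceError, CouplingError
from .infostats import ScoreMatrix, apc_correct
from .msa import Msa, PairedAlignment, concatenate
from .weights import THETA_DCA, identity_weights

Q = 21  # 20 amino acids + gap


@dataclass
class CouplingModel:
    """Fitted single/pair frequencies and mean-field couplings."""

    fi: np.ndarray          # (L, q) single-site frequencies
    couplings: np.ndarray   # (L, q-1, L, q-1) e_ij(a,b) for the first q-1 states
    theta: float
    lam: float
    n_eff: float

    @property
    def length(self) -> int:
        return self.fi.shape[0]

    def e_block(self, i: int, j: int) -> np.ndarray:
        """Full (q, q) coupling block with the gauge state padded with zeros."""
        block = np.zeros((Q, Q))
        block[: Q - 1, : Q - 1] = self.couplings[i, :, j, :]
        return block


def _dca_codes(msa: Msa | np.ndarray) -> np.ndarray:
    codes = msa.codes() if isinstance(msa, Msa) else np.asarray(msa).copy()
    codes = codes.astype(np.int64)
    codes[codes == UNKNOWN_CODE] = GAP_CODE
    return codes


def fit_couplings(
    concat: Msa | np.ndarray,
    theta: float = THETA_DCA,
    lam: float | None = None,
) -> CouplingModel:
    """Fit the mean-field Potts couplings on a concatenated alignment."""
    codes = _dca_codes(concat)
    n, L = codes.shape
    if n < 2:
        raise CouplingError("need at least 2 sequences to fit couplings")
    w = identity_weights(codes, theta).weights
    n_eff = float(w.sum())
    if lam is None:
        lam = n_eff

    # one-hot encoding restricted to the first q-1 states
    onehot = np.zeros((n, L, Q - 1))
    rows = np.arange(n)
    for a in range(Q - 1):
        onehot[:, :, a] = codes == a
    flat = onehot.reshape(n, L * (Q - 1))

    denom = lam + n_eff
    fi_full = np.zeros((L, Q))
    for a in range(Q):
        fi_full[:, a] = (lam / Q + (w[:, None] * (codes == a)).sum(axis=0)) / denom

    pij = (flat.T * w) @ flat  # weighted co-occurrence counts
    pij = (lam / Q**2 + pij) / denom
    fi = fi_full[:, : Q - 1].reshape(L * (Q - 1))
    cov = pij - np.outer(fi, fi)
    # the diagonal site blocks are f_i(a) delta_ab - f_i(a) f_i(b)
    for i in range(L):
        s = slice(i * (Q - 1), (i + 1) * (Q - 1))
        block = np.diag(fi_full[i, : Q - 1])
        # pseudocount for the diagonal block uses lam/q on the diagonal
        diag_counts = np.zeros((Q - 1, Q - 1))
        np.fill_diagonal(diag_counts, (lam / Q + ((w[:, None]) * onehot[:, i, :]).sum(axis=0)) / denom)
        cov[s, s] = diag_counts - np.outer(fi_full[i, : Q - 1], fi_full[i, : Q - 1])

    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        try:
            inv = np.linalg.inv(cov + 1e-8 * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise CouplingError(
                "covariance matrix is singular; raise the pseudocount lambda"
            ) from exc
    couplings = (-inv).reshape(L, Q - 1, L, Q - 1)
    return CouplingModel(fi_full, couplings, theta, float(lam), n_eff)


def _two_site_fields(
    W: np.ndarray, fi: np.ndarray, fj: np.ndarray, tol: float, max_iter: int, damping: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Damped fixed point for the auxiliary fields of the two-site model.

    The residual is the maximal mismatch between the marginals of the
    implied two-site distribution and the target frequencies.
    """
    mu1 = np.full(Q, 1.0 / Q)
    mu2 = np.full(Q, 1.0 / Q)
    resid = np.inf
    for _ in range(max_iter):
        new1 = fi / (W @ mu2)
        new1 /= new1.sum()
        new2 = fj / (W.T @ mu1)
        new2 /= new2.sum()
        mu1 = damping * mu1 + (1 - damping) * new1
        mu2 = damping * mu2 + (1 - damping) * new2
        pdir = W * np.outer(mu1, mu2)
        pdir /= pdir.sum()
        resid = max(
            np.abs(pdir.sum(axis=1) - fi).max(), np.abs(pdir.sum(axis=0) - fj).max()
        )
        if resid < tol:
            break
    return mu1, mu2, resid


def direct_information(
    model: CouplingModel,
    i: int,
    j: int,
    tol: float = 1e-6,
    max_iter: int = 5000,
    damping: float = 0.5,
) -> float:
    """Direct information (bits) between sites i and j (0-based)."""
    if i == j:
        raise ValueError("direct information requires two distinct sites")
    W = np.exp(model.e_block(i, j))
    fi = model.fi[i]
    fj = model.fi[j]
    mu1, mu2, resid = _two_site_fields(W, fi, fj, tol, max_iter, damping)
    if not resid < tol:
        raise ConvergenceError(
            f"two-site marginal matching did not converge (residual {resid:.2e})"
        )
    pdir = W * np.outer(mu1, mu2)
    pdir /= pdir.sum()
    indep = np.outer(fi, fj)
    return float((pdir * np.log2(pdir / indep)).sum())


def di_matrix(
    paired: PairedAlignment,
    theta: float = THETA_DCA,
    lam: float | None = None,
    apc: bool = True,
    tol: float = 1e-6,
    max_iter: int = 5000,
    damping: float = 0.5,
) -> ScoreMatrix:
    """Inter-protein rectangle of DI values from one global model fit."""
    model = fit_couplings(concatenate(paired), theta, lam)
    la = paired.msaA.length
    lb = paired.msaB.length
    values = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            values[i, j] = direct_information(model, i, la + j, tol, max_iter, damping)
    mask = np.zeros_like(values, dtype=bool)
    meta = {
        "theta": theta,
        "lambda": model.lam,
        "n_eff": model.n_eff,
        "log_base": 2,
        "tol": tol,
        "max_iter": max_iter,
        "damping": damping,
        "apc": apc,
    }
    sm = ScoreMatrix("DI", values, mask, meta)
    return apc_correct(sm) if apc else sm
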