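"""Generator matrices and matrix-exponential transition probabilities.

The transition-probability matrix over an interval of length ``dt`` of a
time-homogeneous Markov process with generator Q is ``P(dt) = exp(Q dt)``.
The default exponential is scipy's Padé scaling-and-squaring; a
uniformization (randomisation) series is available both as an independent
cross-check and as a fallback if the Padé route fails.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy.linalg import expm as _pade_expm

from .params import ModelParameters
from .states import StateSpace

__all__ = ["build_generator", "transition_matrix", "uniformization_expm"]

log = logging.getLogger(__name__)


def build_generator(
    params: ModelParameters,
    z: Mapping[str, float],
    space: StateSpace,
) -> np.ndarray:
    """Intensity matrix Q for covariate vector ``z``.

    ``Q[r, s] = λ_rs · exp(β_rs' z)`` for allowed ``(r, s)``; the diagonal is
    set so rows sum to zero; the resolved state's row is identically zero.

    Raises
    ------
    KeyError
        If ``z`` lacks a covariate named in some β_rs (the message names the
        covariate and the transition).
    """
    n = space.n_states
    idx = {s: i for i, s in enumerate(space.states)}
    Q = np.zeros((n, n))
    for (r, s), loglam in params.log_lambda.items():
        eta = loglam
        for cov, coef in params.beta.get((r, s), {}).items():
            try:
                eta += coef * z[cov]
            except KeyError:
                raise KeyError(
                    f"covariate {cov!r} required for transition {r}->{s} "
                    "is missing from the covariate vector"
                ) from None
        Q[idx[r], idx[s]] = np.exp(eta)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float, method: str = "pade") -> np.ndarray:
    """``P(dt) = exp(Q · dt)``; rows are probability vectors.

    ``method`` is ``"pade"`` (scipy scaling-and-squaring, default) or
    ``"uniformization"``.  A numerical failure of the Padé route falls back
    to uniformization with a log message.
    """
    if dt < 0:
        raise ValueError(f"interval length must be non-negative, got {dt}")
    if dt == 0:
        return np.eye(Q.shape[0])
    if method == "uniformization":
        return uniformization_expm(Q, dt)
    if method != "pade":
        raise ValueError(f"unknown method {method!r}")
    P = _pade_expm(Q * dt)
    if not np.all(np.isfinite(P)):
        log.warning("Padé matrix exponential failed; falling back to uniformization")
        P = uniformization_expm(Q, dt)
    # clip tiny negatives from roundoff
    np.clip(P, 0.0, None, out=P)
    return P


def uniformization_expm(Q: np.ndarray, dt: float, tol: float = 1e-14) -> np.ndarray:
    """exp(Q dt) by uniformization: a Poisson-weighted power series.

    With ``mu = max_r (-Q[r,r])`` and stochastic ``B = I + Q/mu``,
    ``exp(Q dt) = Σ_k e^{-mu dt} (mu dt)^k / k! · B^k``.  All terms are
    non-negative, so the series is numerically benign; it is truncated when
    the remaining Poisson mass drops below ``tol``.  Very stiff generators
    (large mu·dt) are handled by halving dt until the series is short and
    squaring the result back up.
    """
    n = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu == 0.0 or dt == 0.0:
        return np.eye(n)
    n_square = 0
    while mu * dt > 64.0:
        dt /= 2.0
        n_square += 1
    B = np.eye(n) + Q / mu
    rate = mu * dt
    term = np.exp(-rate)  # Poisson pmf at k=0
    acc = term * np.eye(n)
    Bk = np.eye(n)
    cum = term
    k = 0
    while 1.0 - cum > tol:
        k += 1
        Bk = Bk @ B
        term *= rate / k
        acc += term * Bk
        cum += term
        if k > 100_000:  # pragma: no cover - safety stop
            raise RuntimeError("uniformization series failed to converge")
    for _ in range(n_square):
        acc = acc @ acc
    return acc
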