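"""Maximum-likelihood inference for the latent-resolution multistate model.

Estimation maximises the marginal panel likelihood over (log λ, β) with a
quasi-Newton optimiser; the covariance of the estimator comes from the
inverse numerical Hessian at the optimum.  The existence of a resolved
subpopulation is a hypothesis on the boundary of the parameter space
(λ_{D0→R} = 0), so its likelihood-ratio statistic is referred to a 50:50
mixture of a χ²₁ distribution and a point mass at zero rather than a plain
χ²₁.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess2

from .data import SubjectHistory
from .generator import build_generator, transition_matrix
from .likelihood import PanelLikelihood
from .params import ModelParameters
from .states import StateSpace

__all__ = [
    "FitResult",
    "fit_mle",
    "wald_intervals",
    "format_estimate",
    "boundary_lrt",
    "resolution_probability",
]

log = logging.getLogger(__name__)

#: Default optimiser settings.  ``ftol`` is the relative log-likelihood
#: change at which the quasi-Newton iteration stops; log-baselines are kept
#: in a wide box so flat directions (e.g. a resolution rate the data cannot
#: identify) do not wander off to ±∞.
DEFAULT_OPTIONS: dict = {
    "maxiter": 500,
    "ftol": 1e-8,
    "hessian_step": 1e-4,
    "loglam_bounds": (-20.0, 10.0),
}


@dataclass
class FitResult:
    """MLE Θ̂ with covariance and convergence diagnostics."""

    theta_hat: ModelParameters
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    n_subjects: int
    n_observations: int
    param_names: list[str] = field(default_factory=list)
    space: StateSpace | None = None
    n_iter: int = 0
    message: str = ""

    @property
    def theta_vector(self) -> np.ndarray:
        return self.theta_hat.pack(self.space)

    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))


def fit_mle(
    dataset: Sequence[SubjectHistory],
    space: StateSpace,
    init: ModelParameters,
    regime: str = "partial",
    options: Mapping | None = None,
    ambiguous_split: tuple[float, float] | None = None,
) -> FitResult:
    """Maximise the marginal panel likelihood over (log λ, β).

    ``regime="complete"`` asserts that every observed code identifies its
    latent state (revealed labels); ``"partial"`` allows ambiguous
    symptom-free codes, which are marginalised over {R, D0}.  The fit is
    deterministic given (dataset, init, options).  Non-convergence flags the
    result rather than raising; a singular Hessian leaves ``vcov`` as None
    with a warning (expected when a boundary rate is weakly identified).
    """
    if regime not in ("complete", "partial"):
        raise ValueError(f"regime must be 'complete' or 'partial', got {regime!r}")
    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})
    init.validate(space)

    if regime == "complete":
        for subj in dataset:
            for obs in subj.observations:
                if len(space.censored_set(obs.code)) != 1:
                    raise ValueError(
                        f"regime='complete' but subject {subj.subject_id!r} has the "
                        f"ambiguous code {obs.code!r} at t={obs.time}"
                    )

    ev = PanelLikelihood(dataset, space, ambiguous_split)
    x0 = init.pack(space)
    n_lam = len(init.log_lambda)

    def negloglik(x: np.ndarray) -> float:
        val = ev.total(init.unpack(x, space))
        return np.inf if not np.isfinite(val) else -val

    lo, hi = opts["loglam_bounds"]
    bounds = [(lo, hi)] * n_lam + [(None, None)] * (x0.size - n_lam)
    scipy_opts = {"maxiter": opts["maxiter"], "ftol": opts["ftol"]}
    if "gtol" in opts:
        scipy_opts["gtol"] = opts["gtol"]
    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        jac=opts.get("jac", "2-point"), options=scipy_opts
    )

    theta_hat = init.unpack(res.x, space)
    vcov = _vcov_from_hessian(negloglik, res.x, opts["hessian_step"])
    return FitResult(
        theta_hat=theta_hat,
        vcov=vcov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_subjects=ev.n_subjects,
        n_observations=ev.n_observations,
        param_names=init.free_names(space),
        space=space,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def _vcov_from_hessian(negloglik, x_opt: np.ndarray, step: float) -> np.ndarray | None:
    """Inverse central-difference Hessian of the negative log-likelihood."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess2(x_opt, negloglik, epsilon=step)
        H = 0.5 * (H + H.T)
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
            raise np.linalg.LinAlgError("non-positive-definite Hessian")
    except np.linalg.LinAlgError as err:
        log.warning("covariance unavailable: %s", err)
        return None
    return 0.5 * (vcov + vcov.T)


def wald_intervals(fit: FitResult, level: float = 0.95) -> dict[str, tuple[float, float, float]]:
    """Per-parameter (estimate, lower, upper) Wald intervals.

    Baseline intensities are estimated on the log scale, so their symmetric
    Wald interval is exponentiated — the reported interval for λ is
    (exp(θ̂ − z·se), exp(θ̂ + z·se)) and is multiplicatively symmetric about
    the estimate.  β coefficients are reported on their natural scale.
    Returns an empty dict when the fit has no covariance.
    """
    if fit.vcov is None:
        return {}
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.se()
    out: dict[str, tuple[float, float, float]] = {}
    for name, est, s in zip(fit.param_names, fit.theta_vector, se):
        lo, hi = est - z * s, est + z * s
        if name.startswith("loglam_"):
            out[name.removeprefix("loglam_")] = (np.exp(est), np.exp(lo), np.exp(hi))
        else:
            out[name.removeprefix("beta_")] = (est, lo, hi)
    return out


def format_estimate(estimate: float, lower: float, upper: float) -> str:
    """Render ``estimate (lower, upper)`` to two significant figures."""
    return f"{estimate:.2g} ({lower:.2g}, {upper:.2g})"


def boundary_lrt(
    loglik_full: float, loglik_null: float, tol: float | None = None
) -> tuple[float, float]:
    """Likelihood-ratio test of a rate pinned at the boundary of its space.

    The null (no resolution transition) is nested in the full model with the
    rate on the boundary λ = 0, so under the null the LR statistic
    T = 2(ℓ_full − ℓ_null) is asymptotically a 50:50 mixture of a point mass
    at zero and χ²₁.  Returns (T, p) with T clipped at zero; p = 1 when
    T = 0 and p = 0.5·P(χ²₁ ≥ T) otherwise.

    ``tol`` absorbs optimiser noise when the null attains the maximum; the
    default is 1e-6 relative to the log-likelihood magnitude.  A null
    log-likelihood above the full model's beyond that is an error (the null
    must be nested).
    """
    if tol is None:
        tol = 1e-6 * max(1.0, abs(loglik_full))
    if loglik_null > loglik_full + tol:
        raise ValueError(
            f"null log-likelihood ({loglik_null}) exceeds the full model's "
            f"({loglik_full}); the null must be nested"
        )
    T = max(0.0, 2.0 * (loglik_full - loglik_null))
    if T < 2.0 * tol:  # differences below optimiser noise count as a boundary tie
        T = 0.0
    p = 1.0 if T == 0.0 else 0.5 * float(stats.chi2.sf(T, df=1))
    return T, p


@dataclass(frozen=True)
class ResolutionEstimate:
    estimate: float
    lower: float | None
    upper: float | None


def resolution_probability(
    fit: FitResult,
    s0: str,
    t: float,
    z: Mapping[str, float] | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ResolutionEstimate:
    """Probability that a subject starting in ``s0`` has resolved before ``t``.

    The point estimate is the (s0, R) entry of exp(Q(Θ̂, z)·t).  The
    confidence interval is obtained by parametric simulation from the
    estimator's asymptotic normal distribution on the working (log λ, β)
    scale: ``n_draws`` parameter vectors are sampled from N(Θ̂, vcov), the
    same transition-probability functional is evaluated at each, and the
    2.5/97.5 percentiles are reported.  Deterministic given ``seed``; the
    interval is absent when the fit carries no covariance.
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    space = fit.space
    z = dict(z or {})
    if s0 == space.resolved:
        return ResolutionEstimate(1.0, 1.0, 1.0)

    i0, iR = space.index(s0), space.index(space.resolved)

    def prob(params: ModelParameters) -> float:
        Q = build_generator(params, z, space)
        return float(transition_matrix(Q, t)[i0, iR])

    point = prob(fit.theta_hat)
    if fit.vcov is None:
        return ResolutionEstimate(point, None, None)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.theta_vector, fit.vcov, size=n_draws)
    vals = np.array([prob(fit.theta_hat.unpack(x, space)) for x in draws])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return ResolutionEstimate(point, float(lo), float(hi))
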