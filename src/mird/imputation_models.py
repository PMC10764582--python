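"""Imputation models fitted to the retrieved-dropout (RD) subset.

Three model families provide the conditional survival function used to
invert imputed event times:

* a Cox PH model refit on bootstrap resamples of the RD subset (the
  non-parametric route);
* a piecewise-exponential PH model (constant hazard on each interval
  between cut points);
* a Weibull accelerated-failure-time model, ``log T = gamma0 + Z gamma +
  sigma * eps`` with Gumbel ``eps``, equivalent to a Weibull PH model with
  ``beta = -gamma / sigma``.

"Proper" imputations draw one parameter vector per imputation, either by
refitting to a bootstrap resample (Cox) or by sampling from the
multivariate-normal large-sample distribution of the MLE (parametric
models).  Positivity-constrained components (hazards, the AFT scale) are
sampled on the log scale so every draw is a valid model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._cox import CoxFit, cox_fit
from ._rng import STREAM_BOOTSTRAP, STREAM_MODEL, stream
from .exceptions import DegenerateDataError, FitError
from .trial_data import TrialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CoxRdFit",
    "PweFit",
    "WeibullAftFit",
    "ParameterDraw",
    "fit_cox_rd",
    "bootstrap_refits",
    "fit_pwe",
    "fit_weibull_aft",
    "draw_parameters_mle",
    "predict_conditional_survival",
]


# ---------------------------------------------------------------------------
# Cox on the RD subset


@dataclass
class CoxRdFit:
    """Cox PH fit on the RD subset (or one bootstrap resample of it)."""

    fit: CoxFit
    covariates: tuple

    @property
    def beta_hat(self) -> np.ndarray:
        return self.fit.beta

    def survival(self, times, z) -> np.ndarray:
        return self.fit.survival(times, z)


def _arrays(rd: TrialDataset, covariates: Sequence[str] | None):
    covs = rd.covariates if covariates is None else [c for c in covariates if c != "trt"]
    time = rd.df["T_obs"].to_numpy(dtype=float)
    event = rd.df["E"].to_numpy(dtype=int)
    Z = rd.df[["trt"] + list(covs)].to_numpy(dtype=float)
    return time, event, Z, ("trt", *covs)


def fit_cox_rd(rd: TrialDataset, covariates: Sequence[str] | None = None) -> CoxRdFit:
    """Cox PH model on the RD subset, adjusting for treatment and covariates."""
    time, event, Z, names = _arrays(rd, covariates)
    if event.sum() < 1:
        raise DegenerateDataError(
            "RD subset has zero events; the RD-based imputation model cannot be "
            "fit — supply more follow-up or choose a different analysis"
        )
    return CoxRdFit(fit=cox_fit(time, event, Z), covariates=names)


def bootstrap_refits(
    rd: TrialDataset,
    B: int,
    seed: int,
    resample: bool = True,
    max_retries: int = 100,
) -> list[CoxRdFit]:
    """B Cox fits on with-replacement resamples of the RD subset.

    ``resample=False`` is a test hook that refits the original subset B
    times.  A resample with zero events is redrawn (bounded retries).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    time, event, Z, names = _arrays(rd, None)
    n = len(time)
    rng = stream(seed, STREAM_BOOTSTRAP)
    fits = []
    for b in range(B):
        if not resample:
            fits.append(CoxRdFit(fit=cox_fit(time, event, Z), covariates=names))
            continue
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if event[idx].sum() >= 1 and np.all(np.ptp(Z[idx], axis=0) > 0):
                break
            logger.warning("bootstrap resample %d redrawn (attempt %d)", b, attempt + 1)
        else:
            raise DegenerateDataError(
                f"could not draw an event-containing bootstrap resample in "
                f"{max_retries} tries"
            )
        fits.append(CoxRdFit(fit=cox_fit(time[idx], event[idx], Z[idx]), covariates=names))
    return fits


def predict_conditional_survival(fit: CoxRdFit, z, times) -> np.ndarray:
    """S(t | z) on a sorted, non-negative grid; S(0) = 1, non-increasing.

    Beyond the last observed RD time the step function carries its last
    value forward (imputed levels landing there are censored at the
    horizon anyway).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted ascending and non-negative")
    last = fit.fit.event_times[-1] if len(fit.fit.event_times) else np.inf
    if times.size and times[-1] > last:
        logger.debug("survival requested beyond last RD event time; carrying forward")
    return fit.survival(times, z)


# ---------------------------------------------------------------------------
# Piecewise exponential


@dataclass
class PweFit:
    """Piecewise-exponential PH fit.

    ``lam[u]`` is the hazard on ``[tau[u-1], tau[u])`` with ``tau`` the
    interior cut points (``tau_0 = 0`` and ``tau_M = inf`` implicit).
    ``cov`` is the joint covariance of ``(log lam[free], beta)`` from the
    observed information; ``free`` marks intervals with at least one event
    (hazards of event-free intervals are 0 and excluded — only reachable in
    ``allow_empty`` mode).
    """

    lam: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    cov: np.ndarray
    covariates: tuple
    free: np.ndarray = field(default=None)
    loglik: float = np.nan
    n_events: int = 0

    def __post_init__(self):
        if self.free is None:
            self.free = np.ones(len(self.lam), dtype=bool)

    @property
    def M(self) -> int:
        return len(self.lam)

    def baseline_cumhaz(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        edges = np.concatenate([[0.0], self.tau])
        widths = np.clip(t[..., None] - edges, 0.0, None)
        caps = np.concatenate([np.diff(edges), [np.inf]])
        return np.sum(self.lam * np.minimum(widths, caps), axis=-1)

    def survival(self, t, z) -> np.ndarray:
        lp = float(np.dot(np.asarray(z, dtype=float), self.beta))
        return np.exp(-self.baseline_cumhaz(t) * np.exp(lp))


def resolve_cutpoints(rd: TrialDataset, cutpoints) -> np.ndarray:
    """Interior cut points; ``"quartiles"`` = 25/50/75% of RD observed times."""
    if isinstance(cutpoints, str):
        if cutpoints != "quartiles":
            raise ValueError(f"unknown cut-point rule {cutpoints!r}")
        t = rd.df["T_obs"].to_numpy(dtype=float)
        tau = np.quantile(t, [0.25, 0.5, 0.75])
    else:
        tau = np.asarray(cutpoints, dtype=float)
    if tau.size and (np.any(np.diff(tau) <= 0) or tau[0] <= 0):
        raise ValueError("cut points must be strictly increasing and positive")
    return tau


def _pwe_sufficients(time, event, tau):
    """Per-interval exposure matrix and event-count matrix."""
    edges = np.concatenate([[0.0], tau, [np.inf]])
    M = len(edges) - 1
    lo, hi = edges[:-1], edges[1:]
    expo = np.clip(np.minimum(time[:, None], hi) - lo, 0.0, None)   # (n, M)
    which = np.searchsorted(tau, time, side="right")                # event interval
    d = np.zeros((len(time), M))
    d[np.arange(len(time)), which] = event
    return expo, d, M


def fit_pwe(
    rd: TrialDataset,
    cutpoints="quartiles",
    covariates: Sequence[str] | None = None,
    allow_empty: bool = False,
    max_iter: int = 100,
) -> PweFit:
    """MLE of the piecewise-exponential PH model on the RD subset.

    Newton–Raphson on ``(log lam, beta)``; the covariance is the inverse
    observed information over the full parameter vector.  By default every
    interval must contain at least one event; ``allow_empty=True`` instead
    pins event-free intervals at hazard 0 (the behavior of R's ``eha``
    fits, useful together with partial-covariance sampling).
    """
    time, event, Z, names = _arrays(rd, covariates)
    tau = resolve_cutpoints(rd, cutpoints)
    expo, dmat, M = _pwe_sufficients(time, event, tau)
    D_u = dmat.sum(axis=0)
    E_u = expo.sum(axis=0)
    if np.any(E_u <= 0):
        u = int(np.flatnonzero(E_u <= 0)[0])
        raise DegenerateDataError(f"interval {u} has zero exposure")
    free = D_u > 0
    if not allow_empty and not free.all():
        u = int(np.flatnonzero(~free)[0])
        raise DegenerateDataError(
            f"interval {u} contains zero events; merge cut points or pass "
            f"allow_empty=True (hazard pinned at 0)"
        )
    if event.sum() < 1:
        raise DegenerateDataError("RD subset has zero events")

    p = Z.shape[1]
    nf = int(free.sum())
    # start at the no-covariate closed form
    lam = np.where(free, np.where(E_u > 0, np.maximum(D_u, 0.5) / E_u, 0.0), 0.0)
    omega = np.log(np.where(free, lam, 1.0))[free]
    beta = np.zeros(p)
    x = np.concatenate([omega, beta])

    def unpack(x):
        lam_full = np.zeros(M)
        lam_full[free] = np.exp(x[:nf])
        return lam_full, x[nf:]

    def ll_grad_hess(x):
        lam_full, beta = unpack(x)
        theta = np.exp(Z @ beta)                     # (n,)
        lam_expo = expo * lam_full                   # (n, M)
        Lam0 = lam_expo.sum(axis=1)                  # baseline cumhaz at t_i
        ll = float(
            np.dot(D_u[free], x[:nf])
            + (event * (Z @ beta)).sum()
            - np.dot(theta, Lam0)
        )
        w = theta[:, None] * lam_expo                # (n, M)
        W_u = w.sum(axis=0)                          # sum_i theta_i lam_u e_iu
        g_omega = (D_u - W_u)[free]
        g_beta = Z.T @ (event - theta * Lam0)
        grad = np.concatenate([g_omega, g_beta])
        H = np.zeros((nf + p, nf + p))
        H[:nf, :nf] = np.diag(-W_u[free])
        cross = -(w.T @ Z)                           # (M, p)
        H[:nf, nf:] = cross[free]
        H[nf:, :nf] = cross[free].T
        H[nf:, nf:] = -(Z * (theta * Lam0)[:, None]).T @ Z
        return ll, grad, H

    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, grad, H = ll_grad_hess(x)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in piecewise-exponential fit") from exc
        scale = 1.0
        for _ in range(30):
            cand = x + scale * step
            cand[nf:] = np.clip(cand[nf:], -20, 20)
            ll_new, _, _ = ll_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        x = cand
        if abs(ll_new - ll_prev) < 1e-12 * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll_new
    else:
        logger.warning("piecewise-exponential Newton did not fully converge")
    ll, grad, H = ll_grad_hess(x)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information in piecewise-exponential fit") from exc
    lam_full, beta = unpack(x)
    return PweFit(
        lam=lam_full,
        tau=tau,
        beta=beta,
        cov=cov,
        covariates=names,
        free=free,
        loglik=ll,
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# Weibull AFT


@dataclass
class WeibullAftFit:
    """Weibull AFT fit: ``log T = gamma0 + Z gamma + sigma * eps``.

    ``cov`` is the covariance of ``(gamma0, gamma, log sigma)`` from the
    observed information.
    """

    sigma: float
    gamma0: float
    gamma: np.ndarray
    cov: np.ndarray
    covariates: tuple
    loglik: float = np.nan
    n_events: int = 0

    @property
    def beta_ph(self) -> np.ndarray:
        """PH-scale coefficients ``beta = -gamma / sigma``."""
        return -self.gamma / self.sigma

    def linear_predictor(self, z) -> float:
        return float(self.gamma0 + np.dot(np.asarray(z, dtype=float), self.gamma))

    def survival(self, t, z) -> np.ndarray:
        eta = self.linear_predictor(z)
        t = np.asarray(t, dtype=float)
        return np.exp(-np.exp(-eta / self.sigma) * np.power(t, 1.0 / self.sigma))


def fit_weibull_aft(
    rd: TrialDataset,
    covariates: Sequence[str] | None = None,
    max_iter: int = 200,
    fixed_sigma: float | None = None,
) -> WeibullAftFit:
    """MLE of the Weibull AFT model on the RD subset.

    Newton–Raphson on ``(gamma0, gamma, log sigma)`` with the analytic
    Gumbel gradient and Hessian; covariance from the observed information.
    ``fixed_sigma`` pins the scale (``fixed_sigma=1`` is the exponential
    submodel); the pinned component then has zero variance.
    """
    time, event, Z, names = _arrays(rd, covariates)
    if event.sum() < 2:
        raise DegenerateDataError("Weibull AFT fit needs at least 2 events")
    logt = np.log(time)
    p = Z.shape[1]
    Zt = np.column_stack([np.ones(len(time)), Z])  # intercept-augmented design

    def ll_grad_hess(x):
        a, s = x[: 1 + p], x[1 + p]
        sigma = np.exp(s)
        w = (logt - Zt @ a) / sigma
        ew = np.exp(np.clip(w, -500, 500))
        ll = float(np.sum(event * (w - s - logt)) - np.sum(ew))
        r = event - ew
        g_a = -(Zt.T @ r) / sigma
        g_s = float(-np.sum(event) - np.sum(w * r))
        grad = np.concatenate([g_a, [g_s]])
        H = np.zeros((p + 2, p + 2))
        H[: 1 + p, : 1 + p] = -(Zt * ew[:, None]).T @ Zt / sigma**2
        cross = (Zt.T @ (r - w * ew)) / sigma
        H[: 1 + p, 1 + p] = cross
        H[1 + p, : 1 + p] = cross
        H[1 + p, 1 + p] = float(np.sum(w * r) - np.sum(w**2 * ew))
        return ll, grad, H

    # exponential-MLE start: log mean time-to-event, sigma = 1
    x = np.concatenate([[np.log(time.sum() / event.sum())], np.zeros(p), [0.0]])
    nparam = p + 2
    free = np.ones(nparam, dtype=bool)
    if fixed_sigma is not None:
        x[1 + p] = np.log(fixed_sigma)
        free[1 + p] = False
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad_full, H_full = ll_grad_hess(x)
        grad = grad_full[free]
        H = H_full[np.ix_(free, free)]
        # damp the Hessian to negative definite so the step always ascends
        top = float(np.linalg.eigvalsh(H)[-1])
        if top > -1e-10:
            H = H - (top + 1e-6 * max(1.0, -np.trace(H) / len(x))) * np.eye(len(H))
        try:
            step_free = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in Weibull AFT fit") from exc
        if not np.all(np.isfinite(step_free)):
            raise FitError("non-finite Newton step in Weibull AFT fit")
        step = np.zeros(nparam)
        step[free] = step_free
        scale = 1.0
        for _ in range(40):
            cand = x + scale * step
            cand[: 1 + p] = np.clip(cand[: 1 + p], -500, 500)
            cand[1 + p] = np.clip(cand[1 + p], -10, 10)
            ll_new, _, _ = ll_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        x = cand
        if abs(ll_new - ll_prev) < 1e-12 * (abs(ll_prev) + 1.0):
            converged = True
            break
        ll_prev = ll_new
    ll, grad_full, H_full = ll_grad_hess(x)
    if not converged and np.linalg.norm(grad_full[free]) > 1e-4 * (1 + len(time)):
        raise FitError("Weibull AFT fit did not converge")
    cov = np.zeros((nparam, nparam))
    try:
        cov[np.ix_(free, free)] = np.linalg.inv(-H_full[np.ix_(free, free)])
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information in Weibull AFT fit") from exc
    return WeibullAftFit(
        sigma=float(np.exp(x[1 + p])),
        gamma0=float(x[0]),
        gamma=x[1 : 1 + p],
        cov=cov,
        covariates=names,
        loglik=ll,
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# proper parameter draws


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled parameter vector for imputation ``b``."""

    kind: str                   # "pwe" | "weibull"
    b: int
    lam: np.ndarray | None = None
    tau: np.ndarray | None = None
    beta: np.ndarray | None = None
    sigma: float | None = None
    gamma0: float | None = None
    gamma: np.ndarray | None = None

    def survival(self, t, z) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        z = np.asarray(z, dtype=float)
        if self.kind == "pwe":
            edges = np.concatenate([[0.0], self.tau])
            widths = np.clip(t[..., None] - edges, 0.0, None)
            caps = np.concatenate([np.diff(edges), [np.inf]])
            H0 = np.sum(self.lam * np.minimum(widths, caps), axis=-1)
            return np.exp(-H0 * np.exp(float(z @ self.beta)))
        eta = self.gamma0 + float(z @ self.gamma)
        return np.exp(-np.exp(-eta / self.sigma) * np.power(t, 1.0 / self.sigma))


def _mvn_draws(mean, cov, B, rng, repair_psd=False):
    cov = np.asarray(cov, dtype=float)
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    floor = -1e-8 * max(vals.max(), 1.0)
    if vals.min() < floor:
        if not repair_psd:
            raise FitError(
                "covariance matrix is not positive semi-definite; pass "
                "repair_psd=True to project onto the nearest PSD matrix"
            )
        logger.warning("projecting covariance onto nearest PSD matrix")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((B, len(mean)))
    return np.asarray(mean) + z @ root.T


def draw_parameters_mle(
    fit: PweFit | WeibullAftFit,
    B: int,
    seed: int,
    partial_cov: bool = False,
    repair_psd: bool = False,
) -> list[ParameterDraw]:
    """B multivariate-normal draws around the MLE ("proper" imputation).

    Hazards and the AFT scale are sampled on the log scale.  For the
    piecewise-exponential model ``partial_cov=True`` reproduces the
    restricted behavior of R's ``eha`` implementation: only ``beta`` is
    sampled and the baseline hazards are held at their MLE.
    """
    rng = stream(seed, STREAM_MODEL)
    draws: list[ParameterDraw] = []
    if isinstance(fit, PweFit):
        nf = int(fit.free.sum())
        p = len(fit.beta)
        if partial_cov:
            mean = fit.beta
            cov = fit.cov[nf:, nf:]
            samples = _mvn_draws(mean, cov, B, rng, repair_psd)
            for b in range(B):
                draws.append(ParameterDraw(kind="pwe", b=b + 1, lam=fit.lam.copy(),
                                           tau=fit.tau, beta=samples[b]))
        else:
            if not fit.free.all():
                raise FitError(
                    "full-covariance sampling requires every interval to "
                    "contain events; refit with different cut points or use "
                    "partial_cov=True"
                )
            mean = np.concatenate([np.log(fit.lam), fit.beta])
            samples = _mvn_draws(mean, fit.cov, B, rng, repair_psd)
            for b in range(B):
                draws.append(ParameterDraw(kind="pwe", b=b + 1,
                                           lam=np.exp(samples[b, :nf]),
                                           tau=fit.tau, beta=samples[b, nf:]))
        return draws
    if isinstance(fit, WeibullAftFit):
        p = len(fit.gamma)
        mean = np.concatenate([[fit.gamma0], fit.gamma, [np.log(fit.sigma)]])
        samples = _mvn_draws(mean, fit.cov, B, rng, repair_psd)
        for b in range(B):
            draws.append(ParameterDraw(kind="weibull", b=b + 1,
                                       sigma=float(np.exp(samples[b, 1 + p])),
                                       gamma0=float(samples[b, 0]),
                                       gamma=samples[b, 1 : 1 + p]))
        return draws
    raise TypeError(f"cannot draw parameters for {type(fit).__name__}")
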