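"""Conditional-survival inversion of imputed event times.

Each missing-data subject observed event-free to time ``c`` receives an
imputed time ``t`` solving ``S(t | Z) / S(c | Z) = u`` with ``u ~ Unif(0,1)``
drawn once per (subject, imputation).  The solution is closed-form for the
piecewise-exponential and Weibull models, and a linear interpolation on a
survival grid for the bootstrap Cox route.  Raw times are then finalized
against the administrative horizon (and the death date where vital-status
follow-up exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._rng import subject_uniforms
from .exceptions import ConfigError, TrialDataError
from .imputation_models import CoxRdFit, ParameterDraw
from .trial_data import MISSING, SubjectRecord, TrialDataset, classify_disposition

__all__ = [
    "ImputedOutcome",
    "draw_uniform",
    "impute_bootstrap",
    "impute_pwe",
    "impute_weibull",
    "impute_j2r",
    "finalize_outcome",
    "impute_dataset",
]


@dataclass(frozen=True)
class ImputedOutcome:
    """Imputed (time, event) for one subject in one imputation."""

    id: object
    t_imputed: float
    E_imputed: int
    b: int = 0
    u: float = np.nan


def draw_uniform(seed: int, subject_id, k: int) -> np.ndarray:
    """k open-interval Uniform(0,1) variates keyed to (seed, subject id).

    Element ``b-1`` is imputation ``b``'s variate; the stream for one
    subject never depends on the other subjects present.
    """
    return subject_uniforms(seed, subject_id, k)


@lru_cache(maxsize=8)
def _uniform_matrix(seed: int, ids: tuple, k: int) -> np.ndarray:
    """(len(ids), k) matrix of per-subject uniforms; cached so the B
    imputations (and the methods of a comparison run) share one pass."""
    return np.array([subject_uniforms(seed, sid, k) for sid in ids])


# ---------------------------------------------------------------------------
# vectorized inversion kernels (public per-subject wrappers below)


def _invert_pwe(draw: ParameterDraw, Z: np.ndarray, c: np.ndarray, u: np.ndarray):
    """Solve S(t|Z)/S(c|Z) = u under a piecewise-exponential draw."""
    lam, tau, beta = draw.lam, draw.tau, draw.beta
    edges = np.concatenate([[0.0], tau])                 # interval left ends
    widths = np.diff(edges)
    # cumulative baseline hazard at each interval's left end
    cumA = np.concatenate([[0.0], np.cumsum(lam[:-1] * widths)]) if tau.size else np.array([0.0])
    lp = Z @ beta
    with np.errstate(over="ignore"):
        theta = np.exp(lp)  # inf at extreme draws => target 0+ => event at c+
    caps = np.concatenate([widths, [np.inf]])
    H0c = np.sum(lam * np.minimum(np.clip(c[:, None] - edges, 0.0, None), caps), axis=1)
    # target baseline cumhaz level:  -log(u*) e^{-lp}  with u* = S(c) u
    # (theta underflow at extreme draws => infinite target => censored later)
    with np.errstate(divide="ignore", over="ignore"):
        target = -np.log(u) / theta + H0c
    idx = np.clip(np.searchsorted(cumA, target, side="right") - 1, 0, len(lam) - 1)
    lam_p = lam[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = edges[idx] + (target - cumA[idx]) / lam_p
    t = np.where(lam_p > 0, t, np.where(target <= cumA[idx], edges[idx], np.inf))
    return t


def _invert_weibull(draw: ParameterDraw, Z: np.ndarray, c: np.ndarray, u: np.ndarray):
    """t = (c^(1/sigma) - exp(eta/sigma) * log u)^sigma."""
    sigma = draw.sigma
    eta = draw.gamma0 + Z @ draw.gamma
    with np.errstate(over="ignore"):
        inner = np.power(c, 1.0 / sigma) - np.exp(eta / sigma) * np.log(u)
        return np.power(inner, sigma)


def _invert_j2r(draw: ParameterDraw, Z: np.ndarray, c: np.ndarray, u: np.ndarray):
    """Reference-based inversion: post-dropout survival from the trt=0 arm.

    Solves S(t | trt=0, X)/S(c | trt=1, X) = u; the result is floored at c
    (the reference distribution may sit below the subject's own at c).
    For trt=0 subjects this reduces exactly to the plain Weibull inversion.
    """
    sigma = draw.sigma
    eta = draw.gamma0 + Z @ draw.gamma
    Z0 = Z.copy()
    Z0[:, 0] = 0.0  # treatment is the first design column
    eta0 = draw.gamma0 + Z0 @ draw.gamma
    with np.errstate(over="ignore"):
        inner = (
            np.exp((eta0 - eta) / sigma) * np.power(c, 1.0 / sigma)
            - np.exp(eta0 / sigma) * np.log(u)
        )
        return np.maximum(np.power(inner, sigma), c)


def _grid(c: float, C: float, width: float) -> np.ndarray:
    """Arithmetic grid from c to C at the given width; endpoints forced."""
    if not c < C:
        raise TrialDataError(f"degenerate grid: c={c} >= C={C}")
    pts = np.arange(c, C, width)
    return np.concatenate([pts, [C]])


def _interp_level(points: np.ndarray, surv: np.ndarray, level: float) -> float:
    """Linear interpolation of the time at a survival level on one grid."""
    if level < surv[-1] or surv[0] <= 0.0:
        return np.inf  # outside the grid (or underflowed): censored upstream
    # first index where survival has dropped to or below the level
    k = int(np.searchsorted(-surv, -level, side="left"))
    if k == 0:
        return float(points[0])
    lo, hi = k - 1, k
    ds = surv[hi] - surv[lo]
    if ds == 0:
        return float(points[lo])
    return float(points[lo] + (points[hi] - points[lo]) / ds * (level - surv[lo]))


def _invert_bootstrap(
    fit: CoxRdFit, Z: np.ndarray, c: np.ndarray, C: np.ndarray,
    u: np.ndarray, width: float,
):
    grids = [_grid(ci, Ci, width) for ci, Ci in zip(c, C)]
    lens = np.array([len(g) for g in grids])
    flat = np.concatenate(grids)
    H0 = fit.fit.baseline_cumhaz(flat)
    lp = Z @ fit.fit.beta
    theta = np.repeat(np.exp(lp), lens)
    surv_flat = np.exp(-H0 * theta)
    out = np.empty(len(c))
    offs = np.concatenate([[0], np.cumsum(lens)])
    for i, g in enumerate(grids):
        s = surv_flat[offs[i]: offs[i + 1]]
        out[i] = _interp_level(g, s, s[0] * u[i])
    return out


# ---------------------------------------------------------------------------
# finalization


def _finalize_arrays(t_raw, C, R, D, death_day):
    """Apply horizon and vital-status rules to raw imputed times."""
    t_raw = np.asarray(t_raw, dtype=float)
    death = np.asarray(death_day, dtype=float)
    has_death = ~np.isnan(death)
    # no vital-status info: event iff before the horizon
    E = (t_raw < C).astype(int)
    t = np.where(E == 1, t_raw, C)
    if has_death.any():
        limit = np.minimum(death, D - R)          # event only if on/before this
        cens = np.minimum(death, C)               # else censored here (+1 convention in C)
        E_d = (t_raw <= limit).astype(int)
        t_d = np.where(E_d == 1, t_raw, cens)
        E = np.where(has_death, E_d, E)
        t = np.where(has_death, t_d, t)
    return t, E


def finalize_outcome(t_raw: float, subject: SubjectRecord, b: int = 0, u: float = np.nan) -> ImputedOutcome:
    """Turn a raw inverted time into the subject's final (time, event).

    Without vital-status data the outcome is an event iff ``t_raw < C``,
    otherwise censored at ``C``.  With a death date, it is an event iff the
    imputed date (``R + t_raw``) is on or before the earlier of the death
    date and the study data-cut; otherwise censored at
    ``min(death_day, C)``.
    """
    death = np.nan if subject.death_day is None else subject.death_day
    D = subject.R + subject.C - 1.0
    t, E = _finalize_arrays(
        np.array([t_raw]), np.array([subject.C]), np.array([subject.R]),
        D, np.array([death]),
    )
    return ImputedOutcome(id=subject.id, t_imputed=float(t[0]), E_imputed=int(E[0]), b=b, u=u)


# ---------------------------------------------------------------------------
# per-subject wrappers


def _subject_arrays(subject: SubjectRecord):
    Z = np.array([[float(subject.trt), *map(float, subject.X)]])
    c = np.array([float(subject.T_obs)])
    return Z, c


def impute_pwe(draw: ParameterDraw, subject: SubjectRecord, u: float, b: int = 0) -> ImputedOutcome:
    """Closed-form piecewise-exponential imputation for one subject."""
    Z, c = _subject_arrays(subject)
    t_raw = _invert_pwe(draw, Z, c, np.array([u]))[0]
    return finalize_outcome(t_raw, subject, b=b, u=u)


def impute_weibull(draw: ParameterDraw, subject: SubjectRecord, u: float, b: int = 0) -> ImputedOutcome:
    """Closed-form Weibull-AFT imputation for one subject."""
    Z, c = _subject_arrays(subject)
    t_raw = _invert_weibull(draw, Z, c, np.array([u]))[0]
    return finalize_outcome(t_raw, subject, b=b, u=u)


def impute_j2r(draw: ParameterDraw, subject: SubjectRecord, u: float, b: int = 0) -> ImputedOutcome:
    """Jump-to-reference imputation (Weibull flavor) for one subject."""
    Z, c = _subject_arrays(subject)
    t_raw = _invert_j2r(draw, Z, c, np.array([u]))[0]
    return finalize_outcome(t_raw, subject, b=b, u=u)


def impute_bootstrap(
    fit: CoxRdFit, subject: SubjectRecord, grid_width_days: float, u: float, b: int = 0
) -> ImputedOutcome:
    """Grid-interpolation imputation under one bootstrap Cox fit.

    Builds the survival grid from ``c`` to ``C``, targets the level
    ``S(c) * u``, and linearly interpolates; a level below ``S(C)`` falls
    outside the grid and is censored at the horizon.
    """
    Z, c = _subject_arrays(subject)
    t_raw = _invert_bootstrap(
        fit, Z, c, np.array([float(subject.C)]), np.array([u]), grid_width_days
    )[0]
    return finalize_outcome(t_raw, subject, b=b, u=u)


# ---------------------------------------------------------------------------
# whole-dataset imputation


_PARAMETRIC = {"pwe": _invert_pwe, "weibull": _invert_weibull, "j2r": _invert_j2r}


def impute_dataset(
    data: TrialDataset,
    method: str,
    model,
    b: int,
    seed: int,
    B_total: int | None = None,
    grid_width: float = 60.0,
    partition=None,
) -> TrialDataset:
    """Complete one copy of the dataset for imputation ``b``.

    Every missing-classified subject's ``(T_obs, E)`` is replaced by the
    imputed outcome; retrieved dropouts and completers are untouched.  The
    subject-level uniform for imputation ``b`` comes from the per-subject
    stream under ``seed`` (shared across methods so comparisons are not
    confounded by Monte-Carlo noise).  Output gains ``imputed`` and
    ``imp_b`` audit columns.
    """
    if method in _PARAMETRIC:
        if not isinstance(model, ParameterDraw):
            raise ConfigError(f"method {method!r} needs a ParameterDraw, got {type(model).__name__}")
        if method == "pwe" and model.kind != "pwe":
            raise ConfigError("pwe imputation needs a piecewise-exponential draw")
        if method in ("weibull", "j2r") and model.kind != "weibull":
            raise ConfigError(f"{method} imputation needs a Weibull draw")
    elif method == "bootstrap":
        if not isinstance(model, CoxRdFit):
            raise ConfigError("bootstrap imputation needs a CoxRdFit")
    else:
        raise ConfigError(f"unknown imputation method {method!r}")

    if partition is None:
        partition = classify_disposition(data)
    out = data.copy()
    out.df["imputed"] = 0
    out.df["imp_b"] = b
    if not partition.missing:
        return out

    miss_mask = out.df["id"].isin(partition.missing).to_numpy()
    sub = out.df.loc[miss_mask]
    Z = sub[["trt"] + [c for c in data.covariates if c != "trt"]].to_numpy(dtype=float)
    c = sub["T_obs"].to_numpy(dtype=float)
    C = sub["C"].to_numpy(dtype=float)
    R = sub["R"].to_numpy(dtype=float)
    death = sub["death_day"].to_numpy(dtype=float)
    k = B_total if B_total is not None else b
    u = _uniform_matrix(int(seed), tuple(sub["id"]), int(k))[:, b - 1]

    if method == "bootstrap":
        t_raw = _invert_bootstrap(model, Z, c, C, u, grid_width)
    else:
        t_raw = _PARAMETRIC[method](model, Z, c, u)
    t_fin, E_fin = _finalize_arrays(t_raw, C, R, data.D, death)
    out.df.loc[miss_mask, "T_obs"] = t_fin
    out.df.loc[miss_mask, "E"] = E_fin
    out.df.loc[miss_mask, "imputed"] = 1
    return out
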