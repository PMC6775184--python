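"""Finger-angle decoders: equilibrium-point musculoskeletal model and OLS.

The musculoskeletal model (MSM) treats each finger as a one-degree-of-freedom
joint actuated by an antagonist flexor/extensor pair of spring-like muscles.
With muscle contraction levels u_n ≥ 0, the joint torque is

    tau(theta) = sum_n a_n (k0_n + k1_n u_n) (l0_n + l1_n u_n − a_n theta)

where a_1 > 0 (flexor moment arm), a_2 < 0 (extensor), and all stiffness
(k0, k1) and length (l0, l1) constants are positive.  The decoded angle is
the equilibrium point where the torques balance.  Solving tau(theta) = 0
exactly gives

    theta_eq = sum_n a_n K_n L_n / sum_n a_n^2 K_n,
    K_n = k0_n + k1_n u_n,  L_n = l0_n + l1_n u_n

whose denominator is strictly positive under the parameter constraints, so
the equilibrium always exists and is unique.  (A commonly quoted variant
with denominator sum_n a_n K_n is not the root of the torque equation and
can divide by zero; this module uses the exact root so the identity
tau(theta_eq) = 0 holds to machine precision.)

theta_eq is invariant to a common positive rescaling of all four k constants,
so k0 of the flexor is pinned to 1 during fitting to remove the flat
direction; fitted parameter values are therefore identified only up to that
normalization and only predictions are comparable across fits.

The linear regression model (LRM) is ordinary least squares
theta = b0 + b1 u_flex + b2 u_ext.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares


@dataclass
class MsmParams:
    """Antagonist-pair parameters; index 0 = flexor, 1 = extensor."""

    a: np.ndarray  # moment arms, a[0] > 0 > a[1]
    k0: np.ndarray  # baseline stiffness, > 0
    k1: np.ndarray  # activation-dependent stiffness, > 0
    l0: np.ndarray  # baseline length constant, > 0
    l1: np.ndarray  # activation-dependent length constant, > 0

    def __post_init__(self):
        for name in ("a", "k0", "k1", "l0", "l1"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,):
                raise ValueError(f"{name} must have shape (2,)")
            setattr(self, name, v)
        if not (self.a[0] > 0 and self.a[1] < 0):
            raise ValueError("moment arms must satisfy a_flexor > 0 > a_extensor")
        for name in ("k0", "k1", "l0", "l1"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} entries must be positive")

    def as_dict(self) -> dict[str, list[float]]:
        return {n: list(map(float, getattr(self, n))) for n in ("a", "k0", "k1", "l0", "l1")}

    @classmethod
    def from_dict(cls, d: dict) -> "MsmParams":
        return cls(**{n: np.asarray(d[n], dtype=float) for n in ("a", "k0", "k1", "l0", "l1")})


@dataclass
class LrmParams:
    """OLS coefficients theta = beta0 + beta1*u_flex + beta2*u_ext."""

    beta0: float
    beta1: float
    beta2: float
    residual_sd: float = 0.0

    def __post_init__(self):
        vals = (self.beta0, self.beta1, self.beta2, self.residual_sd)
        if not np.all(np.isfinite(vals)):
            raise ValueError("LRM parameters must be finite")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass
class ModelFit:
    params: Any
    predicted: np.ndarray
    residuals: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def msm_torque(u1, u2, theta, p: MsmParams):
    """Net joint torque of the antagonist pair (model units)."""
    u1, u2, theta = np.asarray(u1, float), np.asarray(u2, float), np.asarray(theta, float)
    tau = 0.0
    for n, u in ((0, u1), (1, u2)):
        K = p.k0[n] + p.k1[n] * u
        L = p.l0[n] + p.l1[n] * u
        tau = tau + p.a[n] * K * (L - p.a[n] * theta)
    return tau


def msm_equilibrium(u1, u2, p: MsmParams):
    """Angle at which the antagonist torques balance (exact root of the torque)."""
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    num = 0.0
    den = 0.0
    for n, u in ((0, u1), (1, u2)):
        K = p.k0[n] + p.k1[n] * u
        L = p.l0[n] + p.l1[n] * u
        num = num + p.a[n] * K * L
        den = den + p.a[n] ** 2 * K
    return num / den


def _unpack_log_params(p_log: np.ndarray) -> MsmParams:
    # clip keeps exp() and the squared-moment-arm denominator inside float64
    e = np.exp(np.clip(p_log, -40.0, 40.0))
    return MsmParams(
        a=np.array([e[0], -e[1]]),
        k0=np.array([1.0, e[3]]),
        k1=np.array([e[2], e[4]]),
        l0=np.array([e[5], e[7]]),
        l1=np.array([e[6], e[8]]),
    )


def fit_msm(
    u_flex: np.ndarray,
    u_ext: np.ndarray,
    theta: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    max_nfev: int = 400,
) -> ModelFit:
    """Constrained nonlinear least-squares fit of the equilibrium model.

    Minimizes the RMSE between the equilibrium angle and the observed angle.
    Sign and positivity constraints are enforced by a log parameterization
    (k, l = exp(·); a_flexor = exp(·), a_extensor = −exp(·)) with the flexor
    k0 pinned to 1.  Multi-start: one start at the origin of log-space plus
    seeded log-uniform draws in [e^-2, e^2]; best fit by training RMSE wins.

    Degenerate inputs (constant angle and constant activations) are flagged
    in ``diagnostics['degenerate']`` rather than raising.
    """
    u1 = np.asarray(u_flex, float).ravel()
    u2 = np.asarray(u_ext, float).ravel()
    th = np.asarray(theta, float).ravel()
    if not (u1.shape == u2.shape == th.shape):
        raise ValueError("u_flex, u_ext and theta must be aligned, equal-length series")
    n_par = 9
    if th.size < 10 * n_par:
        raise ValueError(f"need at least {10 * n_par} samples to fit {n_par} parameters")
    degenerate = th.std() < 1e-10 and u1.std() < 1e-10 and u2.std() < 1e-10

    def residual(p_log):
        return msm_equilibrium(u1, u2, _unpack_log_params(p_log)) - th

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_par)]
    starts += [rng.uniform(-2.0, 2.0, n_par) for _ in range(max(0, restarts - 1))]
    best = None
    trace = []
    for p0 in starts:
        sol = least_squares(residual, p0, method="trf", max_nfev=max_nfev)
        rmse_val = float(np.sqrt(np.mean(sol.fun**2)))
        trace.append(rmse_val)
        if best is None or rmse_val < best[0]:
            best = (rmse_val, sol)
    rmse_val, sol = best
    params = _unpack_log_params(sol.x)
    predicted = msm_equilibrium(u1, u2, params)
    return ModelFit(
        params=params,
        predicted=predicted,
        residuals=th - predicted,
        diagnostics={
            "rmse": rmse_val,
            "torque_at_fit": msm_torque(u1, u2, predicted, params),
            "restart_rmse": trace,
            "restarts": len(starts),
            "seed": seed,
            "degenerate": degenerate,
            "converged": bool(sol.success),
        },
    )


def msm_predict(u_flex, u_ext, p: MsmParams) -> np.ndarray:
    return msm_equilibrium(u_flex, u_ext, p)


def fit_lrm(u_flex: np.ndarray, u_ext: np.ndarray, theta: np.ndarray) -> ModelFit:
    """Ordinary least squares on the design [1, u_flex, u_ext].

    Rank-deficient designs (e.g. u_flex ≡ u_ext) are solved by the
    minimum-norm solution and flagged in ``diagnostics['collinear']``.
    """
    u1 = np.asarray(u_flex, float).ravel()
    u2 = np.asarray(u_ext, float).ravel()
    th = np.asarray(theta, float).ravel()
    if not (u1.shape == u2.shape == th.shape):
        raise ValueError("u_flex, u_ext and theta must be aligned, equal-length series")
    if th.size < 3:
        raise ValueError("need at least 3 samples")
    X = np.column_stack([np.ones_like(u1), u1, u2])
    beta, _, rank, _ = np.linalg.lstsq(X, th, rcond=None)
    predicted = X @ beta
    resid = th - predicted
    dof = max(th.size - rank, 1)
    params = LrmParams(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    return ModelFit(
        params=params,
        predicted=predicted,
        residuals=resid,
        diagnostics={"rank": int(rank), "collinear": rank < 3},
    )


def lrm_predict(u_flex, u_ext, p: LrmParams) -> np.ndarray:
    """Point prediction theta_hat = beta0 + beta1*u_flex + beta2*u_ext."""
    u1 = np.asarray(u_flex, float)
    u2 = np.asarray(u_ext, float)
    return p.beta0 + p.beta1 * u1 + p.beta2 * u2
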