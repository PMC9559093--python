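"""Interpretable and transformed superpixel parameters.

Each superpixel k has 7 interpretable population parameters: the population
intercept alpha0 (um) and slope alpha1 (um/yr) of the mean trajectory, the
variance D00 of subject random intercepts, the variance D11 of subject random
slopes, their correlation rho (equivalently the covariance D01), and the mean
sigma_m and SD sigma_s of the subject-specific residual SDs sigma_i.

Posterior computation works on an unconstrained 7-vector theta per superpixel:

    theta1 = alpha0
    theta2 = log D00
    theta3 = log D11.0           with D11.0 = D11 - D01^2/D00 = D11 (1 - rho^2)
    theta4 = alpha1
    theta5 = b = D01 / D00       (regression of random slope on random intercept)
    theta6 = nu                  (mean of log sigma_i)
    theta7 = log omega           (SD of log sigma_i)

so that (theta2, theta3, theta5) is a log-Cholesky-like parameterization of
the 2x2 random-effect covariance D, and the subject residual SDs are
log-normal with log-scale parameters (nu, omega).  Any finite theta maps back
to a valid parameter set (positive variances, |rho| < 1), which is what makes
normal hierarchical priors on theta appropriate.

The canonical order of the interpretable 7-vector used throughout is

    (alpha0, ri_sd, alpha1, rs_sd, rho, sigma_m, sigma_s)

with ri_sd = sqrt(D00) and rs_sd = sqrt(D11).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SuperpixelParams",
    "TransformedParams",
    "GlobalHyperparams",
    "INTERPRETABLE_NAMES",
    "interpretable_to_transformed",
    "transformed_to_interpretable",
    "lognormal_sd_moments",
    "lognormal_sd_params",
    "transform_array",
    "back_transform_array",
    "hyperparams_from_interpretable_moments",
    "reference_hyperparams",
]

#: Canonical names/order of the interpretable parameter vector.
INTERPRETABLE_NAMES = (
    "population_intercept",
    "random_intercept_sd",
    "population_slope",
    "random_slope_sd",
    "intercept_slope_correlation",
    "residual_sd_mean",
    "residual_sd_sd",
)


@dataclass(frozen=True)
class SuperpixelParams:
    """The 7 interpretable population parameters of one superpixel."""

    alpha0: float
    alpha1: float
    D00: float
    D11: float
    D01: float
    rho: float
    sigma_m: float
    sigma_s: float

    def __post_init__(self) -> None:
        if not (self.D00 > 0 and self.D11 > 0):
            raise ValueError("random-effect variances must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        scale = np.sqrt(self.D00 * self.D11)
        if abs(self.D01 - self.rho * scale) > 1e-8 * max(1.0, scale):
            raise ValueError("D01 inconsistent with rho * sqrt(D00 * D11)")
        if not self.sigma_m > 0:
            raise ValueError("sigma_m must be positive")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be nonnegative")

    @classmethod
    def from_interpretable(
        cls,
        alpha0: float,
        ri_sd: float,
        alpha1: float,
        rs_sd: float,
        rho: float,
        sigma_m: float,
        sigma_s: float,
    ) -> "SuperpixelParams":
        """Build from the canonical interpretable vector (SD scale)."""
        if ri_sd <= 0 or rs_sd <= 0:
            raise ValueError("random-effect SDs must be positive")
        D00, D11 = ri_sd**2, rs_sd**2
        return cls(
            alpha0=alpha0,
            alpha1=alpha1,
            D00=D00,
            D11=D11,
            D01=rho * ri_sd * rs_sd,
            rho=rho,
            sigma_m=sigma_m,
            sigma_s=sigma_s,
        )

    def to_interpretable(self) -> np.ndarray:
        return np.array(
            [
                self.alpha0,
                np.sqrt(self.D00),
                self.alpha1,
                np.sqrt(self.D11),
                self.rho,
                self.sigma_m,
                self.sigma_s,
            ]
        )


@dataclass(frozen=True)
class TransformedParams:
    """The unconstrained 7-vector theta of one superpixel."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (7,):
            raise ValueError("theta must be a length-7 vector")
        if not np.isfinite(th).all():
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", th)

    def to_array(self) -> np.ndarray:
        return self.theta.copy()


def lognormal_sd_moments(nu: float, omega: float) -> tuple[float, float]:
    """Mean and SD of a log-normal residual SD with log-scale (nu, omega)."""
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    sigma_m = np.exp(nu + omega**2 / 2.0)
    sigma_s = sigma_m * np.sqrt(np.expm1(omega**2))
    return float(sigma_m), float(sigma_s)


def lognormal_sd_params(sigma_m: float, sigma_s: float) -> tuple[float, float]:
    """Inverse of :func:`lognormal_sd_moments`."""
    if sigma_m <= 0:
        raise ValueError("sigma_m must be positive")
    if sigma_s < 0:
        raise ValueError("sigma_s must be nonnegative")
    omega2 = np.log1p((sigma_s / sigma_m) ** 2)
    nu = np.log(sigma_m) - omega2 / 2.0
    return float(nu), float(np.sqrt(omega2))


def interpretable_to_transformed(p: SuperpixelParams) -> TransformedParams:
    """Map interpretable parameters to the unconstrained theta vector."""
    d11_0 = p.D11 * (1.0 - p.rho**2)
    nu, omega = lognormal_sd_params(p.sigma_m, p.sigma_s)
    if omega <= 0:
        raise ValueError(
            "sigma_s must be positive to transform (omega = 0 has no log)"
        )
    theta = np.array(
        [
            p.alpha0,
            np.log(p.D00),
            np.log(d11_0),
            p.alpha1,
            p.D01 / p.D00,
            nu,
            np.log(omega),
        ]
    )
    return TransformedParams(theta)


def transformed_to_interpretable(t: TransformedParams) -> SuperpixelParams:
    """Back-transform; any finite theta yields a valid parameter set."""
    th = t.theta
    D00 = np.exp(th[1])
    d11_0 = np.exp(th[2])
    b = th[4]
    D01 = b * D00
    D11 = d11_0 + b**2 * D00
    # |rho| < 1 holds algebraically; clip so it also holds after rounding
    rho = np.clip(D01 / np.sqrt(D00 * D11), -1 + 1e-12, 1 - 1e-12)
    sigma_m, sigma_s = lognormal_sd_moments(th[5], np.exp(th[6]))
    return SuperpixelParams(
        alpha0=float(th[0]),
        alpha1=float(th[3]),
        D00=float(D00),
        D11=float(D11),
        D01=float(D01),
        rho=float(rho),
        sigma_m=sigma_m,
        sigma_s=sigma_s,
    )


def transform_array(interp: np.ndarray) -> np.ndarray:
    """Vectorized interpretable -> theta on (..., 7) arrays (canonical order)."""
    v = np.asarray(interp, dtype=float)
    a0, ri, a1, rs, rho, sm, ss = np.moveaxis(v, -1, 0)
    D00 = ri**2
    D11 = rs**2
    D01 = rho * ri * rs
    omega2 = np.log1p((ss / sm) ** 2)
    out = np.empty_like(v)
    out[..., 0] = a0
    out[..., 1] = np.log(D00)
    out[..., 2] = np.log(D11 * (1.0 - rho**2))
    out[..., 3] = a1
    out[..., 4] = D01 / D00
    out[..., 5] = np.log(sm) - omega2 / 2.0
    out[..., 6] = 0.5 * np.log(omega2)
    return out


def back_transform_array(theta: np.ndarray) -> np.ndarray:
    """Vectorized theta -> interpretable on (..., 7) arrays (canonical order)."""
    th = np.asarray(theta, dtype=float)
    D00 = np.exp(th[..., 1])
    d11_0 = np.exp(th[..., 2])
    b = th[..., 4]
    D11 = d11_0 + b**2 * D00
    rho = np.clip(b * np.sqrt(D00 / D11), -1 + 1e-12, 1 - 1e-12)
    omega2 = np.exp(2.0 * th[..., 6])
    with np.errstate(over="ignore"):  # extreme theta can overflow sigma moments
        sm = np.exp(th[..., 5] + omega2 / 2.0)
        ss = sm * np.sqrt(np.expm1(omega2))
    out = np.empty_like(th)
    out[..., 0] = th[..., 0]
    out[..., 1] = np.sqrt(D00)
    out[..., 2] = th[..., 3]
    out[..., 3] = np.sqrt(D11)
    out[..., 4] = rho
    out[..., 5] = sm
    out[..., 6] = ss
    return out


@dataclass
class GlobalHyperparams:
    """Across-superpixel law of the transformed parameters (reduced model).

    (theta1, theta2, theta3) are trivariate normal with mean ``mu_c`` and
    covariance ``Sigma_c``; theta4..theta7 are independent normals with means
    ``mu_ind`` and SDs ``tau_ind``.
    """

    mu_c: np.ndarray  # (3,)
    Sigma_c: np.ndarray  # (3, 3)
    mu_ind: np.ndarray  # (4,) for theta4..theta7
    tau_ind: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        self.mu_c = np.asarray(self.mu_c, dtype=float).reshape(3)
        self.Sigma_c = np.asarray(self.Sigma_c, dtype=float).reshape(3, 3)
        self.mu_ind = np.asarray(self.mu_ind, dtype=float).reshape(4)
        self.tau_ind = np.asarray(self.tau_ind, dtype=float).reshape(4)
        if not np.allclose(self.Sigma_c, self.Sigma_c.T, atol=1e-10):
            raise ValueError("Sigma_c must be symmetric")
        if np.linalg.eigvalsh(self.Sigma_c).min() <= 0:
            raise ValueError("Sigma_c must be positive definite")
        if not (self.tau_ind > 0).all():
            raise ValueError("tau_ind must be positive")

    def theta_mean(self) -> np.ndarray:
        out = np.empty(7)
        out[[0, 1, 2]] = self.mu_c
        out[[3, 4, 5, 6]] = self.mu_ind
        return out

    def theta_sd(self) -> np.ndarray:
        out = np.empty(7)
        out[[0, 1, 2]] = np.sqrt(np.diag(self.Sigma_c))
        out[[3, 4, 5, 6]] = self.tau_ind
        return out


def hyperparams_from_interpretable_moments(
    means: np.ndarray,
    sds: np.ndarray,
    correlations: dict[tuple[int, int], float] | None = None,
) -> GlobalHyperparams:
    """Calibrate theta-scale hyperparameters to interpretable-scale moments.

    ``means``/``sds`` are across-superpixel means and SDs of the canonical
    interpretable 7-vector.  The theta-scale mean is the plug-in transform of
    ``means``; the theta-scale covariance is obtained by the delta method
    (numerical Jacobian of the transform at ``means``).  ``correlations``
    gives across-superpixel correlations between interpretable parameters as
    {(i, j): r} on canonical indices; unspecified pairs are treated as
    uncorrelated.  The calibration is approximate (exact only to first
    order), which suffices for constructing generator truths.
    """
    means = np.asarray(means, dtype=float).reshape(7)
    sds = np.asarray(sds, dtype=float).reshape(7)
    corr = np.eye(7)
    for (i, j), r in (correlations or {}).items():
        corr[i, j] = corr[j, i] = r
    cov_interp = corr * np.outer(sds, sds)

    # numerical Jacobian of the interpretable -> theta map at the means
    jac = np.empty((7, 7))
    for j in range(7):
        h = 1e-6 * max(1.0, abs(means[j]))
        up, dn = means.copy(), means.copy()
        up[j] += h
        dn[j] -= h
        jac[:, j] = (transform_array(up) - transform_array(dn)) / (2 * h)

    theta_mean = transform_array(means)
    theta_cov = jac @ cov_interp @ jac.T
    sigma_c = theta_cov[:3, :3]
    # symmetrize and keep strictly positive definite
    sigma_c = (sigma_c + sigma_c.T) / 2.0
    w, V = np.linalg.eigh(sigma_c)
    sigma_c = (V * np.clip(w, 1e-10, None)) @ V.T
    tau_ind = np.sqrt(np.clip(np.diag(theta_cov)[3:], 1e-12, None))
    return GlobalHyperparams(
        mu_c=theta_mean[:3],
        Sigma_c=sigma_c,
        mu_ind=theta_mean[3:],
        tau_ind=tau_ind,
    )


#: Across-superpixel posterior summaries reported for a progressing-glaucoma
#: GCC cohort (111 eyes, 49 superpixels): means, SDs and the three strong
#: pairwise correlations of the interpretable parameters.  Used as the
#: default generator truth for recovery studies.
REFERENCE_INTERP_MEANS = np.array([73.05, 14.84, -0.357, 0.845, -0.266, 1.947, 0.741])
REFERENCE_INTERP_SDS = np.array([13.29, 5.50, 0.266, 0.317, 0.198, 0.249, 0.171])
REFERENCE_INTERP_CORR = {(0, 1): 0.812, (0, 3): 0.739, (1, 3): 0.845}


def reference_hyperparams() -> GlobalHyperparams:
    """Hyperparameters calibrated to the reference cohort's global summaries."""
    return hyperparams_from_interpretable_moments(
        REFERENCE_INTERP_MEANS, REFERENCE_INTERP_SDS, REFERENCE_INTERP_CORR
    )
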