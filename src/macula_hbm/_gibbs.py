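"""Blocked Gibbs / Metropolis-within-Gibbs sampler for the reduced model.

Everything operates on per-(subject, superpixel) sufficient statistics
(n, St, Stt, Sy, Sty, Syy), so a sweep costs a handful of vectorized
operations on (n_subjects, K) arrays regardless of the number of visits.

Update blocks per sweep
-----------------------
conjugate (exact draws):
  * (beta0, beta1)_ik     bivariate normal
  * (alpha0, alpha1)_k    bivariate normal (theta1 prior conditioned on
                          theta2, theta3 inside the trivariate block)
  * theta5_k = b_k        normal (regression of beta1 on beta0)
  * theta6_k = nu_k       normal
  * mu_c                  trivariate normal
  * Sigma_c               inverse-Wishart
  * mu_j (j=4..7)         normal
random-walk Metropolis (log scale, step sizes adapted during burn-in only):
  * log sigma_ik, theta2_k, theta3_k, theta7_k, log tau_j

Cells with no data (profiles removed in cleaning) keep their latent
(beta, log sigma) as exact prior draws; this leaves the joint posterior of
all other quantities unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

MH_TARGET = 0.44  # classic scalar random-walk acceptance target
ADAPT_BATCH = 100


@dataclass
class SuffStats:
    """Per-(subject, superpixel) sufficient statistics of the long table."""

    subjects: list[str]
    labels: list[str]
    N: np.ndarray
    St: np.ndarray
    Stt: np.ndarray
    Sy: np.ndarray
    Sty: np.ndarray
    Syy: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def K(self) -> int:
        return len(self.labels)


def prepare_stats(table: pd.DataFrame) -> SuffStats:
    from .grid_io import parse_label

    subjects = sorted(table["subject_id"].unique())
    labels = sorted(table["superpixel"].unique(), key=lambda s: parse_label(s))
    si = {s: i for i, s in enumerate(subjects)}
    ki = {k: i for i, k in enumerate(labels)}
    n, K = len(subjects), len(labels)
    ii = table["subject_id"].map(si).to_numpy()
    kk = table["superpixel"].map(ki).to_numpy()
    t = table["time_years"].to_numpy(float)
    y = table["thickness_um"].to_numpy(float)

    def acc(w):
        out = np.zeros((n, K))
        np.add.at(out, (ii, kk), w)
        return out

    return SuffStats(
        subjects=subjects,
        labels=labels,
        N=acc(np.ones_like(t)),
        St=acc(t),
        Stt=acc(t * t),
        Sy=acc(y),
        Sty=acc(t * y),
        Syy=acc(y * y),
    )


@dataclass
class PriorConfig:
    """Proper but vague hyperpriors of the reduced model."""

    mu_c_mean: tuple[float, float, float] = (75.0, np.log(150.0), np.log(0.25))
    mu_c_var: float = 1e4
    sigma_c_df: float = 5.0
    sigma_c_scale: float = 0.1
    mu_ind_mean: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    mu_ind_var: float = 1e4
    tau_scale: float = 10.0

    def widened(self, factor: float = 10.0) -> "PriorConfig":
        """Same structure with ``factor``-times wider scales (sensitivity runs)."""
        return PriorConfig(
            mu_c_mean=self.mu_c_mean,
            mu_c_var=self.mu_c_var * factor**2,
            sigma_c_df=self.sigma_c_df,
            sigma_c_scale=self.sigma_c_scale,
            mu_ind_mean=self.mu_ind_mean,
            mu_ind_var=self.mu_ind_var * factor**2,
            tau_scale=self.tau_scale * factor,
        )


@dataclass
class ChainState:
    a0: np.ndarray  # (K,) theta1
    a1: np.ndarray  # (K,) theta4
    th2: np.ndarray
    th3: np.ndarray
    th5: np.ndarray
    nu: np.ndarray
    th7: np.ndarray
    beta0: np.ndarray  # (n, K)
    beta1: np.ndarray
    lsig: np.ndarray
    mu_c: np.ndarray
    Sigma_c: np.ndarray
    mu_ind: np.ndarray
    tau_ind: np.ndarray

    def theta(self) -> np.ndarray:
        return np.stack(
            [self.a0, self.th2, self.th3, self.a1, self.th5, self.nu, self.th7],
            axis=1,
        )


def initial_state(
    stats: SuffStats, rng: np.random.Generator, jitter: float = 0.05
) -> ChainState:
    """Method-of-moments initialization from per-cell least squares."""
    N, St, Stt, Sy, Sty, Syy = (
        stats.N, stats.St, stats.Stt, stats.Sy, stats.Sty, stats.Syy,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        det = N * Stt - St**2
        slope = np.where(det > 1e-12, (N * Sty - St * Sy) / np.where(det > 0, det, 1), np.nan)
        inter = np.where(N > 0, (Sy - slope * St) / np.where(N > 0, N, 1), np.nan)
        sse = Syy - 2 * inter * Sy - 2 * slope * Sty + 2 * inter * slope * St \
            + inter**2 * N + slope**2 * Stt
        rvar = np.where(N > 2, sse / np.maximum(N - 2, 1), np.nan)
    ok = N >= 3
    inter = np.where(ok, inter, np.nan)
    slope = np.where(ok, slope, np.nan)

    a0 = np.nanmean(np.where(ok, inter, np.nan), axis=0)
    a1 = np.nanmean(np.where(ok, slope, np.nan), axis=0)
    a0 = np.where(np.isfinite(a0), a0, np.nanmean(Sy.sum(0) / np.maximum(N.sum(0), 1)))
    a1 = np.where(np.isfinite(a1), a1, 0.0)
    beta0 = np.nan_to_num(inter - a0)
    beta1 = np.nan_to_num(slope - a1)
    lsig = 0.5 * np.log(np.where(np.isfinite(rvar) & (rvar > 0.04), rvar, 4.0))

    v0 = np.maximum(beta0.var(axis=0), 1e-2)
    cov01 = (beta0 * beta1).mean(axis=0) - beta0.mean(axis=0) * beta1.mean(axis=0)
    b = cov01 / v0
    v1res = np.maximum(beta1.var(axis=0) - b**2 * v0, 1e-3)
    nu = lsig.mean(axis=0)
    om = np.maximum(lsig.std(axis=0), 0.05)

    g = rng.standard_normal
    state = ChainState(
        a0=a0 + jitter * g(stats.K),
        a1=a1 + 0.02 * jitter * g(stats.K),
        th2=np.log(v0) + jitter * g(stats.K),
        th3=np.log(v1res) + jitter * g(stats.K),
        th5=b + 0.01 * jitter * g(stats.K),
        nu=nu + jitter * g(stats.K),
        th7=np.log(om) + jitter * g(stats.K),
        beta0=beta0,
        beta1=beta1,
        lsig=lsig,
        mu_c=np.zeros(3),
        Sigma_c=np.eye(3),
        mu_ind=np.zeros(4),
        tau_ind=np.ones(4),
    )
    tc = np.stack([state.a0, state.th2, state.th3], axis=1)
    state.mu_c = tc.mean(axis=0)
    state.Sigma_c = (
        np.cov(tc, rowvar=False) if stats.K >= 2 else np.zeros((3, 3))
    ) + 0.05 * np.eye(3)
    ti = np.stack([state.a1, state.th5, state.nu, state.th7], axis=1)
    state.mu_ind = ti.mean(axis=0)
    state.tau_ind = np.maximum(ti.std(axis=0), 0.05)
    return state


def _sample_bvn(P00, P01, P11, h0, h1, rng):
    """Draw from N(P^-1 h, P^-1) for batches of 2x2 precision matrices."""
    det = P00 * P11 - P01**2
    C00, C01, C11 = P11 / det, -P01 / det, P00 / det
    m0 = C00 * h0 + C01 * h1
    m1 = C01 * h0 + C11 * h1
    L00 = np.sqrt(C00)
    L10 = C01 / L00
    L11 = np.sqrt(np.maximum(C11 - L10**2, 1e-300))
    z0 = rng.standard_normal(np.shape(m0))
    z1 = rng.standard_normal(np.shape(m0))
    return m0 + L00 * z0, m1 + L10 * z0 + L11 * z1


class _Adapter:
    """Batch Robbins-Monro step-size adaptation, frozen after burn-in."""

    def __init__(self, shape, step: float):
        self.step = np.full(shape, step)
        self.acc = np.zeros(shape)
        self.count = 0

    def update(self, accepted, adapting: bool):
        if not adapting:
            return
        self.acc += accepted
        self.count += 1
        if self.count >= ADAPT_BATCH:
            rate = self.acc / self.count
            self.step *= np.exp(np.clip(rate - MH_TARGET, -0.5, 0.5))
            self.acc[:] = 0.0
            self.count = 0


def _mh(x, step, logtarget, rng, adapter: _Adapter, adapting: bool, repeats: int = 1):
    # repeating the kernel is valid (the conditional target is unchanged
    # within a sweep) and speeds mixing of the log-variance parameters
    for _ in range(repeats):
        prop = x + step * rng.standard_normal(x.shape)
        logr = logtarget(prop) - logtarget(x)
        accept = np.log(rng.random(x.shape)) < logr
        adapter.update(accept.astype(float), adapting)
        x = np.where(accept, prop, x)
    return x


def run_chain(
    stats: SuffStats,
    prior: PriorConfig,
    n_burn: int,
    n_keep: int,
    thin: int,
    effect_thin: int,
    rng: np.random.Generator,
    fixed_sigma: float | None = None,
    no_random_effects: bool = False,
    init_jitter: float = 0.05,
) -> dict[str, np.ndarray]:
    """Run one MCMC chain; returns stacked draws."""
    n, K = stats.n_subjects, stats.K
    N, St, Stt, Sy, Sty, Syy = (
        stats.N, stats.St, stats.Stt, stats.Sy, stats.Sty, stats.Syy,
    )
    nodata = N == 0
    s = initial_state(stats, rng, init_jitter)
    if fixed_sigma is not None:
        s.lsig[:] = np.log(fixed_sigma)
    if no_random_effects:
        s.beta0[:] = 0.0
        s.beta1[:] = 0.0

    m0c = np.asarray(prior.mu_c_mean)
    Q0c = np.eye(3) / prior.mu_c_var
    Psi0 = prior.sigma_c_scale * np.eye(3)
    df0 = prior.sigma_c_df
    m0i = np.asarray(prior.mu_ind_mean)
    prec0i = 1.0 / prior.mu_ind_var
    tau_scale2 = prior.tau_scale**2

    ad_lsig = _Adapter((n, K), 0.5)
    ad_th2 = _Adapter((K,), 0.3)
    ad_th3 = _Adapter((K,), 0.3)
    ad_th7 = _Adapter((K,), 0.3)
    ad_tau = _Adapter((4,), 0.3)

    total = n_burn + n_keep * thin
    out_theta = np.empty((n_keep, K, 7))
    out_mu_c = np.empty((n_keep, 3))
    out_sigma_c = np.empty((n_keep, 3, 3))
    out_mu_ind = np.empty((n_keep, 4))
    out_tau_ind = np.empty((n_keep, 4))
    eff_idx: list[int] = []
    eff_b0: list[np.ndarray] = []
    eff_b1: list[np.ndarray] = []
    eff_ls: list[np.ndarray] = []

    for it in range(total):
        adapting = it < n_burn
        Qc = np.linalg.inv(s.Sigma_c)
        s2 = np.exp(2.0 * s.lsig)
        D00 = np.exp(s.th2)
        D110 = np.exp(s.th3)
        b = s.th5
        omega = np.exp(s.th7)
        tau2 = s.tau_ind**2

        if not no_random_effects:
            # --- subject random effects (conjugate bivariate normal) ---
            r1 = Sy - s.a0 * N - s.a1 * St
            r2 = Sty - s.a0 * St - s.a1 * Stt
            iD00 = 1.0 / D00 + b * b / D110
            iD01 = -b / D110
            iD11 = 1.0 / D110
            s.beta0, s.beta1 = _sample_bvn(
                N / s2 + iD00,
                St / s2 + iD01,
                Stt / s2 + iD11,
                r1 / s2,
                r2 / s2,
                rng,
            )

        if fixed_sigma is None:
            # --- subject residual SDs (random-walk MH on log sigma) ---
            A = s.a0 + s.beta0
            B = s.a1 + s.beta1
            SSE = np.maximum(
                Syy - 2 * A * Sy - 2 * B * Sty + 2 * A * B * St
                + A * A * N + B * B * Stt,
                0.0,
            )

            def lt_lsig(x):
                return -N * x - SSE * np.exp(-2.0 * x) / 2.0 \
                    - (x - s.nu) ** 2 / (2.0 * omega**2)

            s.lsig = _mh(s.lsig, ad_lsig.step, lt_lsig, rng, ad_lsig, adapting)
            if nodata.any():  # prior draw where a cell has no observations
                direct = s.nu + omega * rng.standard_normal((n, K))
                s.lsig = np.where(nodata, direct, s.lsig)
            s2 = np.exp(2.0 * s.lsig)

        # --- population lines (conjugate bivariate normal per superpixel) ---
        c1 = s.mu_c[0] - (
            Qc[0, 1] * (s.th2 - s.mu_c[1]) + Qc[0, 2] * (s.th3 - s.mu_c[2])
        ) / Qc[0, 0]
        V1inv = Qc[0, 0]
        w = 1.0 / s2
        rt1 = Sy - s.beta0 * N - s.beta1 * St
        rt2 = Sty - s.beta0 * St - s.beta1 * Stt
        P00 = (N * w).sum(0) + V1inv
        P01 = (St * w).sum(0)
        P11 = (Stt * w).sum(0) + 1.0 / tau2[0]
        h0 = (rt1 * w).sum(0) + c1 * V1inv
        h1 = (rt2 * w).sum(0) + s.mu_ind[0] / tau2[0]
        s.a0, s.a1 = _sample_bvn(P00, P01, P11, h0, h1, rng)

        if not no_random_effects:
            # --- theta5 (slope-on-intercept regression, conjugate) ---
            Sb00 = (s.beta0**2).sum(0)
            Sb01 = (s.beta0 * s.beta1).sum(0)
            prec5 = Sb00 / D110 + 1.0 / tau2[1]
            mean5 = (Sb01 / D110 + s.mu_ind[1] / tau2[1]) / prec5
            s.th5 = mean5 + rng.standard_normal(K) / np.sqrt(prec5)
            b = s.th5

            # --- theta2 = log D00 (MH) ---
            c2 = s.mu_c[1] - (
                Qc[1, 0] * (s.a0 - s.mu_c[0]) + Qc[1, 2] * (s.th3 - s.mu_c[2])
            ) / Qc[1, 1]
            V2 = 1.0 / Qc[1, 1]

            def lt_th2(x):
                return -0.5 * n * x - Sb00 * np.exp(-x) / 2.0 \
                    - (x - c2) ** 2 / (2.0 * V2)

            s.th2 = _mh(s.th2, ad_th2.step, lt_th2, rng, ad_th2, adapting, repeats=2)

            # --- theta3 = log D11.0 (MH) ---
            u = s.beta1 - b * s.beta0
            Su = (u**2).sum(0)
            c3 = s.mu_c[2] - (
                Qc[2, 0] * (s.a0 - s.mu_c[0]) + Qc[2, 1] * (s.th2 - s.mu_c[1])
            ) / Qc[2, 2]
            V3 = 1.0 / Qc[2, 2]

            def lt_th3(x):
                return -0.5 * n * x - Su * np.exp(-x) / 2.0 \
                    - (x - c3) ** 2 / (2.0 * V3)

            s.th3 = _mh(s.th3, ad_th3.step, lt_th3, rng, ad_th3, adapting, repeats=2)

        if fixed_sigma is None:
            # --- theta6 = nu (conjugate) and theta7 = log omega (MH) ---
            Sl = s.lsig.sum(0)
            prec6 = n / omega**2 + 1.0 / tau2[2]
            mean6 = (Sl / omega**2 + s.mu_ind[2] / tau2[2]) / prec6
            s.nu = mean6 + rng.standard_normal(K) / np.sqrt(prec6)

            Sv = ((s.lsig - s.nu) ** 2).sum(0)

            def lt_th7(x):
                return -n * x - Sv * np.exp(-2.0 * x) / 2.0 \
                    - (x - s.mu_ind[3]) ** 2 / (2.0 * tau2[3])

            s.th7 = _mh(s.th7, ad_th7.step, lt_th7, rng, ad_th7, adapting, repeats=2)

        # --- global level ---
        tc = np.stack([s.a0, s.th2, s.th3], axis=1)
        prec = K * Qc + Q0c
        cov = np.linalg.inv(prec)
        mean = cov @ (Qc @ tc.sum(0) + Q0c @ m0c)
        s.mu_c = mean + np.linalg.cholesky(cov) @ rng.standard_normal(3)

        d = tc - s.mu_c
        s.Sigma_c = invwishart.rvs(df=df0 + K, scale=Psi0 + d.T @ d, random_state=rng)

        ti = np.stack([s.a1, s.th5, s.nu, s.th7], axis=1)
        prec_i = K / tau2 + prec0i
        mean_i = (ti.sum(0) / tau2 + m0i * prec0i) / prec_i
        s.mu_ind = mean_i + rng.standard_normal(4) / np.sqrt(prec_i)

        Sq = ((ti - s.mu_ind) ** 2).sum(0)

        def lt_ltau(x):
            return -K * x - Sq * np.exp(-2.0 * x) / 2.0 \
                - np.exp(2.0 * x) / (2.0 * tau_scale2) + x

        ltau = _mh(np.log(s.tau_ind), ad_tau.step, lt_ltau, rng, ad_tau, adapting, repeats=5)
        s.tau_ind = np.exp(ltau)

        if it >= n_burn and (it - n_burn) % thin == 0:
            j = (it - n_burn) // thin
            out_theta[j] = s.theta()
            out_mu_c[j] = s.mu_c
            out_sigma_c[j] = s.Sigma_c
            out_mu_ind[j] = s.mu_ind
            out_tau_ind[j] = s.tau_ind
            if j % effect_thin == 0:
                eff_idx.append(j)
                eff_b0.append(s.beta0.copy())
                eff_b1.append(s.beta1.copy())
                eff_ls.append(s.lsig.copy())

    return {
        "theta": out_theta,
        "mu_c": out_mu_c,
        "sigma_c": out_sigma_c,
        "mu_ind": out_mu_ind,
        "tau_ind": out_tau_ind,
        "effect_index": np.asarray(eff_idx, dtype=int),
        "beta0": np.stack(eff_b0) if eff_b0 else np.empty((0, n, K)),
        "beta1": np.stack(eff_b1) if eff_b1 else np.empty((0, n, K)),
        "log_sigma": np.stack(eff_ls) if eff_ls else np.empty((0, n, K)),
    }
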