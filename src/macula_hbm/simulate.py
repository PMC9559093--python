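"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a longitudinal glaucoma OCT study: ~111 subjects, 4-10
macular scans each over at most 4.2 years, thickness measured on the 7x7
superpixel grid.  Each subject follows a subject-specific line per superpixel
(random intercept + random slope around the population line) with a
subject-specific log-normal residual SD, and the latent vectors are spatially
correlated across superpixels.

Spatial correlation defaults are exponential in grid distance,
corr(k, k') = r^d, attenuated by a factor 0.5 for pairs straddling the
temporal horizontal meridian (between rows 4 and 5, columns 1..4) - the
anatomical raphe across which nerve-fibre-bundle correlations drop sharply.
These defaults are generator conveniences for testing, not estimates from
any cohort.

Random slopes are coupled to random intercepts within a superpixel through
rho_k via the conditional construction beta1 = b * beta0 + sqrt(D11.0) * z,
so cross-superpixel intercept-slope correlations equal rho_k' * C_int(k, k')
and slope-slope correlations are the implied mixture
rho_k rho_k' C_int + sqrt(1 - rho_k^2) sqrt(1 - rho_k'^2) C_slope
(close to C_slope at the default |rho| ~ 0.27).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid_io import LONG_COLUMNS, analysis_labels, parse_label
from .params import (
    GlobalHyperparams,
    SuperpixelParams,
    back_transform_array,
    reference_hyperparams,
)

__all__ = [
    "CohortDesign",
    "SpatialEffectModel",
    "ArtifactConfig",
    "ArtifactTruth",
    "CohortTruth",
    "PCAFixture",
    "grid_correlation",
    "draw_superpixel_params",
    "simulate_cohort",
    "inject_artifacts",
    "build_pca_fixture",
    "true_global_summary",
]


@dataclass(frozen=True)
class CohortDesign:
    """Visit schedule of the emulated study.

    Visit counts are drawn as round(N(visit_mean, visit_sd)) clipped to
    [visit_min, visit_max]; each subject's follow-up length is drawn
    N(followup_mean, followup_sd) truncated to [followup_min, followup_max]
    and visits are spread evenly over it with Gaussian jitter, never closer
    than ``min_gap`` years.  Follow-up is kept >= 2 years and visit gaps
    >= 0.25 years so that an uncorrupted cohort passes the default
    eligibility rules untouched.
    """

    n_subjects: int = 111
    visit_mean: float = 7.3
    visit_sd: float = 1.1
    visit_min: int = 4
    visit_max: int = 10
    followup_mean: float = 3.59
    followup_sd: float = 0.44
    followup_min: float = 2.0
    followup_max: float = 4.2
    min_gap: float = 0.25
    time_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0 < self.followup_min <= self.followup_max):
            raise ValueError("invalid follow-up window")
        if self.visit_min < 2 or self.visit_max < self.visit_min:
            raise ValueError("invalid visit-count range")
        if self.min_gap <= 0:
            raise ValueError("min_gap must be positive")


def grid_correlation(
    r: float, attenuation: float = 0.5, labels: list[str] | None = None
) -> np.ndarray:
    """Exponential-decay correlation r^d on the grid, meridian-attenuated.

    d is the Euclidean distance between (row, col) positions.  Pairs on
    opposite sides of the temporal horizontal meridian (rows <= 4 vs >= 5,
    both columns <= 4) are multiplied by ``attenuation``.  The result is
    projected to the nearest unit-diagonal PSD matrix by eigenvalue clipping
    (the raw attenuated matrix can be slightly indefinite).
    """
    if not 0 < r < 1:
        raise ValueError("decay r must be in (0, 1)")
    labels = labels or analysis_labels()
    pos = np.array([[lab.row, lab.col] for lab in map(parse_label, labels)], float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    C = r**d
    superior = pos[:, 0] <= 4
    temporal = pos[:, 1] <= 4
    straddle = (superior[:, None] != superior[None, :]) & temporal[:, None] & temporal[None, :]
    C = C * np.where(straddle, attenuation, 1.0)
    for _ in range(20):
        w, V = np.linalg.eigh(C)
        if w.min() >= -1e-10:
            break
        C = (V * np.clip(w, 1e-8, None)) @ V.T
        dg = np.sqrt(np.diag(C))
        C = C / np.outer(dg, dg)
    return (C + C.T) / 2.0


def _check_correlation(C: np.ndarray, name: str, K: int) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (K, K):
        raise ValueError(f"{name} must be {K}x{K}")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(C).min() < -1e-8:
        raise ValueError(f"{name} is not positive semi-definite")
    return C


@dataclass
class SpatialEffectModel:
    """Per-superpixel parameters plus cross-superpixel correlations."""

    params: list[SuperpixelParams]
    C_int: np.ndarray
    C_slope: np.ndarray
    C_logsd: np.ndarray
    C_res: np.ndarray
    labels: list[str] = field(default_factory=analysis_labels)

    def __post_init__(self) -> None:
        K = len(self.labels)
        if len(self.params) != K:
            raise ValueError("need one SuperpixelParams per label")
        self.C_int = _check_correlation(self.C_int, "C_int", K)
        self.C_slope = _check_correlation(self.C_slope, "C_slope", K)
        self.C_logsd = _check_correlation(self.C_logsd, "C_logsd", K)
        self.C_res = _check_correlation(self.C_res, "C_res", K)

    @classmethod
    def default(
        cls,
        seed: int,
        hyper: GlobalHyperparams | None = None,
        r_int: float = 0.8,
        r_slope: float = 0.5,
        r_logsd: float = 0.35,
        r_res: float = 0.3,
    ) -> "SpatialEffectModel":
        """Reference-calibrated superpixel parameters + default correlations."""
        labels = analysis_labels()
        params = draw_superpixel_params(hyper or reference_hyperparams(), len(labels), seed)
        return cls(
            params=params,
            C_int=grid_correlation(r_int, labels=labels),
            C_slope=grid_correlation(r_slope, labels=labels),
            C_logsd=grid_correlation(r_logsd, labels=labels),
            C_res=grid_correlation(r_res, labels=labels),
            labels=labels,
        )


@dataclass
class CohortTruth:
    """Latent draws behind a simulated cohort."""

    labels: list[str]
    subjects: list[str]
    params: list[SuperpixelParams]
    theta: np.ndarray  # (K, 7) only when drawn from a hierarchy, else NaN
    beta0: np.ndarray  # (n, K)
    beta1: np.ndarray  # (n, K)
    sigma: np.ndarray  # (n, K)
    visit_times: list[np.ndarray]


def draw_superpixel_params(
    hyper: GlobalHyperparams, K: int, seed: int
) -> list[SuperpixelParams]:
    """Draw K superpixel parameter sets from the reduced-model hierarchy."""
    theta = draw_theta(hyper, K, seed)
    from .params import TransformedParams, transformed_to_interpretable

    return [transformed_to_interpretable(TransformedParams(t)) for t in theta]


def draw_theta(hyper: GlobalHyperparams, K: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    theta = np.empty((K, 7))
    L = np.linalg.cholesky(hyper.Sigma_c)
    theta[:, :3] = hyper.mu_c + rng.standard_normal((K, 3)) @ L.T
    theta[:, 3:] = hyper.mu_ind + hyper.tau_ind * rng.standard_normal((K, 4))
    return theta


def _param_arrays(params: list[SuperpixelParams]) -> dict[str, np.ndarray]:
    from .params import lognormal_sd_params

    a0 = np.array([p.alpha0 for p in params])
    a1 = np.array([p.alpha1 for p in params])
    D00 = np.array([p.D00 for p in params])
    D110 = np.array([p.D11 * (1 - p.rho**2) for p in params])
    b = np.array([p.D01 / p.D00 for p in params])
    nu_om = np.array([lognormal_sd_params(p.sigma_m, p.sigma_s) for p in params])
    return dict(a0=a0, a1=a1, D00=D00, D110=D110, b=b, nu=nu_om[:, 0], omega=nu_om[:, 1])


def _visit_times(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    n = int(np.clip(np.round(rng.normal(design.visit_mean, design.visit_sd)),
                    design.visit_min, design.visit_max))
    while True:
        fu = rng.normal(design.followup_mean, design.followup_sd)
        if design.followup_min <= fu <= design.followup_max:
            break
    for _ in range(100):
        gaps = fu / (n - 1) + design.time_jitter * rng.standard_normal(n - 1)
        gaps = np.clip(gaps, design.min_gap, None)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        times *= fu / times[-1]
        if np.diff(times).min() >= design.min_gap * 0.85 and np.diff(times).min() > 0.2:
            return times
    raise RuntimeError("could not draw a valid visit schedule")  # pragma: no cover


def simulate_cohort(
    model: SpatialEffectModel,
    design: CohortDesign | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a cohort; returns the long table and every latent draw."""
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    K = len(model.labels)
    n = design.n_subjects
    pa = _param_arrays(model.params)

    jitter = 1e-10 * np.eye(K)
    L_int = np.linalg.cholesky(model.C_int + jitter)
    L_slope = np.linalg.cholesky(model.C_slope + jitter)
    L_logsd = np.linalg.cholesky(model.C_logsd + jitter)
    L_res = np.linalg.cholesky(model.C_res + jitter)

    z0 = rng.standard_normal((n, K)) @ L_int.T
    z1 = rng.standard_normal((n, K)) @ L_slope.T
    z2 = rng.standard_normal((n, K)) @ L_logsd.T
    beta0 = np.sqrt(pa["D00"]) * z0
    beta1 = pa["b"] * beta0 + np.sqrt(pa["D110"]) * z1
    sigma = np.exp(pa["nu"] + pa["omega"] * z2)

    subjects = [f"S{i + 1:03d}" for i in range(n)]
    eyes = rng.choice(["OD", "OS"], size=n)
    rows_subj, rows_eye, rows_t, rows_lab, rows_y = [], [], [], [], []
    visit_times: list[np.ndarray] = []
    for i in range(n):
        times = _visit_times(design, rng)
        visit_times.append(times)
        eps = sigma[i] * (rng.standard_normal((times.size, K)) @ L_res.T)
        # floor at a small positive thickness: the linear-Gaussian model has
        # unbounded tails but thickness cannot be negative (truncation is
        # vanishingly rare at the default parameter scale)
        y = np.maximum(
            pa["a0"] + beta0[i]
            + np.outer(times, pa["a1"] + beta1[i])
            + eps,
            0.5,
        )
        for j, t in enumerate(times):
            rows_subj.extend([subjects[i]] * K)
            rows_eye.extend([eyes[i]] * K)
            rows_t.extend([t] * K)
            rows_lab.extend(model.labels)
            rows_y.extend(y[j])

    table = pd.DataFrame(
        {
            "subject_id": rows_subj,
            "eye": rows_eye,
            "time_years": np.round(np.asarray(rows_t), 6),
            "superpixel": rows_lab,
            "thickness_um": np.asarray(rows_y),
        },
        columns=LONG_COLUMNS,
    )
    truth = CohortTruth(
        labels=list(model.labels),
        subjects=subjects,
        params=list(model.params),
        theta=np.full((K, 7), np.nan),
        beta0=beta0,
        beta1=beta1,
        sigma=sigma,
        visit_times=visit_times,
    )
    return table, truth


def true_global_summary(params: list[SuperpixelParams]) -> dict[str, float]:
    """Empirical across-superpixel summary of the realized generator truth."""
    from .params import INTERPRETABLE_NAMES

    V = np.array([p.to_interpretable() for p in params])
    out: dict[str, float] = {}
    for j, name in enumerate(INTERPRETABLE_NAMES):
        out[f"global_mean_{name}"] = float(V[:, j].mean())
        out[f"global_sd_{name}"] = float(V[:, j].std(ddof=1))
    pairs = [(0, 1), (0, 3), (1, 3)]
    for i, j in pairs:
        r = np.corrcoef(V[:, i], V[:, j])[0, 1]
        out[f"corr_{INTERPRETABLE_NAMES[i]}__{INTERPRETABLE_NAMES[j]}"] = float(r)
    return out


@dataclass(frozen=True)
class ArtifactConfig:
    """How many corruptions to inject for exercising the cleaning stage."""

    n_zeros: int = 7
    n_single_spikes: int = 173
    n_double_spike_profiles: int = 18
    spike_magnitude: tuple[float, float] = (25.0, 40.0)

    def __post_init__(self) -> None:
        if min(self.n_zeros, self.n_single_spikes, self.n_double_spike_profiles) < 0:
            raise ValueError("artifact counts must be nonnegative")
        lo, hi = self.spike_magnitude
        if not 0 < lo <= hi:
            raise ValueError("invalid spike magnitude range")


@dataclass
class ArtifactTruth:
    """Ground-truth labels of every injected corruption."""

    zeros: pd.DataFrame  # subject_id, superpixel, time_years
    single_spikes: pd.DataFrame  # subject_id, superpixel, time_years
    double_profiles: pd.DataFrame  # subject_id, superpixel
    double_spike_times: pd.DataFrame  # subject_id, superpixel, time_years


def inject_artifacts(
    table: pd.DataFrame, cfg: ArtifactConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, ArtifactTruth]:
    """Zero out records and add isolated spikes with known ground truth.

    Spikes are added at interior visit positions that are not adjacent to a
    profile endpoint (a >2*delta jump next to an endpoint would trigger the
    endpoint rule and add a second flag), magnitude uniform in
    ``spike_magnitude`` with random sign; double-spike profiles receive two
    spikes at least two positions apart.  Zeroed records are placed in
    otherwise untouched profiles.
    """
    cfg = cfg or ArtifactConfig()
    rng = np.random.default_rng(seed)
    out = table.copy().reset_index(drop=True)

    groups = {
        key: prof.sort_values("time_years")
        for key, prof in out.groupby(["subject_id", "superpixel"], sort=False)
    }
    keys = list(groups)
    rng.shuffle(keys)

    double_ok = [k for k in keys if len(groups[k]) >= 7]
    if len(double_ok) < cfg.n_double_spike_profiles:
        raise ValueError("not enough long profiles for double-spike injection")
    doubles = double_ok[: cfg.n_double_spike_profiles]
    used = set(doubles)
    single_ok = [k for k in keys if k not in used and len(groups[k]) >= 5]
    if len(single_ok) < cfg.n_single_spikes:
        raise ValueError("not enough profiles for single-spike injection")
    singles = single_ok[: cfg.n_single_spikes]
    used.update(singles)
    zero_pool = out.index[
        ~out.set_index(["subject_id", "superpixel"]).index.isin(used)
    ]
    if len(zero_pool) < cfg.n_zeros:
        raise ValueError("not enough untouched records for zero injection")
    zero_idx = rng.choice(zero_pool.to_numpy(), size=cfg.n_zeros, replace=False)

    def _spike(prof: pd.DataFrame, positions: list[int]) -> None:
        for pos in positions:
            idx = prof.index[pos]
            mag = rng.uniform(*cfg.spike_magnitude) * rng.choice([-1.0, 1.0])
            out.loc[idx, "thickness_um"] = max(
                out.loc[idx, "thickness_um"] + mag, 0.5
            )

    single_rows = []
    for key in singles:
        prof = groups[key]
        pos = int(rng.integers(2, len(prof) - 2))
        _spike(prof, [pos])
        single_rows.append(prof.iloc[pos][["subject_id", "superpixel", "time_years"]])

    double_rows, double_time_rows = [], []
    for key in doubles:
        prof = groups[key]
        m = len(prof)
        p1 = int(rng.integers(2, m - 4))
        p2 = int(rng.integers(p1 + 2, m - 2))
        _spike(prof, [p1, p2])
        double_rows.append(pd.Series({"subject_id": key[0], "superpixel": key[1]}))
        for pos in (p1, p2):
            double_time_rows.append(
                prof.iloc[pos][["subject_id", "superpixel", "time_years"]]
            )

    out.loc[zero_idx, "thickness_um"] = 0.0
    truth = ArtifactTruth(
        zeros=out.loc[zero_idx, ["subject_id", "superpixel", "time_years"]].reset_index(drop=True),
        single_spikes=pd.DataFrame(single_rows).reset_index(drop=True),
        double_profiles=pd.DataFrame(double_rows).reset_index(drop=True),
        double_spike_times=pd.DataFrame(double_time_rows).reset_index(drop=True),
    )
    return out, truth


@dataclass
class PCAFixture:
    """Draws from a zero-mean MVN with a prescribed eigenvalue spectrum."""

    samples: np.ndarray  # (n_draws, K)
    covariance: np.ndarray  # (K, K) population covariance
    eigenvalues: np.ndarray  # (K,) descending
    eigenvectors: np.ndarray  # (K, K) columns
    fractions: np.ndarray  # (K,) eigenvalue proportions


def _structured_eigenvectors(K: int, rng: np.random.Generator) -> np.ndarray:
    """First three PCs mimic global / superior-inferior / nasal-temporal
    contrasts on the 7x7 grid; the rest is a random orthonormal completion."""
    labels = analysis_labels()
    pos = np.array([[lab.row, lab.col] for lab in map(parse_label, labels)], float)
    v1 = np.ones(K)
    v2 = np.where(pos[:, 0] <= 3, 1.0, np.where(pos[:, 0] >= 5, -1.0, 0.0))
    v3 = np.where(pos[:, 1] >= 5, 1.0, np.where(pos[:, 1] <= 3, -1.0, 0.0))
    V = np.stack([v1, v2, v3], axis=1)
    V /= np.linalg.norm(V, axis=0)
    # random orthonormal completion via QR of the projected remainder
    M = rng.standard_normal((K, K - 3))
    M -= V @ (V.T @ M)
    Q, _ = np.linalg.qr(M)
    return np.concatenate([V, Q], axis=1)


def build_pca_fixture(
    fractions, K: int = 49, n_draws: int = 2000, seed: int = 0
) -> PCAFixture:
    """Build an MVN sample whose population spectrum has the given leading
    variance fractions; the remainder is spread equally over the other
    dimensions."""
    fr = np.asarray(fractions, dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    if fr.sum() > 1 + 1e-12:
        raise ValueError("fractions must sum to at most 1")
    if fr.size > K:
        raise ValueError("more fractions than dimensions")
    rng = np.random.default_rng(seed)
    full = np.empty(K)
    full[: fr.size] = fr
    full[fr.size:] = (1.0 - fr.sum()) / (K - fr.size) if K > fr.size else 0.0
    order = np.argsort(full)[::-1]
    full = full[order]

    if K == 49:
        V = _structured_eigenvectors(K, rng)
    else:  # small-K harness: random orthonormal basis
        Q, _ = np.linalg.qr(rng.standard_normal((K, K)))
        V = Q
    lam = full * K  # total variance K; only proportions matter
    cov = (V * lam) @ V.T
    samples = rng.standard_normal((n_draws, K)) @ (V * np.sqrt(lam)).T
    return PCAFixture(
        samples=samples,
        covariance=cov,
        eigenvalues=lam,
        eigenvectors=V,
        fractions=full,
    )
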