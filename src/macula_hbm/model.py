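"""The multivariate Bayesian hierarchical longitudinal model.

For subject i, visit time t_ij, superpixel k:

    y_ijk = alpha0_k + alpha1_k t_ij + beta0_ik + beta1_ik t_ij + eps_ijk
    eps_ijk ~ N(0, sigma_ik^2)
    (beta0_ik, beta1_ik) ~ N2(0, D_k),     log sigma_ik ~ N(nu_k, omega_k^2)

with superpixel-level parameters tied together through the reduced
hierarchical prior on the transformed 7-vector theta_k (see
:mod:`macula_hbm.params`): (theta1, theta2, theta3)_k trivariate normal,
theta4..theta7 independent normals, and proper vague hyperpriors.

Posterior sampling is the blocked Gibbs scheme of :mod:`macula_hbm._gibbs`.
The default configuration (3 chains x 3000 kept draws after 1500 burn-in) is
a desk-scale setting; a publication-scale configuration (3 x 150 000
iterations, 50 000 burn-in, thinning 50) is available via
:meth:`MCMCConfig.publication_scale`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._gibbs import PriorConfig, SuffStats, prepare_stats, run_chain
from .grid_io import GridMap, analysis_labels, validate_long_table
from .params import INTERPRETABLE_NAMES, back_transform_array

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "PosteriorDraws",
    "HierarchicalGCCModel",
    "fit_mcmc",
    "summarize_global",
    "posterior_mean_maps",
    "log_likelihood",
]

#: Pairs of interpretable parameters whose across-superpixel correlation is
#: reported (canonical indices): intercept~RI-SD, intercept~RS-SD, RI-SD~RS-SD.
SUMMARY_CORR_PAIRS = ((0, 1), (0, 3), (1, 3))


@dataclass(frozen=True)
class MCMCConfig:
    """chains x (burn_in + draws * thin) iterations; ``draws`` are kept
    post-thinning draws per chain.  ``effect_thin`` controls how sparsely
    subject-level effects are stored (memory)."""

    chains: int = 3
    burn_in: int = 1500
    draws: int = 3000
    thin: int = 1
    effect_thin: int = 10

    @classmethod
    def publication_scale(cls) -> "MCMCConfig":
        return cls(chains=3, burn_in=50_000, draws=3000, thin=50, effect_thin=10)


@dataclass
class PosteriorDraws:
    """Stacked posterior draws of all model unknowns.

    ``theta`` holds the full chain for superpixel-level transformed
    parameters; subject-level effects are stored for the thinned subset
    ``effect_index`` of draws.
    """

    theta: np.ndarray  # (S, K, 7)
    mu_c: np.ndarray  # (S, 3)
    sigma_c: np.ndarray  # (S, 3, 3)
    mu_ind: np.ndarray  # (S, 4)
    tau_ind: np.ndarray  # (S, 4)
    chain: np.ndarray  # (S,)
    effect_index: np.ndarray  # (Se,) indices into 0..S-1
    beta0: np.ndarray  # (Se, n, K)
    beta1: np.ndarray  # (Se, n, K)
    log_sigma: np.ndarray  # (Se, n, K)
    subjects: list[str]
    labels: list[str]
    table: pd.DataFrame = field(repr=False)
    diagnostics: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    def interpretable(self) -> np.ndarray:
        """Back-transformed draws, shape (S, K, 7) in canonical order."""
        return back_transform_array(self.theta)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            outdir / "draws.npz",
            theta=self.theta,
            mu_c=self.mu_c,
            sigma_c=self.sigma_c,
            mu_ind=self.mu_ind,
            tau_ind=self.tau_ind,
            chain=self.chain,
            effect_index=self.effect_index,
            beta0=self.beta0,
            beta1=self.beta1,
            log_sigma=self.log_sigma,
        )
        self.table.to_csv(outdir / "table.csv", index=False)
        manifest = {
            "subjects": self.subjects,
            "labels": self.labels,
            "n_draws": int(self.n_draws),
            "arrays": {
                "theta": "(draw, superpixel, transformed-parameter 1..7)",
                "beta0/beta1/log_sigma": "(stored effect draw, subject, superpixel)",
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        if self.diagnostics is not None:
            self.diagnostics.to_csv(outdir / "diagnostics.csv")

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        arrs = np.load(outdir / "draws.npz")
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)
        table = pd.read_csv(
            outdir / "table.csv", dtype={"subject_id": str, "superpixel": str}
        )
        diag = None
        if (outdir / "diagnostics.csv").exists():
            diag = pd.read_csv(outdir / "diagnostics.csv", index_col=0)
        return cls(
            theta=arrs["theta"],
            mu_c=arrs["mu_c"],
            sigma_c=arrs["sigma_c"],
            mu_ind=arrs["mu_ind"],
            tau_ind=arrs["tau_ind"],
            chain=arrs["chain"],
            effect_index=arrs["effect_index"],
            beta0=arrs["beta0"],
            beta1=arrs["beta1"],
            log_sigma=arrs["log_sigma"],
            subjects=manifest["subjects"],
            labels=manifest["labels"],
            table=table,
            diagnostics=diag,
        )


def _diagnostics(chunks: list[dict[str, np.ndarray]]) -> pd.DataFrame:
    """Split-chain R-hat and effective sample size for the hyperparameters."""
    names, series = [], []
    for j in range(3):
        names.append(f"mu_c[{j}]")
        series.append(np.stack([c["mu_c"][:, j] for c in chunks]))
    for j in range(3):
        names.append(f"sigma_c[{j},{j}]")
        series.append(np.stack([c["sigma_c"][:, j, j] for c in chunks]))
    for j, nm in enumerate(["mu_theta4", "mu_theta5", "mu_theta6", "mu_theta7"]):
        names.append(nm)
        series.append(np.stack([c["mu_ind"][:, j] for c in chunks]))
    for j, nm in enumerate(["tau_theta4", "tau_theta5", "tau_theta6", "tau_theta7"]):
        names.append(nm)
        series.append(np.stack([c["tau_ind"][:, j] for c in chunks]))
    rows = []
    for nm, arr in zip(names, series):
        da = az.convert_to_dataset(arr)  # (chain, draw)
        rows.append(
            {
                "parameter": nm,
                "rhat": float(az.rhat(da)["x"].values),
                "ess_bulk": float(az.ess(da)["x"].values),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


class HierarchicalGCCModel(BaseEstimator):
    """Scikit-learn style estimator for the hierarchical longitudinal model.

    Parameters mirror :class:`MCMCConfig` and :class:`PriorConfig`; ``fit``
    expects a validated long table (one row per subject-visit-superpixel)
    and exposes the posterior on fitted attributes:

    ``draws_``
        :class:`PosteriorDraws` with all sampled unknowns.
    ``summary_``
        Global (across-superpixel) posterior summary table.
    ``diagnostics_``
        Split-chain R-hat / ESS for the hyperparameters.

    ``fixed_sigma`` and ``no_random_effects`` reduce the model to plain
    (weighted) Bayesian linear regression; used by closed-form oracle checks.
    """

    def __init__(
        self,
        chains: int = 3,
        burn_in: int = 1500,
        draws: int = 3000,
        thin: int = 1,
        effect_thin: int = 10,
        prior: PriorConfig | None = None,
        random_state: int = 0,
        fixed_sigma: float | None = None,
        no_random_effects: bool = False,
    ) -> None:
        self.chains = chains
        self.burn_in = burn_in
        self.draws = draws
        self.thin = thin
        self.effect_thin = effect_thin
        self.prior = prior
        self.random_state = random_state
        self.fixed_sigma = fixed_sigma
        self.no_random_effects = no_random_effects

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalGCCModel":
        table = validate_long_table(X)
        if not np.isfinite(table["thickness_um"]).all():
            raise ValueError("non-finite thickness values")
        stats = prepare_stats(table)
        if stats.n_subjects < 2:
            raise ValueError("need at least 2 subjects per superpixel")
        prior = self.prior or PriorConfig()
        ss = np.random.SeedSequence(self.random_state)
        chunks = []
        for c, child in enumerate(ss.spawn(self.chains)):
            rng = np.random.default_rng(child)
            chunks.append(
                run_chain(
                    stats,
                    prior,
                    n_burn=self.burn_in,
                    n_keep=self.draws,
                    thin=self.thin,
                    effect_thin=self.effect_thin,
                    rng=rng,
                    fixed_sigma=self.fixed_sigma,
                    no_random_effects=self.no_random_effects,
                    init_jitter=0.05 * (1 + c),
                )
            )
        diag = _diagnostics(chunks) if (self.chains >= 2 and self.draws >= 4) else None
        offs = np.arange(self.chains) * self.draws
        self.draws_ = PosteriorDraws(
            theta=np.concatenate([c["theta"] for c in chunks]),
            mu_c=np.concatenate([c["mu_c"] for c in chunks]),
            sigma_c=np.concatenate([c["sigma_c"] for c in chunks]),
            mu_ind=np.concatenate([c["mu_ind"] for c in chunks]),
            tau_ind=np.concatenate([c["tau_ind"] for c in chunks]),
            chain=np.repeat(np.arange(self.chains), self.draws),
            effect_index=np.concatenate(
                [c["effect_index"] + o for c, o in zip(chunks, offs)]
            ),
            beta0=np.concatenate([c["beta0"] for c in chunks]),
            beta1=np.concatenate([c["beta1"] for c in chunks]),
            log_sigma=np.concatenate([c["log_sigma"] for c in chunks]),
            subjects=stats.subjects,
            labels=stats.labels,
            table=table,
            diagnostics=diag,
        )
        self.labels_ = stats.labels
        self.subjects_ = stats.subjects
        self.diagnostics_ = diag
        self.summary_ = summarize_global(self.draws_)
        return self

    def summarize_global(self) -> pd.DataFrame:
        return summarize_global(self.draws_)

    def posterior_mean_maps(self) -> dict[str, GridMap]:
        return posterior_mean_maps(self.draws_)


def fit_mcmc(
    table: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Functional wrapper over :class:`HierarchicalGCCModel`."""
    mcmc = mcmc or MCMCConfig()
    model = HierarchicalGCCModel(
        chains=mcmc.chains,
        burn_in=mcmc.burn_in,
        draws=mcmc.draws,
        thin=mcmc.thin,
        effect_thin=mcmc.effect_thin,
        prior=priors,
        random_state=seed,
    )
    model.fit(table)
    return model.draws_


def _per_draw_summaries(draws: PosteriorDraws) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S, 7) across-superpixel means, (S, 7) SDs, (S, 3) correlations."""
    interp = draws.interpretable()  # (S, K, 7)
    means = interp.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sds = interp.std(axis=1, ddof=1) if interp.shape[1] > 1 else np.full_like(means, np.nan)
    corrs = np.empty((interp.shape[0], len(SUMMARY_CORR_PAIRS)))
    centered = interp - means[:, None, :]
    denom = sds * np.sqrt(interp.shape[1] - 1)
    for m, (i, j) in enumerate(SUMMARY_CORR_PAIRS):
        num = (centered[:, :, i] * centered[:, :, j]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrs[:, m] = num / (denom[:, i] * denom[:, j])
    return means, sds, corrs


def summarize_global(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary of across-superpixel means, SDs and correlations.

    Per draw, all superpixels are back-transformed to the interpretable
    scale and summarized empirically across the K superpixels; the table
    reports posterior mean, SD and central 95% interval of each summary.
    Correlations undefined for degenerate draws (zero across-superpixel SD)
    are reported as missing.
    """
    means, sds, corrs = _per_draw_summaries(draws)
    rows = []

    def add(name: str, samples: np.ndarray) -> None:
        samples = samples[np.isfinite(samples)]
        if samples.size == 0:
            rows.append(
                {"summary": name, "mean": np.nan, "sd": np.nan,
                 "q2.5": np.nan, "q97.5": np.nan}
            )
            return
        rows.append(
            {
                "summary": name,
                "mean": float(samples.mean()),
                "sd": float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
                "q2.5": float(np.quantile(samples, 0.025)),
                "q97.5": float(np.quantile(samples, 0.975)),
            }
        )

    for j, nm in enumerate(INTERPRETABLE_NAMES):
        add(f"global_mean_{nm}", means[:, j])
    for j, nm in enumerate(INTERPRETABLE_NAMES):
        add(f"global_sd_{nm}", sds[:, j])
    for m, (i, j) in enumerate(SUMMARY_CORR_PAIRS):
        add(
            f"corr_{INTERPRETABLE_NAMES[i]}__{INTERPRETABLE_NAMES[j]}",
            corrs[:, m],
        )
    return pd.DataFrame(rows).set_index("summary")


def posterior_mean_maps(draws: PosteriorDraws) -> dict[str, GridMap]:
    """One 7x7 posterior-mean map per interpretable parameter."""
    if sorted(draws.labels) != sorted(analysis_labels()):
        raise ValueError("posterior_mean_maps requires the full 7x7 grid")
    interp = draws.interpretable().mean(axis=0)  # (K, 7)
    maps = {}
    for j, nm in enumerate(INTERPRETABLE_NAMES):
        maps[nm] = GridMap.from_dict(
            dict(zip(draws.labels, interp[:, j])), name=nm
        )
    return maps


def log_likelihood(
    table: pd.DataFrame,
    params: dict[str, "object"],
    effects: pd.DataFrame,
) -> float:
    """Gaussian log likelihood of the long table under given parameters.

    ``params`` maps superpixel label -> :class:`SuperpixelParams` (only
    alpha0/alpha1 are used); ``effects`` has columns subject_id, superpixel,
    beta0, beta1, sigma covering every (subject, superpixel) in the table.
    """
    t = validate_long_table(table)
    merged = t.merge(effects, on=["subject_id", "superpixel"], how="left")
    if merged["sigma"].isna().any():
        missing = merged.loc[
            merged["sigma"].isna(), ["subject_id", "superpixel"]
        ].drop_duplicates()
        raise ValueError(f"missing subject effects for {missing.values.tolist()}")
    a0 = merged["superpixel"].map(lambda k: params[k].alpha0).to_numpy(float)
    a1 = merged["superpixel"].map(lambda k: params[k].alpha1).to_numpy(float)
    tt = merged["time_years"].to_numpy(float)
    mean = a0 + a1 * tt + merged["beta0"].to_numpy(float) + merged["beta1"].to_numpy(float) * tt
    sig = merged["sigma"].to_numpy(float)
    z = (merged["thickness_um"].to_numpy(float) - mean) / sig
    return float(-0.5 * np.sum(z**2) - np.sum(np.log(sig)) - 0.5 * z.size * np.log(2 * np.pi))
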