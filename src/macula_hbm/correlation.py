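"""Posterior cross-superpixel covariance/correlation of effects and residuals.

For each stored posterior draw, the subject random intercepts, random
slopes, log residual SDs (rows = subjects) or the subject-visit residuals
(rows = visits) form a rows x 49 matrix; the sample covariance across rows
(pairwise-complete where cleaning removed cells) is averaged over draws, and
the reported correlation matrix is derived from that posterior-mean
covariance.  Averaging per-draw correlation matrices instead is available
via ``method="mean_correlation"``.

Correlations of log residual *variances* equal those of log residual SDs
(log variance = 2 log SD, and correlation is affine-invariant), so the log
SD is the stored quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .grid_io import parse_label
from .model import PosteriorDraws

__all__ = [
    "KINDS",
    "EffectCovariance",
    "effect_matrix",
    "iter_effect_matrices",
    "cross_superpixel_correlation",
    "correlogram",
    "adjacent_mean_correlation",
]

KINDS = ("intercept", "slope", "log_residual_sd", "residual")


@dataclass
class EffectCovariance:
    """49x49 covariance and correlation for one effect kind."""

    kind: str
    covariance: np.ndarray
    correlation: np.ndarray
    n_draws: int
    labels: list[str]


def _table_arrays(draws: PosteriorDraws):
    t = draws.table
    si = {s: i for i, s in enumerate(draws.subjects)}
    ki = {k: i for i, k in enumerate(draws.labels)}
    ii = t["subject_id"].map(si).to_numpy()
    kk = t["superpixel"].map(ki).to_numpy()
    tt = t["time_years"].to_numpy(float)
    yy = t["thickness_um"].to_numpy(float)
    # visit rows: unique (subject, time)
    visit_key = pd.MultiIndex.from_arrays([t["subject_id"], t["time_years"]])
    codes, _ = pd.factorize(visit_key, sort=True)
    return ii, kk, tt, yy, codes


def _presence_mask(draws: PosteriorDraws) -> np.ndarray:
    """(n_subjects, K) True where a (subject, superpixel) profile has data."""
    ii, kk, *_ = _table_arrays(draws)
    mask = np.zeros((len(draws.subjects), len(draws.labels)), dtype=bool)
    mask[ii, kk] = True
    return mask


def _one_matrix(draws: PosteriorDraws, kind: str, draw: int, cache) -> np.ndarray:
    ii, kk, tt, yy, visit = cache["arrays"]
    if kind in ("intercept", "slope", "log_residual_sd"):
        arr = {
            "intercept": draws.beta0,
            "slope": draws.beta1,
            "log_residual_sd": draws.log_sigma,
        }[kind][draw].copy()
        arr[~cache["mask"]] = np.nan
        return arr
    # residuals: rows are subject-visits
    s = draws.effect_index[draw]
    theta = draws.theta[s]
    a0, a1 = theta[:, 0], theta[:, 3]
    b0 = draws.beta0[draw]
    b1 = draws.beta1[draw]
    fitted = a0[kk] + a1[kk] * tt + b0[ii, kk] + b1[ii, kk] * tt
    out = np.full((visit.max() + 1, len(draws.labels)), np.nan)
    out[visit, kk] = yy - fitted
    return out


def _cache(draws: PosteriorDraws) -> dict:
    ii, kk, tt, yy, visit = _table_arrays(draws)
    mask = np.zeros((len(draws.subjects), len(draws.labels)), dtype=bool)
    mask[ii, kk] = True
    return {"arrays": (ii, kk, tt, yy, visit), "mask": mask}


def effect_matrix(draws: PosteriorDraws, kind: str, draw: int = 0) -> np.ndarray:
    """Rows x 49 effect matrix for one stored effect draw.

    Rows are subjects (intercept/slope/log_residual_sd) or subject-visits
    (residual); ``draw`` indexes the stored (thinned) effect draws.  Cells
    removed in cleaning are NaN.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")
    return _one_matrix(draws, kind, draw, _cache(draws))


def iter_effect_matrices(draws: PosteriorDraws, kind: str) -> Iterator[np.ndarray]:
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")
    cache = _cache(draws)
    for d in range(len(draws.effect_index)):
        yield _one_matrix(draws, kind, d, cache)


def pairwise_complete_cov(X: np.ndarray, min_rows: int = 3) -> np.ndarray:
    """Sample covariance across rows using pairwise-complete observations.

    Columns with fewer than ``min_rows`` complete pairs get NaN entries.
    Exact matrix-product implementation (no per-pair loops).
    """
    M = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    n = M.T @ M  # pairwise counts
    S = X0.T @ X0
    sum_p = X0.T @ M  # sum of column p over rows where q present
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (S - sum_p * sum_p.T / n) / (n - 1)
    cov[n < min_rows] = np.nan
    return (cov + cov.T) / 2.0


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def cross_superpixel_correlation(
    draws: PosteriorDraws,
    kind: str,
    method: str = "mean_covariance",
    min_rows: int = 3,
) -> EffectCovariance:
    """Posterior-mean 49x49 covariance and its correlation matrix."""
    if method not in ("mean_covariance", "mean_correlation"):
        raise ValueError("method must be 'mean_covariance' or 'mean_correlation'")
    covs, corrs = [], []
    for X in iter_effect_matrices(draws, kind):
        cov = pairwise_complete_cov(X, min_rows=min_rows)
        covs.append(cov)
        if method == "mean_correlation":
            corrs.append(_cov_to_corr(cov))
    mean_cov = np.nanmean(np.stack(covs), axis=0) if covs else np.full(
        (draws.K, draws.K), np.nan
    )
    # pairwise-complete estimation can leave the average slightly indefinite;
    # project onto the PSD cone (exact no-op for complete data)
    if np.isfinite(mean_cov).all():
        w, V = np.linalg.eigh((mean_cov + mean_cov.T) / 2.0)
        if w.min() < 0:
            mean_cov = (V * np.clip(w, 0.0, None)) @ V.T
    if method == "mean_correlation":
        corr = np.nanmean(np.stack(corrs), axis=0)
        np.fill_diagonal(corr, 1.0)
    else:
        corr = _cov_to_corr(mean_cov)
    return EffectCovariance(
        kind=kind,
        covariance=mean_cov,
        correlation=corr,
        n_draws=len(covs),
        labels=list(draws.labels),
    )


def correlogram(ec: EffectCovariance) -> np.ndarray:
    """Nested (7, 7, 7, 7) grid: outer index = reference superpixel,
    inner 7x7 = its correlation with every superpixel (reference cell 1)."""
    K = len(ec.labels)
    pos = [parse_label(lab) for lab in ec.labels]
    if K != 49 or sorted((p.row, p.col) for p in pos) != [
        (r, c) for r in range(1, 8) for c in range(1, 8)
    ]:
        raise ValueError("correlogram requires the full 7x7 grid")
    out = np.full((7, 7, 7, 7), np.nan)
    for a, pa in enumerate(pos):
        for b, pb in enumerate(pos):
            out[pa.row - 1, pa.col - 1, pb.row - 1, pb.col - 1] = ec.correlation[a, b]
    return out


def adjacent_mean_correlation(ec: EffectCovariance) -> float:
    """Mean correlation over grid-adjacent (distance-1) superpixel pairs."""
    pos = np.array([[p.row, p.col] for p in map(parse_label, ec.labels)], float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = np.isclose(d, 1.0)
    vals = ec.correlation[adj]
    return float(np.nanmean(vals))
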