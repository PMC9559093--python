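"""Shared fixtures: small synthetic cohorts and reusable model factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from macula_hbm import SuperpixelParams
from macula_hbm.simulate import CohortDesign, SpatialEffectModel, grid_correlation


def small_labels(nrow: int = 3, ncol: int = 3) -> list[str]:
    """A small sub-grid of valid superpixel labels for fast tests."""
    return [f"{r}.{c}" for r in range(1, nrow + 1) for c in range(1, ncol + 1)]


def make_params(
    K: int,
    alpha0: float = 73.0,
    ri_sd: float = 14.0,
    alpha1: float = -0.36,
    rs_sd: float = 0.85,
    rho: float = -0.27,
    sigma_m: float = 1.9,
    sigma_s: float = 0.7,
) -> list[SuperpixelParams]:
    return [
        SuperpixelParams.from_interpretable(
            alpha0, ri_sd, alpha1, rs_sd, rho, sigma_m, sigma_s
        )
        for _ in range(K)
    ]


def small_effect_model(
    labels: list[str] | None = None,
    low_noise: bool = False,
    draw_params_seed: int | None = None,
    **overrides,
) -> SpatialEffectModel:
    """Constant parameters by default; ``draw_params_seed`` draws them from
    the reference hierarchy instead (realistic across-superpixel spread,
    which model fits need — zero spread sits in the hierarchy's funnel)."""
    labels = labels or small_labels()
    K = len(labels)
    if draw_params_seed is not None:
        from macula_hbm.params import reference_hyperparams
        from macula_hbm.simulate import draw_superpixel_params

        params = draw_superpixel_params(reference_hyperparams(), K, draw_params_seed)
    else:
        kw = dict(sigma_m=0.5, sigma_s=1e-6) if low_noise else {}
        kw.update(overrides)
        params = make_params(K, **kw)
    return SpatialEffectModel(
        params=params,
        C_int=grid_correlation(0.8, labels=labels),
        C_slope=grid_correlation(0.5, labels=labels),
        C_logsd=grid_correlation(0.35, labels=labels),
        C_res=grid_correlation(0.3, labels=labels),
        labels=labels,
    )


def small_design(n_subjects: int = 8) -> CohortDesign:
    return CohortDesign(n_subjects=n_subjects)


def toy_table() -> pd.DataFrame:
    """A tiny fully valid long table with two subjects and two superpixels."""
    rows = []
    for si, s in enumerate(("A", "B")):
        for t in (0.0, 0.5, 1.1, 2.3):
            for ki, k in enumerate(("4.4", "4.5")):
                rows.append((s, "OD", t, k, 80.0 + (si * 3 + int(t * 10) + ki) % 7))
    return pd.DataFrame(
        rows, columns=["subject_id", "eye", "time_years", "superpixel", "thickness_um"]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
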