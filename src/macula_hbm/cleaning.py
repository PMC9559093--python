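"""Data eligibility and artifact removal for longitudinal thickness tables.

The cleaning pipeline applies, in order:

1. visit filtering — visits closer than ``min_visit_gap`` years to the
   previously retained visit are dropped (all superpixels of that visit),
   visits beyond ``max_followup`` years are dropped, and subjects left with
   fewer than ``min_visits`` visits or less than ``min_followup`` years of
   follow-up are removed entirely;
2. zero removal — thickness values of exactly 0 are erroneous exports;
3. spike removal per (subject, superpixel) profile — an interior
   observation is flagged when it rises (or falls) by more than ``delta`` um
   relative to *both* neighbours (same-sign double exceedance); an endpoint
   is flagged when it differs from its only neighbour by more than
   ``2 * delta``.  Flags are computed in a single pass on the original
   profile.  A profile with >= ``profile_outlier_limit`` flags is removed
   whole; a profile with exactly one flag loses only that observation.

Every removed record carries exactly one rule tag, and the report reconciles
input = retained + removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid_io import validate_long_table

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "LongTableCleaner",
    "filter_visits",
    "remove_zeros",
    "detect_spike_outliers",
    "apply_cleaning",
]

logger = logging.getLogger(__name__)

#: Rule tags carried by removed records.
RULES = (
    "short_interval",
    "late_visit",
    "ineligible_subject",
    "zero",
    "single_outlier",
    "outlying_profile",
)

_REMOVAL_COLUMNS = ["subject_id", "superpixel", "time_years", "rule"]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the cleaning pipeline (units: years, um, counts)."""

    min_visit_gap: float = 0.2
    max_followup: float = 4.2
    min_visits: int = 4
    min_followup: float = 2.0
    spike_threshold: float = 10.0
    profile_outlier_limit: int = 2

    def __post_init__(self) -> None:
        for name in ("min_visit_gap", "max_followup", "min_followup", "spike_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_visits < 1:
            raise ValueError("min_visits must be >= 1")
        if self.profile_outlier_limit < 2:
            raise ValueError("profile_outlier_limit must be >= 2")


@dataclass
class CleaningReport:
    """Counts and per-record provenance of everything the pipeline removed."""

    n_input: int
    n_retained: int
    n_zeros: int
    n_single_outliers: int
    n_outlying_profiles: int
    n_profile_observations: int
    n_short_interval: int
    n_late_visit: int
    n_ineligible_subject: int
    removals: pd.DataFrame = field(repr=False)

    @property
    def n_removed(self) -> int:
        return len(self.removals)

    def counts(self) -> dict[str, int]:
        d = asdict(self)
        d.pop("removals")
        return d

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts(),
            "removals": self.removals.to_dict(orient="records"),
        }


def _empty_removals() -> pd.DataFrame:
    return pd.DataFrame(columns=_REMOVAL_COLUMNS)


def _tag(records: pd.DataFrame, rule: str) -> pd.DataFrame:
    out = records.loc[:, ["subject_id", "superpixel", "time_years"]].copy()
    out["rule"] = rule
    return out


def filter_visits(
    table: pd.DataFrame, cfg: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply visit-interval, follow-up-window and subject-eligibility rules.

    Returns the retained table and a removal provenance frame.
    """
    cfg = cfg or CleaningConfig()
    table = validate_long_table(table)
    removals: list[pd.DataFrame] = []
    keep_mask = pd.Series(True, index=table.index)

    for subject, sub in table.groupby("subject_id", sort=False):
        times = np.sort(sub["time_years"].unique())
        retained: list[float] = []
        for t in times:
            if t > cfg.max_followup:
                rows = sub[sub["time_years"] == t]
                removals.append(_tag(rows, "late_visit"))
                keep_mask[rows.index] = False
            elif retained and t - retained[-1] < cfg.min_visit_gap:
                rows = sub[sub["time_years"] == t]
                removals.append(_tag(rows, "short_interval"))
                keep_mask[rows.index] = False
            else:
                retained.append(t)
        followup = retained[-1] - retained[0] if retained else 0.0
        if len(retained) < cfg.min_visits or followup < cfg.min_followup:
            rows = sub[keep_mask[sub.index]]
            removals.append(_tag(rows, "ineligible_subject"))
            keep_mask[rows.index] = False

    removed = (
        pd.concat(removals, ignore_index=True) if removals else _empty_removals()
    )
    return table[keep_mask].reset_index(drop=True), removed


def remove_zeros(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop thickness == 0 records (erroneous exports), tagging them "zero"."""
    zero = table["thickness_um"] == 0.0
    removed = _tag(table[zero], "zero")
    return table[~zero].reset_index(drop=True), removed


def detect_spike_outliers(values: np.ndarray, delta: float) -> set[int]:
    """Flag isolated spikes/dips in a time-ordered thickness sequence.

    Interior index j is flagged iff (y_j - y_{j-1}) and (y_j - y_{j+1}) have
    the same sign and both magnitudes exceed ``delta``.  Endpoints are
    flagged iff they differ from their only neighbour by more than
    ``2 * delta``.  Single pass on the original sequence; no iteration after
    removal.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        warnings.warn(
            f"profile of length {y.size} < 3: spike detection skipped",
            stacklevel=2,
        )
        return set()
    flags: set[int] = set()
    left = y[1:-1] - y[:-2]
    right = y[1:-1] - y[2:]
    interior = (np.sign(left) == np.sign(right)) & (np.abs(left) > delta) & (
        np.abs(right) > delta
    )
    flags.update(np.nonzero(interior)[0] + 1)
    if abs(y[0] - y[1]) > 2 * delta:
        flags.add(0)
    if abs(y[-1] - y[-2]) > 2 * delta:
        flags.add(y.size - 1)
    return flags


def apply_cleaning(
    table: pd.DataFrame, cfg: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full pipeline: visit rules -> zeros -> per-profile spikes."""
    cfg = cfg or CleaningConfig()
    table = validate_long_table(table)
    n_input = len(table)

    kept, visit_removed = filter_visits(table, cfg)
    kept, zero_removed = remove_zeros(kept)

    removal_frames = [visit_removed, zero_removed]
    drop_index: list[np.ndarray] = []
    n_profiles_removed = 0
    n_profile_obs = 0
    n_single = 0

    for _, prof in kept.groupby(["subject_id", "superpixel"], sort=False):
        prof = prof.sort_values("time_years")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = detect_spike_outliers(prof["thickness_um"].to_numpy(), cfg.spike_threshold)
        if len(flags) >= cfg.profile_outlier_limit:
            removal_frames.append(_tag(prof, "outlying_profile"))
            drop_index.append(prof.index.to_numpy())
            n_profiles_removed += 1
            n_profile_obs += len(prof)
        elif len(flags) == 1:
            rows = prof.iloc[sorted(flags)]
            removal_frames.append(_tag(rows, "single_outlier"))
            drop_index.append(rows.index.to_numpy())
            n_single += 1

    if drop_index:
        kept = kept.drop(index=np.concatenate(drop_index)).reset_index(drop=True)

    removals = pd.concat(
        [f for f in removal_frames if len(f)], ignore_index=True
    ) if any(len(f) for f in removal_frames) else _empty_removals()

    by_rule = removals["rule"].value_counts().to_dict() if len(removals) else {}
    report = CleaningReport(
        n_input=n_input,
        n_retained=len(kept),
        n_zeros=by_rule.get("zero", 0),
        n_single_outliers=by_rule.get("single_outlier", 0),
        n_outlying_profiles=n_profiles_removed,
        n_profile_observations=by_rule.get("outlying_profile", 0),
        n_short_interval=by_rule.get("short_interval", 0),
        n_late_visit=by_rule.get("late_visit", 0),
        n_ineligible_subject=by_rule.get("ineligible_subject", 0),
        removals=removals,
    )
    assert report.n_retained + report.n_removed == report.n_input
    return kept, report


class LongTableCleaner(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping :func:`apply_cleaning`.

    ``transform`` returns the cleaned long table and stores the removal
    report on ``report_``.
    """

    def __init__(
        self,
        min_visit_gap: float = 0.2,
        max_followup: float = 4.2,
        min_visits: int = 4,
        min_followup: float = 2.0,
        spike_threshold: float = 10.0,
        profile_outlier_limit: int = 2,
    ) -> None:
        self.min_visit_gap = min_visit_gap
        self.max_followup = max_followup
        self.min_visits = min_visits
        self.min_followup = min_followup
        self.spike_threshold = spike_threshold
        self.profile_outlier_limit = profile_outlier_limit

    def _config(self) -> CleaningConfig:
        return CleaningConfig(
            min_visit_gap=self.min_visit_gap,
            max_followup=self.max_followup,
            min_visits=self.min_visits,
            min_followup=self.min_followup,
            spike_threshold=self.spike_threshold,
            profile_outlier_limit=self.profile_outlier_limit,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "LongTableCleaner":
        validate_long_table(X)
        self._config()  # validates thresholds
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cleaned, report = apply_cleaning(X, self._config())
        self.report_ = report
        return cleaned
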