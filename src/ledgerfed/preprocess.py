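"""Unified preprocessing: eligibility filtering, hourly gridding, winsorized
train-only normalization, forward-fill imputation with mask channels, and
training-time augmentation.

Order of operations is fixed and documented: deduplicate exact records ->
hourly mean -> winsor clip to training 1st/99th percentiles -> record the
missingness mask -> forward fill along time -> training-mean imputation of
leading gaps -> z-score with training statistics (sd floored at 1e-8 so
constant variables map to zero). All statistics are fitted on the training
split only; applying an unfitted state is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ledgerfed.cohort import RawCohort
from ledgerfed.errors import (
    ConfigurationError,
    DataError,
    FitError,
    SchemaError,
    SplitError,
)

SD_FLOOR = 1e-8
T_HOURS = 48


@dataclass
class GriddedEpisode:
    """Pre-imputation hourly grid for one patient; NaN marks undefined cells."""

    patient_id: str
    site_id: str
    grid: np.ndarray  # (T, D) with NaN for unobserved cells
    label: int


@dataclass
class EpisodeTensor:
    """Model-ready episode: values X, missingness mask M, outcome y.

    ``normalized`` guards against double application of the transform.
    """

    patient_id: str
    site_id: str
    X: np.ndarray  # (T, D) float
    M: np.ndarray  # (T, D) in {0, 1}
    y: int
    normalized: bool = False


@dataclass
class PreprocessorState:
    """Training-set statistics applied identically to every split."""

    variable_ids: list[str]
    winsor_low: np.ndarray
    winsor_high: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray
    impute_value: np.ndarray
    fitted_on: str = "train"


@dataclass
class SplitAssignment:
    """Exhaustive, disjoint patient-level mapping to train/val/test."""

    assignment: dict[str, str] = field(default_factory=dict)

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]


def filter_eligible(cohort: RawCohort, horizon_hours: int = T_HOURS) -> tuple[RawCohort, dict]:
    """Drop patients without a valid label or without any observed event
    inside the first ``horizon_hours`` hours.

    Returns the retained cohort and a per-reason exclusion count
    (``missing_label``, ``insufficient_window``).
    """
    horizon_minutes = horizon_hours * 60
    out = cohort.copy()
    exclusions = {"missing_label": 0, "insufficient_window": 0}

    labels = out.outcomes["label"]
    valid_label = labels.notna() & labels.isin([0, 1])
    exclusions["missing_label"] = int((~valid_label).sum())
    labeled = set(out.outcomes.loc[valid_label, "patient_id"])

    in_window = cohort.measurements["minutes_from_admission"] < horizon_minutes
    observed = set(cohort.measurements.loc[in_window, "patient_id"])
    keep = {p for p in labeled if p in observed}
    exclusions["insufficient_window"] = len(labeled) - len(keep)

    out.measurements = out.measurements[out.measurements["patient_id"].isin(keep)].reset_index(drop=True)
    out.outcomes = out.outcomes[out.outcomes["patient_id"].isin(keep)].reset_index(drop=True)
    out.statics = out.statics[out.statics["patient_id"].isin(keep)].reset_index(drop=True)
    out.latent = out.latent[out.latent["patient_id"].isin(keep)].reset_index(drop=True)
    return out, exclusions


def hourly_aggregate(
    cohort: RawCohort, variable_ids: list[str], horizon_hours: int = T_HOURS
) -> list[GriddedEpisode]:
    """Align events to the 1-h grid; cell (t, d) is the mean of variable d's
    events in hour t (half-open [60t, 60t+60) minutes), NaN when no event.

    Exact duplicate records are removed before averaging. Events with
    negative timestamps raise :class:`DataError`.
    """
    m = cohort.measurements
    if (m["minutes_from_admission"] < 0).any():
        raise DataError("event with negative minutes_from_admission")
    m = m.drop_duplicates()
    m = m[m["minutes_from_admission"] < horizon_hours * 60]
    var_index = {v: i for i, v in enumerate(variable_ids)}
    D = len(variable_ids)

    site_of = dict(zip(cohort.outcomes["patient_id"], _site_lookup(cohort)))
    label_of = dict(zip(cohort.outcomes["patient_id"], cohort.outcomes["label"]))

    grids: dict[str, np.ndarray] = {
        pid: np.full((horizon_hours, D), np.nan) for pid in cohort.outcomes["patient_id"]
    }
    if len(m):
        hours = (m["minutes_from_admission"] // 60).to_numpy()
        agg = (
            m.assign(hour=hours)
            .groupby(["patient_id", "variable_id", "hour"], sort=False)["value"]
            .mean()
        )
        for (pid, vid, hour), value in agg.items():
            if pid in grids and vid in var_index:
                grids[pid][int(hour), var_index[vid]] = value

    return [
        GriddedEpisode(pid, site_of.get(pid, ""), grid, int(label_of[pid]))
        for pid, grid in grids.items()
    ]


def _site_lookup(cohort: RawCohort) -> list[str]:
    site_map = (
        cohort.measurements.drop_duplicates("patient_id").set_index("patient_id")["site_id"]
        if len(cohort.measurements)
        else pd.Series(dtype=object)
    )
    return [site_map.get(pid, "") for pid in cohort.outcomes["patient_id"]]


def fit_preprocessor(train_episodes: list[GriddedEpisode], variable_ids: list[str]) -> PreprocessorState:
    """Fit winsor bounds (linear-interpolation 1st/99th percentiles), means,
    sds and imputation means over observed training cells only.

    A variable never observed in training raises :class:`FitError` naming it.
    """
    if not train_episodes:
        raise FitError("empty training set")
    D = len(variable_ids)
    stacked = np.stack([e.grid for e in train_episodes])  # (N, T, D)
    lo = np.empty(D)
    hi = np.empty(D)
    mean = np.empty(D)
    sd = np.empty(D)
    for d in range(D):
        vals = stacked[:, :, d]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise FitError(f"variable {variable_ids[d]} never observed in training set")
        lo[d] = np.percentile(vals, 1, method="linear")
        hi[d] = np.percentile(vals, 99, method="linear")
        clipped = np.clip(vals, lo[d], hi[d])
        mean[d] = clipped.mean()
        sd[d] = clipped.std(ddof=0)
    return PreprocessorState(
        variable_ids=list(variable_ids),
        winsor_low=lo,
        winsor_high=hi,
        train_mean=mean,
        train_sd=sd,
        impute_value=mean.copy(),
    )


def transform(state: PreprocessorState, episodes: list[GriddedEpisode]) -> list[EpisodeTensor]:
    """Clip, mask, forward-fill, mean-impute and z-score each episode.

    The mask records exactly where an observation existed pre-imputation;
    output values contain no NaN. Already-normalized tensors are refused by
    the ``normalized`` flag set here.
    """
    if state is None or state.fitted_on is None:
        raise SchemaError("preprocessor state is not fitted")
    D = len(state.variable_ids)
    sd = np.maximum(state.train_sd, SD_FLOOR)
    out = []
    for ep in episodes:
        if ep.grid.shape[1] != D:
            raise SchemaError(
                f"episode {ep.patient_id}: {ep.grid.shape[1]} variables, state has {D}"
            )
        grid = ep.grid
        M = (~np.isnan(grid)).astype(np.int8)
        X = np.clip(grid, state.winsor_low, state.winsor_high)
        # forward fill along time, then training-mean imputation of leading gaps
        df = pd.DataFrame(X)
        X = df.ffill(axis=0).to_numpy()
        nan_mask = np.isnan(X)
        X[nan_mask] = np.broadcast_to(state.impute_value, X.shape)[nan_mask]
        X = (X - state.train_mean) / sd
        out.append(EpisodeTensor(ep.patient_id, ep.site_id, X, M, ep.label, normalized=True))
    return out


def augment(
    episodes: list[EpisodeTensor],
    noise_sd: float,
    mask_prob: float,
    seed: int = 0,
) -> list[EpisodeTensor]:
    """Training-time augmentation: Gaussian noise on X plus whole-channel
    sensor dropout (zeroed values and mask). Labels are untouched."""
    if not 0 <= mask_prob <= 1:
        raise ConfigurationError("mask_prob must be in [0, 1]")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for ep in episodes:
        X = ep.X.copy()
        M = ep.M.copy()
        if noise_sd > 0:
            X += rng.normal(0.0, noise_sd, size=X.shape)
        if mask_prob > 0:
            dropped = rng.random(X.shape[1]) < mask_prob
            X[:, dropped] = 0.0
            M[:, dropped] = 0
        out.append(EpisodeTensor(ep.patient_id, ep.site_id, X, M, ep.y, normalized=ep.normalized))
    return out


def split_cohort(
    patient_ids: list[str],
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Patient-level random split; sizes are floor-based with the remainder
    assigned to train, shuffled under the seed."""
    if len(patient_ids) < 3:
        raise SplitError("need at least 3 patients to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must be positive and sum to 1")
    ids = sorted(patient_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    assignment = {}
    for rank, idx in enumerate(perm):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        assignment[ids[idx]] = split
    return SplitAssignment(assignment)
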