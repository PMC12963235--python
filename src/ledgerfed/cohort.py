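"""Synthetic multi-center ICU cohort generator.

Real multi-center EHR extracts are credentialed and cannot ship with the
package, so every downstream stage (preprocessing, risk model, federation,
governance) is exercised on cohorts drawn from a known latent risk model:

* each patient carries a latent severity ``z ~ N(0, 1)``;
* each clinical variable follows an order-1 autoregressive trajectory whose
  level is shifted by ``severity_slope * z``, then mapped through a per-site
  affine transform (scale then shift) to emulate multi-center distribution
  shift;
* observation events are thinned to a per-variable observation rate times a
  per-site missingness multiplier, producing realistic sparsity including
  leading gaps;
* the binary in-hospital mortality label is drawn from a logistic model on
  ``z`` whose intercept is calibrated per site so the expected prevalence
  matches the site profile, then flipped with the site's label-noise rate.

The latent severities are retained alongside the cohort purely as an oracle
for tests (e.g. the Bayes AUROC of ``z`` against the labels); no downstream
component may read them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ledgerfed.errors import (
    ConfigurationError,
    FormatError,
    GenerationError,
    LookupError_,
)

# Candidate observation ticks are laid on a regular sub-hourly grid; each kept
# event receives an integer-minute jitter so timestamps look irregular.
TICK_MINUTES = 30

MEASUREMENTS_COLUMNS = ["patient_id", "site_id", "variable_id", "minutes_from_admission", "value"]
STATICS_COLUMNS = ["patient_id", "age", "sex"]
OUTCOMES_COLUMNS = ["patient_id", "label"]
LATENT_COLUMNS = ["patient_id", "severity"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class VariableSpec:
    """One clinical variable of the multivariate stream.

    ``severity_slope`` shifts the trajectory mean per unit latent severity;
    ``observation_rate`` is the per-tick probability that the variable is
    actually measured; ``autocorrelation`` is the per-tick AR(1) coefficient.
    """

    variable_id: str
    baseline_mean: float
    baseline_sd: float
    severity_slope: float
    observation_rate: float
    autocorrelation: float

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ConfigurationError(f"{self.variable_id}: baseline_sd must be > 0")
        if not 0 < self.observation_rate <= 1:
            raise ConfigurationError(f"{self.variable_id}: observation_rate must be in (0, 1]")
        if not 0 <= self.autocorrelation < 1:
            raise ConfigurationError(f"{self.variable_id}: autocorrelation must be in [0, 1)")


@dataclass(frozen=True)
class SiteProfile:
    """Per-site distribution shift: affine measurement shift/scale, a global
    missingness multiplier, outcome prevalence and label-noise rate."""

    site_id: str
    n_patients: int
    mean_shift: tuple[float, ...]
    scale_factor: tuple[float, ...]
    missingness_multiplier: float
    prevalence: float
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"site {self.site_id}: n_patients must be positive")
        if any(s <= 0 for s in self.scale_factor):
            raise ConfigurationError(f"site {self.site_id}: scale_factor entries must be > 0")
        if not 0 < self.prevalence < 1:
            raise ConfigurationError(f"site {self.site_id}: prevalence must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ConfigurationError(f"site {self.site_id}: label_noise must be in [0, 0.5)")
        if self.missingness_multiplier <= 0:
            raise ConfigurationError(f"site {self.site_id}: missingness_multiplier must be > 0")


@dataclass
class RawCohort:
    """Event-level cohort: measurement stream, static features, outcomes, and
    the oracle-only latent severities."""

    measurements: pd.DataFrame
    statics: pd.DataFrame
    outcomes: pd.DataFrame
    latent: pd.DataFrame
    horizon_minutes: int

    def patient_ids(self) -> list[str]:
        return list(self.outcomes["patient_id"])

    def copy(self) -> "RawCohort":
        return RawCohort(
            measurements=self.measurements.copy(),
            statics=self.statics.copy(),
            outcomes=self.outcomes.copy(),
            latent=self.latent.copy(),
            horizon_minutes=self.horizon_minutes,
        )


def calibrate_intercept(prevalence: float, slope: float, site_id: str = "?") -> float:
    """Solve E_{z~N(0,1)}[expit(a + slope*z)] = prevalence for the intercept a.

    The expectation is evaluated by Gauss-Hermite quadrature; it is strictly
    increasing in ``a``, so a bracketing root-find suffices.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def expected(a: float) -> float:
        return float(np.sum(weights * expit(a + slope * nodes)))

    lo, hi = -40.0, 40.0
    try:
        if not expected(lo) <= prevalence <= expected(hi):
            raise ValueError("target outside achievable range")
        return float(brentq(lambda a: expected(a) - prevalence, lo, hi, xtol=1e-12))
    except ValueError as exc:
        raise GenerationError(
            f"site {site_id}: prevalence calibration failed for target {prevalence}"
        ) from exc


def _ar1_path(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary standardized AR(1) path of length n."""
    eps = rng.standard_normal(n)
    u = np.empty(n)
    u[0] = eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        u[t] = rho * u[t - 1] + c * eps[t]
    return u


def generate_cohort(
    variables: list[VariableSpec],
    sites: list[SiteProfile],
    horizon_hours: int = 48,
    seed: int = 0,
    label_slope: float = 3.0,
) -> RawCohort:
    """Generate a multi-center cohort from the latent-severity model.

    ``label_slope`` is the logistic coefficient linking latent severity to the
    mortality label; larger values give a sharper Bayes-optimal AUROC.
    Identical arguments and seed reproduce the cohort record for record.
    """
    if not variables or not sites:
        raise ConfigurationError("need at least one variable and one site")
    if horizon_hours < 48:
        raise ConfigurationError("horizon_hours must be at least 48")
    for site in sites:
        if len(site.mean_shift) != len(variables) or len(site.scale_factor) != len(variables):
            raise ConfigurationError(
                f"site {site.site_id}: mean_shift/scale_factor must have one entry per variable"
            )

    horizon_minutes = horizon_hours * 60
    n_ticks = horizon_minutes // TICK_MINUTES
    rng = np.random.default_rng(seed)

    rows_pid: list[str] = []
    rows_site: list[str] = []
    rows_var: list[str] = []
    rows_min: list[int] = []
    rows_val: list[float] = []
    statics_rows = []
    outcome_rows = []
    latent_rows = []

    for site in sites:
        intercept = calibrate_intercept(site.prevalence, label_slope, site.site_id)
        for p in range(site.n_patients):
            pid = f"{site.site_id}-p{p:05d}"
            z = float(rng.standard_normal())
            age = float(np.clip(rng.normal(65.0, 15.0), 18.0, 100.0))
            sex = int(rng.integers(0, 2))
            p_death = float(expit(intercept + label_slope * z))
            label = int(rng.random() < p_death)
            if site.label_noise > 0 and rng.random() < site.label_noise:
                label = 1 - label
            for d, var in enumerate(variables):
                keep_p = min(1.0, var.observation_rate * site.missingness_multiplier)
                keep = rng.random(n_ticks) < keep_p
                u = _ar1_path(rng, n_ticks, var.autocorrelation)
                jitter = rng.integers(0, TICK_MINUTES, size=n_ticks)
                values = var.baseline_mean + var.severity_slope * z + var.baseline_sd * u
                values = site.scale_factor[d] * values + site.mean_shift[d]
                kept = np.flatnonzero(keep)
                for t in kept:
                    rows_pid.append(pid)
                    rows_site.append(site.site_id)
                    rows_var.append(var.variable_id)
                    rows_min.append(int(t * TICK_MINUTES + jitter[t]))
                    rows_val.append(float(values[t]))
            statics_rows.append((pid, age, sex))
            outcome_rows.append((pid, label))
            latent_rows.append((pid, z))

    measurements = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "site_id": rows_site,
            "variable_id": rows_var,
            "minutes_from_admission": np.asarray(rows_min, dtype=np.int64),
            "value": np.asarray(rows_val, dtype=float),
        }
    )
    statics = pd.DataFrame(statics_rows, columns=STATICS_COLUMNS)
    outcomes = pd.DataFrame(outcome_rows, columns=OUTCOMES_COLUMNS)
    latent = pd.DataFrame(latent_rows, columns=LATENT_COLUMNS)
    return RawCohort(measurements, statics, outcomes, latent, horizon_minutes)


def perturb_cohort(
    cohort: RawCohort,
    extra_missingness: float,
    noise_sd: float,
    seed: int = 0,
) -> RawCohort:
    """Robustness corruption: thin events and add per-variable-rescaled noise.

    Each event is independently deleted with probability ``extra_missingness``;
    surviving values receive zero-mean Gaussian noise with standard deviation
    ``noise_sd`` in standardized units, i.e. multiplied per variable by the
    empirical standard deviation of that variable's values in the input cohort
    (floor 1.0 for degenerate constant variables). Outcomes are unchanged.
    """
    if not 0 <= extra_missingness < 1:
        raise ConfigurationError("extra_missingness must be in [0, 1)")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    out = cohort.copy()
    if extra_missingness == 0 and noise_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    m = out.measurements
    keep = rng.random(len(m)) >= extra_missingness
    m = m.loc[keep].reset_index(drop=True)
    if noise_sd > 0 and len(m):
        scales = m.groupby("variable_id")["value"].std(ddof=0)
        scales = scales.where(scales > 0, 1.0)
        per_event_scale = m["variable_id"].map(scales).to_numpy()
        m["value"] = m["value"].to_numpy() + noise_sd * per_event_scale * rng.standard_normal(len(m))
    out.measurements = m
    return out


def corrupt_labels(
    cohort: RawCohort,
    node_patient_ids: set[str] | list[str],
    flip_fraction: float,
    seed: int = 0,
) -> RawCohort:
    """Flip exactly round(flip_fraction * |ids|) labels among the named
    patients, selected without replacement under the seed.

    Applying the same corruption twice with the same seed restores the
    original labels (the flip is an involution on the selected set).
    """
    ids = sorted(set(node_patient_ids))
    known = set(cohort.outcomes["patient_id"])
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise LookupError_(f"unknown patient ids: {unknown[:5]}")
    if not 0 <= flip_fraction <= 1:
        raise ConfigurationError("flip_fraction must be in [0, 1]")
    n_flip = int(round(flip_fraction * len(ids)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(np.asarray(ids, dtype=object), size=n_flip, replace=False)) if n_flip else set()
    out = cohort.copy()
    mask = out.outcomes["patient_id"].isin(chosen)
    out.outcomes.loc[mask, "label"] = 1 - out.outcomes.loc[mask, "label"]
    return out


def write_cohort(cohort: RawCohort, directory) -> None:
    """Write the cohort as comma-separated UTF-8 tables with header rows.

    Files: measurements.csv, statics.csv, outcomes.csv, plus latent.csv (the
    oracle severities, read back when present) and a one-line horizon.txt
    carrying the stay-length bound in minutes. Floats use the %.10g format,
    so a read-write round trip reproduces values to 10 significant digits.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    cohort.measurements.to_csv(
        os.path.join(directory, "measurements.csv"), index=False, float_format=_FLOAT_FMT
    )
    cohort.statics.to_csv(os.path.join(directory, "statics.csv"), index=False, float_format=_FLOAT_FMT)
    cohort.outcomes.to_csv(os.path.join(directory, "outcomes.csv"), index=False)
    cohort.latent.to_csv(os.path.join(directory, "latent.csv"), index=False, float_format=_FLOAT_FMT)
    with open(os.path.join(directory, "horizon.txt"), "w", encoding="utf-8") as fh:
        fh.write(str(cohort.horizon_minutes) + "\n")


def _read_table(path: str, columns: list[str]) -> pd.DataFrame:
    import os

    if not os.path.exists(path):
        raise FormatError(f"missing table file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed csv
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if list(df.columns) != columns:
        raise FormatError(f"{path}: header mismatch, expected {columns}, got {list(df.columns)}")
    return df


def read_cohort(directory) -> RawCohort:
    """Read a cohort written by :func:`write_cohort`, validating the schema.

    Violations (missing file, header mismatch, non-numeric value, label
    outside {0,1}, negative timestamp) raise :class:`FormatError` naming the
    file and the offending line (1-based, counting the header as line 1).
    """
    import os

    mpath = os.path.join(directory, "measurements.csv")
    measurements = _read_table(mpath, MEASUREMENTS_COLUMNS)
    statics = _read_table(os.path.join(directory, "statics.csv"), STATICS_COLUMNS)
    opath = os.path.join(directory, "outcomes.csv")
    outcomes = _read_table(opath, OUTCOMES_COLUMNS)
    lpath = os.path.join(directory, "latent.csv")
    latent = (
        _read_table(lpath, LATENT_COLUMNS)
        if os.path.exists(lpath)
        else pd.DataFrame(columns=LATENT_COLUMNS)
    )

    for col in ("minutes_from_admission", "value"):
        numeric = pd.to_numeric(measurements[col], errors="coerce")
        bad = numeric.isna() & measurements[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise FormatError(f"{mpath}: non-numeric {col} at line {line}")
        measurements[col] = numeric
    neg = measurements["minutes_from_admission"] < 0
    if neg.any():
        raise FormatError(f"{mpath}: negative minutes_from_admission at line {int(neg.idxmax()) + 2}")

    labels = pd.to_numeric(outcomes["label"], errors="coerce")
    bad = labels.isna() | ~labels.isin([0, 1])
    if bad.any():
        raise FormatError(f"{opath}: label outside {{0,1}} at line {int(bad.idxmax()) + 2}")
    outcomes["label"] = labels.astype(int)

    hpath = os.path.join(directory, "horizon.txt")
    if os.path.exists(hpath):
        with open(hpath, encoding="utf-8") as fh:
            horizon_minutes = int(fh.read().strip())
    else:
        horizon_minutes = 48 * 60
    return RawCohort(measurements, statics, outcomes, latent, horizon_minutes)


# ---------------------------------------------------------------------------
# Documented presets (16 variables loosely modeled on common ICU vitals/labs).
# The strong-signal preset is the study condition for learning-sanity checks;
# the zero-signal preset severs all feature-label dependence.
# ---------------------------------------------------------------------------

_PRESET_TABLE = [
    # variable_id, mean, sd, slope (units of sd), obs_rate, autocorr
    ("heart_rate", 85.0, 14.0, +0.9, 0.90, 0.85),
    ("sbp", 120.0, 18.0, -0.9, 0.85, 0.80),
    ("dbp", 68.0, 12.0, -0.7, 0.85, 0.80),
    ("resp_rate", 18.0, 4.5, +1.0, 0.85, 0.75),
    ("spo2", 96.5, 2.5, -1.1, 0.90, 0.70),
    ("temperature", 37.0, 0.7, +0.5, 0.60, 0.85),
    ("gcs", 13.5, 2.2, -1.2, 0.50, 0.90),
    ("lactate", 1.8, 1.0, +1.2, 0.20, 0.80),
    ("creatinine", 1.2, 0.7, +0.8, 0.25, 0.95),
    ("bun", 22.0, 12.0, +0.7, 0.25, 0.95),
    ("wbc", 10.5, 4.0, +0.6, 0.25, 0.90),
    ("hemoglobin", 11.5, 2.0, -0.4, 0.25, 0.95),
    ("platelets", 220.0, 80.0, -0.5, 0.22, 0.95),
    ("sodium", 139.0, 4.0, -0.3, 0.30, 0.90),
    ("potassium", 4.1, 0.5, +0.4, 0.30, 0.85),
    ("glucose", 135.0, 40.0, +0.5, 0.35, 0.80),
]


def default_variables(signal: float = 1.0) -> list[VariableSpec]:
    """The 16-variable preset; ``signal`` scales every severity slope
    (1.0 = strong-signal study condition, 0.0 = no-signal control)."""
    return [
        VariableSpec(
            variable_id=vid,
            baseline_mean=mean,
            baseline_sd=sd,
            severity_slope=signal * slope * sd,
            observation_rate=rate,
            autocorrelation=rho,
        )
        for vid, mean, sd, slope, rate, rho in _PRESET_TABLE
    ]


def single_site(
    n_patients: int,
    prevalence: float = 0.12,
    label_noise: float = 0.0,
    site_id: str = "siteA",
    n_variables: int = len(_PRESET_TABLE),
) -> SiteProfile:
    """A shift-free site profile (identity affine transform)."""
    return SiteProfile(
        site_id=site_id,
        n_patients=n_patients,
        mean_shift=tuple(0.0 for _ in range(n_variables)),
        scale_factor=tuple(1.0 for _ in range(n_variables)),
        missingness_multiplier=1.0,
        prevalence=prevalence,
        label_noise=label_noise,
    )


def multi_site(
    n_patients_per_site: tuple[int, ...],
    seed: int = 0,
    base_prevalence: float = 0.12,
    variables: list[VariableSpec] | None = None,
) -> list[SiteProfile]:
    """Heterogeneous site profiles with mild random mean shifts (0.15 sd per
    variable), scale factors, missingness multipliers and prevalence spread."""
    if variables is None:
        variables = default_variables()
    sds = np.array([v.baseline_sd for v in variables])
    n_variables = len(variables)
    rng = np.random.default_rng(seed)
    sites = []
    for i, n in enumerate(n_patients_per_site):
        shift = rng.normal(0.0, 0.15, size=n_variables) * sds
        scale = np.exp(rng.normal(0.0, 0.08, size=n_variables))
        sites.append(
            SiteProfile(
                site_id=f"site{chr(ord('A') + i)}",
                n_patients=n,
                mean_shift=tuple(float(s) for s in shift),
                scale_factor=tuple(float(s) for s in scale),
                missingness_multiplier=float(np.exp(rng.normal(0.0, 0.2))),
                prevalence=float(np.clip(base_prevalence * np.exp(rng.normal(0.0, 0.2)), 0.02, 0.5)),
                label_noise=0.0,
            )
        )
    return sites
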