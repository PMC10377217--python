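"""Synthetic cohort generator with a planted anomalous subpopulation.

The generator emulates a young-adult low back pain survey cohort
(n ≈ 1021, ~73% female, ages 18-35) whose raw data are not public.  Each
subject carries two correlated latent severities:

* ``D`` — psychological distress, standard normal;
* ``V`` — physical (lumbar) severity, ``V = rho*D + sqrt(1-rho^2)*eps``.

Observable variables derive from the latents:

* DASS-21 and PCS-D item blocks from ``D``, ODI items from the mixture
  ``0.5*V + 0.5*D``, all through a graded-threshold ordinal model
  (:func:`draw_item_block`);
* 6-week low back pain event counts from a negative binomial whose
  log-mean is affine in ``V`` (overdispersed, matching the skewed count
  IQRs such surveys show);
* lumbar-pathology and mental-illness diagnosis flags from logistic
  models on ``V`` and ``D`` respectively;
* demographics from truncated normals, independent of the latents.

A fraction ``anomalous_frac`` of subjects is *anomalous*: their latents
are shifted upward by ``anomaly_shift`` and, when ``anomaly_decouple`` is
set, each questionnaire block is generated from its own freshly drawn
independent latent (plus extra item noise).  Anomalous subjects are thus
both more severe and *decoupled* — their variables no longer obey the
population's correlation structure, which is exactly the signature the
downstream reconstruction network should flag.

All randomness flows through a single seeded generator consumed in a
fixed, documented order (demographics, anomaly flags, latents, decoupling
latents, observation noise, counts, diagnoses, then item blocks
instrument by instrument), so a config+seed pair reproduces a cohort
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from lbpanomaly.errors import ValidationError

__all__ = [
    "CohortConfig",
    "DEFAULT_THRESHOLDS",
    "generate_cohort",
    "draw_item_block",
    "planted_truth",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_config",
    "save_config",
]

# Graded-threshold tables per instrument (ascending latent cut points).
# Calibrated so that a typical subject (latent 0, item noise SD 1) yields
# medians of the order seen in young-adult LBP surveys: ODI ~ 10%, doubled
# DASS stress ~ 10, anxiety ~ 6, depression ~ 8, PCS-D total low single
# digits.
DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "odi": (0.7, 1.6, 2.5, 3.4, 4.3),
    "dass_stress": (0.2, 1.2, 2.2),
    "dass_anxiety": (0.8, 1.6, 2.4),
    "dass_depression": (0.6, 1.4, 2.2),
    "pcs": (1.5, 2.2, 2.9, 3.6),
}

ODI_COLUMNS = [f"odi_q{i}" for i in range(1, 11)]
DASS_COLUMNS = [f"dass_q{i}" for i in range(1, 22)]
PCS_COLUMNS = [f"pcs_q{i}" for i in range(1, 15)]

BASE_COLUMNS = [
    "id", "age", "sex", "body_mass", "height", "bmi",
    "mental_illness_dx", "lumbar_pathology_dx", "lbp_events_6wk",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the reference study conditions: 1021 subjects, 73%
    female, ages 18-35 (mean 24.68), mean height 167.9 cm, mean body mass
    65.8 kg, a 25% anomalous subpopulation shifted by +1 latent SD with
    decoupled questionnaire blocks, latent distress-physical correlation
    0.6, unit item noise and 0.05 SD observation noise on standardized
    continuous variables.
    """

    n: int = 1021
    female_prop: float = 0.73
    age_range: tuple[float, float] = (18.0, 35.0)
    age_mean: float = 24.68
    age_sd: float = 4.0
    height_mean: float = 167.9  # cm
    height_sd: float = 8.0
    mass_mean: float = 65.8  # kg
    mass_sd: float = 12.0
    anomalous_frac: float = 0.25
    latent_corr: float = 0.6
    anomaly_shift: float = 1.0
    anomaly_decouple: bool = True
    decouple_noise_factor: float = 1.5
    item_noise: float = 1.0
    obs_noise: float = 0.05
    count_dispersion: float = 2.0
    count_log_mean: float = 1.386  # log mean events at V = 0 (~4 events)
    count_slope: float = 0.35
    lumbar_dx_intercept: float = -1.5
    lumbar_dx_slope: float = 0.9
    mental_dx_intercept: float = -1.8
    mental_dx_slope: float = 0.9
    thresholds: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        for name in ("female_prop", "anomalous_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValidationError("latent_corr must lie in (-1, 1)")
        for name in ("item_noise", "obs_noise", "age_sd", "height_sd",
                     "mass_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.count_dispersion <= 0:
            raise ValidationError("count_dispersion must be > 0")
        for key, th in self.thresholds.items():
            arr = np.asarray(th, dtype=float)
            if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
                raise ValidationError(
                    f"thresholds[{key!r}] must be strictly ascending")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["thresholds"] = {k: list(v) for k, v in self.thresholds.items()}
        return d


def draw_item_block(latent: float, n_items: int, n_categories: int,
                    thresholds: Sequence[float], sigma_item: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one subject's ordinal item block from a graded-threshold model.

    Each item is the count of thresholds exceeded by
    ``latent + Normal(0, sigma_item)`` (an independent draw per item), so
    values lie in ``0..n_categories-1`` and category probabilities follow
    normal-CDF differences across the threshold grid.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) != n_categories - 1:
        raise ValidationError(
            f"need {n_categories - 1} thresholds, got {len(thresholds)}")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be strictly ascending")
    x = latent + rng.normal(0.0, sigma_item, size=n_items)
    return np.searchsorted(thresholds, x, side="left").astype(int)


def _item_matrix(latents: np.ndarray, n_items: int,
                 thresholds: Sequence[float], sigma: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized graded-threshold draw: one row of items per subject."""
    thresholds = np.asarray(thresholds, dtype=float)
    noise = rng.standard_normal((len(latents), n_items))
    x = latents[:, None] + sigma[:, None] * noise
    return np.searchsorted(thresholds, x, side="left").astype(int)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, n: int) -> np.ndarray:
    """Rejection-sampled truncated normal (fixed draw order)."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < low) | (out > high)
    # loop terminates quickly for the calibrated ranges used here
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a cohort table under the latent-factor model.

    Returns a DataFrame with one row per subject: demographics, diagnosis
    flags, the 6-week LBP event count, the three item blocks and the
    hidden ``truth_anomalous`` label.  The generating config (including
    the seed) is stored in ``df.attrs['config']``.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    # -- demographics (draw order fixed: sex, age, height, mass) --
    sex_female = rng.random(n) < cfg.female_prop
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd,
                            cfg.age_range[0], cfg.age_range[1], n)
    height = _truncated_normal(rng, cfg.height_mean, cfg.height_sd,
                               140.0, 210.0, n)
    mass = _truncated_normal(rng, cfg.mass_mean, cfg.mass_sd,
                             38.0, 140.0, n)

    # -- anomaly flags and latents --
    anomalous = rng.random(n) < cfg.anomalous_frac
    d_latent = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    rho = cfg.latent_corr
    v_latent = rho * d_latent + np.sqrt(1.0 - rho * rho) * eps
    shift = cfg.anomaly_shift * anomalous
    d_latent = d_latent + shift
    v_latent = v_latent + shift

    # block-specific latents; decoupled anomalous subjects get fresh
    # independent draws (still centred at the shifted severity)
    fresh = rng.standard_normal((3, n)) + cfg.anomaly_shift
    if cfg.anomaly_decouple:
        mask = anomalous
    else:
        mask = np.zeros(n, dtype=bool)
    odi_latent = np.where(mask, fresh[0], 0.5 * v_latent + 0.5 * d_latent)
    dass_latent = np.where(mask, fresh[1], d_latent)
    pcs_latent = np.where(mask, fresh[2], d_latent)

    # -- observation noise on continuous measurements --
    obs = rng.standard_normal((3, n))
    age = np.clip(age + cfg.obs_noise * cfg.age_sd * obs[0], *cfg.age_range)
    height = height + cfg.obs_noise * cfg.height_sd * obs[1]
    mass = mass + cfg.obs_noise * cfg.mass_sd * obs[2]
    bmi = mass / (height / 100.0) ** 2

    # -- counts and diagnoses --
    mu = np.exp(cfg.count_log_mean + cfg.count_slope * v_latent)
    r = cfg.count_dispersion
    lbp_events = rng.negative_binomial(r, r / (r + mu)) if n else (
        np.zeros(0, dtype=int))
    p_lumbar = _logistic(cfg.lumbar_dx_intercept + cfg.lumbar_dx_slope
                         * v_latent)
    lumbar_dx = (rng.random(n) < p_lumbar).astype(int)
    p_mental = _logistic(cfg.mental_dx_intercept + cfg.mental_dx_slope
                         * d_latent)
    mental_dx = (rng.random(n) < p_mental).astype(int)

    # -- item blocks (ODI, DASS stress/anxiety/depression, PCS) --
    sigma = np.where(mask, cfg.item_noise * cfg.decouple_noise_factor,
                     cfg.item_noise)
    th = cfg.thresholds
    odi_items = _item_matrix(odi_latent, 10, th["odi"], sigma, rng)
    dass = np.zeros((n, 21), dtype=int)
    from lbpanomaly.scoring import (DASS_ANXIETY_ITEMS,
                                    DASS_DEPRESSION_ITEMS,
                                    DASS_STRESS_ITEMS)
    dass[:, list(DASS_STRESS_ITEMS)] = _item_matrix(
        dass_latent, 7, th["dass_stress"], sigma, rng)
    dass[:, list(DASS_ANXIETY_ITEMS)] = _item_matrix(
        dass_latent, 7, th["dass_anxiety"], sigma, rng)
    dass[:, list(DASS_DEPRESSION_ITEMS)] = _item_matrix(
        dass_latent, 7, th["dass_depression"], sigma, rng)
    pcs_items = _item_matrix(pcs_latent, 14, th["pcs"], sigma, rng)

    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": np.round(age, 2),
        "sex": np.where(sex_female, "F", "M"),
        "body_mass": np.round(mass, 2),
        "height": np.round(height, 2),
        "mental_illness_dx": mental_dx,
        "lumbar_pathology_dx": lumbar_dx,
        "lbp_events_6wk": np.asarray(lbp_events, dtype=int),
    })
    df.insert(5, "bmi", np.round(df["body_mass"]
                                 / (df["height"] / 100.0) ** 2, 2))
    for j, c in enumerate(ODI_COLUMNS):
        df[c] = odi_items[:, j]
    for j, c in enumerate(DASS_COLUMNS):
        df[c] = dass[:, j]
    for j, c in enumerate(PCS_COLUMNS):
        df[c] = pcs_items[:, j]
    df["truth_anomalous"] = anomalous.astype(int)
    df.attrs["config"] = cfg.to_dict()
    return df


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def planted_truth(cohort: pd.DataFrame) -> np.ndarray:
    """Return the hidden anomaly labels of a generated cohort."""
    if "truth_anomalous" not in cohort.columns:
        raise ValidationError("cohort has no truth_anomalous column")
    return cohort["truth_anomalous"].to_numpy(dtype=int)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path,
                     with_truth: bool = False) -> None:
    """Write a cohort CSV; the hidden truth column only on request."""
    df = cohort if with_truth else cohort.drop(
        columns=["truth_anomalous"], errors="ignore")
    df.to_csv(path, index=False)
    cfg = cohort.attrs.get("config")
    if cfg is not None:
        Path(str(path) + ".provenance.json").write_text(
            json.dumps(cfg, indent=2) + "\n")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Blank ODI cells are kept as missing (skipped items); all other item
    columns must be complete.
    """
    df = pd.read_csv(path)
    for c in ODI_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    return df


def load_config(path: str | Path) -> CohortConfig:
    """Load a cohort config from a flat key-value YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must hold a flat mapping")
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if "thresholds" in raw:
        raw["thresholds"] = {k: tuple(v) for k, v in raw["thresholds"].items()}
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**raw)


def save_config(cfg: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
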