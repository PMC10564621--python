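"""Synthetic sex-stratified cohorts with correlated scanner measures.

The generator emulates the structure of a scanner + BIA study population:

* ~30 scanner measures per participant drawn from a latent-factor Gaussian
  model with three factors (overall body size, central adiposity, limb
  muscularity).  Factor loadings produce the strong positive correlations
  seen among real girths and volumes; per-measure uniqueness keeps the
  covariance full rank.  Standardised latent values are mapped affinely to
  plausible units (girths/lengths in cm, volumes in litres).
* body-composition outcomes (RFM %, VAT kg, SMI kg/m^2) that are sparse
  linear functions of a few "true" measures on the standardised scale, plus
  an age gradient and Gaussian noise.  Skeletal muscle mass is stored as
  SMM = SMI * height_m^2 so the index round-trips through the cohort layer.
* lifestyle answers (education 1-7, activity 1-5, five weekly food-frequency
  flags) drawn independently of the outcomes by default, so selection tests
  can isolate the behaviour of the scan measures.

Because the true support, coefficients and covariance are known, downstream
tests can score support recovery and calibration exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import DEFAULT_SCAN_MEASURES, FOOD_FLAG_COLUMNS, CohortTable
from .errors import ConfigError, UsageError

OUTCOMES = ("rfm", "vat", "smi")

# measure -> (category, male mean, male sd, female mean, female sd)
# category drives the factor loadings below.
_MEASURE_TABLE: dict[str, tuple[str, float, float, float, float]] = {
    "waist_girth": ("central", 95.0, 11.0, 84.0, 11.5),
    "high_waist_girth": ("central", 97.0, 10.5, 80.0, 10.5),
    "hip_girth": ("central", 102.0, 7.5, 100.0, 8.5),
    "seat_girth": ("central", 101.0, 7.5, 101.0, 8.5),
    "maximum_belly_circumference": ("central", 98.0, 11.5, 88.0, 12.0),
    "bust_chest_girth_horizontal": ("central", 103.0, 8.0, 95.0, 8.5),
    "mid_neck_girth": ("central", 40.0, 3.0, 33.5, 2.6),
    "upper_arm_girth": ("limb", 31.0, 3.2, 29.0, 3.4),
    "forearm_girth": ("limb", 27.5, 2.2, 24.0, 2.2),
    "wrist_girth": ("limb", 17.5, 1.2, 15.5, 1.1),
    "thigh_girth_horizontal": ("limb", 57.0, 5.0, 58.0, 5.5),
    "knee_girth": ("limb", 39.0, 3.0, 38.0, 3.2),
    "calf_girth": ("limb", 38.0, 2.8, 36.5, 2.9),
    "ankle_girth": ("limb", 23.5, 1.8, 21.5, 1.7),
    "volume_belly": ("central", 12.0, 2.8, 9.5, 2.7),
    "volume_hip": ("central", 16.5, 3.0, 16.0, 3.2),
    "volume_chest": ("central", 19.0, 3.0, 15.5, 2.8),
    "volume_thigh": ("limb", 13.5, 2.2, 13.8, 2.4),
    "volume_arm": ("limb", 3.4, 0.6, 2.9, 0.6),
    "volume_forearm": ("limb", 1.6, 0.3, 1.3, 0.25),
    "volume_leg": ("limb", 10.5, 1.6, 10.2, 1.7),
    "volume_calf": ("limb", 4.1, 0.7, 3.8, 0.7),
    "volume_torso": ("size", 38.0, 6.0, 31.0, 5.5),
    "volume_total": ("size", 78.0, 11.0, 65.0, 10.0),
    "neck_to_waist_center_back": ("frame", 47.0, 3.0, 42.0, 2.8),
    "cross_shoulder_over_neck": ("frame", 49.0, 3.0, 44.5, 2.8),
    "arm_length": ("frame", 62.0, 3.2, 57.0, 3.0),
    "inside_leg_length": ("frame", 80.0, 4.5, 75.0, 4.2),
    "shoulder_width": ("frame", 42.0, 2.6, 38.0, 2.5),
    "back_width": ("frame", 38.0, 2.6, 35.0, 2.5),
}

# factor loadings per measure category on (size, central adiposity, limb
# muscularity); squared norms stay below 1 so uniqueness is positive.
_CATEGORY_LOADINGS = {
    "size": (0.72, 0.35, 0.35),
    "central": (0.52, 0.62, 0.12),
    "limb": (0.52, 0.15, 0.60),
    "frame": (0.62, 0.08, 0.20),
}

# sparse truth on the standardised-measure scale (outcome units per SD of the
# measure).  Effect sizes within a support are kept of comparable magnitude so
# every support member carries a detectable share of the signal at the default
# cohort sizes -- the calibration a support-recovery testbed needs.
_DEFAULT_SUPPORT = {
    "rfm": {
        "volume_belly": 2.4,
        "volume_hip": 2.2,
        "waist_girth": 2.2,
        "volume_thigh": 2.0,
        "mid_neck_girth": -2.0,
    },
    "vat": {
        "waist_girth": 0.60,
        "volume_belly": 0.55,
        "hip_girth": -0.50,
        "upper_arm_girth": 0.50,
        "volume_hip": 0.50,
    },
    "smi": {
        "volume_thigh": 0.42,
        "forearm_girth": 0.40,
        "volume_chest": 0.38,
        "waist_girth": -0.36,
        "volume_hip": 0.36,
    },
}

_DEFAULT_AGE_EFFECTS = {"rfm": 0.12, "vat": 0.030, "smi": -0.015}
_SEX_DEFAULTS = {
    # baseline outcome levels at the midpoint age, and height distribution
    "male": {"rfm": 23.3, "vat": 2.6, "smi": 9.5, "height": (176.0, 7.1)},
    "female": {"rfm": 30.5, "vat": 0.9, "smi": 7.0, "height": (164.8, 6.6)},
}
_DEFAULT_LIFESTYLE = {
    "education_probs": (0.02, 0.05, 0.18, 0.11, 0.21, 0.21, 0.22),
    "activity_probs": (0.05, 0.09, 0.40, 0.30, 0.16),
    "food_flag_probs": (0.5, 0.6, 0.4, 0.5, 0.35),
}


@dataclass
class SyntheticConfig:
    """Generator settings for one sex stratum."""

    sex: str = "male"
    n: int = 100
    measure_names: tuple[str, ...] = tuple(_MEASURE_TABLE)
    n_factors: int = 3
    loadings_scale: float = 1.0
    true_support: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SUPPORT.items()}
    )
    #: target population R^2 per outcome; residual SD is derived analytically
    population_r2: Mapping[str, float] = field(
        default_factory=lambda: {"rfm": 0.80, "vat": 0.80, "smi": 0.80}
    )
    #: explicit residual SDs; overrides population_r2 when set
    noise_sd: Mapping[str, float] | None = None
    age_range: tuple[int, int] = (18, 90)
    age_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_EFFECTS)
    )
    lifestyle_probs: Mapping[str, tuple] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_LIFESTYLE.items()}
    )
    seed: int = 0

    def __post_init__(self):
        if self.sex not in _SEX_DEFAULTS:
            raise ConfigError(f"sex must be male or female, got {self.sex!r}")
        unknown = [m for m in self.measure_names if m not in _MEASURE_TABLE]
        if unknown:
            raise ConfigError(f"unknown measure names: {unknown}")
        for outcome, support in self.true_support.items():
            missing = [m for m in support if m not in self.measure_names]
            if missing:
                raise ConfigError(f"{outcome} support references absent measures {missing}")
            if not all(np.isfinite(list(support.values()))):
                raise ConfigError(f"{outcome} support has non-finite effect sizes")
        L, uniq = self._factor_structure()
        if np.any(uniq < 0):
            bad = [self.measure_names[i] for i in np.where(uniq < 0)[0]]
            raise ConfigError(
                f"loading matrix yields a non-PSD covariance (uniqueness < 0 for {bad})"
            )
        if self.noise_sd is not None and any(s <= 0 for s in self.noise_sd.values()):
            raise ConfigError("noise_sd entries must be > 0")

    # -- covariance structure ----------------------------------------------
    def _factor_structure(self) -> tuple[np.ndarray, np.ndarray]:
        """(p x k) loadings and per-measure uniqueness variances (unit-variance scale)."""
        L = np.array(
            [_CATEGORY_LOADINGS[_MEASURE_TABLE[m][0]][: self.n_factors] for m in self.measure_names]
        )
        L = self.loadings_scale * L
        uniq = 1.0 - np.sum(L**2, axis=1)
        return L, uniq

    @property
    def correlation(self) -> np.ndarray:
        """Population correlation matrix of the scan measures."""
        L, uniq = self._factor_structure()
        return L @ L.T + np.diag(uniq)

    @property
    def measure_means(self) -> np.ndarray:
        col = 1 if self.sex == "male" else 3
        return np.array([_MEASURE_TABLE[m][col] for m in self.measure_names])

    @property
    def measure_sds(self) -> np.ndarray:
        col = 2 if self.sex == "male" else 4
        return np.array([_MEASURE_TABLE[m][col] for m in self.measure_names])

    def signal_variance(self, outcome: str) -> float:
        """Population variance of the true linear predictor (incl. age term)."""
        support = self.true_support.get(outcome, {})
        idx = {m: i for i, m in enumerate(self.measure_names)}
        beta = np.zeros(len(self.measure_names))
        for m, b in support.items():
            beta[idx[m]] = b
        lo, hi = self.age_range
        var_age = (hi - lo) ** 2 / 12.0
        slope = self.age_effects.get(outcome, 0.0)
        return float(beta @ self.correlation @ beta + slope**2 * var_age)

    def resolved_noise_sd(self, outcome: str) -> float:
        if self.noise_sd is not None and outcome in self.noise_sd:
            return float(self.noise_sd[outcome])
        r2 = float(self.population_r2[outcome])
        if not 0 < r2 < 1:
            raise ConfigError(f"population_r2[{outcome}] must be in (0,1), got {r2}")
        sig = self.signal_variance(outcome)
        return float(np.sqrt(sig * (1.0 - r2) / r2))


@dataclass
class CohortConfig:
    """Two independent per-sex configurations plus the master seed."""

    male: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(sex="male"))
    female: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(sex="female"))
    seed: int = 0


@dataclass
class StratumTruth:
    sex: str
    measure_names: tuple[str, ...]
    measure_means: np.ndarray
    measure_sds: np.ndarray
    correlation: np.ndarray  # standardised-scale covariance of the measures
    beta: dict[str, dict[str, float]]  # per outcome, standardised scale
    age_effects: dict[str, float]
    age_mid: float
    outcome_base: dict[str, float]
    noise_sd: dict[str, float]
    population_r2: dict[str, float]

    @property
    def covariance(self) -> np.ndarray:
        """Generator covariance of the scan measures in their own units."""
        d = np.diag(self.measure_sds)
        return d @ self.correlation @ d

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        for key in ("measure_means", "measure_sds", "correlation"):
            payload[key] = np.asarray(payload[key]).tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SyntheticTruth:
    strata: dict[str, StratumTruth]

    def __getitem__(self, sex: str) -> StratumTruth:
        return self.strata[sex]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {s: json.loads(t.to_json()) for s, t in self.strata.items()}, indent=2
        )
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _generate_stratum(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, StratumTruth]:
    p = len(cfg.measure_names)
    n = cfg.n
    L, uniq = cfg._factor_structure()
    factors = rng.standard_normal((n, cfg.n_factors))
    unique_noise = rng.standard_normal((n, p)) * np.sqrt(uniq)
    x_std = factors @ L.T + unique_noise  # unit variance per column
    measures = cfg.measure_means + cfg.measure_sds * x_std

    lo, hi = cfg.age_range
    age = rng.integers(lo, hi + 1, size=n)
    h_mean, h_sd = _SEX_DEFAULTS[cfg.sex]["height"]
    height = rng.normal(h_mean, h_sd, size=n)
    # weight tracks total body volume (density ~1 kg/l) with measurement noise
    vol_total = (
        measures[:, cfg.measure_names.index("volume_total")]
        if "volume_total" in cfg.measure_names
        else np.full(n, 70.0)
    )
    weight = np.clip(1.0 * vol_total + rng.normal(0.0, 1.5, size=n), 30.0, None)

    edu_p = np.asarray(cfg.lifestyle_probs["education_probs"], dtype=float)
    act_p = np.asarray(cfg.lifestyle_probs["activity_probs"], dtype=float)
    food_p = np.asarray(cfg.lifestyle_probs["food_flag_probs"], dtype=float)
    education = rng.choice(np.arange(1, 8), size=n, p=edu_p / edu_p.sum())
    activity = rng.choice(np.arange(1, 6), size=n, p=act_p / act_p.sum())
    flags = rng.random((n, len(food_p))) < food_p

    age_mid = (lo + hi) / 2.0
    idx = {m: i for i, m in enumerate(cfg.measure_names)}
    base = {o: _SEX_DEFAULTS[cfg.sex][o] for o in OUTCOMES}
    outcomes: dict[str, np.ndarray] = {}
    noise_sds: dict[str, float] = {}
    for outcome in OUTCOMES:
        support = cfg.true_support.get(outcome, {})
        eta = np.full(n, base[outcome], dtype=float)
        for m, b in support.items():
            eta += b * x_std[:, idx[m]]
        eta += cfg.age_effects.get(outcome, 0.0) * (age - age_mid)
        sd = cfg.resolved_noise_sd(outcome)
        noise_sds[outcome] = sd
        outcomes[outcome] = eta + rng.normal(0.0, sd, size=n)
    # physical clipping (documented left/right censoring; rare under defaults)
    outcomes["rfm"] = np.clip(outcomes["rfm"], 0.0, 100.0)
    outcomes["vat"] = np.clip(outcomes["vat"], 0.0, None)
    outcomes["smi"] = np.clip(outcomes["smi"], 0.1, None)

    smm = outcomes["smi"] * (height / 100.0) ** 2
    df = pd.DataFrame({"id": [f"{cfg.sex[0]}{i:04d}" for i in range(n)], "sex": cfg.sex, "age": age})
    df["height_cm"] = height
    df["weight_kg"] = weight
    for m in cfg.measure_names:
        df[m] = measures[:, idx[m]]
    df["rfm_pct"] = outcomes["rfm"]
    df["vat_kg"] = outcomes["vat"]
    df["smm_kg"] = smm
    df["education_raw"] = education
    df["activity_raw"] = activity
    for j, col in enumerate(FOOD_FLAG_COLUMNS):
        df[col] = flags[:, j].astype(int)

    pop_r2 = {
        o: cfg.signal_variance(o) / (cfg.signal_variance(o) + noise_sds[o] ** 2)
        for o in OUTCOMES
    }
    truth = StratumTruth(
        sex=cfg.sex,
        measure_names=tuple(cfg.measure_names),
        measure_means=cfg.measure_means,
        measure_sds=cfg.measure_sds,
        correlation=cfg.correlation,
        beta={o: dict(cfg.true_support.get(o, {})) for o in OUTCOMES},
        age_effects={o: cfg.age_effects.get(o, 0.0) for o in OUTCOMES},
        age_mid=age_mid,
        outcome_base=base,
        noise_sd=noise_sds,
        population_r2=pop_r2,
    )
    return df, truth


def generate_cohort(config: CohortConfig | SyntheticConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a synthetic cohort; deterministic given the config (incl. seed).

    Accepts a full two-sex :class:`CohortConfig` or a single-stratum
    :class:`SyntheticConfig`.
    """
    if isinstance(config, SyntheticConfig):
        strata_cfgs = {config.sex: config}
        seed = config.seed
    else:
        strata_cfgs = {"male": config.male, "female": config.female}
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(strata_cfgs))
    frames, truths = [], {}
    for child, (sex, cfg) in zip(children, sorted(strata_cfgs.items())):
        df, truth = _generate_stratum(cfg, np.random.default_rng(child))
        frames.append(df)
        truths[sex] = truth
    data = pd.concat(frames, ignore_index=True)
    vd = {m: (DEFAULT_SCAN_MEASURES[m], "scan") for m in next(iter(truths.values())).measure_names}
    return CohortTable(data, vd), SyntheticTruth(truths)


def realized_r2(truth: StratumTruth, cohort: CohortTable | pd.DataFrame, outcome: str) -> float:
    """Variance explained by the true linear predictor on the realised sample.

    Computed as 1 - Var(y - eta)/Var(y) with eta rebuilt from the stored
    coefficients; equals 1 exactly in the noiseless limit and ~0 for a
    pure-noise configuration.
    """
    if outcome not in OUTCOMES:
        raise UsageError(f"unknown outcome {outcome!r}")
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    df = df[df["sex"] == truth.sex]
    if df.empty:
        raise UsageError(f"cohort has no rows for stratum {truth.sex!r}")
    missing = [m for m in truth.beta[outcome] if m not in df.columns]
    if missing:
        raise UsageError(f"cohort lacks truth measures {missing}; truth/cohort mismatch")
    eta = np.full(len(df), truth.outcome_base[outcome], dtype=float)
    for m, b in truth.beta[outcome].items():
        j = truth.measure_names.index(m)
        eta += b * (df[m].to_numpy() - truth.measure_means[j]) / truth.measure_sds[j]
    eta += truth.age_effects[outcome] * (df["age"].to_numpy() - truth.age_mid)
    if outcome == "rfm":
        y = df["rfm_pct"].to_numpy()
    elif outcome == "vat":
        y = df["vat_kg"].to_numpy()
    else:
        y = df["smm_kg"].to_numpy() / (df["height_cm"].to_numpy() / 100.0) ** 2
    var_y = np.var(y)
    if var_y == 0:
        return float("nan")
    return float(1.0 - np.var(y - eta) / var_y)
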