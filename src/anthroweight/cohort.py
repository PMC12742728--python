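"""Synthetic quota-sampled anthropometric cohorts.

The generator emulates the structure of a quota-sampled adult validation
cohort: equal counts in every sex x nutrition-category stratum, sex-specific
height distributions, BMI drawn inside each category's interval, and the
remaining measurements (circumferences, knee height, skinfold) derived as
linear functions of weight, height, BMI and sex plus Gaussian noise —
physiologically correlated, but making no claim to model the true joint
anthropometry of any population.

Default marginal parameters are calibrated so that, with the default 30
participants per stratum (240 total), the cohort medians sit near a typical
young-adult field cohort: median weight ~64.5 kg, median height ~162.5 cm,
and circumference medians in the usual adult ranges.

Sampling is fully deterministic given the seed: one shared
``numpy.random.Generator`` per cohort, consumed stratum by stratum in a fixed
order (sex outer, nutrition inner), so appending strata never perturbs the
draws of earlier ones. Truncated normals are sampled exactly with
``scipy.stats.truncnorm``; impossible truncation bounds are a config error,
never silently relaxed.

"Planted-truth" cohorts (:func:`plant_equation_truth`) overwrite the measured
weight with one equation's own prediction plus Gaussian noise, giving a cohort
on which that equation is ground truth — the basis for ranking-recovery tests
of the validation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equations import get_equation, predict_all
from .metrics import NUTRITION_LEVELS, bmi as compute_bmi
from .records import MEASUREMENT_FIELDS

__all__ = ["SyntheticConfig", "generate_cohort", "plant_equation_truth", "ConfigError"]


class ConfigError(ValueError):
    """The synthetic-cohort configuration is internally inconsistent."""


#: BMI interval of each nutrition category (WHO adult cutoffs); the sampling
#: interval for the open-ended categories is closed at a physiological extreme.
BMI_INTERVALS = {
    "underweight": (14.0, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 45.0),
}


@dataclass(frozen=True)
class LinearDerivation:
    """One derived measurement: icpt + w*W + h*H + b*BMI + sex_offset + noise."""

    intercept: float = 0.0
    weight_coef: float = 0.0
    height_coef: float = 0.0
    bmi_coef: float = 0.0
    sex_offset: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": 0.0})
    noise_sd: float = 1.0
    min_value: float = 1.0  # hard positivity floor, enforced by truncation


def _default_derivations() -> Mapping[str, LinearDerivation]:
    return {
        # calibrated against typical adult medians: MAC ~28.6 cm, AC ~81.8 cm,
        # CC ~34.5 cm, HC ~96.5 cm at 64.5 kg; KH ~51.5 cm at 162.5 cm;
        # SST ~12 mm at BMI 25 (higher in women).
        "mac": LinearDerivation(intercept=8.0, weight_coef=0.32, noise_sd=1.5,
                                min_value=11.0),
        "ac": LinearDerivation(intercept=30.0, weight_coef=0.80, noise_sd=3.0,
                               min_value=41.0),
        "cc": LinearDerivation(intercept=15.0, weight_coef=0.302, noise_sd=1.2,
                               min_value=16.0),
        "hc": LinearDerivation(intercept=45.25, weight_coef=0.80, noise_sd=3.0,
                               sex_offset={"male": -3.25, "female": 3.25},
                               min_value=51.0),
        "kh": LinearDerivation(height_coef=0.317, noise_sd=1.2, min_value=31.0),
        "sst": LinearDerivation(intercept=-8.0, bmi_coef=0.80, noise_sd=3.0,
                                sex_offset={"male": -1.5, "female": 1.5},
                                min_value=3.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``n_per_stratum`` participants are drawn in each of the 8 sex x nutrition
    strata (default 30, i.e. 240 total). ``height_params`` gives sex-specific
    Normal mean/SD in cm; ``bmi_params`` gives per-category Normal location/
    scale, truncated to the category's BMI interval. ``age_lognorm`` is
    (median_years_above_18, sigma) of a shifted lognormal, capped at 90.
    """

    n_per_stratum: int = 30
    seed: int = 0
    height_params: Mapping[str, tuple] = field(
        default_factory=lambda: {"male": (167.0, 8.5), "female": (159.0, 6.4)})
    bmi_params: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "underweight": (17.2, 1.5),
            "normal": (21.7, 2.0),
            "overweight": (27.3, 1.5),
            "obese": (33.5, 3.0),
        })
    correlation_params: Mapping[str, LinearDerivation] = field(
        default_factory=_default_derivations)
    age_lognorm: tuple = (11.0, 0.887)
    planted_equation: Optional[str] = None
    planted_noise_sd: float = 0.0

    def validate(self) -> None:
        if self.n_per_stratum < 1:
            raise ConfigError("n_per_stratum must be >= 1")
        if self.planted_noise_sd < 0:
            raise ConfigError("planted_noise_sd must be >= 0")
        for sex, (mu, sd) in self.height_params.items():
            if sd <= 0:
                raise ConfigError(f"height SD for {sex} must be > 0")
        for level in NUTRITION_LEVELS:
            if level not in self.bmi_params:
                raise ConfigError(f"bmi_params missing category {level!r}")
            mu, sd = self.bmi_params[level]
            lo, hi = BMI_INTERVALS[level]
            if sd <= 0:
                raise ConfigError(f"BMI SD for {level} must be > 0")
            if not (lo < hi):
                raise ConfigError(f"empty BMI interval for {level}")
            # a location many SDs outside its interval makes the truncated
            # density vanish — reject rather than sample a numerical fiction
            if mu < lo - 6 * sd or mu > hi + 6 * sd:
                raise ConfigError(
                    f"BMI location {mu} for {level} is irreconcilable with "
                    f"interval [{lo}, {hi}) at SD {sd}")
        for var, deriv in self.correlation_params.items():
            if deriv.noise_sd <= 0:
                raise ConfigError(f"noise SD for {var} must be > 0")


def _trunc_normal(rng, mu, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``config.seed``.

    Returns a record-set frame with columns ``id``, ``sex``,
    ``nutrition_stratum`` (the quota label) and all measurement fields. Every
    record's measured-weight BMI falls inside its stratum's interval by
    construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_stratum
    frames = []
    counter = 0
    for sex in ("male", "female"):
        h_mu, h_sd = config.height_params[sex]
        for level in NUTRITION_LEVELS:
            b_mu, b_sd = config.bmi_params[level]
            b_lo, b_hi = BMI_INTERVALS[level]
            height = _trunc_normal(rng, h_mu, h_sd, 130.0, 210.0, n)
            # sample strictly inside the category so classification is exact
            bmi = _trunc_normal(rng, b_mu, b_sd, b_lo, np.nextafter(b_hi, b_lo), n)
            weight = bmi * (height / 100.0) ** 2
            stratum = pd.DataFrame({
                "id": [f"S{counter + i:04d}" for i in range(n)],
                "sex": sex,
                "nutrition_stratum": level,
                "height": height,
                "weight": weight,
            })
            counter += n
            for var, d in config.correlation_params.items():
                mu = (d.intercept + d.weight_coef * weight
                      + d.height_coef * height + d.bmi_coef * bmi
                      + d.sex_offset.get(sex, 0.0))
                stratum[var] = _trunc_normal(rng, mu, d.noise_sd,
                                             d.min_value, np.inf, n)
            med, sigma = config.age_lognorm
            age = 18.0 + np.exp(rng.normal(np.log(med), sigma, n))
            stratum["age"] = np.minimum(age, 90.0)
            frames.append(stratum)
    out = pd.concat(frames, ignore_index=True)
    cols = ["id", "sex", "nutrition_stratum", *MEASUREMENT_FIELDS]
    return out[cols]


def plant_equation_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Cohort whose measured weight IS one equation's prediction plus noise.

    Measurement fields are generated exactly as in :func:`generate_cohort`;
    the measured weight is then replaced by ``config.planted_equation``'s
    prediction plus Normal(0, planted_noise_sd) noise, truncated positive.
    On such a cohort the planted equation is ground truth, so a correct
    validation pipeline must rank it at (or near, under noise) the top.
    """
    if config.planted_equation is None:
        raise ConfigError("planted_equation must be set")
    spec = get_equation(config.planted_equation)  # raises for unknown id
    generated = {"sex", *MEASUREMENT_FIELDS}
    absent = spec.required_variables - generated
    if absent:
        raise ConfigError(
            f"planted equation {spec.equation_id} requires fields the "
            f"generator does not produce: {sorted(absent)}")
    cohort = generate_cohort(config)
    preds = predict_all(cohort, [config.planted_equation])
    if not preds["evaluable"].all():  # cannot happen with generated fields
        raise ConfigError("planted equation non-evaluable on generated cohort")
    truth = preds["predicted_kg"].to_numpy(dtype=float)
    # separate stream keyed off the cohort seed, so the measurement draws are
    # identical to the unplanted cohort with the same config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.planted_noise_sd > 0:
        noise_sd = config.planted_noise_sd
        weight = truth + _trunc_normal(
            rng, 0.0, noise_sd, 20.0 - truth, np.inf, truth.size)
    else:
        weight = truth
    if np.any(weight <= 0):
        raise ConfigError("planted weights not strictly positive")
    out = cohort.copy()
    out["weight"] = weight
    return out
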