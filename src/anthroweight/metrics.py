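"""Method-comparison accuracy statistics: P10/P20, MPE, Bland-Altman.

Conventions (fixed and documented, since the source tables in this literature
are often silent or inconsistent about them):

* percentage error is signed, ``100 * (predicted - actual) / actual``;
* "within 10%" is boundary-inclusive (``|rel. error| <= 0.10`` counts);
* Bland-Altman differences are ``predicted - actual`` (estimate minus
  reference); the plot x-axis is the pair mean;
* limits of agreement use the 1.96 multiplier; 95% confidence intervals for
  the bias and for each limit use SE = s/sqrt(n) and SE = s*sqrt(3/n)
  respectively, with a Student-t critical value at n-1 df (Bland & Altman's
  classic large-sample recipe).

P10 > 70% and P20 > 95% are the clinical-adequacy thresholds conventionally
used for weight estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equations import EQUATION_IDS, get_equation, predict_all
from .records import parse_sex

__all__ = [
    "percent_error",
    "p_within",
    "mean_percentage_error",
    "bland_altman",
    "BlandAltmanResult",
    "bmi",
    "classify_nutrition",
    "NUTRITION_LEVELS",
    "AccuracyReport",
    "accuracy_report",
    "stratified_accuracy",
]

NUTRITION_LEVELS = ("underweight", "normal", "overweight", "obese")


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty input: paired accuracy metrics need n >= 1")
    if np.any(a <= 0):
        raise ValueError("actual weights must be strictly positive")
    return p, a


def percent_error(predicted: float, actual: float) -> float:
    """Signed relative error in percent: 100 * (predicted - actual) / actual."""
    if actual <= 0:
        raise ValueError("actual weight must be strictly positive")
    return 100.0 * (predicted - actual) / actual


def p_within(predicted, actual, tolerance: float) -> float:
    """Percentage of pairs with |predicted - actual| / actual <= tolerance.

    Boundary-inclusive: a prediction off by exactly ``tolerance`` counts.
    ``tolerance`` is a fraction (0.10 for P10, 0.20 for P20).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    p, a = _paired(predicted, actual)
    within = np.abs(p - a) / a <= tolerance
    return 100.0 * within.sum() / within.size


def mean_percentage_error(predicted, actual) -> float:
    """Arithmetic mean of the signed percentage errors."""
    p, a = _paired(predicted, actual)
    return float(np.mean(100.0 * (p - a) / a))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, limits of agreement and their 95% CIs, plus per-pair plot points."""

    n: int
    bias: float                      # mean(predicted - actual), kg
    sd: float                        # sample SD of differences (n-1)
    loa_lower: float                 # bias - 1.96*sd
    loa_upper: float                 # bias + 1.96*sd
    bias_ci: tuple                   # 95% CI of bias
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    degenerate: bool                 # zero-variance differences
    points: pd.DataFrame = field(repr=False)  # columns: mean, difference


def bland_altman(predicted, actual) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of predicted vs measured weight.

    Differences are predicted - actual. Requires n >= 3 so the confidence
    intervals have at least 2 degrees of freedom. Zero-variance differences
    collapse the limits onto the bias; the result is flagged ``degenerate``
    and its CIs are zero-width rather than invalid.
    """
    p, a = _paired(predicted, actual)
    n = p.size
    if n < 3:
        raise ValueError("Bland-Altman CIs need n >= 3 (df >= 2)")
    d = p - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = sd == 0.0
    loa_lo = bias - 1.96 * sd
    loa_hi = bias + 1.96 * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    points = pd.DataFrame({"mean": (p + a) / 2.0, "difference": d})
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower_ci=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_upper_ci=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        degenerate=degenerate,
        points=points,
    )


def bmi(weight: float, height: float) -> float:
    """Body-mass index, kg/m^2, from weight in kg and height in cm."""
    if np.any(np.asarray(weight) <= 0) or np.any(np.asarray(height) <= 0):
        raise ValueError("weight and height must be strictly positive")
    return weight / (np.asarray(height, dtype=float) / 100.0) ** 2


def classify_nutrition(bmi_value: float) -> str:
    """WHO adult BMI category.

    <18.5 underweight; [18.5, 25) normal; [25, 30) overweight; >=30 obese.
    Lower boundaries inclusive.
    """
    b = float(bmi_value)
    if b <= 0 or math.isnan(b):
        raise ValueError("BMI must be strictly positive")
    if b < 18.5:
        return "underweight"
    if b < 25.0:
        return "normal"
    if b < 30.0:
        return "overweight"
    return "obese"


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy of one equation on one record set (or stratum thereof)."""

    equation_id: str
    axis: str                 # overall / sex / nutrition
    level: str                # overall, male/female, or a nutrition category
    n_input: int
    n_evaluated: int
    p10: Optional[float]
    p20: Optional[float]
    mpe: Optional[float]
    ba_bias: Optional[float]
    ba_loa_lower: Optional[float]
    ba_loa_upper: Optional[float]
    ba_bias_ci: Optional[tuple]
    ba_loa_lower_ci: Optional[tuple]
    ba_loa_upper_ci: Optional[tuple]
    n_implausible: int = 0    # non-positive predicted weights (flagged, kept)

    def __post_init__(self):
        if self.n_evaluated > 0 and self.p10 is not None and self.p20 is not None:
            if not (0.0 <= self.p10 <= self.p20 <= 100.0):
                raise AssertionError(
                    f"P10 <= P20 invariant violated for {self.equation_id} "
                    f"{self.axis}/{self.level}: {self.p10} vs {self.p20}"
                )


_NULL_BA = dict(
    mpe=None, ba_bias=None, ba_loa_lower=None, ba_loa_upper=None,
    ba_bias_ci=None, ba_loa_lower_ci=None, ba_loa_upper_ci=None,
)


def accuracy_report(
    equation_id: str,
    predicted,
    actual,
    *,
    axis: str = "overall",
    level: str = "overall",
    n_input: Optional[int] = None,
) -> AccuracyReport:
    """Full accuracy summary for one equation on paired predictions.

    NaN predictions (non-evaluable records) are dropped pairwise and reported
    through ``n_evaluated``; they are never imputed. A stratum left with no
    evaluable pairs yields null metrics, not an error.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    keep = ~np.isnan(p) & ~np.isnan(a)
    p, a = p[keep], a[keep]
    n_in = int(n_input if n_input is not None else keep.size)
    if p.size == 0:
        return AccuracyReport(
            equation_id=equation_id, axis=axis, level=level,
            n_input=n_in, n_evaluated=0, p10=None, p20=None, **_NULL_BA,
        )
    ba = bland_altman(p, a) if p.size >= 3 else None
    return AccuracyReport(
        equation_id=equation_id,
        axis=axis,
        level=level,
        n_input=n_in,
        n_evaluated=int(p.size),
        p10=p_within(p, a, 0.10),
        p20=p_within(p, a, 0.20),
        mpe=mean_percentage_error(p, a),
        ba_bias=ba.bias if ba else None,
        ba_loa_lower=ba.loa_lower if ba else None,
        ba_loa_upper=ba.loa_upper if ba else None,
        ba_bias_ci=ba.bias_ci if ba else None,
        ba_loa_lower_ci=ba.loa_lower_ci if ba else None,
        ba_loa_upper_ci=ba.loa_upper_ci if ba else None,
        n_implausible=int((p <= 0).sum()),
    )


def _strata(records: pd.DataFrame, axis: str) -> list:
    """(level, boolean mask) pairs for one stratification axis."""
    if axis == "overall":
        return [("overall", np.ones(len(records), dtype=bool))]
    if axis == "sex":
        sexes = records["sex"].map(lambda s: parse_sex(s).value)
        return [(lvl, (sexes == lvl).to_numpy()) for lvl in ("female", "male")]
    if axis == "nutrition":
        w = pd.to_numeric(records["weight"], errors="coerce")
        h = pd.to_numeric(records["height"], errors="coerce")
        ok = (w > 0) & (h > 0)
        cat = pd.Series("", index=records.index, dtype=object)
        cat[ok] = (w[ok] / (h[ok] / 100.0) ** 2).map(classify_nutrition)
        return [(lvl, (cat == lvl).to_numpy()) for lvl in NUTRITION_LEVELS]
    raise ValueError(f"unknown stratification axis {axis!r}")


def stratified_accuracy(
    records: pd.DataFrame,
    equation_ids: Optional[Sequence[str]] = None,
    axes: Sequence[str] = ("overall", "sex", "nutrition"),
) -> pd.DataFrame:
    """Accuracy of each equation overall and within sex / nutrition strata.

    Nutrition strata are assigned from BMI of the *measured* weight and
    height. Returns one row per equation x stratum with the full
    :class:`AccuracyReport` fields; strata with no records yield n=0 rows
    with null metrics.
    """
    if equation_ids is None:
        equation_ids = list(EQUATION_IDS)
    if "weight" not in records.columns:
        raise ValueError("records must carry measured weight for validation")
    preds = predict_all(records, equation_ids)
    actual = pd.to_numeric(records["weight"], errors="coerce").to_numpy(dtype=float)

    rows = []
    for axis in axes:
        for level, mask in _strata(records, axis):
            for eq in equation_ids:
                eq_pred = preds.loc[preds["equation_id"] == eq, "predicted_kg"]
                eq_pred = eq_pred.to_numpy(dtype=float)
                rep = accuracy_report(
                    eq, eq_pred[mask], actual[mask],
                    axis=axis, level=level, n_input=int(mask.sum()),
                )
                rows.append(rep.__dict__)
    out = pd.DataFrame(rows)
    return out
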