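"""End-to-end validation runs and report writing.

:func:`run_validation` composes prediction, stratified accuracy and the
descriptive summary into a :class:`ReportBundle`; :func:`write_reports`
serialises the bundle deterministically:

* ``overall_accuracy.csv`` — one row per equation with P10, P20, MPE, bias
  and limits of agreement (display precision, 2 dp half-up);
* ``subgroup_accuracy.csv`` — P10/P20 per equation within sex and nutrition
  strata;
* ``bland_altman_<eq>.csv`` — per-pair (mean, difference) points plus the
  bias and LOA reference lines, ready for external plotting;
* ``descriptives.csv`` — median (IQR) per variable, overall and by sex;
* ``report.json`` — every metric at full machine precision;
* ``manifest.json`` — inputs, seed, package version, conventions in force.

CSV outputs carry rounded display values; the JSON carries full precision.
Comparisons against published tables use display values, internal tests use
machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .equations import EQUATION_IDS, predict_all
from .io import describe_cohort
from .metrics import NUTRITION_LEVELS, bland_altman, stratified_accuracy

__all__ = ["ReportBundle", "run_validation", "write_reports", "round_display"]

#: conventions echoed into every manifest, so a report is self-describing
CONVENTIONS = {
    "percent_error": "100 * (predicted - actual) / actual",
    "p_within_boundary": "inclusive (<= tolerance)",
    "bland_altman_difference": "predicted - actual; x-axis is pair mean",
    "loa": "bias +/- 1.96 * SD(differences, ddof=1)",
    "loa_ci": "t(n-1) critical value; SE bias = s/sqrt(n), SE LOA = s*sqrt(3/n)",
    "bmi_categories": "WHO adult: <18.5 / [18.5,25) / [25,30) / >=30",
    "quantiles": "linear interpolation between order statistics",
    "display_rounding": "2 decimal places, half-up",
}


def round_display(value, places: int = 2):
    """Half-up decimal rounding for display columns (banker's rounding would
    drift from the usual clinical-table convention)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ReportBundle:
    records: pd.DataFrame
    predictions: pd.DataFrame            # tidy id x equation frame
    accuracy: pd.DataFrame               # stratified_accuracy output
    descriptives: pd.DataFrame
    bland_altman_points: Mapping[str, pd.DataFrame]
    manifest: dict

    @property
    def overall(self) -> pd.DataFrame:
        """One row per equation, overall stratum."""
        df = self.accuracy[self.accuracy["axis"] == "overall"]
        return df.reset_index(drop=True)

    @property
    def subgroups(self) -> pd.DataFrame:
        df = self.accuracy[self.accuracy["axis"] != "overall"]
        return df.reset_index(drop=True)


def run_validation(
    records: pd.DataFrame,
    equation_ids: Optional[Sequence[str]] = None,
    axes: Sequence[str] = ("overall", "sex", "nutrition"),
    *,
    manifest_extra: Optional[dict] = None,
) -> ReportBundle:
    """Run the full accuracy pipeline on an ingested record set."""
    equation_ids = list(equation_ids or EQUATION_IDS)
    predictions = predict_all(records, equation_ids)
    accuracy = stratified_accuracy(records, equation_ids, axes=axes)
    descriptives = describe_cohort(records)

    actual = pd.to_numeric(records["weight"], errors="coerce").to_numpy(float)
    ba_points: dict[str, pd.DataFrame] = {}
    for eq in equation_ids:
        pred = predictions.loc[
            predictions["equation_id"] == eq, "predicted_kg"
        ].to_numpy(float)
        keep = ~np.isnan(pred) & ~np.isnan(actual)
        if keep.sum() >= 3:
            ba_points[eq] = bland_altman(pred[keep], actual[keep]).points

    n_implausible = int(
        (predictions["predicted_kg"].to_numpy(float) <= 0).sum()
    )
    manifest = {
        "package": "anthroweight",
        "version": __version__,
        "n_records": int(len(records)),
        "equations": equation_ids,
        "axes": list(axes),
        "n_implausible_predictions": n_implausible,
        "conventions": CONVENTIONS,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    return ReportBundle(
        records=records,
        predictions=predictions,
        accuracy=accuracy,
        descriptives=descriptives,
        bland_altman_points=ba_points,
        manifest=manifest,
    )


def _display_overall(accuracy: pd.DataFrame) -> pd.DataFrame:
    df = accuracy[accuracy["axis"] == "overall"].copy()
    out = pd.DataFrame({
        "equation": df["equation_id"],
        "n": df["n_evaluated"],
        "P10": df["p10"].map(round_display),
        "P20": df["p20"].map(round_display),
        "MPE": df["mpe"].map(round_display),
        "bias_kg": df["ba_bias"].map(round_display),
        "LLOA_kg": df["ba_loa_lower"].map(round_display),
        "ULOA_kg": df["ba_loa_upper"].map(round_display),
        "n_implausible": df["n_implausible"],
    })
    return out.reset_index(drop=True)


def _display_subgroups(accuracy: pd.DataFrame) -> pd.DataFrame:
    df = accuracy[accuracy["axis"] != "overall"].copy()
    out = pd.DataFrame({
        "axis": df["axis"],
        "stratum": df["level"],
        "equation": df["equation_id"],
        "n": df["n_evaluated"],
        "P10": df["p10"].map(round_display),
        "P20": df["p20"].map(round_display),
    })
    return out.reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, tuple):
        return [_jsonable(x) for x in obj]
    return obj


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the bundle under *out_dir*; byte-identical for identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _display_overall(bundle.accuracy).to_csv(out / "overall_accuracy.csv", index=False)
    _display_subgroups(bundle.accuracy).to_csv(
        out / "subgroup_accuracy.csv", index=False)

    desc = bundle.descriptives.copy()
    for col in desc.columns:
        if col.endswith(("_median", "_q1", "_q3")):
            desc[col] = desc[col].map(round_display)
    desc.to_csv(out / "descriptives.csv", index=False)

    for eq, points in bundle.bland_altman_points.items():
        row = bundle.accuracy[
            (bundle.accuracy["axis"] == "overall")
            & (bundle.accuracy["equation_id"] == eq)
        ].iloc[0]
        pts = points.copy()
        pts["bias_line"] = row["ba_bias"]
        pts["lloa_line"] = row["ba_loa_lower"]
        pts["uloa_line"] = row["ba_loa_upper"]
        pts.to_csv(out / f"bland_altman_{eq}.csv", index=False)

    full = {
        "accuracy": [
            {k: _jsonable(v) for k, v in rec.items()}
            for rec in bundle.accuracy.to_dict(orient="records")
        ],
        "descriptives": [
            {k: _jsonable(v) for k, v in rec.items()}
            for rec in bundle.descriptives.to_dict(orient="records")
        ],
    }
    (out / "report.json").write_text(
        json.dumps(full, indent=2, sort_keys=True, allow_nan=False) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    return out
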