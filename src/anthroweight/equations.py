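"""Published anthropometric weight-prediction equations.

The registry encodes nine linear equations from the method-comparison
literature, transcribed at full printed precision:

=====  ==========  ======================================  =============
id     name        variables                               sex handling
=====  ==========  ======================================  =============
Ch     Chumlea     MAC, CC, SST, KH                        two branches
R1     Rabito 1    MAC, AC, CC, SST                        single
R2     Rabito 2    MAC, AC, CC                             single
R3     Rabito 3    MAC, AC, CC, coded sex                  coded term
Cr     Crandall    MAC, H                                  two branches
L      Lorenz      H, AC, HC                               two branches
KK     Kokong      H                                       single
J      Jung        KH, MAC, age                            two branches
C      Cattermole  MAC                                     single
=====  ==========  ======================================  =============

Equations with a coded-sex term use male=1, female=2 (``sex_code``). All
predictions are returned at full floating precision; any rounding is a
report-formatting concern. Negative predictions (possible at extreme small
inputs) are returned as-is and flagged implausible downstream — masking them
would hide exactly the pathology a validation study is meant to expose.

Coefficients are data, not code, so the transcription can be audited in one
place (:data:`REGISTRY`, or the YAML-ish dump from :func:`registry_to_text`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import AnthropometricRecord, Sex, parse_sex

__all__ = [
    "EquationSpec",
    "REGISTRY",
    "EQUATION_IDS",
    "get_equation",
    "predict_weight",
    "predict_all",
    "EvaluabilityError",
    "UnknownEquationError",
    "registry_to_text",
]


class UnknownEquationError(KeyError):
    """Requested equation id is not in the registry."""


class EvaluabilityError(ValueError):
    """A required variable is missing, so the equation cannot be evaluated."""


@dataclass(frozen=True)
class CoefficientSet:
    """One linear rule: sum(coef * variable) + intercept."""
    coefficients: Mapping[str, float]
    intercept: float


@dataclass(frozen=True)
class EquationSpec:
    """A named linear weight-prediction rule.

    ``branches`` is keyed by ``"all"`` for a single coefficient set, or by
    ``"male"``/``"female"`` when the equation has separate published branches.
    The pseudo-variable ``sex_code`` (male=1, female=2) may appear among the
    coefficients of a single-branch equation.
    """

    equation_id: str
    display_name: str
    required_variables: frozenset
    branches: Mapping[str, CoefficientSet]
    provenance_r2: Optional[Mapping[str, Optional[float]]] = None

    @property
    def sex_specific(self) -> bool:
        return "all" not in self.branches

    @property
    def needs_sex(self) -> bool:
        return self.sex_specific or any(
            "sex_code" in b.coefficients for b in self.branches.values()
        )

    def branch_for(self, sex: Sex | str) -> CoefficientSet:
        if not self.sex_specific:
            return self.branches["all"]
        return self.branches[parse_sex(sex).value]

    def __post_init__(self) -> None:
        for branch in self.branches.values():
            for var in branch.coefficients:
                record_field = "sex" if var == "sex_code" else var
                if record_field not in self.required_variables:
                    raise ValueError(
                        f"{self.equation_id}: coefficient variable {var!r} "
                        "not listed in required_variables"
                    )
        if self.sex_specific and set(self.branches) != {"male", "female"}:
            raise ValueError(
                f"{self.equation_id}: sex-specific equation needs exactly "
                "male and female branches"
            )


def _spec(eq_id, name, required, branches, r2=None) -> EquationSpec:
    return EquationSpec(
        equation_id=eq_id,
        display_name=name,
        required_variables=frozenset(required),
        branches=branches,
        provenance_r2=r2,
    )


#: The nine evaluable equations, coefficients exactly as published.
REGISTRY: Mapping[str, EquationSpec] = {
    "Ch": _spec(
        "Ch", "Chumlea", {"mac", "cc", "sst", "kh", "sex"},
        {
            "female": CoefficientSet(
                {"mac": 0.98, "cc": 1.27, "sst": 0.40, "kh": 0.87}, -62.35),
            "male": CoefficientSet(
                {"mac": 1.73, "cc": 0.98, "sst": 0.37, "kh": 1.16}, -81.69),
        },
        r2={"female": 0.85, "male": 0.90},
    ),
    "R1": _spec(
        "R1", "Rabito 1", {"mac", "ac", "cc", "sst"},
        {"all": CoefficientSet(
            {"mac": 0.5030, "ac": 0.5632, "cc": 1.3180, "sst": 0.0339},
            -43.1560)},
        r2={"all": 0.93},
    ),
    "R2": _spec(
        "R2", "Rabito 2", {"mac", "ac", "cc"},
        {"all": CoefficientSet(
            {"mac": 0.4808, "ac": 0.5646, "cc": 1.316}, -42.2450)},
        r2={"all": 0.93},
    ),
    "R3": _spec(
        "R3", "Rabito 3", {"mac", "ac", "cc", "sex"},
        {"all": CoefficientSet(
            {"mac": 0.5759, "ac": 0.5263, "cc": 1.2452, "sex_code": -4.8689},
            -32.9241)},
        r2={"all": 0.94},
    ),
    "Cr": _spec(
        "Cr", "Crandall", {"mac", "height", "sex"},
        {
            "female": CoefficientSet({"mac": 2.15, "height": 0.54}, -64.6),
            "male": CoefficientSet({"mac": 3.29, "height": 0.43}, -93.2),
        },
        r2={"female": 0.55, "male": 0.59},
    ),
    "L": _spec(
        "L", "Lorenz", {"height", "ac", "hc", "sex"},
        {
            "male": CoefficientSet(
                {"height": 0.60035, "ac": 0.785, "hc": 0.392}, -137.432),
            "female": CoefficientSet(
                {"height": 0.4053, "ac": 0.325, "hc": 0.836}, -110.924),
        },
        r2={"male": 0.85, "female": 0.82},
    ),
    "KK": _spec(
        "KK", "Kokong", {"height"},
        {"all": CoefficientSet({"height": 1.0}, -100.0)},
        r2={"all": 1.0},
    ),
    "J": _spec(
        "J", "Jung", {"kh", "mac", "age", "sex"},
        {
            "male": CoefficientSet(
                {"kh": 0.928, "mac": 2.508, "age": -0.144}, -42.543),
            "female": CoefficientSet(
                {"kh": 0.826, "mac": 2.116, "age": -0.133}, -31.486),
        },
        # female value as published; implausibly low next to the male 0.81
        # but kept verbatim — provenance metadata only, never computed with.
        r2={"male": 0.81, "female": 0.133},
    ),
    "C": _spec(
        "C", "Cattermole", {"mac"},
        {"all": CoefficientSet({"mac": 4.0}, -50.0)},
        r2=None,
    ),
}

#: Registry order, used for deterministic report layout.
EQUATION_IDS: tuple = tuple(REGISTRY)


def get_equation(equation_id: str) -> EquationSpec:
    try:
        return REGISTRY[equation_id]
    except KeyError:
        raise UnknownEquationError(
            f"unknown equation id {equation_id!r}; known: {sorted(REGISTRY)}"
        ) from None


def predict_weight(record: AnthropometricRecord, equation_id: str) -> float:
    """Evaluate one equation on one record, in kg at full precision.

    Raises :class:`EvaluabilityError` naming the missing variable(s) if the
    record lacks any required input, and :class:`UnknownEquationError` for an
    id not in the registry.
    """
    spec = get_equation(equation_id)
    missing = record.missing(sorted(spec.required_variables - {"sex"}))
    if spec.needs_sex and record.sex is None:
        missing.append("sex")
    if missing:
        raise EvaluabilityError(
            f"equation {equation_id} not evaluable for participant "
            f"{record.participant_id!r}: missing {', '.join(missing)}"
        )
    branch = spec.branch_for(record.sex)
    total = branch.intercept
    for var, coef in branch.coefficients.items():
        total += coef * record.get(var)
    return total


def predict_all(
    records: pd.DataFrame,
    equation_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Evaluate equations over a record-set frame.

    Returns a tidy frame with one row per record x equation, in input order:
    ``id``, ``equation_id``, ``predicted_kg`` (NaN when not evaluable),
    ``evaluable`` (bool), ``missing`` (comma-joined variable names, empty when
    evaluable). Non-evaluable cells are flagged, never imputed. An empty
    record set yields an empty frame (with a warning, not an error).
    """
    if equation_ids is None:
        equation_ids = list(EQUATION_IDS)
    specs = [get_equation(e) for e in equation_ids]

    if len(records) == 0:
        import warnings

        warnings.warn("predict_all called on an empty record set", stacklevel=2)
        return pd.DataFrame(
            columns=["id", "equation_id", "predicted_kg", "evaluable", "missing"]
        )

    sexes = records["sex"].map(lambda s: parse_sex(s).value)
    sex_codes = sexes.map({"male": 1, "female": 2}).to_numpy(dtype=float)

    def column(var: str) -> np.ndarray:
        if var == "sex_code":
            return sex_codes
        if var in records.columns:
            return pd.to_numeric(records[var], errors="coerce").to_numpy(dtype=float)
        return np.full(len(records), np.nan)

    pieces = []
    for spec in specs:
        pred = np.zeros(len(records))
        if spec.sex_specific:
            for sex_label, branch in spec.branches.items():
                mask = (sexes == sex_label).to_numpy()
                vals = np.full(len(records), branch.intercept)
                for var, coef in branch.coefficients.items():
                    vals = vals + coef * column(var)
                pred = np.where(mask, vals, pred)
        else:
            branch = spec.branches["all"]
            pred = np.full(len(records), branch.intercept)
            for var, coef in branch.coefficients.items():
                pred = pred + coef * column(var)

        needed = sorted(spec.required_variables - {"sex"})
        missing_mask = {v: np.isnan(column(v)) for v in needed}
        any_missing = np.zeros(len(records), dtype=bool)
        for m in missing_mask.values():
            any_missing |= m
        missing_str = [
            ",".join(v for v in needed if missing_mask[v][i]) if any_missing[i] else ""
            for i in range(len(records))
        ]
        pieces.append(pd.DataFrame({
            "id": records["id"].to_numpy(),
            "equation_id": spec.equation_id,
            "predicted_kg": np.where(any_missing, np.nan, pred),
            "evaluable": ~any_missing,
            "missing": missing_str,
        }))

    out = pd.concat(pieces, ignore_index=True)
    # deterministic ordering: input record order, then requested equation order
    order = {e: i for i, e in enumerate(equation_ids)}
    out["_rec"] = np.concatenate([np.arange(len(records))] * len(specs))
    out["_eq"] = out["equation_id"].map(order)
    out = out.sort_values(["_rec", "_eq"], kind="stable").drop(columns=["_rec", "_eq"])
    return out.reset_index(drop=True)


def registry_to_text() -> str:
    """Human-readable dump of the registry, one block per equation, for audit."""
    lines = []
    for spec in REGISTRY.values():
        lines.append(f"[{spec.equation_id}] {spec.display_name}")
        lines.append(f"  requires: {', '.join(sorted(spec.required_variables))}")
        for branch_name, branch in spec.branches.items():
            terms = " + ".join(
                f"({coef:+g} x {var})" for var, coef in branch.coefficients.items()
            )
            lines.append(f"  {branch_name}: W = {terms} {branch.intercept:+g}")
        if spec.provenance_r2:
            r2 = ", ".join(
                f"{k}={v}" for k, v in spec.provenance_r2.items() if v is not None
            )
            lines.append(f"  provenance R2: {r2}")
        lines.append("")
    return "\n".join(lines)
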