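"""Phenotype arithmetic: chlorophyll content and expression fold change.

Chlorophyll a, b and total are computed from absorbances at 664 nm and
649 nm of a 95% ethanol extract:

    chl_a = 13.36 * A664 - 5.19 * A649
    chl_b = 27.43 * A649 - 8.12 * A664
    total =  5.24 * A664 + 22.24 * A649

The coefficients satisfy total == chl_a + chl_b identically.  Values
are in the formula's own concentration units; the amount per leaf area
is concentration x extract volume / leaf area.  Negative chl_a or chl_b
(possible for absorbance ratios outside the plausible range) triggers a
warning, not an error.

Relative expression fold change divides the reference-gene-normalized
quantity of the treated sample by that of the control:

    fold = (target_treated / reference_treated)
         / (target_control / reference_control)

Inputs are linear-scale quantities already corrected for the reference
gene's amplification model; no Cq conversion is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd


@dataclass
class ChlorophyllMeasurement:
    a664: float
    a649: float
    extract_volume_ml: float = 20.0
    leaf_area_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a664 < 0 or self.a649 < 0:
            raise ValueError("absorbances must be non-negative")


def chlorophyll_content(m: ChlorophyllMeasurement) -> Tuple[float, float, float]:
    """(chl_a, chl_b, total) from the two absorbances."""
    chl_a = 13.36 * m.a664 - 5.19 * m.a649
    chl_b = 27.43 * m.a649 - 8.12 * m.a664
    total = 5.24 * m.a664 + 22.24 * m.a649
    if chl_a < 0 or chl_b < 0:
        warnings.warn(
            f"negative chlorophyll component (a={chl_a:.4g}, b={chl_b:.4g}); "
            "check the absorbance readings", stacklevel=2)
    return chl_a, chl_b, total


def normalize_per_area(total: float, m: ChlorophyllMeasurement) -> float:
    """Chlorophyll amount per cm^2: concentration x volume / leaf area."""
    if m.leaf_area_cm2 is None or m.leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive for per-area normalization")
    return total * m.extract_volume_ml / m.leaf_area_cm2


@dataclass
class ExpressionQuad:
    """Linear-scale expression quantities for one gene in one contrast."""

    target_treated: float
    reference_treated: float
    target_control: float
    reference_control: float

    def __post_init__(self) -> None:
        for name in ("target_treated", "reference_treated",
                     "target_control", "reference_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def fold_change(q: ExpressionQuad) -> float:
    """Treated normalized expression over control normalized expression."""
    if q.reference_treated == 0 or q.reference_control == 0:
        raise ValueError("reference quantities must be positive")
    control_ratio = q.target_control / q.reference_control
    if control_ratio == 0:
        raise ValueError("control normalized ratio is zero; fold change undefined")
    return (q.target_treated / q.reference_treated) / control_ratio


# --- table fronts used by the CLI ------------------------------------------

def chlorophyll_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add chl_a / chl_b / chl_total (+ per-area when leaf_area_cm2 given)
    columns to a table with columns sample, A664, A649[, volume_ml, leaf_area_cm2]."""
    out = df.copy()
    rows = []
    for _, r in df.iterrows():
        m = ChlorophyllMeasurement(
            float(r["A664"]), float(r["A649"]),
            float(r.get("volume_ml", 20.0) or 20.0),
            float(r["leaf_area_cm2"]) if "leaf_area_cm2" in df.columns else None,
        )
        a, b, tot = chlorophyll_content(m)
        row = {"chl_a": a, "chl_b": b, "chl_total": tot}
        if m.leaf_area_cm2 is not None:
            row["chl_total_per_cm2"] = normalize_per_area(tot, m)
        rows.append(row)
    return pd.concat([out, pd.DataFrame(rows, index=df.index)], axis=1)


def fold_change_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a fold_change column to a table with columns sample,
    target_treated, reference_treated, target_control, reference_control."""
    out = df.copy()
    out["fold_change"] = [
        fold_change(ExpressionQuad(
            float(r["target_treated"]), float(r["reference_treated"]),
            float(r["target_control"]), float(r["reference_control"])))
        for _, r in df.iterrows()
    ]
    return out
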