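"""Study report tables.

Layouts mirror how QCA validation studies print their results: a paired
measurement table (both arms as mean ± SD plus the paired p-value), a
median-difference table (median and 25th–75th percentile of the absolute
per-case differences), and a one-row overlap-metric table (median and IQR
of each metric, in percent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ComparisonResult, median_iqr

MEASUREMENT_ROWS = (
    ("stenosis_percent", "Diameter Stenosis (%)"),
    ("lesion_mm", "Diameter at lesion (mm)"),
    ("proximal_mm", "Diameter at proximal obstruction border (mm)"),
    ("distal_mm", "Diameter at distal obstruction border (mm)"),
)

OVERLAP_COLUMNS = (
    ("accuracy", "Accuracy (%)"),
    ("sensitivity", "Sensitivity (%)"),
    ("specificity", "Specificity (%)"),
    ("ppv", "Positive predictive value (%)"),
    ("npv", "Negative predictive value (%)"),
    ("iou", "Intersection over Union (%)"),
    ("dice", "Dice Score (%)"),
)


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def measurements_table(comparisons: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Both arms as mean ± SD with the paired test p-value per parameter."""
    rows = []
    for key, label in MEASUREMENT_ROWS:
        c = comparisons[key]
        rows.append({
            "Parameter": label,
            "Original Image": f"{_fmt(c.original_mean)} ± {_fmt(c.original_sd)}",
            "AI Generated Segmented Image": f"{_fmt(c.segmented_mean)} ± {_fmt(c.segmented_sd)}",
            "P-value": f"{c.p_value:.3f}" if c.p_value >= 0.001 else "< 0.001",
            "Test": c.test_name,
        })
    return pd.DataFrame(rows)


def differences_table(comparisons: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Median (IQ 25th – 75th) of absolute original-segmented differences."""
    rows = []
    for key, label in MEASUREMENT_ROWS:
        c = comparisons[key]
        rows.append({
            "Parameter": label,
            "Difference": f"{_fmt(c.diff_median)} ({_fmt(c.diff_q25)}–{_fmt(c.diff_q75)})",
        })
    return pd.DataFrame(rows)


def overlap_table(cases: pd.DataFrame) -> pd.DataFrame:
    """One row: median (IQR) of each overlap metric (%), over included cases."""
    row = {}
    for key, label in OVERLAP_COLUMNS:
        vals = cases[f"{key}_percent"].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        med, q25, q75 = median_iqr(vals)
        row[label] = f"{_fmt(med, 1)} ({_fmt(q25, 1)}–{_fmt(q75, 1)})"
    return pd.DataFrame([row])


def to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (no external dependencies)."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)
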