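"""Tabular reporting of prevalence curves in the field's customary format."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .combine import PrevalenceCurve


def format_pct(estimate: float, lower: float | None = None,
               upper: float | None = None) -> str:
    """Render an estimate (and CI) as integer percentages: "62% (57%-67%)"."""
    est = f"{estimate * 100:.0f}%"
    if lower is None or upper is None or np.isnan(lower) or np.isnan(upper):
        return est
    return f"{est} ({lower * 100:.0f}%-{upper * 100:.0f}%)"


def report_table(curves: list[PrevalenceCurve], ages: list[int]) -> pd.DataFrame:
    """Entity x sex x age table with formatted percentage strings.

    One row per (entity, sex, requested age); requested ages must lie on each
    curve's grid.  An empty curve list yields an empty table with the header.
    """
    rows = []
    for curve in curves:
        for age in ages:
            idx = np.flatnonzero(curve.ages == age)
            if idx.size == 0:
                raise KeyError(f"age {age} not on the grid of {curve.entity}/{curve.sex}")
            i = idx[0]
            lo = curve.lower[i] if curve.lower is not None else None
            hi = curve.upper[i] if curve.upper is not None else None
            rows.append({
                "entity": curve.entity, "sex": curve.sex, "age": age,
                "prevalence": format_pct(curve.estimates[i], lo, hi),
            })
    return pd.DataFrame(rows, columns=["entity", "sex", "age", "prevalence"])
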