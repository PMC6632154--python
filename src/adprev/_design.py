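"""Shared design-matrix construction for all regression stages.

Age enters every model as z = (age - 75) / 10 so that intercepts refer to a
75-year-old and coefficients are per decade; education enters as indicator
columns for the four attained-education categories with "13-16" as reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_CENTER = 75.0
AGE_SCALE = 10.0

EDU_LEVELS = ["<12", "12", "13-16", ">16"]
EDU_REF = "13-16"

#: term vocabulary accepted by :func:`design_matrix`
TERMS = ("z", "z2", "male", "z_male", "edu")


def age_z(age) -> np.ndarray:
    """Centered/scaled age: (age - 75) / 10."""
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


def design_matrix(frame: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix (with leading intercept column) from a record frame.

    Parameters
    ----------
    frame
        Must have ``age`` and ``sex`` columns; ``education`` if "edu" is in
        *terms*.  Missing education falls into the reference category.
    terms
        Subset of :data:`TERMS`, in any order.

    Returns
    -------
    (X, names)
        X has shape (n, 1 + len(expanded terms)).
    """
    n = len(frame)
    z = age_z(frame["age"].to_numpy())
    male = (frame["sex"].to_numpy() == "male").astype(float)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for t in terms:
        if t == "z":
            cols.append(z)
            names.append("z")
        elif t == "z2":
            cols.append(z * z)
            names.append("z2")
        elif t == "male":
            cols.append(male)
            names.append("male")
        elif t == "z_male":
            cols.append(z * male)
            names.append("z_male")
        elif t == "edu":
            edu = frame["education"].to_numpy(dtype=object)
            for lev in EDU_LEVELS:
                if lev == EDU_REF:
                    continue
                cols.append((edu == lev).astype(float))
                names.append(f"edu[{lev}]")
        else:
            raise ValueError(f"unknown design term {t!r}; allowed: {TERMS}")
    return np.column_stack(cols), names
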