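"""Preparation of the site x environmental-variable table.

Environmental gradients measured in heterogeneous units (pH units, g/kg,
individuals/m^2, ...) are brought onto a common 1-100 scale before response
modeling, so that niche optima and ecological distances are comparable across
variables.  This module also computes the land-use intensity (LUI) index from
its mowing/grazing/fertilization components and screens the variable set for
collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rescale_variable",
    "rescale_table",
    "compute_lui",
    "correlation_screen",
    "CorrelationScreen",
]


def rescale_variable(values) -> np.ndarray:
    """Affinely rescale one variable to the common [1, 100] gradient scale.

    The observed minimum maps to 1 and the observed maximum to 100:

        x' = 1 + 99 * (x - min) / (max - min)

    Missing values (NaN) are ignored when determining min/max and propagate
    unchanged to the output.

    Parameters
    ----------
    values : array-like of float
        Raw measurements for a single variable across sites.

    Returns
    -------
    numpy.ndarray
        Rescaled values in [1, 100], same shape as the input.

    Raises
    ------
    ValueError
        If fewer than two distinct non-missing values are present (the
        rescaling is undefined for a constant variable).
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or np.nanmax(finite) == np.nanmin(finite):
        raise ValueError(
            "rescaling requires at least two distinct non-missing values"
        )
    lo, hi = finite.min(), finite.max()
    return 1.0 + 99.0 * (x - lo) / (hi - lo)


def rescale_table(env: pd.DataFrame) -> pd.DataFrame:
    """Rescale every column of a site x variable table to [1, 100].

    Columns are rescaled independently using each variable's own observed
    min/max across sites.  Missing cells stay missing.
    """
    out = {}
    for col in env.columns:
        out[col] = rescale_variable(env[col].to_numpy(dtype=float))
    return pd.DataFrame(out, index=env.index)


def compute_lui(mowing, grazing, fertilization) -> np.ndarray:
    """Land-use intensity index per plot.

    Each management component is standardized by its overall mean and the
    index is the square root of the component sum:

        LUI = sqrt(m / mean(m) + g / mean(g) + f / mean(f))

    A component whose mean is zero (no plot mowed/grazed/fertilized at all)
    contributes 0 by convention.

    Parameters
    ----------
    mowing, grazing, fertilization : array-like of float
        Non-negative per-plot component intensities (cuts per year, livestock
        units, kg N / ha / yr).

    Returns
    -------
    numpy.ndarray
        Dimensionless LUI, one value per plot.
    """
    comps = [np.asarray(v, dtype=float) for v in (mowing, grazing, fertilization)]
    n = comps[0].shape[0]
    if any(c.shape[0] != n for c in comps):
        raise ValueError("component vectors must have equal length")
    if any((c < 0).any() for c in comps):
        raise ValueError("management components must be non-negative")
    total = np.zeros(n)
    for c in comps:
        mean = c.mean()
        if mean > 0:
            total += c / mean
    return np.sqrt(total)


@dataclass
class CorrelationScreen:
    """Pairwise Pearson correlation summary of an environment table."""

    matrix: pd.DataFrame          # full symmetric correlation matrix
    pairs: pd.DataFrame           # one row per unordered variable pair
    n_pairs: int                  # C(V, 2)
    mean_abs_r: float
    n_above: int                  # pairs with |r| > threshold
    threshold: float


def correlation_screen(env: pd.DataFrame, threshold: float = 0.7) -> CorrelationScreen:
    """Screen a site x variable table for collinearity.

    Computes all C(V, 2) unordered pairwise Pearson correlations
    (pairwise-complete over sites), their mean absolute value, and the count
    of strongly correlated pairs (|r| > ``threshold``).

    Raises
    ------
    ValueError
        If fewer than 2 variables or 3 sites are supplied, or a variable is
        constant (correlation undefined).
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    stds = env.std(skipna=True)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant variable(s) with undefined correlation: {constant}")

    corr = env.corr(method="pearson")  # pairwise-complete by construction
    cols = list(env.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rows.append((cols[i], cols[j], corr.iloc[i, j]))
    pairs = pd.DataFrame(rows, columns=["var1", "var2", "r"])
    abs_r = pairs["r"].abs()
    return CorrelationScreen(
        matrix=corr,
        pairs=pairs,
        n_pairs=len(pairs),
        mean_abs_r=float(abs_r.mean()),
        n_above=int((abs_r > threshold).sum()),
        threshold=threshold,
    )
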