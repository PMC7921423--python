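"""Extreme-outlier trimming shared by the quantification pipelines.

Values outside [Q1 - k*IQR, Q3 + k*IQR] with k = 5 are treated as extreme
outliers (a far stricter fence than Tukey's k = 1.5, so only pathological
cells/fields are removed). Quartiles use linear interpolation.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["iqr_bounds", "trim_extreme_values"]

DEFAULT_IQR_FACTOR = 5.0
MIN_N_FOR_TRIM = 4  # quartiles are not meaningful below this


def iqr_bounds(values, k: float = DEFAULT_IQR_FACTOR) -> tuple[float, float]:
    """Lower and upper fences Q1 - k*IQR, Q3 + k*IQR."""
    arr = np.asarray(list(values), dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def trim_extreme_values(values, k: float = DEFAULT_IQR_FACTOR) -> np.ndarray:
    """Boolean retention mask: True where the value is not an extreme outlier.

    With fewer than four values no trimming is applied (warning): the
    quartile fences would be dominated by the values under test.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < MIN_N_FOR_TRIM:
        warnings.warn(
            f"only {arr.size} values: extreme-outlier trim skipped", stacklevel=2
        )
        return np.ones(arr.size, dtype=bool)
    lo, hi = iqr_bounds(arr, k=k)
    return (arr >= lo) & (arr <= hi)
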