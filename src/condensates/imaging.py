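"""Condensate quantification from fluorescence images.

Two readouts mirroring the microscopy assays:

* per-cell condensate count/size from a single-channel image restricted to
  a cell mask (Gaussian smoothing, local mean threshold, particle
  analysis) — the live-cell readout;
* field-averaged total condensate intensity with internal-standard
  normalisation — the in vitro droplet assay, where the amount of
  condensate in a sample is the mean total particle intensity over
  (by default five) imaged fields.

Images are plain 2D arrays; TIFF I/O lives in :mod:`condensates.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .outliers import trim_extreme_values

__all__ = [
    "QuantParams",
    "detect_condensates",
    "quantify_invitro",
    "normalize_to_standard",
    "trim_extreme_values",
]


@dataclass(frozen=True)
class QuantParams:
    """Detection settings (the pilot-calibrated knobs of the assay).

    ``threshold_offset`` is added to the local mean: a pixel is foreground
    when its smoothed value exceeds local_mean + offset. ``bg_sigma`` is
    the large-scale Gaussian used as a rolling-ball-equivalent background
    estimate for the in vitro fields.
    """

    sigma: float = 1.0  # px, Gaussian smoothing
    window: int = 31  # px, local-threshold neighbourhood (odd)
    threshold_offset: float = 10.0  # intensity units above the local mean
    min_area: int = 4  # px^2, smallest particle kept
    bg_sigma: float = 20.0  # px, background-estimation scale (in vitro)
    n_fields: int = 5  # fields imaged per in vitro sample

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


def detect_condensates(
    image: np.ndarray, mask: np.ndarray, params: QuantParams = QuantParams()
) -> dict:
    """Count and measure condensates inside a cell mask.

    Pipeline: Gaussian smoothing -> local mean threshold (+offset) ->
    restriction to the mask -> connected components -> discard particles
    below ``min_area``. An image with no particle above threshold returns
    count 0. Both the smoothing and the local threshold are invariant to
    image-wide additive offsets.

    Returns a dict with ``count``, ``areas`` (px^2, descending),
    ``total_intensity`` (sum of background-subtracted intensity over
    particle pixels) and the label image.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")

    smoothed = ndimage.gaussian_filter(image, params.sigma, mode="nearest")
    # skimage subtracts its offset from the local mean; negate to add
    local_thresh = filters.threshold_local(
        smoothed, params.window, method="mean", offset=-params.threshold_offset
    )
    binary = (smoothed > local_thresh) & mask
    labels, n_raw = ndimage.label(binary)
    if n_raw:
        raw_areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(raw_areas >= params.min_area)
        keep = keep[keep > 0]  # drop background label
        relabel = np.zeros(n_raw + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        binary = labels > 0
    count = int(labels.max())

    areas = np.bincount(labels.ravel())[1:]
    total = float((smoothed - local_thresh)[binary].sum()) if count else 0.0
    return {
        "count": int(count),
        "areas": sorted((int(a) for a in areas), reverse=True),
        "total_intensity": total,
        "labels": labels,
    }


def _background_correct(image: np.ndarray, params: QuantParams) -> np.ndarray:
    """Subtract a large-scale Gaussian background estimate (clipped at 0)."""
    bg = ndimage.gaussian_filter(image, params.bg_sigma, mode="nearest")
    return np.clip(image - bg, 0.0, None)


def quantify_invitro(
    fields: list[np.ndarray], params: QuantParams = QuantParams()
) -> tuple[float, pd.DataFrame]:
    """Amount of condensate in one sample from its imaged fields.

    Each field is background-corrected, particles are detected, and the
    field's total particle intensity is summed; the sample amount is the
    mean over fields. Returns ``(amount, per-field table)``.
    """
    if len(fields) == 0:
        raise ValueError("need at least one field image")
    rows = []
    for i, field_img in enumerate(fields):
        corrected = _background_correct(np.asarray(field_img, dtype=float), params)
        result = detect_condensates(
            corrected, np.ones(corrected.shape, dtype=bool), params
        )
        rows.append(
            {
                "field": i,
                "count": result["count"],
                "total_intensity": result["total_intensity"],
            }
        )
    table = pd.DataFrame(rows)
    return float(table["total_intensity"].mean()), table


def normalize_to_standard(
    amounts, standard_amount: float, control_mean: float | None = None
) -> np.ndarray:
    """Express sample amounts relative to the internal standard.

    Each amount is divided by the standard sample's amount; when comparing
    across experiments, the standardised values are further divided by the
    mean of the control samples (``control_mean``).
    """
    if not standard_amount > 0:
        raise ValueError("internal standard amount must be > 0")
    rel = np.asarray(list(amounts), dtype=float) / standard_amount
    if control_mean is not None:
        if not control_mean > 0:
            raise ValueError("control mean must be > 0")
        rel = rel / control_mean
    return rel
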