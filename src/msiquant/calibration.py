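"""Calibration of normalized ion signal against spotted drug amount per area.

Drops containing known drug amounts (0.2-15 pmol per spot) placed on
control tissue give a linear relation between the mean (normalized) ion
signal over each spot ROI and the spotted amount per surface, in
pmol/mm^2.  An ordinary least-squares line through those points is then
inverted to express any ROI's mean signal as an absolute amount per area.

The per-spot signal summary is the mean over valid pixels, which is
robust to spot-size differences and consistent with an amount-per-surface
x axis.  The fit is unweighted and not forced through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msi_data import IonImage, ROI
from .normalization import NormalizedImage


@dataclass
class CalibrationSpot:
    """A calibration drop: its ROI on the section and the spotted amount."""

    roi: ROI
    amount_pmol: float

    def __post_init__(self) -> None:
        if not self.amount_pmol > 0:
            raise ValueError("amount_pmol must be > 0")


@dataclass
class CalibrationCurve:
    """Linear model: signal = slope * (amount per area) + intercept.

    ``points`` holds the fitted (pmol/mm^2, mean signal) pairs, sorted by
    amount; ``amount_range`` is the calibrated x span, used to flag
    extrapolation on inversion.
    """

    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]]
    amount_range: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("calibration curve needs >= 3 points")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")
        self.points = sorted(self.points)

    def predict(self, amount_per_area: float) -> float:
        return self.slope * amount_per_area + self.intercept

    def to_json(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "points": [list(p) for p in self.points],
            "amount_range_pmol_per_mm2": list(self.amount_range),
        }


@dataclass
class QuantResult:
    """A reverse-calculated amount per area, with provenance flags."""

    amount_pmol_per_mm2: float
    extrapolated: bool
    n_valid_pixels: int | None = None


def build_calibration(
    spots: list[CalibrationSpot], image: NormalizedImage | IonImage
) -> CalibrationCurve:
    """Fit the OLS calibration line from spot ROIs on one section.

    x = amount_pmol / ROI area (pmol/mm^2); y = mean signal over the spot's
    valid pixels.  R^2 is the squared Pearson correlation of (x, y).
    """
    if len({s.amount_pmol for s in spots}) < 3:
        raise ValueError("calibration needs >= 3 spots with distinct amounts")
    xs, ys = [], []
    for spot in spots:
        vals = spot.roi.pixel_values(image)
        if vals.size == 0:
            raise ValueError(
                f"calibration spot ({spot.amount_pmol} pmol) has no valid pixels")
        xs.append(spot.amount_pmol / spot.roi.area_mm2(image.pixel_size_um))
        ys.append(float(vals.mean()))
    x = np.array(xs)
    y = np.array(ys)
    if np.var(x) == 0:
        raise ValueError("zero variance in amount per area")
    fit = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        points=list(zip(x.tolist(), y.tolist())),
        amount_range=(float(x.min()), float(x.max())),
    )


def invert(curve: CalibrationCurve, signal: float) -> QuantResult:
    """Reverse-calculate amount per area from a mean signal.

    Returns (signal - intercept) / slope; the result is flagged as
    extrapolated when it falls outside the calibrated amount range
    (including negative amounts for signals below the intercept).
    """
    if not curve.slope > 0:
        raise ValueError("calibration slope must be > 0 for inversion")
    amount = (signal - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    return QuantResult(amount_pmol_per_mm2=float(amount),
                       extrapolated=not lo <= amount <= hi)


def quantify_roi(
    image: NormalizedImage | IonImage, roi: ROI, curve: CalibrationCurve
) -> QuantResult:
    """Mean signal over the ROI's valid pixels, inverted to pmol/mm^2."""
    vals = roi.pixel_values(image)
    if vals.size == 0:
        raise ValueError("ROI has no valid pixels")
    result = invert(curve, float(vals.mean()))
    result.n_valid_pixels = int(vals.size)
    return result
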