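"""Per-pixel internal-standard normalization and reproducibility metrics.

Ion suppression — the local loss of analyte signal caused by co-located
tissue components — varies between tissues and within one tumor section.
Because a deuterated internal standard sprayed uniformly over the section
suffers the same suppression at each pixel, dividing the drug ion image
by the internal-standard ion image pixel-wise cancels the suppression
field and leaves a ratio proportional to the local drug amount.

Pixels where the internal standard falls below a floor are masked rather
than clipped: dividing by a near-zero standard would produce unbounded
ratios that reflect noise, not drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msi_data import IonImage, ROI, SectionStack, whole_image_roi

#: default internal-standard floor, as a fraction of the median valid intensity
DEFAULT_ISTD_FLOOR_FRACTION = 0.05


@dataclass
class NormalizedImage:
    """Per-pixel drug / internal-standard ratio image (dimensionless)."""

    values: np.ndarray
    mask: np.ndarray
    istd_floor: float
    pixel_size_um: float
    provenance: tuple[str, str] = ("", "")
    n_masked_low_istd: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        valid = self.values[self.mask]
        if valid.size and (not np.isfinite(valid).all() or (valid < 0).any()):
            raise ValueError("valid ratios must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class RSDReport:
    """Relative standard deviation (100 * sd / mean) before and after normalization."""

    roi_label: str
    rsd_raw: float
    rsd_norm: float
    n_pixels_raw: int
    n_pixels_norm: int


@dataclass
class SeriesComparison:
    """Welch t-test comparison of two serial-section series.

    Per-section whole-section mean drug/istd ratios and mean internal-standard
    intensities, with two-sided t statistics and p-values for each quantity.
    """

    mean_ratio_a: np.ndarray
    mean_ratio_b: np.ndarray
    mean_istd_a: np.ndarray
    mean_istd_b: np.ndarray
    t_ratio: float
    p_ratio: float
    t_istd: float
    p_istd: float


def default_istd_floor(istd: IonImage) -> float:
    """5% of the median valid internal-standard intensity."""
    valid = istd.valid_values()
    if valid.size == 0:
        raise ValueError("no valid internal-standard pixels")
    return DEFAULT_ISTD_FLOOR_FRACTION * float(np.median(valid))


def normalize(
    drug: IonImage, istd: IonImage, istd_floor: float | None = None
) -> NormalizedImage:
    """Divide the drug image by the internal-standard image pixel-wise.

    A pixel is valid when it is valid in both inputs and the internal
    standard is at least ``istd_floor`` (default: 5% of the median valid
    internal-standard intensity).  The number of pixels lost to the floor
    is reported on the result.
    """
    if drug.shape != istd.shape:
        raise ValueError(f"shape mismatch: drug {drug.shape} vs istd {istd.shape}")
    if drug.pixel_size_um != istd.pixel_size_um:
        raise ValueError("pixel_size_um mismatch between channels")
    if istd_floor is None:
        istd_floor = default_istd_floor(istd)
    if not istd_floor > 0:
        raise ValueError("istd_floor must be > 0")

    common = drug.mask & istd.mask
    mask = common & (istd.values >= istd_floor)
    if not mask.any():
        raise ValueError("no valid internal-standard signal (all pixels masked)")
    values = np.zeros(drug.shape)
    values[mask] = drug.values[mask] / istd.values[mask]
    return NormalizedImage(
        values,
        mask,
        istd_floor=float(istd_floor),
        pixel_size_um=drug.pixel_size_um,
        provenance=(drug.label, istd.label),
        n_masked_low_istd=int(common.sum() - mask.sum()),
    )


def rsd_percent(image: IonImage | NormalizedImage, roi: ROI | None = None) -> float:
    """RSD% = 100 * sample standard deviation / mean over valid ROI pixels."""
    vals = roi.pixel_values(image) if roi is not None else image.valid_values()
    if vals.size < 2:
        raise ValueError("RSD needs at least 2 valid pixels")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    return 100.0 * float(vals.std(ddof=1)) / mean


def rsd_report(
    drug: IonImage, istd: IonImage, roi: ROI | None = None,
    istd_floor: float | None = None, label: str = "",
) -> RSDReport:
    """Whole-ROI RSD% of the raw drug signal and of the normalized ratio.

    Both figures are reported because the variability of interest can be
    assessed on either scale; the normalized one removes shared
    suppression-driven variability.
    """
    norm = normalize(drug, istd, istd_floor)
    if roi is None:
        roi = whole_image_roi(drug)
    raw_vals = roi.pixel_values(drug)
    norm_vals = roi.pixel_values(norm)
    return RSDReport(
        roi_label=label,
        rsd_raw=rsd_percent(drug, roi),
        rsd_norm=rsd_percent(norm, roi),
        n_pixels_raw=int(raw_vals.size),
        n_pixels_norm=int(norm_vals.size),
    )


def compare_series(
    stack_a: SectionStack,
    stack_b: SectionStack,
    whole_section_rois: tuple[list[ROI] | None, list[ROI] | None] = (None, None),
    istd_floor: float | None = None,
) -> SeriesComparison:
    """Compare two serial-section series on whole-section summary statistics.

    For every section the mean drug/istd ratio and the mean internal-standard
    intensity are computed over the whole-section ROI; the two series are then
    compared with a two-sided Welch (unequal-variance) t-test on each quantity.
    """
    if len(stack_a) < 2 or len(stack_b) < 2:
        raise ValueError("each series needs at least 2 sections")

    def _summaries(stack: SectionStack, rois) -> tuple[np.ndarray, np.ndarray]:
        ratios, istds = [], []
        for i, (drug, istd) in enumerate(stack.sections):
            roi = rois[i] if rois is not None else whole_image_roi(drug)
            norm = normalize(drug, istd, istd_floor)
            rvals = roi.pixel_values(norm)
            ivals = roi.pixel_values(istd)
            if rvals.size == 0 or ivals.size == 0:
                raise ValueError(f"section {i}: ROI has no valid pixels")
            ratios.append(float(rvals.mean()))
            istds.append(float(ivals.mean()))
        return np.array(ratios), np.array(istds)

    ratio_a, istd_a = _summaries(stack_a, whole_section_rois[0])
    ratio_b, istd_b = _summaries(stack_b, whole_section_rois[1])

    def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("degenerate input: both series have zero variance")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)

    t_r, p_r = _welch(ratio_a, ratio_b)
    t_i, p_i = _welch(istd_a, istd_b)
    return SeriesComparison(ratio_a, ratio_b, istd_a, istd_b, t_r, p_r, t_i, p_i)
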