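"""Background thresholding, percent-positive pixels, and particle analysis.

The drug-coverage metric is the percentage of ROI pixels whose normalized
signal exceeds a background threshold estimated from untreated control
sections: threshold = mean + k * sd of the pooled control pixels
(default k = 3).  Positivity is a strict exceedance; ties at the
threshold count as negative.

"Particle analysis" then describes the spatial arrangement of positive
pixels: connected clusters (8-connectivity by default, as in ImageJ) are
measured for count, size, perimeter and circularity.  The perimeter is
the count of exposed pixel edges (4-neighbourhood boundary) scaled by the
pixel size; circularity = 4*pi*area/perimeter^2, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .msi_data import ROI
from .normalization import NormalizedImage

DEFAULT_K = 3.0


@dataclass
class ThresholdModel:
    """Background statistics from untreated controls and the positivity cutoff."""

    mean_bg: float
    sd_bg: float
    k: float
    n_control_pixels: int

    def __post_init__(self) -> None:
        if self.sd_bg < 0:
            raise ValueError("sd_bg must be >= 0")
        if self.n_control_pixels < 2:
            raise ValueError("need >= 2 control pixels")

    @property
    def threshold(self) -> float:
        return self.mean_bg + self.k * self.sd_bg

    def to_json(self) -> dict:
        return {"mean_bg": self.mean_bg, "sd_bg": self.sd_bg, "k": self.k,
                "threshold": self.threshold,
                "n_control_pixels": self.n_control_pixels}


@dataclass
class ParticleStats:
    """Summary of connected clusters of positive pixels."""

    n_particles: int
    mean_size_px: float
    mean_size_mm2: float
    mean_perimeter_edges: float
    mean_perimeter_mm: float
    mean_circularity: float
    table: pd.DataFrame = field(repr=False)


@dataclass
class HeterogeneityReport:
    """Percent-positive pixels plus particle statistics for one section/ROI."""

    percent_positive: float
    threshold: float
    n_positive: int
    n_valid: int
    particles: ParticleStats
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError("percent_positive must be in [0, 100]")


def estimate_threshold(
    control_images: list[NormalizedImage],
    rois: list[ROI | None] | None = None,
    k: float = DEFAULT_K,
) -> ThresholdModel:
    """Pool valid control pixels and set threshold = mean + k * sd (sample sd)."""
    pooled = []
    for i, img in enumerate(control_images):
        roi = rois[i] if rois is not None else None
        vals = roi.pixel_values(img) if roi is not None else img.valid_values()
        pooled.append(np.asarray(vals, dtype=float))
    pixels = np.concatenate(pooled) if pooled else np.empty(0)
    if pixels.size < 2:
        raise ValueError("need >= 2 pooled control pixels to estimate background")
    return ThresholdModel(
        mean_bg=float(pixels.mean()),
        sd_bg=float(pixels.std(ddof=1)),
        k=float(k),
        n_control_pixels=int(pixels.size),
    )


def percent_positive(
    image: NormalizedImage, roi: ROI | None = None, threshold: float = 0.0
) -> float:
    """100 * #{valid ROI pixels with value > threshold} / #{valid ROI pixels}."""
    vals = roi.pixel_values(image) if roi is not None else image.valid_values()
    if vals.size == 0:
        raise ValueError("ROI has no valid pixels")
    return 100.0 * float((vals > threshold).sum()) / vals.size


def positive_mask(image: NormalizedImage, threshold: float) -> np.ndarray:
    """Boolean mask of valid pixels strictly above the threshold."""
    return image.mask & (image.values > threshold)


def _exposed_edges(labels: np.ndarray) -> np.ndarray:
    """Per-label count of pixel edges facing background or the grid boundary.

    Two distinct components are never 4-adjacent (4-adjacency would merge
    them under either connectivity), so an exposed edge is exactly an edge
    to a zero pixel or off the grid.
    """
    padded = np.pad(labels, 1)
    n = int(labels.max())
    edges = np.zeros(n + 1, dtype=int)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr:padded.shape[0] - 1 + dr,
                       1 + dc:padded.shape[1] - 1 + dc]
        exposed = (labels > 0) & (neigh == 0)
        edges += np.bincount(labels[exposed], minlength=n + 1)
    return edges


def particle_analysis(
    image: NormalizedImage, threshold: float, connectivity: int = 8
) -> ParticleStats:
    """Measure connected clusters of positive pixels.

    ``connectivity`` is 4 (edge neighbours) or 8 (edges + diagonals,
    ImageJ's default).  Sizes and perimeters are reported both in pixel
    units and in physical units from the image's pixel size.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = positive_mask(image, threshold)
    labels = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
    n = int(labels.max())
    px_mm = image.pixel_size_um / 1000.0
    if n == 0:
        empty = pd.DataFrame(columns=["particle_id", "size_px", "size_mm2",
                                      "perimeter_edges", "perimeter_mm",
                                      "circularity"])
        return ParticleStats(0, float("nan"), float("nan"), float("nan"),
                             float("nan"), float("nan"), empty)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    edges = _exposed_edges(labels)[1:]
    area_mm2 = sizes * px_mm**2
    perim_mm = edges * px_mm
    circ = np.minimum(1.0, 4.0 * np.pi * area_mm2 / perim_mm**2)
    table = pd.DataFrame({
        "particle_id": np.arange(1, n + 1),
        "size_px": sizes,
        "size_mm2": area_mm2,
        "perimeter_edges": edges,
        "perimeter_mm": perim_mm,
        "circularity": circ,
    })
    return ParticleStats(
        n_particles=n,
        mean_size_px=float(sizes.mean()),
        mean_size_mm2=float(area_mm2.mean()),
        mean_perimeter_edges=float(edges.mean()),
        mean_perimeter_mm=float(perim_mm.mean()),
        mean_circularity=float(circ.mean()),
        table=table,
    )


def heterogeneity_report(
    image: NormalizedImage,
    threshold_model: ThresholdModel | float,
    roi: ROI | None = None,
    connectivity: int = 8,
    label: str = "",
) -> HeterogeneityReport:
    """Percent-positive and particle statistics for one section."""
    thr = (threshold_model.threshold
           if isinstance(threshold_model, ThresholdModel) else float(threshold_model))
    vals = roi.pixel_values(image) if roi is not None else image.valid_values()
    if vals.size == 0:
        raise ValueError("ROI has no valid pixels")
    n_pos = int((vals > thr).sum())
    return HeterogeneityReport(
        percent_positive=100.0 * n_pos / vals.size,
        threshold=thr,
        n_positive=n_pos,
        n_valid=int(vals.size),
        particles=particle_analysis(image, thr, connectivity),
        label=label,
    )
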