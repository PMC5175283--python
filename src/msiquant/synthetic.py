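"""Phantom MSI sections with ground truth.

The generator emulates the measurement conditions of quantitative
drug-imaging experiments on tumor sections: a 100 x 100 um raster, a drug
channel and a uniformly sprayed deuterated-internal-standard channel, a
spatially smooth multiplicative ion-suppression field that varies within
a section, tumor compartments (viable / necrotic / fibrotic) with
compartment-dependent drug levels, calibration spot series (0.2-15 pmol
per spot), untreated control sections, and serial sections with jittered
compartment boundaries.

Forward model per pixel::

    drug = gain * density * suppression * noise  + background
    istd = istd_nominal   * suppression * noise' + background

with ``density`` the true drug amount per area (pmol/mm^2), ``gain`` the
detector response (counts per pmol/mm^2), lognormal multiplicative
spray/detector noise (intensities stay positive) and additive Gaussian
background truncated at zero.  With zero noise the drug/istd ratio equals
(gain / istd_nominal) * density exactly: the suppression field cancels.

Archetypes mimic qualitative xenograft patterns: ``homogeneous`` (even
drug), ``necrotic_core`` (central drug-free core), ``patchy_vascular``
(drug decaying away from seeded vessel points), ``fibrotic`` (low-drug
lamellae) and ``scant`` (sparse perfused patches).  Compartment geometry
uses seeded blob/lamella primitives: only the macro-scale distribution
drives the downstream metrics, so histological realism is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import CalibrationSpot
from .msi_data import IonImage, SectionStack, make_circular_roi

ARCHETYPES = ("homogeneous", "necrotic_core", "patchy_vascular", "fibrotic",
              "scant")


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom specimen.

    Densities are pmol/mm^2; the defaults put the viable-tissue signal two
    orders of magnitude above background so that detection limits, not
    signal scarcity, set the measured support — matching sections from
    drug-treated animals where the drug channel is clearly detectable.
    """

    shape: tuple[int, int] = (80, 80)
    pixel_size_um: float = 100.0
    archetype: str = "homogeneous"
    # compartment drug levels, pmol/mm^2
    density_viable: float = 8.0
    density_necrotic: float = 0.0
    density_fibrotic: float = 0.0
    # compartment geometry
    necrotic_fraction: float = 0.35
    fibrotic_fraction: float = 0.45
    n_vessels: int = 25
    decay_length_um: float = 400.0
    vessel_support_cutoff: float = 0.15
    # ion-suppression field
    s_min: float = 0.4
    s_max: float = 1.0
    suppression_correlation_px: float = 8.0
    # detector / spray
    gain: float = 50.0
    istd_nominal: float = 100.0
    noise_cv: float = 0.05
    background_mean: float = 0.5
    background_sd: float = 0.15
    # sectioning
    n_sections: int = 1
    section_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not 0 < self.s_min <= self.s_max:
            raise ValueError("need 0 < s_min <= s_max")
        if self.noise_cv < 0 or self.background_sd < 0:
            raise ValueError("noise scales must be >= 0")
        for frac in (self.necrotic_fraction, self.fibrotic_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("compartment fractions must be in [0, 1]")


#: compartment label codes in PhantomTruth.compartments
OUTSIDE, VIABLE, NECROTIC, FIBROTIC = 0, 1, 2, 3


@dataclass
class PhantomTruth:
    """Ground truth for one phantom section."""

    density: np.ndarray            # pmol/mm^2
    compartments: np.ndarray       # OUTSIDE/VIABLE/NECROTIC/FIBROTIC codes
    suppression: np.ndarray
    tissue_mask: np.ndarray
    positive_percent: float        # % of tissue pixels with density > 0
    zone_densities: dict[str, float] | None = None


@dataclass
class PhantomSection:
    drug: IonImage
    istd: IonImage
    truth: PhantomTruth


def sections_to_stack(sections: list[PhantomSection], spacing_um: float = 300.0,
                      group: str = "treated", **kw) -> SectionStack:
    return SectionStack([(s.drug, s.istd) for s in sections],
                        spacing_um=spacing_um, group=group, **kw)


# ---------------------------------------------------------------------------
# Field primitives
# ---------------------------------------------------------------------------

def make_suppression_field(
    shape: tuple[int, int],
    correlation_length: float,
    s_min: float,
    s_max: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth positive field in [s_min, s_max].

    Seeded white noise is low-pass filtered with a Gaussian kernel of
    sigma = ``correlation_length`` (pixels) and min-max rescaled, so the
    output attains s_min and s_max exactly and is deterministic per seed.
    """
    if not 0 < s_min <= s_max:
        raise ValueError("need 0 < s_min <= s_max")
    if not correlation_length > 0:
        raise ValueError("correlation_length must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if s_min == s_max:
        return np.full(shape, float(s_min))
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=correlation_length,
                                     mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        return np.full(shape, 0.5 * (s_min + s_max))
    return s_min + (smooth - lo) * (s_max - s_min) / (hi - lo)


def _smooth_noise(shape, sigma, rng):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                   mode="reflect")


def _tissue_suppression(cfg: "PhantomConfig", tissue: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Suppression field spanning [s_min, s_max] over the tissue pixels.

    The field emulates ion suppression varying *within the section*, so the
    stated bounds are attained on tissue: rescaling over the whole grid
    could leave the section itself on a nearly flat patch of the field.
    """
    field = make_suppression_field(tissue.shape,
                                   cfg.suppression_correlation_px,
                                   cfg.s_min, cfg.s_max, rng=rng)
    if cfg.s_min == cfg.s_max or not tissue.any():
        return field
    lo, hi = field[tissue].min(), field[tissue].max()
    if hi == lo:
        return np.full(tissue.shape, 0.5 * (cfg.s_min + cfg.s_max))
    return cfg.s_min + (field - lo) * (cfg.s_max - cfg.s_min) / (hi - lo)


def _tissue_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Elliptical section outline with a mildly irregular boundary."""
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    y = (rr - (nr - 1) / 2) / (0.44 * nr)
    x = (cc - (nc - 1) / 2) / (0.44 * nc)
    radius = np.sqrt(x**2 + y**2)
    wobble = 0.06 * _smooth_noise(shape, max(2.0, min(nr, nc) / 10), rng)
    return radius + wobble <= 1.0


def _distorted_radius(shape, rng, jitter_sigma=4.0, jitter_amp=0.18):
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    y = (rr - (nr - 1) / 2) / (0.5 * nr)
    x = (cc - (nc - 1) / 2) / (0.5 * nc)
    r = np.sqrt(x**2 + y**2)
    return r + jitter_amp * _smooth_noise(shape, jitter_sigma, rng)


def _fraction_blob(field: np.ndarray, tissue: np.ndarray, fraction: float,
                   low_side: bool = True) -> np.ndarray:
    """Tissue subset of the given area fraction, taken from one tail of a field."""
    if fraction <= 0:
        return np.zeros_like(tissue)
    q = fraction if low_side else 1.0 - fraction
    cut = np.quantile(field[tissue], q)
    sel = (field <= cut) if low_side else (field >= cut)
    return sel & tissue


# ---------------------------------------------------------------------------
# Compartments and densities per archetype
# ---------------------------------------------------------------------------

def _compartments(cfg: PhantomConfig, tissue: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (density map pmol/mm^2, compartment label map)."""
    labels = np.where(tissue, VIABLE, OUTSIDE)
    density = np.where(tissue, cfg.density_viable, 0.0)
    shape = tissue.shape

    if cfg.archetype == "homogeneous":
        pass

    elif cfg.archetype == "necrotic_core":
        core = _fraction_blob(_distorted_radius(shape, rng), tissue,
                              cfg.necrotic_fraction, low_side=True)
        labels[core] = NECROTIC
        density[core] = cfg.density_necrotic

    elif cfg.archetype == "fibrotic":
        # lamellae: thresholded warped sinusoid gives low-drug bands
        nr, nc = shape
        rr, cc = np.mgrid[0:nr, 0:nc]
        theta = rng.uniform(0, np.pi)
        period = max(6.0, min(nr, nc) / 5)
        warp = 2.5 * _smooth_noise(shape, 6.0, rng)
        phase = 2 * np.pi * ((rr * np.cos(theta) + cc * np.sin(theta)) / period)
        bands = np.sin(phase + warp)
        fib = _fraction_blob(bands, tissue, cfg.fibrotic_fraction, low_side=False)
        labels[fib] = FIBROTIC
        density[fib] = cfg.density_fibrotic

    elif cfg.archetype in ("patchy_vascular", "scant"):
        n_vessels = cfg.n_vessels if cfg.archetype == "patchy_vascular" else max(
            3, cfg.n_vessels // 5)
        decay_px = cfg.decay_length_um / cfg.pixel_size_um
        if cfg.archetype == "scant":
            decay_px *= 0.7
        coords = np.argwhere(tissue)
        idx = rng.choice(coords.shape[0], size=min(n_vessels, coords.shape[0]),
                         replace=False)
        vessel = np.zeros(shape, dtype=bool)
        vessel[tuple(coords[idx].T)] = True
        dist_px = ndimage.distance_transform_edt(~vessel)
        penetration = np.exp(-dist_px / decay_px)
        penetration[penetration < cfg.vessel_support_cutoff] = 0.0
        density = np.where(tissue, cfg.density_viable * penetration, 0.0)
        labels = np.where(tissue, np.where(density > 0, VIABLE, NECROTIC),
                          OUTSIDE)

    return density, labels


# ---------------------------------------------------------------------------
# Section rendering
# ---------------------------------------------------------------------------

def _render_channels(
    cfg: PhantomConfig, density: np.ndarray, tissue: np.ndarray,
    suppression: np.ndarray, rng: np.random.Generator, label: str,
) -> tuple[IonImage, IonImage]:
    def observe(signal: np.ndarray) -> np.ndarray:
        noise = (np.exp(rng.normal(0.0, cfg.noise_cv, signal.shape))
                 if cfg.noise_cv > 0 else 1.0)
        bg = (np.clip(rng.normal(cfg.background_mean, cfg.background_sd,
                                 signal.shape), 0, None)
              if cfg.background_sd > 0 else cfg.background_mean)
        return signal * suppression * noise + bg

    drug_vals = observe(cfg.gain * density)
    istd_vals = observe(np.full(density.shape, cfg.istd_nominal))
    drug = IonImage(np.where(tissue, drug_vals, 0.0), tissue.copy(),
                    cfg.pixel_size_um, target_mz=284.2, mz_tolerance=0.25,
                    label=f"{label}:drug")
    istd = IonImage(np.where(tissue, istd_vals, 0.0), tissue.copy(),
                    cfg.pixel_size_um, target_mz=289.2, mz_tolerance=0.25,
                    label=f"{label}:istd")
    return drug, istd


def make_phantom(config: PhantomConfig) -> list[PhantomSection]:
    """Generate ``config.n_sections`` serial phantom sections with truth.

    Serial sections re-draw the compartment boundaries with a jittered
    geometry stream (scaled by ``section_jitter``), emulating non-adjacent
    sections ~300 um apart; noise and suppression are redrawn per section.
    Fully deterministic for a fixed config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    geom_seeds = ss.spawn(config.n_sections)
    noise_seeds = ss.spawn(config.n_sections)
    sections = []
    for i in range(config.n_sections):
        # section_jitter == 0 freezes the compartment geometry across sections;
        # otherwise each section re-draws boundaries from its own stream
        geom_rng = np.random.default_rng(
            geom_seeds[i if config.section_jitter > 0 else 0])
        noise_rng = np.random.default_rng(noise_seeds[i])
        tissue = _tissue_mask(config.shape, geom_rng)
        density, labels = _compartments(config, tissue, geom_rng)
        supp = _tissue_suppression(config, tissue, geom_rng)
        drug, istd = _render_channels(config, density, tissue, supp, noise_rng,
                                      label=f"{config.archetype}/s{i}")
        truth = PhantomTruth(
            density=density, compartments=labels, suppression=supp,
            tissue_mask=tissue,
            positive_percent=100.0 * float((density[tissue] > 0).mean()),
        )
        sections.append(PhantomSection(drug, istd, truth))
    return sections


def make_zoned_phantom(
    shape: tuple[int, int] = (80, 80),
    densities: tuple[float, float, float] = (9.52, 4.555, 2.0),
    fractions: tuple[float, float] = (0.22, 0.38),
    seed: int = 0,
    **config_overrides,
) -> PhantomSection:
    """Phantom with a designed three-level drug contrast (high/mid/low).

    Concentric compartments (high core, mid ring, low periphery) carry the
    given densities; ``fractions`` are the tissue-area fractions of the
    high core and mid ring.  The default densities put the high zone 4.76x
    above the low zone and 2.09x above the mid zone, the intra-tumor
    contrast scale reported for paclitaxel in poorly perfused xenografts.
    """
    cfg = PhantomConfig(shape=shape, seed=seed, archetype="homogeneous",
                        **config_overrides)
    d_high, d_mid, d_low = densities
    f_high, f_mid = fractions
    child = np.random.SeedSequence(seed).spawn(1)[0]
    geom_rng, noise_rng = (np.random.default_rng(s) for s in child.spawn(2))
    tissue = _tissue_mask(shape, geom_rng)
    radius = _distorted_radius(shape, geom_rng)
    core = _fraction_blob(radius, tissue, f_high, low_side=True)
    ring = _fraction_blob(radius, tissue, f_high + f_mid, low_side=True) & ~core
    density = np.where(tissue, d_low, 0.0)
    density[ring] = d_mid
    density[core] = d_high
    labels = np.where(tissue, VIABLE, OUTSIDE)
    supp = _tissue_suppression(cfg, tissue, geom_rng)
    drug, istd = _render_channels(cfg, density, tissue, supp, noise_rng,
                                  label="zoned/s0")
    truth = PhantomTruth(
        density=density, compartments=labels, suppression=supp,
        tissue_mask=tissue,
        positive_percent=100.0 * float((density[tissue] > 0).mean()),
        zone_densities={"high": d_high, "mid": d_mid, "low": d_low},
    )
    return PhantomSection(drug, istd, truth)


# ---------------------------------------------------------------------------
# Calibration and control sections
# ---------------------------------------------------------------------------

DEFAULT_CAL_AMOUNTS = (0.2, 0.5, 1.5, 5.0, 10.0, 15.0)


def make_calibration_section(
    amounts_pmol: tuple[float, ...] = DEFAULT_CAL_AMOUNTS,
    spot_pixels: int = 25,
    spacing_px: int = 16,
    pixel_size_um: float = 100.0,
    s_min: float = 0.4,
    s_max: float = 1.0,
    gain: float = 50.0,
    istd_nominal: float = 100.0,
    noise_cv: float = 0.01,
    background_mean: float = 0.1,
    background_sd: float = 0.03,
    seed: int = 0,
) -> tuple[IonImage, IonImage, list[CalibrationSpot]]:
    """Control-tissue section with a dilution series of drug spots.

    Spots are laid out on a grid, each a circular ROI of ``spot_pixels``
    pixels; every spot receives its own ion-suppression factor drawn
    uniformly from [s_min, s_max], shared by both channels (the scenario
    in which internal-standard normalization rescues calibration
    linearity).  Drug signal per spot pixel = gain x (amount / spot area)
    x suppression x noise + background.
    """
    if len(set(amounts_pmol)) != len(amounts_pmol) or any(
            a <= 0 for a in amounts_pmol):
        raise ValueError("amounts must be distinct and positive")
    rng = np.random.default_rng(seed)
    n = len(amounts_pmol)
    ncols = min(3, n)
    nrows = int(np.ceil(n / ncols))
    shape = (nrows * spacing_px + spacing_px // 2,
             ncols * spacing_px + spacing_px // 2)

    centres = [((i // ncols) * spacing_px + spacing_px // 2 + spacing_px // 4,
                (i % ncols) * spacing_px + spacing_px // 2 + spacing_px // 4)
               for i in range(n)]
    rois = [make_circular_roi(c, spot_pixels, shape) for c in centres]
    taken: set[tuple[int, int]] = set()
    for roi in rois:
        if taken & set(roi.coords):
            raise ValueError("calibration spots overlap; increase spacing_px")
        taken |= set(roi.coords)

    spot_suppression = rng.uniform(s_min, s_max, size=n)
    supp = np.full(shape, 0.5 * (s_min + s_max))
    signal = np.zeros(shape)
    area_mm2 = spot_pixels * (pixel_size_um / 1000.0) ** 2
    for roi, amount, s in zip(rois, amounts_pmol, spot_suppression):
        rr, cc = roi.indices()
        supp[rr, cc] = s
        signal[rr, cc] = gain * (amount / area_mm2)

    def observe(sig):
        noise = (np.exp(rng.normal(0.0, noise_cv, shape)) if noise_cv > 0 else 1.0)
        bg = (np.clip(rng.normal(background_mean, background_sd, shape), 0, None)
              if background_sd > 0 else background_mean)
        return sig * supp * noise + bg

    drug = IonImage(observe(signal), None, pixel_size_um, target_mz=284.2,
                    mz_tolerance=0.25, label="calibration:drug")
    istd = IonImage(observe(np.full(shape, istd_nominal)), None, pixel_size_um,
                    target_mz=289.2, mz_tolerance=0.25, label="calibration:istd")
    spots = [CalibrationSpot(roi, amount)
             for roi, amount in zip(rois, amounts_pmol)]
    return drug, istd, spots


def make_control_section(
    shape: tuple[int, int] = (80, 80),
    background_mean: float = 0.5,
    background_sd: float = 0.15,
    istd_nominal: float = 100.0,
    s_min: float = 0.4,
    s_max: float = 1.0,
    suppression_correlation_px: float = 8.0,
    noise_cv: float = 0.05,
    pixel_size_um: float = 100.0,
    seed: int = 0,
) -> tuple[IonImage, IonImage]:
    """Untreated-control section: drug channel carries background noise only."""
    rng = np.random.default_rng(seed)
    supp = make_suppression_field(shape, suppression_correlation_px, s_min,
                                  s_max, rng=rng)
    bg = (np.clip(rng.normal(background_mean, background_sd, shape), 0, None)
          if background_sd > 0 else np.full(shape, float(background_mean)))
    drug = IonImage(bg, None, pixel_size_um, target_mz=284.2,
                    mz_tolerance=0.25, label="control:drug")
    noise = (np.exp(rng.normal(0.0, noise_cv, shape)) if noise_cv > 0 else 1.0)
    bg2 = (np.clip(rng.normal(background_mean, background_sd, shape), 0, None)
           if background_sd > 0 else background_mean)
    istd = IonImage(istd_nominal * supp * noise + bg2, None, pixel_size_um,
                    target_mz=289.2, mz_tolerance=0.25, label="control:istd")
    return drug, istd


# ---------------------------------------------------------------------------
# Optional spectral mode
# ---------------------------------------------------------------------------

def images_to_spectra(
    drug: IonImage, istd: IonImage,
    mz_drug: float = 284.2, mz_istd: float = 289.2,
    mz_range: tuple[float, float] = (250.0, 300.0),
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Render an image pair as per-pixel two-peak spectra.

    Each valid pixel gets a spectrum with peaks at the drug and internal
    standard m/z plus zero-intensity anchor points at the acquisition
    range ends, for exercising ion-image extraction and imzML round-trips.
    """
    if drug.shape != istd.shape:
        raise ValueError("channel shapes differ")
    lo, hi = mz_range
    spectra = {}
    for r, c in zip(*np.nonzero(drug.mask & istd.mask)):
        mzs = np.array([lo, mz_drug, mz_istd, hi])
        ints = np.array([0.0, drug.values[r, c], istd.values[r, c], 0.0])
        spectra[(int(r), int(c))] = (mzs, ints)
    return spectra
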