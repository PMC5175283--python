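"""Core data model for MSI ion images, ROIs and section stacks.

An *ion image* is the 2-D map obtained by summing, at every raster pixel,
the spectral intensity falling inside a closed m/z window around a target
ion (e.g. the paclitaxel side-chain fragment at m/z 284.2, or the sprayed
deuterated internal standard d5-PTX at m/z 289.2).  Pixels are squares;
the default raster is 100 x 100 um.  Grids are 0-based (row, col) with
row 0 at the top.

Readers/writers cover imzML 1.1 (+ ibd binary, via pyimzML) and a plain
CSV grid dialect: one numeric cell per pixel, ``NA`` marking a masked
pixel, and ``#key=value`` header lines for metadata.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_PIXEL_SIZE_UM = 100.0
#: default half-width of the m/z extraction window, in Da
DEFAULT_MZ_TOL = 0.25

_IMS_NS = "{http://psi.hupo.org/ms/mzml}"


class MSIFormatError(ValueError):
    """A file did not parse under the named standard (imzML/ibd or CSV grid)."""


class ROIError(ValueError):
    """An ROI definition is empty, out of bounds, or infeasible."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IonImage:
    """Rectangular per-pixel intensity grid for one extracted m/z channel.

    Parameters
    ----------
    values
        2-D float array of non-negative intensities (ion-count units).
    mask
        2-D boolean array, ``True`` marking valid (tissue) pixels.
    pixel_size_um
        Physical edge of one square pixel, in micrometres.
    target_mz, mz_tolerance
        Centre and half-width (Da) of the extraction window, if known.
    label
        Free-text provenance (tissue, section index, channel).
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    target_mz: float | None = None
    mz_tolerance: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("valid pixel intensities must be finite")
        if (self.values[self.mask] < 0).any():
            raise ValueError("valid pixel intensities must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.mz_tolerance is not None and not self.mz_tolerance > 0:
            raise ValueError("mz_tolerance must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    def valid_values(self) -> np.ndarray:
        """Intensities of valid pixels, as a flat array."""
        return self.values[self.mask]

    def copy(self) -> "IonImage":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class ROI:
    """A region of interest: an explicit set of (row, col) pixel coordinates."""

    coords: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        coords = tuple((int(r), int(c)) for r, c in self.coords)
        if not coords:
            raise ROIError("ROI must contain at least one pixel")
        if len(set(coords)) != len(coords):
            raise ROIError("ROI contains duplicate pixels")
        self.coords = coords

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def area_mm2(self, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
        """Physical area = pixel count x pixel area."""
        return self.n_pixels * (pixel_size_um / 1000.0) ** 2

    def check_inside(self, grid_shape: tuple[int, int]) -> None:
        nr, nc = grid_shape
        for r, c in self.coords:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ROIError(f"ROI pixel ({r}, {c}) outside grid {grid_shape}")

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays usable for fancy indexing."""
        rows = np.fromiter((r for r, _ in self.coords), dtype=int)
        cols = np.fromiter((c for _, c in self.coords), dtype=int)
        return rows, cols

    def pixel_values(self, image) -> np.ndarray:
        """Valid-pixel values of ``image`` inside this ROI."""
        self.check_inside(image.shape)
        rows, cols = self.indices()
        sel = image.mask[rows, cols]
        return image.values[rows, cols][sel]

    def to_json(self) -> dict:
        return {"kind": "pixels", "coords": [list(rc) for rc in self.coords]}


@dataclass
class SectionStack:
    """Ordered serial sections of one specimen: (drug, internal standard) pairs."""

    sections: list[tuple[IonImage, IonImage]]
    spacing_um: float = 300.0
    subject_id: str = ""
    organ: str = ""
    group: str = "treated"

    def __post_init__(self) -> None:
        if self.group not in ("treated", "control"):
            raise ValueError("group must be 'treated' or 'control'")
        if self.spacing_um < 0:
            raise ValueError("spacing_um must be >= 0")
        sizes = {
            img.pixel_size_um for pair in self.sections for img in pair
        }
        if len(sizes) > 1:
            raise ValueError("all sections must share pixel_size_um")

    def __len__(self) -> int:
        return len(self.sections)


# ---------------------------------------------------------------------------
# Ion-image extraction from spectra
# ---------------------------------------------------------------------------

def extract_ion_image(
    spectra_source: Mapping[tuple[int, int], tuple[Sequence[float], Sequence[float]]]
    | Iterable[tuple[tuple[int, int], Sequence[float], Sequence[float]]],
    mz: float,
    tol: float = DEFAULT_MZ_TOL,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    label: str = "",
    acquired_mz_range: tuple[float, float] | None = None,
) -> IonImage:
    """Extract an ion image by summing intensity in the closed window [mz-tol, mz+tol].

    ``spectra_source`` maps (row, col) coordinates to (mz_array, intensity_array)
    pairs, or is an iterable of ``(coord, mzs, intensities)`` triples.  The grid
    spans the coordinate bounding box; pixels without a spectrum are masked.

    When ``acquired_mz_range`` is given (e.g. the instrument's m/z 250-300),
    the window must lie inside it.  Otherwise the range is inferred from the
    observed peaks, which only bound it from inside, so the window is merely
    required to overlap the inferred span.

    Raises
    ------
    ValueError
        If the window falls outside the acquired m/z range, or coordinates
        are duplicated.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if isinstance(spectra_source, Mapping):
        items = [(coord, *spec) for coord, spec in spectra_source.items()]
    else:
        items = [(coord, mzs, ints) for coord, mzs, ints in spectra_source]
    if not items:
        raise ValueError("spectra_source is empty")
    coords = [c for c, _, _ in items]
    if len(set(coords)) != len(coords):
        raise ValueError("duplicate pixel coordinates in spectra_source")

    if acquired_mz_range is not None:
        mz_lo, mz_hi = acquired_mz_range
        if mz - tol < mz_lo or mz + tol > mz_hi:
            raise ValueError(
                f"extraction window [{mz - tol:g}, {mz + tol:g}] outside "
                f"acquired m/z range [{mz_lo:g}, {mz_hi:g}]"
            )
    else:
        mz_lo, mz_hi = np.inf, -np.inf
        for _, mzs, _ in items:
            mzs = np.asarray(mzs, dtype=float)
            if mzs.size:
                mz_lo = min(mz_lo, float(mzs.min()))
                mz_hi = max(mz_hi, float(mzs.max()))
        if mz + tol < mz_lo or mz - tol > mz_hi:
            raise ValueError(
                f"extraction window [{mz - tol:g}, {mz + tol:g}] outside "
                f"acquired m/z range [{mz_lo:g}, {mz_hi:g}]"
            )

    rows = [r for (r, _c) in coords]
    cols = [c for (_r, c) in coords]
    r0, c0 = min(rows), min(cols)
    shape = (max(rows) - r0 + 1, max(cols) - c0 + 1)
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for (r, c), mzs, ints in items:
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        inwin = (mzs >= mz - tol) & (mzs <= mz + tol)
        values[r - r0, c - c0] = float(ints[inwin].sum())
        mask[r - r0, c - c0] = True
    return IonImage(values, mask, pixel_size_um, target_mz=mz, mz_tolerance=tol,
                    label=label)


# ---------------------------------------------------------------------------
# Circular ROIs
# ---------------------------------------------------------------------------

def make_circular_roi(
    center: tuple[int, int], n_pixels: int, grid_shape: tuple[int, int]
) -> ROI:
    """The ``n_pixels`` grid pixels nearest to ``center`` (Euclidean, pixel centres).

    Ties are broken by (row, col) lexicographic order, so the result is
    deterministic and has exactly ``n_pixels`` members.  This realizes the
    "circular ROI of N pixels" construction exactly, which a rasterized
    radius cannot.
    """
    if n_pixels < 1:
        raise ROIError("n_pixels must be >= 1")
    nr, nc = grid_shape
    r0, c0 = int(center[0]), int(center[1])
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ROIError(f"center {center} outside grid {grid_shape}")
    if n_pixels > nr * nc:
        raise ROIError(f"grid {grid_shape} has fewer than {n_pixels} pixels")
    rr, cc = np.mgrid[0:nr, 0:nc]
    rr = rr.ravel()
    cc = cc.ravel()
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    order = np.lexsort((cc, rr, d2))[:n_pixels]
    return ROI(tuple(zip(rr[order].tolist(), cc[order].tolist())))


def whole_image_roi(image: IonImage) -> ROI:
    """ROI covering every valid pixel of ``image``."""
    rows, cols = np.nonzero(image.mask)
    if rows.size == 0:
        raise ROIError("image has no valid pixels")
    return ROI(tuple(zip(rows.tolist(), cols.tolist())))


def roi_from_json(spec: dict | str, grid_shape: tuple[int, int]) -> ROI:
    """Resolve an ROI JSON spec (circle or explicit pixels) on a grid."""
    if isinstance(spec, str):
        spec = json.loads(spec)
    kind = spec.get("kind")
    if kind == "circle":
        return make_circular_roi(tuple(spec["center"]), int(spec["n_pixels"]),
                                 grid_shape)
    if kind == "pixels":
        roi = ROI(tuple((r, c) for r, c in spec["coords"]))
        roi.check_inside(grid_shape)
        return roi
    raise ROIError(f"unknown ROI kind {kind!r}")


# ---------------------------------------------------------------------------
# Grid I/O: CSV dialect and imzML
# ---------------------------------------------------------------------------

def write_grid(image: IonImage, path: str | Path, format: str | None = None) -> Path:
    """Write an ion image as a CSV grid or as imzML (+ ibd).

    Round-trips with :func:`read_grid` losslessly for values, mask,
    pixel size and target m/z (imzML crops fully-masked border rows/columns,
    since absent pixels are simply not written).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv_grid":
        _write_csv_grid(image, path)
    elif fmt == "imzml":
        _write_imzml(image, path)
    else:
        raise MSIFormatError(f"unknown format {fmt!r}")
    return path


def read_grid(
    path: str | Path,
    format: str | None = None,
    mz: float | None = None,
    tol: float | None = None,
) -> IonImage:
    """Read an ion image written by :func:`write_grid`, or any imzML file.

    For imzML input with full spectra, ``mz`` and ``tol`` select the
    extraction window; for single-peak-per-pixel files (as written by
    :func:`write_grid`) they are inferred.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv_grid":
        return _read_csv_grid(path)
    if fmt == "imzml":
        return _read_imzml(path, mz=mz, tol=tol)
    raise MSIFormatError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv_grid"
    if suffix == ".imzml":
        return "imzml"
    raise MSIFormatError(f"cannot infer format from suffix {suffix!r}")


def _write_csv_grid(image: IonImage, path: Path) -> None:
    lines = [f"#pixel_size_um={image.pixel_size_um!r}"]
    if image.target_mz is not None:
        lines.append(f"#target_mz={image.target_mz!r}")
    if image.mz_tolerance is not None:
        lines.append(f"#mz_tolerance={image.mz_tolerance!r}")
    if image.label:
        lines.append(f"#label={image.label}")
    for r in range(image.shape[0]):
        cells = [
            repr(float(image.values[r, c])) if image.mask[r, c] else "NA"
            for c in range(image.shape[1])
        ]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")


def _read_csv_grid(path: Path) -> IonImage:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise MSIFormatError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
        else:
            rows.append([cell.strip() for cell in line.split(",")])
    if not rows:
        raise MSIFormatError(f"{path}: no data rows")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise MSIFormatError(f"{path}: ragged CSV rows (expected {ncols} columns)")
    values = np.zeros((len(rows), ncols))
    mask = np.zeros((len(rows), ncols), dtype=bool)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell.upper() == "NA":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise MSIFormatError(
                    f"{path}: row {i + 1}, column {j + 1}: bad cell {cell!r}"
                ) from exc
            mask[i, j] = True
    return IonImage(
        values,
        mask,
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        target_mz=float(meta["target_mz"]) if "target_mz" in meta else None,
        mz_tolerance=float(meta["mz_tolerance"]) if "mz_tolerance" in meta else None,
        label=meta.get("label", ""),
    )


def _write_imzml(image: IonImage, path: Path) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    if image.target_mz is None:
        raise MSIFormatError("imzML output requires target_mz to be set")
    mz = float(image.target_mz)
    with ImzMLWriter(
        str(path), mode="processed", intensity_dtype=np.float64
    ) as writer:
        for r, c in zip(*np.nonzero(image.mask)):
            # imzML coordinates are 1-based (x, y) = (col+1, row+1)
            writer.addSpectrum([mz], [float(image.values[r, c])],
                               (int(c) + 1, int(r) + 1))
    # pyimzML forces a '.imzML' suffix; honour the path the caller asked for
    written = path.with_suffix(".imzML")
    if written != path and written.exists():
        written.rename(path)
    _inject_imzml_metadata(path, image)


def _inject_imzml_metadata(path: Path, image: IonImage) -> None:
    """Add pixel size cvParams (IMS:1000046/47) and window userParams.

    pyimzML's writer does not emit pixel size; the imzML controlled
    vocabulary defines it in scanSettings, where ImzMLParser reads it back.
    """
    ET.register_namespace("", _IMS_NS.strip("{}"))
    tree = ET.parse(path)
    scan = tree.getroot().find(f"{_IMS_NS}scanSettingsList/{_IMS_NS}scanSettings")
    if scan is None:
        raise MSIFormatError(f"{path}: no scanSettings element")
    for accession, name in (("IMS:1000046", "pixel size (x)"),
                            ("IMS:1000047", "pixel size y")):
        ET.SubElement(scan, f"{_IMS_NS}cvParam", {
            "cvRef": "IMS", "accession": accession, "name": name,
            "value": repr(float(image.pixel_size_um)),
        })
    if image.mz_tolerance is not None:
        ET.SubElement(scan, f"{_IMS_NS}userParam", {
            "name": "mz_tolerance", "value": repr(float(image.mz_tolerance))})
    if image.label:
        ET.SubElement(scan, f"{_IMS_NS}userParam",
                      {"name": "label", "value": image.label})
    tree.write(path, xml_declaration=True, encoding="utf-8")


def _read_imzml(path: Path, mz: float | None, tol: float | None) -> IonImage:
    from pyimzml.ImzMLParser import ImzMLParser

    if not path.exists():
        raise MSIFormatError(f"{path}: no such file")
    try:
        parser = ImzMLParser(str(path))
        spectra = {}
        for i, (x, y, *_z) in enumerate(parser.coordinates):
            coord = (int(y) - 1, int(x) - 1)
            if coord in spectra:
                raise MSIFormatError(f"{path}: duplicate coordinate {coord}")
            mzs, ints = parser.getspectrum(i)
            spectra[coord] = (np.asarray(mzs, dtype=float),
                              np.asarray(ints, dtype=float))
    except MSIFormatError:
        raise
    except Exception as exc:
        raise MSIFormatError(f"{path}: malformed imzML/ibd: {exc}") from exc
    if not spectra:
        raise MSIFormatError(f"{path}: file contains no spectra")

    pixel_size = parser.imzmldict.get("pixel size x", DEFAULT_PIXEL_SIZE_UM)
    user = _read_imzml_userparams(path)
    if tol is None and "mz_tolerance" in user:
        tol = float(user["mz_tolerance"])
    if mz is None:
        all_mz = np.unique(np.concatenate([s[0] for s in spectra.values()]))
        if all_mz.size != 1:
            raise MSIFormatError(
                f"{path}: multiple m/z values present; pass mz= and tol= to "
                "select an extraction window"
            )
        mz = float(all_mz[0])
    if tol is None:
        tol = DEFAULT_MZ_TOL
    # closed-window sum per pixel; grid spans the coordinate bounding box
    values_by_coord = {}
    for coord, (mzs, ints) in spectra.items():
        inwin = (mzs >= mz - tol) & (mzs <= mz + tol)
        values_by_coord[coord] = float(ints[inwin].sum())
    rows = [r for r, _ in values_by_coord]
    cols = [c for _, c in values_by_coord]
    r0, c0 = min(rows), min(cols)
    shape = (max(rows) - r0 + 1, max(cols) - c0 + 1)
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for (r, c), v in values_by_coord.items():
        values[r - r0, c - c0] = v
        mask[r - r0, c - c0] = True
    return IonImage(values, mask, pixel_size_um=float(pixel_size),
                    target_mz=mz, mz_tolerance=tol, label=user.get("label", ""))


def _read_imzml_userparams(path: Path) -> dict[str, str]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MSIFormatError(f"{path}: malformed imzML XML: {exc}") from exc
    out = {}
    scan = tree.getroot().find(f"{_IMS_NS}scanSettingsList/{_IMS_NS}scanSettings")
    if scan is not None:
        for up in scan.findall(f"{_IMS_NS}userParam"):
            out[up.get("name")] = up.get("value")
    return out
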