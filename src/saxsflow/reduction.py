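"""Detector-frame reduction: geometry, masking, background subtraction, integration.

The geometry model is a flat detector mounted orthogonal to the incident
beam.  Each pixel is mapped to the in-plane radius ``r`` from the beam
center, the scattering angle ``2theta = atan(r / D)``, the scattering vector
magnitude ``q = (4 pi / lambda) sin(theta)`` and the azimuth ``chi``
measured counter-clockwise (on screen) from the +column axis.  Detector
tilt and geometric distortion are out of scope.

Units: wavelength in angstrom, distances in mm, q in inverse angstrom,
angles in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GeometryCalibration",
    "MaskImage",
    "Curve",
    "CakePattern",
    "load_calibration",
    "pixel_map",
    "threshold_mask",
    "combine_masks",
    "subtract_background",
    "azimuthal_integrate",
    "radial_integrate",
    "integrate_2d",
]


@dataclass(frozen=True)
class GeometryCalibration:
    """Beam/detector geometry.

    Attributes
    ----------
    wavelength : float
        X-ray wavelength in angstrom.
    distance : float
        Sample-to-detector distance along the beam, mm.
    center_row, center_col : float
        Beam center in pixel coordinates (row 0 at top).
    pixel_size_row, pixel_size_col : float
        Pixel pitch in mm.
    """

    wavelength: float
    distance: float
    center_row: float
    center_col: float
    pixel_size_row: float
    pixel_size_col: float

    def __post_init__(self) -> None:
        for name in ("wavelength", "distance", "pixel_size_row", "pixel_size_col"):
            if getattr(self, name) <= 0:
                raise ValueError(f"calibration field {name!r} must be positive")
        if not (0.1 <= self.wavelength <= 10.0):
            warnings.warn(
                f"wavelength {self.wavelength} A outside the usual X-ray band "
                "(0.1-10 A); check units",
                stacklevel=2,
            )

    def as_dict(self) -> dict:
        return {
            "wavelength": self.wavelength,
            "distance": self.distance,
            "center_row": self.center_row,
            "center_col": self.center_col,
            "pixel_size_row": self.pixel_size_row,
            "pixel_size_col": self.pixel_size_col,
        }


@dataclass
class MaskImage:
    """Pixel exclusion map.  Nonzero/True means the pixel is EXCLUDED."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_excluded(self) -> int:
        return int(self.mask.sum())


#: recognised abscissa kinds for 1-D profiles
XKINDS = ("q", "two_theta", "distance", "azimuth")


@dataclass
class Curve:
    """A 1-D profile: abscissa, intensity, optional uncertainty."""

    x: np.ndarray
    y: np.ndarray
    yerr: Optional[np.ndarray] = None
    xkind: str = "q"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.yerr is not None:
            self.yerr = np.asarray(self.yerr, dtype=float)
            if self.yerr.shape != self.x.shape:
                raise ValueError("yerr length must match x")
            if np.any(self.yerr < 0):
                raise ValueError("yerr must be nonnegative")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("curve abscissa must be strictly increasing")
        if self.xkind not in XKINDS:
            raise ValueError(f"unknown xkind {self.xkind!r}; expected one of {XKINDS}")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class CakePattern:
    """Azimuthally regrouped 2-D pattern on an (azimuth, q) grid."""

    grid: np.ndarray            # (n_chi, n_q); NaN marks empty cells
    q_axis: np.ndarray          # q bin centers
    chi_axis: np.ndarray        # chi bin centers, deg
    counts: np.ndarray = None   # pixels per cell

    def __post_init__(self) -> None:
        if self.grid.shape != (len(self.chi_axis), len(self.q_axis)):
            raise ValueError("cake grid dimensions must match axes")


# -- calibration files -------------------------------------------------------

_PONI_KEYS = {"wavelength", "distance", "poni1", "poni2", "pixelsize1", "pixelsize2"}


def load_calibration(path) -> GeometryCalibration:
    """Parse a key/value calibration text file.

    Two dialects are accepted:

    * PONI-style (the convention popularised by azimuthal-integration
      software): ``Wavelength`` (m), ``Distance`` (m), ``Poni1``/``Poni2``
      (m, beam intersection along the row/column axes), ``PixelSize1``/
      ``PixelSize2`` (m).  All values are converted to this package's units
      (angstrom / mm).
    * native: ``wavelength_A``, ``distance_mm``, ``center_row``,
      ``center_col``, ``pixel_size_row_mm``, ``pixel_size_col_mm``.

    Lines starting with ``#`` and blank lines are ignored; keys are
    case-insensitive and may be separated from values by ``:`` or ``=``.
    """
    kv: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for sep in (":", "="):
                if sep in line:
                    key, _, val = line.partition(sep)
                    try:
                        kv[key.strip().lower()] = float(val.strip())
                    except ValueError:
                        pass  # non-numeric entries (detector name, ...) are ignored
                    break
    native = {"wavelength_a", "distance_mm", "center_row", "center_col"}
    if native <= set(kv):
        return GeometryCalibration(
            wavelength=_require(kv, path, "wavelength_a"),
            distance=_require(kv, path, "distance_mm"),
            center_row=_require(kv, path, "center_row"),
            center_col=_require(kv, path, "center_col"),
            pixel_size_row=_require(kv, path, "pixel_size_row_mm"),
            pixel_size_col=_require(kv, path, "pixel_size_col_mm"),
        )
    # PONI dialect, SI units
    pix1 = _require(kv, path, "pixelsize1") * 1e3   # m -> mm, row pitch
    pix2 = _require(kv, path, "pixelsize2") * 1e3
    return GeometryCalibration(
        wavelength=_require(kv, path, "wavelength") * 1e10,   # m -> A
        distance=_require(kv, path, "distance") * 1e3,        # m -> mm
        center_row=_require(kv, path, "poni1") * 1e3 / pix1,  # m -> pixel
        center_col=_require(kv, path, "poni2") * 1e3 / pix2,
        pixel_size_row=pix1,
        pixel_size_col=pix2,
    )


def _require(kv: dict, path, key: str) -> float:
    if key not in kv:
        raise KeyError(f"calibration file {path}: missing required key {key!r}")
    if kv[key] <= 0:
        raise ValueError(f"calibration file {path}: key {key!r} must be positive")
    return kv[key]


# -- pixel coordinate maps ---------------------------------------------------

def pixel_map(cal: GeometryCalibration, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Per-pixel geometry arrays for a detector of the given shape.

    Returns a dict with keys ``r`` (mm, in-plane distance from beam
    center), ``two_theta`` (deg), ``q`` (1/A) and ``chi`` (deg in
    [0, 360), measured from the +column axis toward the -row axis, i.e.
    counter-clockwise on screen).
    """
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    dy = (rows - cal.center_row) * cal.pixel_size_row     # +down, mm
    dx = (cols - cal.center_col) * cal.pixel_size_col     # +right, mm
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, cal.distance)               # rad
    q = (4.0 * np.pi / cal.wavelength) * np.sin(two_theta / 2.0)
    chi = np.degrees(np.arctan2(-dy, dx)) % 360.0
    return {"r": r, "two_theta": np.degrees(two_theta), "q": q, "chi": chi}


# -- masking -----------------------------------------------------------------

def threshold_mask(frame: np.ndarray, lower: float, upper: float) -> MaskImage:
    """Exclude pixels whose value lies strictly outside [lower, upper]."""
    if lower > upper:
        raise ValueError(f"threshold lower bound {lower} exceeds upper bound {upper}")
    frame = np.asarray(frame)
    return MaskImage((frame < lower) | (frame > upper))


def combine_masks(*masks: Optional[MaskImage]) -> Optional[MaskImage]:
    """Union of exclusions across any number of masks (None entries skipped)."""
    arrays = [m.mask for m in masks if m is not None]
    if not arrays:
        return None
    out = arrays[0].copy()
    for a in arrays[1:]:
        if a.shape != out.shape:
            raise ValueError("cannot combine masks of different shapes")
        out |= a
    return MaskImage(out)


# -- background subtraction --------------------------------------------------

def subtract_background(
    sample: np.ndarray,
    background: np.ndarray,
    t_sample: float = 1.0,
    t_background: float = 1.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Transmission-corrected background subtraction.

    ``corrected = sample / t_sample - scale * background / t_background``.
    Transmissions are beam transmission factors in (0, 1]; negative results
    are retained (no clipping) so downstream statistics stay unbiased.
    """
    if not (0 < t_sample <= 1) or not (0 < t_background <= 1):
        raise ValueError("transmission factors must lie in (0, 1]")
    sample = np.asarray(sample, dtype=float)
    background = np.asarray(background, dtype=float)
    if sample.shape != background.shape:
        raise ValueError(
            f"sample shape {sample.shape} != background shape {background.shape}"
        )
    return sample / t_sample - scale * background / t_background


# -- integration -------------------------------------------------------------

def _kahn_polarization(two_theta_deg: np.ndarray, chi_deg: np.ndarray,
                       factor: float) -> np.ndarray:
    """Kahn polarization correction factor P(2theta, chi; f).

    P = (1 + cos^2(2theta) - f*cos(2chi)*sin^2(2theta)) / 2, the standard
    synchrotron form; P = 1 at 2theta = 0 and the measured intensity is
    divided by P.  ``factor`` is the polarization fraction in [-1, 1]
    (positive = horizontal polarization).
    """
    tt = np.radians(two_theta_deg)
    chi = np.radians(chi_deg)
    return 0.5 * (1.0 + np.cos(tt) ** 2 - factor * np.cos(2 * chi) * np.sin(tt) ** 2)


def _corrected_intensity(
    frame: np.ndarray,
    maps: dict,
    polarization: Optional[float],
    solid_angle: bool,
) -> np.ndarray:
    vals = np.asarray(frame, dtype=float)
    if polarization is not None:
        vals = vals / _kahn_polarization(maps["two_theta"], maps["chi"], polarization)
    if solid_angle:
        vals = vals / np.cos(np.radians(maps["two_theta"])) ** 3
    return vals


def _select(frame, cal, mask, maps=None):
    frame = np.asarray(frame, dtype=float)
    if maps is None:
        maps = pixel_map(cal, frame.shape)
    if mask is not None:
        if mask.mask.shape != frame.shape:
            raise ValueError("mask shape does not match frame shape")
        keep = ~mask.mask
    else:
        keep = np.ones(frame.shape, dtype=bool)
    return frame, maps, keep


def _bin_mean(values, coords, sigmas, lo, hi, n_bins):
    """Histogram mean (and optional Poisson error) over equal-width bins.

    Bins are half-open [edge_i, edge_{i+1}) with the last bin closed so the
    upper limit is included.  Returns (centers, mean, err, counts) restricted
    to populated bins.
    """
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(coords, edges) - 1, 0, n_bins - 1)
    inside = (coords >= lo) & (coords <= hi)
    idx, values = idx[inside], values[inside]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    populated = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = sums[populated] / counts[populated]
    err = None
    if sigmas is not None:
        var = np.bincount(idx, weights=sigmas[inside] ** 2, minlength=n_bins)
        err = np.sqrt(var[populated]) / counts[populated]
    return centers[populated], mean, err, counts[populated]


def azimuthal_integrate(
    frame: np.ndarray,
    cal: GeometryCalibration,
    mask: Optional[MaskImage] = None,
    n_bins: int = 200,
    xkind: str = "q",
    q_range: Optional[tuple[float, float]] = None,
    chi_range: Optional[tuple[float, float]] = None,
    compute_err: bool = False,
    polarization: Optional[float] = None,
    solid_angle: bool = False,
    maps: Optional[dict] = None,
) -> Curve:
    """Azimuthal (radial-abscissa) integration of a 2-D frame to a 1-D profile.

    Unmasked pixels, optionally restricted to a ``chi_range`` (degrees) and
    ``q_range``, are averaged in ``n_bins`` equal-width bins of the chosen
    abscissa (``q`` [1/A], ``two_theta`` [deg] or ``distance`` [mm, radial
    position on the detector face]).  Empty bins are omitted from the output
    rather than reported as zeros.  With ``compute_err`` the per-bin
    uncertainty follows a Poisson counting model:
    ``sigma_pixel = sqrt(max(counts, 1))``, ``sigma_bin = sqrt(sum sigma^2)/m``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if xkind not in ("q", "two_theta", "distance"):
        raise ValueError(f"azimuthal integration abscissa must not be {xkind!r}")
    frame, maps, keep = _select(frame, cal, mask, maps)
    coord = maps["q"] if xkind == "q" else (
        maps["two_theta"] if xkind == "two_theta" else maps["r"])
    if chi_range is not None:
        lo_c, hi_c = chi_range
        chi = maps["chi"]
        keep = keep & ((chi >= lo_c) & (chi <= hi_c) if lo_c <= hi_c
                       else (chi >= lo_c) | (chi <= hi_c))  # wrap through 0
    if q_range is not None:
        keep = keep & (maps["q"] >= q_range[0]) & (maps["q"] <= q_range[1])
    if not keep.any():
        raise ValueError("all pixels are masked or outside the requested ranges")
    vals = _corrected_intensity(frame, maps, polarization, solid_angle)[keep]
    coords = coord[keep]
    sig = np.sqrt(np.maximum(frame[keep], 1.0)) if compute_err else None
    if q_range is not None and xkind == "q":
        lo, hi = q_range
    else:
        lo, hi = coords.min(), coords.max()
    x, y, yerr, counts = _bin_mean(vals, coords, sig, lo, hi, n_bins)
    return Curve(x, y, yerr, xkind=xkind, meta={"bin_counts": counts})


def radial_integrate(
    frame: np.ndarray,
    cal: GeometryCalibration,
    mask: Optional[MaskImage] = None,
    n_bins: int = 360,
    q_range: Optional[tuple[float, float]] = None,
    maps: Optional[dict] = None,
) -> Curve:
    """Intensity vs azimuth within a q annulus (orientation analysis)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    frame, maps, keep = _select(frame, cal, mask, maps)
    if q_range is not None:
        keep = keep & (maps["q"] >= q_range[0]) & (maps["q"] <= q_range[1])
    if not keep.any():
        raise ValueError("q annulus contains no unmasked pixels")
    x, y, _, counts = _bin_mean(frame[keep], maps["chi"][keep], None, 0.0, 360.0, n_bins)
    return Curve(x, y, None, xkind="azimuth", meta={"bin_counts": counts})


def integrate_2d(
    frame: np.ndarray,
    cal: GeometryCalibration,
    mask: Optional[MaskImage] = None,
    n_q_bins: int = 100,
    n_chi_bins: int = 36,
    q_range: Optional[tuple[float, float]] = None,
    maps: Optional[dict] = None,
) -> CakePattern:
    """Regroup a frame onto an (azimuth, q) grid ("cake").

    Cell value is the mean intensity of contributing pixels; empty cells are
    NaN.  Collapsing the cake over azimuth with pixel-count weights agrees
    with :func:`azimuthal_integrate` on the same q binning.
    """
    if n_q_bins < 1 or n_chi_bins < 1:
        raise ValueError("bin counts must be >= 1")
    frame, maps, keep = _select(frame, cal, mask, maps)
    q, chi = maps["q"], maps["chi"]
    if q_range is not None:
        keep = keep & (q >= q_range[0]) & (q <= q_range[1])
        q_lo, q_hi = q_range
    else:
        if not keep.any():
            raise ValueError("all pixels are masked")
        q_lo, q_hi = q[keep].min(), q[keep].max()
    if not keep.any():
        raise ValueError("all pixels are masked or outside q_range")
    qs, chis, vals = q[keep], chi[keep], np.asarray(frame, float)[keep]
    q_edges = np.linspace(q_lo, q_hi, n_q_bins + 1)
    chi_edges = np.linspace(0.0, 360.0, n_chi_bins + 1)
    qi = np.clip(np.digitize(qs, q_edges) - 1, 0, n_q_bins - 1)
    ci = np.clip(np.digitize(chis, chi_edges) - 1, 0, n_chi_bins - 1)
    flat = ci * n_q_bins + qi
    counts = np.bincount(flat, minlength=n_chi_bins * n_q_bins)
    sums = np.bincount(flat, weights=vals, minlength=n_chi_bins * n_q_bins)
    with np.errstate(invalid="ignore"):
        grid = (sums / counts).reshape(n_chi_bins, n_q_bins)
    return CakePattern(
        grid=grid,
        q_axis=0.5 * (q_edges[:-1] + q_edges[1:]),
        chi_axis=0.5 * (chi_edges[:-1] + chi_edges[1:]),
        counts=counts.reshape(n_chi_bins, n_q_bins),
    )
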