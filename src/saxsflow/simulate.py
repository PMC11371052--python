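"""Synthetic-data generators.

Everything the pipeline consumes can be generated here from known ground
truth: isotropic detector frames following a radial intensity law I(q),
anisotropic ("fiber") frames with a Gaussian azimuthal modulation,
analytic 1-D scattering curves, and full tomographic scan series in which
each frame's scattering-peak amplitude encodes one line integral of a 2-D
phantom.  With Poisson noise enabled, the seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np

from .reduction import GeometryCalibration, pixel_map
from .sources import Frame, END_OF_STREAM_KEY, encode_message
from . import tomo

__all__ = [
    "FrameRecipe",
    "default_calibration",
    "make_radial_law",
    "sphere_form_factor",
    "make_curve",
    "simulate_isotropic_frame",
    "simulate_fiber_frame",
    "simulate_tomo_scan",
    "disk_phantom",
    "write_scan_hdf5",
    "write_frames_tiff",
    "replay_zmq",
    "RADIAL_LAWS",
]


def default_calibration(**overrides) -> GeometryCalibration:
    """A plausible SAXS geometry: Cu K-alpha, 1 m distance, 172 um pixels."""
    kw = dict(wavelength=1.54, distance=1000.0, center_row=None,
              center_col=None, pixel_size_row=0.172, pixel_size_col=0.172)
    kw.update(overrides)
    if kw["center_row"] is None:
        kw["center_row"] = 127.5
    if kw["center_col"] is None:
        kw["center_col"] = 127.5
    return GeometryCalibration(**kw)


# -- radial intensity laws ---------------------------------------------------

def sphere_form_factor(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Scattered intensity of a homogeneous sphere of the given radius (A).

    ``I(q) = i0 * [3 (sin qR - qR cos qR) / (qR)^3]^2``; the q -> 0 limit is
    ``i0``.  The radius of gyration of a sphere is ``sqrt(3/5) * R``.
    """
    qr = np.asarray(q, dtype=float) * radius
    out = np.full_like(qr, float(i0))
    nz = qr != 0
    out[nz] = i0 * (3 * (np.sin(qr[nz]) - qr[nz] * np.cos(qr[nz])) / qr[nz] ** 3) ** 2
    return out


def _law_constant(c=1.0):
    return lambda q: np.full_like(np.asarray(q, float), float(c))

def _law_power(amplitude=1.0, exponent=2.0, q_floor=1e-4):
    return lambda q: amplitude / np.maximum(np.asarray(q, float), q_floor) ** exponent

def _law_guinier(i0=100.0, rg=30.0):
    return lambda q: i0 * np.exp(-(np.asarray(q, float) ** 2) * rg ** 2 / 3.0)

def _law_porod(k=1.0, background=0.0, q_floor=1e-4):
    return lambda q: k / np.maximum(np.asarray(q, float), q_floor) ** 4 + background

def _law_sphere(radius=50.0, i0=1.0):
    return lambda q: sphere_form_factor(q, radius, i0)

def _law_gaussian_peak(amplitude=1.0, center=0.1, sigma=0.01, background=0.0):
    return lambda q: amplitude * np.exp(
        -0.5 * ((np.asarray(q, float) - center) / sigma) ** 2) + background


RADIAL_LAWS: dict[str, Callable] = {
    "constant": _law_constant,
    "power": _law_power,
    "guinier": _law_guinier,
    "porod": _law_porod,
    "sphere": _law_sphere,
    "gaussian_peak": _law_gaussian_peak,
}


def make_radial_law(name: str, **params) -> Callable[[np.ndarray], np.ndarray]:
    if name not in RADIAL_LAWS:
        raise KeyError(f"unknown radial law {name!r}; choose from {sorted(RADIAL_LAWS)}")
    return RADIAL_LAWS[name](**params)


def make_curve(law, q: np.ndarray, xkind: str = "q"):
    """Sample an analytic law on a q grid as a :class:`~saxsflow.reduction.Curve`."""
    from .reduction import Curve

    fn = law if callable(law) else make_radial_law(law)
    q = np.asarray(q, dtype=float)
    return Curve(q, fn(q), xkind=xkind)


# -- frame recipes -----------------------------------------------------------

@dataclass
class FrameRecipe:
    """Everything needed to render one synthetic detector frame.

    ``radial_law`` is either a name from :data:`RADIAL_LAWS` (with
    ``law_params``) or a callable q -> intensity.  ``azimuth_modulation``
    is an optional ``(chi0_deg, width_deg, amplitude)`` triple producing
    ``I * (1 + amplitude * gaussian(chi; chi0, width))`` wrapped on the
    circle.  ``noise`` is ``'none'`` or ``'poisson'``.
    """

    shape: tuple[int, int] = (256, 256)
    cal: Optional[GeometryCalibration] = None
    radial_law: object = "constant"
    law_params: dict = field(default_factory=dict)
    azimuth_modulation: Optional[tuple[float, float, float]] = None
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cal is None:
            n = self.shape
            self.cal = default_calibration(center_row=(n[0] - 1) / 2,
                                           center_col=(n[1] - 1) / 2)
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.azimuth_modulation is not None and self.azimuth_modulation[1] <= 0:
            raise ValueError("azimuth modulation width must be positive")

    def law(self) -> Callable:
        if callable(self.radial_law):
            return self.radial_law
        return make_radial_law(self.radial_law, **self.law_params)


def _render(recipe: FrameRecipe, maps: Optional[dict] = None) -> np.ndarray:
    if maps is None:
        maps = pixel_map(recipe.cal, recipe.shape)
    intensity = recipe.law()(maps["q"])
    if np.any(intensity < 0):
        raise ValueError("radial law produced negative intensities")
    if recipe.azimuth_modulation is not None:
        chi0, width, amp = recipe.azimuth_modulation
        dchi = (maps["chi"] - chi0 + 180.0) % 360.0 - 180.0   # wrapped difference
        intensity = intensity * (1.0 + amp * np.exp(-0.5 * (dchi / width) ** 2))
    if recipe.noise == "poisson":
        rng = np.random.default_rng(recipe.seed)
        intensity = rng.poisson(intensity).astype(float)
    return intensity


def simulate_isotropic_frame(recipe: FrameRecipe, index: int = 0,
                             maps: Optional[dict] = None) -> Frame:
    """Render a frame whose pixel value is ``radial_law(q(pixel))``."""
    if recipe.azimuth_modulation is not None:
        raise ValueError("isotropic recipe must not carry an azimuth modulation")
    return Frame(_render(recipe, maps), index=index)


def simulate_fiber_frame(recipe: FrameRecipe, index: int = 0,
                         maps: Optional[dict] = None) -> Frame:
    """Render an anisotropic frame with a Gaussian azimuthal intensity peak."""
    if recipe.azimuth_modulation is None:
        raise ValueError("fiber recipe requires an azimuth_modulation")
    return Frame(_render(recipe, maps), index=index)


# -- tomographic scan series -------------------------------------------------

def disk_phantom(n: int, radius_frac: float = 0.3, value: float = 1.0) -> np.ndarray:
    """Uniform disk of radius ``radius_frac`` of the grid half-width."""
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    return np.where(np.hypot(rr - c, cc - c) <= radius_frac * n / 2.0, value, 0.0)


def simulate_tomo_scan(
    phantom: np.ndarray,
    angles_deg: np.ndarray,
    n_translations: int,
    frame_shape: tuple[int, int] = (64, 64),
    cal: Optional[GeometryCalibration] = None,
    peak_q: float = 0.02,
    peak_sigma: float = 0.002,
    baseline: float = 0.0,
    noise: str = "none",
    seed: int = 0,
) -> Iterator[Frame]:
    """Emit a scanning-tomography frame series from a 2-D phantom.

    For every (angle, translation) on the scan grid, the phantom's line
    integral ``s`` for that ray modulates the amplitude of an isotropic
    Gaussian scattering ring at ``peak_q``: the frame is
    ``s * exp(-(q - peak_q)^2 / 2 sigma^2) + baseline``.  Integrating each
    frame azimuthally and summing an ROI around the peak therefore recovers
    a quantity proportional to ``s``, so the full pipeline
    (integrate -> ROI -> sinogram -> reconstruct) recovers the phantom.
    Frames carry ``angle`` and ``translation`` coords and cover the grid
    exactly once, angle-major.
    """
    phantom = np.asarray(phantom, dtype=float)
    if np.any(phantom < 0):
        raise ValueError("phantom must be nonnegative")
    angles_deg = np.asarray(angles_deg, dtype=float)
    sino = tomo.forward_project(phantom, angles_deg, n_translations)
    if cal is None:
        cal = default_calibration(center_row=(frame_shape[0] - 1) / 2,
                                  center_col=(frame_shape[1] - 1) / 2)
    maps = pixel_map(cal, frame_shape)
    ring = np.exp(-0.5 * ((maps["q"] - peak_q) / peak_sigma) ** 2)
    rng = np.random.default_rng(seed)
    index = 0
    for i, ang in enumerate(angles_deg):
        for j, t in enumerate(sino.translations):
            image = sino.data[i, j] * ring + baseline
            if noise == "poisson":
                image = rng.poisson(image).astype(float)
            yield Frame(image, index=index,
                        coords={"angle": float(ang), "translation": float(t)})
            index += 1


# -- persistence of simulated stacks ----------------------------------------

def write_scan_hdf5(frames, path, dataset: str = "entry/data",
                    dtype=np.float32) -> int:
    """Write a frame stream to HDF5 (stack + per-frame coord datasets)."""
    import h5py

    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    stack = np.stack([f.image for f in frames]).astype(dtype)
    with h5py.File(path, "w") as h5:
        h5.create_dataset(dataset, data=stack)
        coord_names = sorted({k for f in frames for k in f.coords})
        for name in coord_names:
            h5.create_dataset(f"coords/{name}",
                              data=np.array([f.coords.get(name, np.nan)
                                             for f in frames]))
    return len(frames)


def write_frames_tiff(frames, directory, prefix: str = "frame") -> list[str]:
    """Write each frame as ``<prefix><index>.tif``; returns the file list."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = directory / f"{prefix}{f.index}.tif"
        tifffile.imwrite(p, np.asarray(f.image, dtype=np.float32))
        paths.append(str(p))
    return paths


# -- ZMQ replay publisher ----------------------------------------------------

def replay_zmq(frames, endpoint, encoder=encode_message,
               bind: bool = True) -> int:
    """Publish frames as key-value messages on a ZMQ PUSH socket.

    Each message carries the image under ``endpoint.data_key``, the frame's
    coords under ``coords`` and its meta entries; an end-of-stream sentinel
    follows the last frame.  Paired with
    :func:`saxsflow.sources.iter_zmq` this reproduces the input stream
    exactly.  Returns the number of frames published.
    """
    import zmq

    ctx = zmq.Context.instance()
    sock = ctx.socket(zmq.PUSH)
    try:
        if bind:
            sock.bind(endpoint.url)
        else:
            sock.connect(endpoint.url)
    except zmq.ZMQError as exc:
        sock.close(linger=0)
        raise OSError(f"cannot bind ZMQ endpoint {endpoint.url}: {exc}") from exc
    count = 0
    try:
        for frame in frames:
            msg = {endpoint.data_key: np.asarray(frame.image),
                   "coords": dict(frame.coords), **frame.meta}
            sock.send(encoder(msg))
            count += 1
        sock.send(encoder({END_OF_STREAM_KEY: True}))
    finally:
        sock.close(linger=5000)
    return count
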