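"""Parallel-beam scanning tomography: sinogram assembly and 2-D reconstruction.

The projection operator is a ray-driven Joseph-style discretisation: for
each (angle, translation) a ray is sampled at unit steps and each sample is
spread onto its four neighbouring pixels with bilinear weights.  The whole
operator is assembled once as a sparse matrix ``A``, so forward projection
(``A x``), plain backprojection (``A^T p``) and every iterative scheme use
an exactly matched operator/adjoint pair.

Geometry: square image of side ``n``; translations span the inscribed
circle, i.e. ``t`` in ``[-(n-1)/2, (n-1)/2]`` pixel units; pixels outside
the inscribed circle are set to zero by convention.  At angle 0 the rays
run along image rows, so the projection equals the image's column sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator

__all__ = [
    "Sinogram",
    "ReconConfig",
    "assemble_sinogram",
    "projection_matrix",
    "forward_project",
    "reconstruct",
    "RECON_METHODS",
    "FBP_FILTERS",
]

RECON_METHODS = ("BP", "FBP", "ART", "SIRT", "SART", "CGLS")
FBP_FILTERS = ("ramlak", "shepp-logan", "hann")


@dataclass
class Sinogram:
    """Projection data: rows are rotation angles, columns are translations."""

    data: np.ndarray
    angles: np.ndarray          # degrees, strictly increasing
    translations: np.ndarray    # detector positions (pixel units or mm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.data.shape != (self.angles.size, self.translations.size):
            raise ValueError("sinogram shape must be (n_angles, n_translations)")
        if self.angles.size > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("sinogram angles must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")


@dataclass
class ReconConfig:
    """Reconstruction settings.

    ``iterations`` applies to ART/SIRT/SART/CGLS; ``relaxation`` to
    ART/SART (default 1.0) and SIRT (default 0.9); ``filter`` to FBP.
    """

    method: str = "FBP"
    grid_size: int = 64
    iterations: int = 20
    relaxation: Optional[float] = None
    filter: str = "ramlak"

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in RECON_METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {RECON_METHODS}")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.method in ("ART", "SIRT", "SART", "CGLS") and self.iterations < 1:
            raise ValueError("iterations must be >= 1 for iterative methods")
        if self.relaxation is None:
            self.relaxation = 0.9 if self.method == "SIRT" else 1.0
        if not (0 < self.relaxation <= 2):
            raise ValueError("relaxation must lie in (0, 2]")
        if self.method == "FBP" and self.filter.lower() not in FBP_FILTERS:
            raise ValueError(f"unknown FBP filter {self.filter!r}")


# -- sinogram assembly -------------------------------------------------------

def assemble_sinogram(records: Iterable[tuple[float, dict]]) -> Sinogram:
    """Place (scalar, coords) records onto the (angle, translation) grid.

    ``records`` yields pairs of a scalar value and a coords mapping holding
    ``angle`` and ``translation``.  Arrival order is irrelevant; the grid is
    inferred from the distinct coordinate values seen.  A duplicate cell is
    overwritten (last wins) with a warning; cells still empty at the end
    raise an error listing the missing (angle, translation) pairs.
    """
    entries = []
    for value, coords in records:
        if "angle" not in coords or "translation" not in coords:
            raise ValueError("each record needs 'angle' and 'translation' coords")
        entries.append((float(coords["angle"]), float(coords["translation"]), float(value)))
    if not entries:
        raise ValueError("no records to assemble")
    angles = np.unique([e[0] for e in entries])
    trans = np.unique([e[1] for e in entries])
    data = np.full((angles.size, trans.size), np.nan)
    a_idx = {a: i for i, a in enumerate(angles)}
    t_idx = {t: j for j, t in enumerate(trans)}
    for a, t, v in entries:
        i, j = a_idx[a], t_idx[t]
        if not np.isnan(data[i, j]):
            warnings.warn(f"duplicate sinogram cell (angle={a}, translation={t}); "
                          "keeping the last value", stacklevel=2)
        data[i, j] = v
    missing = np.argwhere(np.isnan(data))
    if missing.size:
        cells = [(float(angles[i]), float(trans[j])) for i, j in missing[:20]]
        raise ValueError(f"incomplete scan grid; missing (angle, translation) cells: "
                         f"{cells}{' ...' if len(missing) > 20 else ''}")
    return Sinogram(data, angles, trans)


# -- projection operator -----------------------------------------------------

_MATRIX_CACHE: dict = {}


def projection_matrix(n: int, angles_deg: np.ndarray,
                      n_translations: Optional[int] = None) -> sp.csr_matrix:
    """Sparse parallel-beam projector for an n x n image.

    Rows are ordered angle-major: row ``i * n_translations + j`` is the ray
    at ``angles_deg[i]``, translation ``t_j``, with translations
    ``linspace(-(n-1)/2, (n-1)/2, n_translations)``.
    """
    if n_translations is None:
        n_translations = n
    angles_deg = np.asarray(angles_deg, dtype=float)
    key = (n, n_translations, angles_deg.tobytes())
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    radius = (n - 1) / 2.0
    t = np.linspace(-radius, radius, n_translations)
    s = np.linspace(-radius, radius, n)          # unit steps along the ray
    rows_out, cols_out, weights = [], [], []
    for i, ang in enumerate(np.radians(angles_deg)):
        e_s = np.array([np.cos(ang), np.sin(ang)])    # along-ray, (row, col)
        e_t = np.array([-np.sin(ang), np.cos(ang)])   # detector axis
        # sample coordinates: (n_translations, n_s, 2)
        pts = (radius
               + t[:, None, None] * e_t[None, None, :]
               + s[None, :, None] * e_s[None, None, :])
        r0 = np.floor(pts[..., 0]).astype(np.int64)
        c0 = np.floor(pts[..., 1]).astype(np.int64)
        fr = pts[..., 0] - r0
        fc = pts[..., 1] - c0
        ray_index = i * n_translations + np.arange(n_translations)
        ray_index = np.broadcast_to(ray_index[:, None], fr.shape)
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            rr, cc = r0 + dr, c0 + dc
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n) & (w > 0)
            rows_out.append(ray_index[ok])
            cols_out.append((rr * n + cc)[ok])
            weights.append(w[ok])
    A = sp.coo_matrix(
        (np.concatenate(weights),
         (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(angles_deg.size * n_translations, n * n),
    ).tocsr()
    if len(_MATRIX_CACHE) > 8:          # keep memory bounded
        _MATRIX_CACHE.clear()
    _MATRIX_CACHE[key] = A
    return A


def forward_project(image: np.ndarray, angles_deg: np.ndarray,
                    n_translations: Optional[int] = None) -> Sinogram:
    """Line integrals of a square image along parallel rays (unit pixel step)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("forward projection expects a square 2-D image")
    n = image.shape[0]
    if n_translations is None:
        n_translations = n
    A = projection_matrix(n, angles_deg, n_translations)
    sino = (A @ image.ravel()).reshape(len(np.atleast_1d(angles_deg)), n_translations)
    radius = (n - 1) / 2.0
    return Sinogram(sino, np.atleast_1d(np.asarray(angles_deg, float)),
                    np.linspace(-radius, radius, n_translations))


# -- reconstruction ----------------------------------------------------------

def _inscribed_circle_mask(n: int) -> np.ndarray:
    radius = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    return np.hypot(rr - radius, cc - radius) <= radius + 0.5


def _filter_projections(data: np.ndarray, dt: float, kind: str) -> np.ndarray:
    """Apply the FBP ramp-family filter in the frequency domain.

    Projections are zero-padded to the next power of two >= 2 * width.
    """
    n_t = data.shape[1]
    m = 1 << int(np.ceil(np.log2(max(2 * n_t, 2))))
    freqs = np.fft.fftfreq(m, d=dt)
    ramp = np.abs(freqs)
    kind = kind.lower()
    if kind == "shepp-logan":
        nyq = 0.5 / dt
        arg = np.pi * freqs / (2 * nyq)
        window = np.ones_like(freqs)
        nz = freqs != 0
        window[nz] = np.sin(arg[nz]) / arg[nz]
        ramp = ramp * window
    elif kind == "hann":
        nyq = 0.5 / dt
        ramp = ramp * 0.5 * (1 + np.cos(np.pi * freqs / nyq))
    padded = np.zeros((data.shape[0], m))
    padded[:, :n_t] = data
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * ramp[None, :], axis=1))
    return filtered[:, :n_t]


def _residual_monitor(residuals: list[float]) -> None:
    growth = 0
    for a, b in zip(residuals, residuals[1:]):
        growth = growth + 1 if b > a * (1 + 1e-12) else 0
        if growth > 3:
            warnings.warn("iterative reconstruction residual grew for more than "
                          "3 consecutive iterations; returning current iterate",
                          stacklevel=3)
            return


def reconstruct(sino: Sinogram, cfg: ReconConfig,
                residual_log: Optional[list] = None) -> np.ndarray:
    """Reconstruct a 2-D slice from a parallel-beam sinogram.

    Methods: plain backprojection (BP, scaled by pi/n_angles), filtered
    backprojection (FBP), Kaczmarz row-action ART, fully simultaneous SIRT,
    per-angle-block SART and conjugate-gradient least squares (CGLS).
    Iterative methods start from a zero image and sweep angles in ascending
    order, so runs are deterministic.  ``residual_log``, when given, is
    filled with the per-iteration residual norms ``||A x - p||``.
    """
    n = cfg.grid_size
    n_angles, n_t = sino.data.shape
    if n_t < 2:
        raise ValueError("sinogram must have at least 2 translations")
    if n_t > 4 * n:
        raise ValueError(f"detector length {n_t} inconsistent with grid size {n}")
    A = projection_matrix(n, sino.angles, n_t)
    p = sino.data.ravel()
    radius = (n - 1) / 2.0
    dt = (2 * radius) / (n_t - 1)

    if cfg.method == "BP":
        x = (np.pi / n_angles) * dt * (A.T @ p)
    elif cfg.method == "FBP":
        q = _filter_projections(sino.data, dt, cfg.filter).ravel()
        x = (np.pi / n_angles) * dt * (A.T @ q)
    elif cfg.method == "CGLS":
        x = _cgls(A, p, cfg.iterations, residual_log)
    elif cfg.method == "SIRT":
        x = _sirt(A, p, cfg.iterations, cfg.relaxation, residual_log)
    elif cfg.method == "SART":
        x = _sart(A, p, n_angles, cfg.iterations, cfg.relaxation, residual_log)
    else:  # ART
        x = _art(A, p, cfg.iterations, cfg.relaxation, residual_log)

    if residual_log:
        _residual_monitor(residual_log)
    image = x.reshape(n, n)
    image[~_inscribed_circle_mask(n)] = 0.0
    return image


def _cgls(A, p, iterations, residual_log):
    x = np.zeros(A.shape[1])
    r = p.copy()
    s = A.T @ r
    d = s.copy()
    gamma = s @ s
    for _ in range(iterations):
        q = A @ d
        denom = q @ q
        if denom <= 0:
            break
        alpha = gamma / denom
        x += alpha * d
        r -= alpha * q
        if residual_log is not None:
            residual_log.append(float(np.linalg.norm(r)))
        s = A.T @ r
        gamma_new = s @ s
        if gamma <= 0:
            break
        d = s + (gamma_new / gamma) * d
        gamma = gamma_new
    return x


def _sirt(A, p, iterations, lam, residual_log):
    row_sum = np.asarray(A.sum(axis=1)).ravel()
    col_sum = np.asarray(A.sum(axis=0)).ravel()
    r_inv = np.divide(1.0, row_sum, out=np.zeros_like(row_sum), where=row_sum > 0)
    c_inv = np.divide(1.0, col_sum, out=np.zeros_like(col_sum), where=col_sum > 0)
    x = np.zeros(A.shape[1])
    for _ in range(iterations):
        resid = p - A @ x
        x += lam * c_inv * (A.T @ (r_inv * resid))
        if residual_log is not None:
            residual_log.append(float(np.linalg.norm(p - A @ x)))
    return x


def _sart(A, p, n_angles, iterations, lam, residual_log):
    n_rays = A.shape[0]
    block = n_rays // n_angles
    row_sum = np.asarray(A.sum(axis=1)).ravel()
    r_inv = np.divide(1.0, row_sum, out=np.zeros_like(row_sum), where=row_sum > 0)
    x = np.zeros(A.shape[1])
    blocks = []
    for b in range(n_angles):
        sl = slice(b * block, (b + 1) * block)
        Ab = A[sl]
        cs = np.asarray(Ab.sum(axis=0)).ravel()
        c_inv = np.divide(1.0, cs, out=np.zeros_like(cs), where=cs > 0)
        blocks.append((Ab, r_inv[sl], c_inv, p[sl]))
    for _ in range(iterations):
        for Ab, ri, ci, pb in blocks:
            x += lam * ci * (Ab.T @ (ri * (pb - Ab @ x)))
        if residual_log is not None:
            residual_log.append(float(np.linalg.norm(p - A @ x)))
    return x


def _art(A, p, iterations, lam, residual_log):
    """Kaczmarz sweeps in fixed row order (angles ascending)."""
    A = A.tocsr()
    x = np.zeros(A.shape[1])
    indptr, indices, data = A.indptr, A.indices, A.data
    norms = np.asarray(A.multiply(A).sum(axis=1)).ravel()
    for _ in range(iterations):
        for i in range(A.shape[0]):
            if norms[i] <= 0:
                continue
            lo, hi = indptr[i], indptr[i + 1]
            cols = indices[lo:hi]
            vals = data[lo:hi]
            resid = p[i] - vals @ x[cols]
            x[cols] += lam * resid / norms[i] * vals
        if residual_log is not None:
            residual_log.append(float(np.linalg.norm(p - A @ x)))
    return x


def reconstruct_stack(sinos: Iterable[Sinogram], cfg: ReconConfig) -> np.ndarray:
    """Reconstruct each slice independently and stack along axis 0."""
    return np.stack([reconstruct(s, cfg) for s in sinos], axis=0)
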