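# Methods

This note documents the models, numerical choices and limitations behind
saxsflow, in the spirit of a beamline software methods section.

## Detector geometry and integration

The detector is modelled as flat and orthogonal to the incident beam.
For a pixel at in-plane distance r (mm) from the beam center, the
scattering angle is 2θ = atan(r/D) with D the sample–detector distance,
the scattering vector magnitude q = (4π/λ) sin θ (Å⁻¹), and the azimuth χ
is measured from the +column axis toward the −row axis (counter-clockwise
on screen), in degrees on [0°, 360°).  Detector tilt, rotation and
geometric distortion are **not** modelled; calibrations produced for
tilted detectors will be mis-mapped.  Calibration files are key/value
text in either a PONI-style SI-unit dialect (`Wavelength`, `Distance`,
`Poni1/2`, `PixelSize1/2`, all in metres, converted on load) or a native
dialect already in Å/mm/pixels.

Integration assigns each pixel wholly to the bin containing its center
(no pixel splitting) over equal-width, half-open bins `[lo, hi)` with the
final bin closed.  The bin statistic is the **mean** of contributing
pixels, so integration is linear in the frame and a uniform frame yields
a flat profile.  Empty bins are omitted from the output curve rather than
reported as zeros, because zero-filled bins would corrupt downstream
log-space fits.  Masks use the convention nonzero = excluded; imported
masks with the opposite convention are handled by an `invert` flag, and
threshold masks are unioned with whatever mask is already attached to the
stream.

Optional per-pixel corrections before averaging:

* **Polarization** — divide by the Kahn factor
  P = ½(1 + cos²2θ − f·cos 2χ·sin²2θ) with polarization fraction
  f ∈ [−1, 1]; P = 1 on axis.
* **Solid angle** — divide by cos³2θ (flat-detector solid-angle falloff);
  off by default.
* **Uncertainty** — a Poisson counting model: σ_pixel = √max(counts, 1),
  σ_bin = √(Σσ²)/m for m pixels in the bin.  This is a model choice, not a
  propagated detector variance.

The "distance" abscissa of 1-D profiles is the radial position r on the
detector face in mm.

## Curve analysis

* **ROI intensity** sums y over the closed interval lo ≤ x ≤ hi and
  reports the contributing point count; an empty ROI is an error.
* **Single-peak fitting** uses lmfit's Gaussian plus linear background
  model.  The reported amplitude is the peak height; the area
  A·σ·√(2π) is reported alongside.  Non-convergence or an amplitude
  indistinguishable from zero (|area| < 2·σ_area) is flagged via
  `converged=False`, never silently returned.  Lorentzian/pseudo-Voigt
  profiles are left to plugin node types.
* **Guinier fit** is a linear regression of ln I on q² (weighted by
  (y/σ)² when uncertainties are present, the delta-method variance of
  ln y).  The slope must be negative; Rg = √(−3·slope).  When no range is
  given, the fit starts at the first point and the upper end is shrunk
  iteratively until q_max·Rg ≤ 1.3 self-consistently — the standard
  validity heuristic for globular scatterers; the limit is a parameter.
* **Porod fit** regresses q⁴I on q⁴, giving the Porod constant K as
  intercept and the flat background B as slope; the exponent is fixed at
  4 (sharp interfaces).  K ≤ 0 is treated as an error by default.  The
  default fit range is the top third of the measured q span.
* **Integral invariant** Q = ∫₀^∞ q²I dq is assembled in three parts:
  the Guinier model integrated numerically from 0 to q_min, the trapezoid
  rule on q²(I − B) over the measured grid, and the closed-form Porod
  tail ∫_{q_max}^∞ K/q² dq = K/q_max.  Both upstream results are hard
  dependencies: the workflow validator rejects an invariant node whose
  ancestry lacks the Guinier and Porod operations, and the library call
  raises `MissingDependencyError`.
* **T parameter** uses the stereological two-phase form T = 4Q/(πK),
  the volume-to-surface chord length used in bone SAXS.  Different
  facilities occasionally normalise this quantity differently; the factor
  is documented here precisely so results can be compared.  On the sphere
  form factor the full chain reproduces the mean chord 4R/3 within ~2 %
  (limited by the oscillatory Porod tail).

## Tomography

Geometry is parallel-beam: a ray is indexed by (angle θ, translation t),
with t spanning the inscribed circle of the n×n reconstruction grid in
pixel units.  The projector is ray-driven: each ray is sampled at unit
steps and each sample spreads onto its four neighbouring pixels with
bilinear weights.  The whole operator is assembled once per
(grid, angles, detector) triple as a sparse matrix A, so forward
projection, backprojection and all iterative schemes share an **exactly
matched operator/adjoint pair** (A, Aᵀ).  At angle 0 the projection of any
image equals its column sums exactly; on a common (odd-sized) grid the
projector agrees with scikit-image's `radon` to machine precision.
Pixels outside the inscribed circle are set to zero by convention.

Reconstruction methods, all returning images on the same centred grid:

* **BP** — plain backprojection, scaled by π/n_angles (and by the
  translation spacing so values are resolution-independent).
* **FBP** — frequency-domain ramp filtering (Ram-Lak; Shepp-Logan and
  Hann windows available) with zero-padding to the next power of two
  ≥ 2·n_translations, then BP.
* **ART** — Kaczmarz row sweeps x ← x + λ(pᵢ − aᵢ·x)/‖aᵢ‖²·aᵢ in fixed
  row order (angles ascending), λ default 1.0.
* **SIRT** — simultaneous update x ← x + λ·C·Aᵀ·R·(p − Ax) with row/column
  sum normalisations R, C; λ default 0.9.
* **SART** — the same update restricted to one angle's block of rays at a
  time, λ default 1.0.
* **CGLS** — conjugate gradients on the normal equations of A.

Iterative methods start from a zero image with a default of 20 iterations
and fixed sweep order, so runs are deterministic.  A residual log is
available; residual growth over more than three consecutive iterations
emits a divergence warning and returns the current iterate.  ART's
row-action loop is the slowest method and is intended for modest grids.
The upstream acquisition system's centre of rotation is assumed to
coincide with the scan's translation centre; no automatic centring is
performed.  3-D volumes are stacks of independently reconstructed slices.

## Workflow engine

Nodes declare typed parameters (integer, float, string, tuple, boolean,
enumeration, io); data sources and sinks are bound through io parameters.
Validation checks acyclicity (naming the offending nodes), arity, source
uniqueness, parameter types and declared upstream-type requirements
before any frame is processed.  Execution is a deliberately
single-threaded per-frame pipeline: initialisation (file reads) happens
exactly once, then every node runs exactly once per frame in topological
order.  The error policy is halt-on-error by default, with an explicit
skip-frame mode, since deployments differ on which is safer.

Node outputs are `ResultBundle`s carrying the payload, a data-kind tag,
plot metadata (the headless stand-in for display widgets), persisted
scalar `out_params`, and an in-memory `context` mapping that the engine
merges along edges.  The context is how a calibration loaded once, the
current mask, or a Guinier result reaches downstream consumers without
being re-serialised per frame; anything that must be persisted goes
through `out_params` or the bundle data.  Per-frame scalars carry the
frame's scan coordinates in `out_params` so a sink can assemble 2-D maps.

Cross-frame accumulators (sinogram assembly, reconstruction, storage)
implement a finalize phase that runs once after the stream, again in
topological order.  Storage is chunk-buffered: records are flushed every
`chunk_size` frames and at stream end, so the final file contents are
independent of the chunk size; all node initialisation parameters and all
out_params are stored alongside the data in both HDF5 and TXT layouts.
Workflows persist as JSON with canonical ordering
(`{version, nodes:[{id,type,params}], edges:[[src,dst,slot]]}`), so
save → load → save is byte-identical and configs diff cleanly.

Plugins are plain Python files in a directory; any module-level
`NodeType` (or a `NODE_TYPES` list) is registered.  Malformed files are
skipped with a logged warning; duplicate display names are hard errors
naming both origins.

ZMQ streaming uses a PUSH/PULL pair so each frame is consumed exactly
once; messages are key/value mappings with a configurable image key, a
pluggable decoder (default: a self-describing pickle codec), a reserved
end-of-stream sentinel key and an idle timeout.  The same logical stack
delivered by file or by replay produces bitwise-identical persisted
results.

## Synthetic data

The generators exist so that every pipeline stage can be tested against
known ground truth: isotropic frames evaluate a radial law I(q) at each
pixel's q; fiber frames multiply it by 1 + a·exp(−Δχ²/2w²) with the
angular difference wrapped on the circle; tomographic scans emit one
frame per (angle, translation) whose Gaussian scattering ring at
q₀ = 0.02 Å⁻¹ (mid-range of the default 1 m, Cu-Kα, 172 µm-pixel
geometry) has amplitude equal to the phantom's line integral for that
ray.  Noise is limited to Poisson counting statistics, fully determined
by the seed.  Detector point-spread, dark current, flat-field structure
and realistic backgrounds are deliberately absent — passing tests
demonstrate the correctness of the algorithms, not robustness to every
instrumental artefact of real beamline data.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to keep the full suite
fast while leaving discretisation effects visible: 256² detector frames
with 200 bins for integration accuracy (interior-bin error ≲ 1.5 %),
128² phantoms with 180 angles for FBP fidelity (NRMSE ≈ 0.024, matching
the scikit-image reference on identical inputs), and a 64² phantom at 90
angles (5760 frames) for the end-to-end scan workflow
(NRMSE ≈ 0.04 after least-squares intensity scaling, since the ROI
scalar is proportional, not equal, to the line integral).
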