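"""Built-in workflow node types.

Each node type wraps one operation of the reduction / analysis / tomography
layers in the engine's :class:`~saxsflow.engine.NodeType` contract: typed
parameters, a per-frame ``run`` and, for cross-frame accumulators
(sinogram, reconstruction, storage), a ``finalize`` step.  Heavy
initialisation (calibration files, masks, background frames) happens once
per run in ``init``; per-pixel geometry maps are computed lazily on the
first frame and cached for the rest of the stream.
"""

from __future__ import annotations

import numpy as np

from . import analysis, reduction, tomo
from .engine import NodeRegistry, NodeType, ParamSpec, ResultBundle
from .reduction import Curve
from .sources import Frame

__all__ = ["builtin_registry", "BUILTIN_NODE_TYPES"]


def _frame_of(bundle: ResultBundle) -> Frame:
    if bundle.data_kind != "frame" or not isinstance(bundle.data, Frame):
        raise TypeError(f"expected a frame input, got data_kind "
                        f"{bundle.data_kind!r} from node {bundle.producer!r}")
    return bundle.data


def _curve_of(bundle: ResultBundle) -> Curve:
    if bundle.data_kind != "curve" or not isinstance(bundle.data, Curve):
        raise TypeError(f"expected a curve input, got data_kind "
                        f"{bundle.data_kind!r} from node {bundle.producer!r}")
    return bundle.data


def _calibration_from(ctx: dict) -> reduction.GeometryCalibration:
    cal = ctx.get("calibration")
    if cal is None:
        raise RuntimeError("no calibration in the workflow context; add an "
                           "Import Calibration node upstream")
    return cal


def _merged_context(inputs) -> dict:
    ctx = {}
    for b in inputs:
        ctx.update(b.context)
    return ctx


def _maps_for(state: dict, cal, shape):
    key = (id(cal), shape)
    if state.get("maps_key") != key:
        state["maps"] = reduction.pixel_map(cal, shape)
        state["maps_key"] = key
    return state["maps"]


def _opt_range(value):
    return tuple(value) if value else None


# -- data source -------------------------------------------------------------

def _parse_coords_spec(spec: str) -> dict:
    out = {}
    for item in filter(None, (s.strip() for s in spec.split(","))):
        name, _, dpath = item.partition("=")
        if not dpath:
            raise ValueError(f"coords spec entry {item!r} must be name=dataset")
        out[name.strip()] = dpath.strip()
    return out


def _open_source(params: dict):
    from . import sources

    kind = params["source_type"]
    if kind == "hdf5":
        return sources.iter_hdf5(params["path"], params["dataset"],
                                 coords_datasets=_parse_coords_spec(params["coords"]))
    if kind == "tif":
        return sources.iter_tif(params["path"])
    if kind == "txt":
        return sources.iter_txt(params["path"])
    if kind == "zmq":
        endpoint = sources.StreamEndpoint(params["address"], params["port"],
                                          params["data_key"])
        return sources.iter_zmq(endpoint, timeout_s=params["timeout"])
    raise ValueError(f"unknown source type {kind!r}")


DATA_SOURCE = NodeType(
    function_text="Data Source",
    function_tip="Stream detector frames from HDF5/TIF/TXT files or a live "
                 "ZMQ stream",
    params=(
        ParamSpec("source_type", "enumeration", "hdf5",
                  "where frames come from", ("hdf5", "tif", "txt", "zmq")),
        ParamSpec("path", "io", "", "file path or glob (file sources)"),
        ParamSpec("dataset", "string", "entry/data", "HDF5 dataset path"),
        ParamSpec("coords", "string", "",
                  "per-frame scan coords as name=dataset[,name=dataset] "
                  "(HDF5 sources)"),
        ParamSpec("address", "string", "127.0.0.1", "ZMQ server address"),
        ParamSpec("port", "integer", 5556, "ZMQ server port"),
        ParamSpec("data_key", "string", "image",
                  "message key holding the frame image (ZMQ)"),
        ParamSpec("timeout", "float", 30.0, "ZMQ idle timeout, seconds"),
    ),
    arity=(0, 0),
    open_stream=_open_source,
    category="source",
)


# -- preprocessing -----------------------------------------------------------

def _init_calibration(params, ctx):
    return {"cal": reduction.load_calibration(params["path"])}


def _run_calibration(state, inputs, params):
    frame = _frame_of(inputs[0])
    cal = state["cal"]
    return ResultBundle(data=frame, data_kind="frame",
                        out_params=cal.as_dict(),
                        context={"calibration": cal})


IMPORT_CALIBRATION = NodeType(
    function_text="Import Calibration",
    function_tip="Load a PONI-style geometry calibration file once and "
                 "attach it to the stream",
    params=(ParamSpec("path", "io", "", "calibration file path"),),
    init=_init_calibration,
    run=_run_calibration,
    category="preprocess",
)


def _load_mask_array(path: str, dataset: str) -> np.ndarray:
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        import tifffile
        return np.asarray(tifffile.imread(p))
    if p.endswith((".h5", ".hdf5", ".nxs")):
        import h5py
        with h5py.File(p, "r") as h5:
            if dataset not in h5:
                raise KeyError(f"mask file {p}: no dataset {dataset!r}")
            return np.asarray(h5[dataset])
    return np.loadtxt(p, comments="#", ndmin=2)


def _init_mask(params, ctx):
    arr = _load_mask_array(params["path"], params["dataset"])
    mask = arr == 0 if params["invert"] else arr != 0
    return {"mask": reduction.MaskImage(mask)}


def _run_mask(state, inputs, params):
    frame = _frame_of(inputs[0])
    mask = reduction.combine_masks(inputs[0].context.get("mask"), state["mask"])
    return ResultBundle(data=frame, data_kind="frame",
                        out_params={"n_masked": mask.n_excluded},
                        context={"mask": mask})


IMPORT_MASK = NodeType(
    function_text="Import Mask File",
    function_tip="Load a pixel mask image (nonzero = excluded) and attach "
                 "it to the stream",
    params=(
        ParamSpec("path", "io", "", "mask image path (TIFF/HDF5/TXT)"),
        ParamSpec("dataset", "string", "mask", "HDF5 dataset path"),
        ParamSpec("invert", "boolean", False,
                  "set for masks using the zero = excluded convention"),
    ),
    init=_init_mask,
    run=_run_mask,
    category="preprocess",
)


def _run_threshold_mask(state, inputs, params):
    frame = _frame_of(inputs[0])
    mask = reduction.threshold_mask(frame.image, params["lower"], params["upper"])
    mask = reduction.combine_masks(inputs[0].context.get("mask"), mask)
    return ResultBundle(data=frame, data_kind="frame",
                        out_params={"n_masked": mask.n_excluded},
                        context={"mask": mask})


THRESHOLD_MASK = NodeType(
    function_text="Threshold Mask 2D",
    function_tip="Exclude pixels outside an intensity band; the mask is "
                 "unioned with any imported mask",
    params=(
        ParamSpec("lower", "float", -np.inf, "lowest included pixel value"),
        ParamSpec("upper", "float", np.inf, "highest included pixel value"),
    ),
    run=_run_threshold_mask,
    category="preprocess",
)


def _init_background(params, ctx):
    from . import sources

    path = str(params["background_path"])
    if path.endswith((".tif", ".tiff")):
        frames = list(sources.iter_tif(path))
    elif path.endswith((".h5", ".hdf5", ".nxs")):
        frames = list(sources.iter_hdf5(path, params["dataset"]))
    else:
        frames = list(sources.iter_txt(path))
    if not frames:
        raise ValueError(f"background file {path} holds no frames")
    # multi-frame backgrounds are averaged
    bg = np.mean([f.image for f in frames], axis=0)
    return {"background": bg}


def _run_background(state, inputs, params):
    frame = _frame_of(inputs[0])
    corrected = reduction.subtract_background(
        frame.image, state["background"],
        t_sample=params["transmission_sample"],
        t_background=params["transmission_background"],
        scale=params["scale"])
    out = Frame(corrected, index=frame.index, coords=dict(frame.coords),
                meta=dict(frame.meta))
    return ResultBundle(data=out, data_kind="frame",
                        context={"frame": out})


BACKGROUND_SUBTRACTION = NodeType(
    function_text="Background Subtraction",
    function_tip="Transmission-corrected background subtraction: "
                 "sample/T_s - scale * background/T_b",
    params=(
        ParamSpec("background_path", "io", "", "background frame file"),
        ParamSpec("dataset", "string", "entry/data", "HDF5 dataset path"),
        ParamSpec("transmission_sample", "float", 1.0, "sample transmission"),
        ParamSpec("transmission_background", "float", 1.0,
                  "background transmission"),
        ParamSpec("scale", "float", 1.0, "background scale factor"),
    ),
    init=_init_background,
    run=_run_background,
    category="preprocess",
)


# -- integration -------------------------------------------------------------

def _run_azimuthal(state, inputs, params):
    frame = _frame_of(inputs[0])
    ctx = inputs[0].context
    cal = _calibration_from(ctx)
    maps = _maps_for(state, cal, frame.image.shape)
    curve = reduction.azimuthal_integrate(
        frame.image, cal, mask=ctx.get("mask"),
        n_bins=params["n_bins"], xkind=params["xkind"],
        q_range=_opt_range(params["q_range"]),
        chi_range=_opt_range(params["chi_range"]),
        compute_err=params["compute_err"],
        polarization=(params["polarization_factor"]
                      if params["polarization"] else None),
        solid_angle=params["solid_angle"], maps=maps)
    return ResultBundle(
        data=curve, data_kind="curve",
        plot_meta={"legend": f"frame {frame.index}", "title": "1-D profile",
                   "xlabel": {"q": "q (1/A)", "two_theta": "2theta (deg)",
                              "distance": "r (mm)"}[params["xkind"]],
                   "ylabel": "I (a.u.)", "line_style": "-"},
        context={"azimuthal_curve": curve})


AZIMUTHAL_INTEGRATION = NodeType(
    function_text="Azimuthal Integration",
    function_tip="Average a masked 2-D frame into a 1-D profile I(q), "
                 "I(2theta) or I(r), with optional uncertainty, "
                 "polarization and solid-angle corrections",
    params=(
        ParamSpec("n_bins", "integer", 200, "number of abscissa bins"),
        ParamSpec("xkind", "enumeration", "q", "abscissa kind",
                  ("q", "two_theta", "distance")),
        ParamSpec("q_range", "tuple", (), "(q_min, q_max); empty = full"),
        ParamSpec("chi_range", "tuple", (),
                  "(chi_min, chi_max) deg azimuth selection; empty = full"),
        ParamSpec("compute_err", "boolean", False,
                  "propagate Poisson uncertainties"),
        ParamSpec("polarization", "boolean", False,
                  "apply the Kahn polarization correction"),
        ParamSpec("polarization_factor", "float", 0.95,
                  "polarization fraction in [-1, 1]"),
        ParamSpec("solid_angle", "boolean", False,
                  "apply the cos^3(2theta) solid-angle correction"),
    ),
    run=_run_azimuthal,
    category="integrate",
)


def _run_radial(state, inputs, params):
    frame = _frame_of(inputs[0])
    ctx = inputs[0].context
    cal = _calibration_from(ctx)
    maps = _maps_for(state, cal, frame.image.shape)
    curve = reduction.radial_integrate(
        frame.image, cal, mask=ctx.get("mask"), n_bins=params["n_bins"],
        q_range=_opt_range(params["q_range"]), maps=maps)
    return ResultBundle(data=curve, data_kind="curve",
                        plot_meta={"legend": f"frame {frame.index}",
                                   "xlabel": "chi (deg)", "ylabel": "I (a.u.)",
                                   "title": "radial profile", "line_style": "-"},
                        context={"radial_curve": curve})


RADIAL_INTEGRATION = NodeType(
    function_text="Radial Integration",
    function_tip="Average a q annulus into an intensity-vs-azimuth profile "
                 "(fiber orientation analysis)",
    params=(
        ParamSpec("n_bins", "integer", 360, "number of azimuth bins"),
        ParamSpec("q_range", "tuple", (), "(q_min, q_max) annulus; "
                  "empty = full"),
    ),
    run=_run_radial,
    category="integrate",
)


def _run_integrate_2d(state, inputs, params):
    frame = _frame_of(inputs[0])
    ctx = inputs[0].context
    cal = _calibration_from(ctx)
    maps = _maps_for(state, cal, frame.image.shape)
    cake = reduction.integrate_2d(
        frame.image, cal, mask=ctx.get("mask"),
        n_q_bins=params["n_q_bins"], n_chi_bins=params["n_chi_bins"],
        q_range=_opt_range(params["q_range"]), maps=maps)
    return ResultBundle(data=cake, data_kind="cake",
                        plot_meta={"xlabel": "q (1/A)", "ylabel": "chi (deg)",
                                   "title": "regrouped pattern"},
                        context={"cake": cake})


INTEGRATION_2D = NodeType(
    function_text="2D Integration",
    function_tip="Regroup a frame onto an (azimuth, q) grid",
    params=(
        ParamSpec("n_q_bins", "integer", 100, "q bins"),
        ParamSpec("n_chi_bins", "integer", 36, "azimuth bins"),
        ParamSpec("q_range", "tuple", (), "(q_min, q_max); empty = full"),
    ),
    run=_run_integrate_2d,
    category="integrate",
)


# -- curve analysis ----------------------------------------------------------

def _run_roi(state, inputs, params):
    curve = _curve_of(inputs[0])
    total, n = analysis.roi_intensity(curve, params["lo"], params["hi"])
    coords = inputs[0].context.get("coords", {})
    out_params = {"roi_sum": total, "roi_points": n,
                  **{f"coord_{k}": v for k, v in coords.items()}}
    return ResultBundle(data=total, data_kind="scalar", out_params=out_params,
                        plot_meta={"legend": "ROI intensity"})


ROI_INTENSITY = NodeType(
    function_text="ROI Intensity",
    function_tip="Sum curve intensity over an abscissa region of interest; "
                 "carries the frame's scan coordinates for mapping",
    params=(
        ParamSpec("lo", "float", 0.0, "ROI lower abscissa bound"),
        ParamSpec("hi", "float", 1.0, "ROI upper abscissa bound"),
    ),
    run=_run_roi,
    category="analysis",
)


def _run_peak_fit(state, inputs, params):
    curve = _curve_of(inputs[0])
    result = analysis.fit_single_peak(curve, window=_opt_range(params["window"]))
    coords = inputs[0].context.get("coords", {})
    return ResultBundle(
        data=result.amplitude, data_kind="scalar",
        out_params={**result.as_dict(),
                    "converged": int(result.converged),
                    **{f"coord_{k}": v for k, v in coords.items()}},
        context={"peak_fit": result},
        plot_meta={"legend": "Gaussian + linear baseline fit"})


SINGLE_PEAK_FITTING = NodeType(
    function_text="Single Peak Fitting",
    function_tip="Least-squares fit of a Gaussian peak with linear baseline",
    params=(ParamSpec("window", "tuple", (),
                      "(lo, hi) abscissa fit window; empty = full"),),
    run=_run_peak_fit,
    category="analysis",
)


def _run_guinier(state, inputs, params):
    curve = inputs[0].context.get("azimuthal_curve") or _curve_of(inputs[0])
    result = analysis.guinier_fit(curve, q_range=_opt_range(params["q_range"]),
                                  qmax_rg_limit=params["qmax_rg_limit"])
    return ResultBundle(data=result.rg, data_kind="scalar",
                        out_params=result.as_dict(),
                        context={"guinier": result},
                        plot_meta={"legend": "Guinier fit",
                                   "xlabel": "q^2", "ylabel": "ln I"})


GUINIER_OPERATION = NodeType(
    function_text="Guinier Operation",
    function_tip="Guinier fit ln I = ln I0 - q^2 Rg^2 / 3 at low q",
    params=(
        ParamSpec("q_range", "tuple", (), "(q_min, q_max); empty = automatic"),
        ParamSpec("qmax_rg_limit", "float", 1.3,
                  "validity limit on q_max * Rg for the automatic range"),
    ),
    run=_run_guinier,
    category="analysis",
)


def _run_porod(state, inputs, params):
    curve = inputs[0].context.get("azimuthal_curve") or _curve_of(inputs[0])
    result = analysis.porod_fit(curve, q_range=_opt_range(params["q_range"]))
    corrected = Curve(curve.x, curve.y - result.b, curve.yerr, xkind=curve.xkind)
    return ResultBundle(data=corrected, data_kind="curve",
                        out_params=result.as_dict(),
                        context={"porod": result, "azimuthal_curve": curve},
                        plot_meta={"legend": "Porod-corrected profile",
                                   "xlabel": "q (1/A)", "ylabel": "I - B"})


POROD_OPERATION = NodeType(
    function_text="Porod Operation",
    function_tip="Porod tail fit I = K/q^4 + B; emits the "
                 "background-corrected curve",
    params=(ParamSpec("q_range", "tuple", (),
                      "(q_min, q_max) tail range; empty = top third"),),
    run=_run_porod,
    category="analysis",
)


def _run_invariant(state, inputs, params):
    ctx = _merged_context(inputs)
    curve = ctx.get("azimuthal_curve")
    if curve is None:
        raise RuntimeError("Integral Invariant needs an azimuthal profile "
                           "upstream")
    result = analysis.integral_invariant(curve, ctx.get("guinier"),
                                         ctx.get("porod"))
    return ResultBundle(data=result.q_inv, data_kind="scalar",
                        out_params=result.as_dict(),
                        context={"invariant": result})


INTEGRAL_INVARIANT = NodeType(
    function_text="Integral Invariant",
    function_tip="Total scattering power Q = int q^2 I dq with Guinier "
                 "low-q and Porod high-q extrapolations; requires both "
                 "upstream operations",
    arity=(1, 2),
    run=_run_invariant,
    requires_upstream=frozenset({"Guinier Operation", "Porod Operation"}),
    category="analysis",
)


def _run_t_parameter(state, inputs, params):
    ctx = _merged_context(inputs)
    invariant, porod = ctx.get("invariant"), ctx.get("porod")
    if invariant is None or porod is None:
        raise RuntimeError("T Parameter needs Integral Invariant and Porod "
                           "results upstream")
    t = analysis.t_parameter(invariant, porod)
    return ResultBundle(data=t, data_kind="scalar", out_params={"T": t})


T_PARAMETER = NodeType(
    function_text="T Parameter",
    function_tip="Volume-to-surface chord length T = 4 Q / (pi K) of an "
                 "ideal two-phase system",
    run=_run_t_parameter,
    requires_upstream=frozenset({"Integral Invariant"}),
    category="analysis",
)


# -- tomography --------------------------------------------------------------

def _init_sinogram(params, ctx):
    return {"records": []}


def _run_sinogram(state, inputs, params):
    bundle = inputs[0]
    if bundle.data_kind != "scalar":
        raise TypeError("Sinogram node expects a scalar input (ROI intensity "
                        "or peak amplitude)")
    coords = bundle.context.get("coords", {})
    state["records"].append((float(bundle.data), dict(coords)))
    return ResultBundle(data=None, data_kind="none")


def _finalize_sinogram(state, inputs, params):
    sino = tomo.assemble_sinogram(state["records"])
    return ResultBundle(data=sino.data, data_kind="frame",
                        out_params={"n_angles": len(sino.angles),
                                    "n_translations": len(sino.translations)},
                        context={"sinogram": sino},
                        plot_meta={"xlabel": "translation", "ylabel": "angle",
                                   "title": "sinogram"})


SINOGRAM = NodeType(
    function_text="Sinogram",
    function_tip="Accumulate per-frame scalars onto the (angle, translation) "
                 "scan grid",
    init=_init_sinogram,
    run=_run_sinogram,
    finalize=_finalize_sinogram,
    category="tomo",
)


def _run_reconstruction(state, inputs, params):
    return ResultBundle(data=None, data_kind="none")


def _finalize_reconstruction(state, inputs, params):
    sino = None
    for b in inputs:
        if b is not None and "sinogram" in b.context:
            sino = b.context["sinogram"]
    if sino is None:
        raise RuntimeError("Reconstruction needs an upstream Sinogram node")
    cfg = tomo.ReconConfig(
        method=params["method"], grid_size=params["grid_size"],
        iterations=params["iterations"],
        relaxation=params["relaxation"] if params["relaxation"] > 0 else None,
        filter=params["filter"])
    image = tomo.reconstruct(sino, cfg)
    return ResultBundle(data=image, data_kind="frame",
                        out_params={"method": params["method"],
                                    "grid_size": params["grid_size"]},
                        context={"reconstruction": image},
                        plot_meta={"title": f"{params['method']} reconstruction"})


RECONSTRUCTION = NodeType(
    function_text="Reconstruction",
    function_tip="Reconstruct a 2-D slice from the assembled sinogram "
                 "(BP/FBP/ART/SIRT/SART/CGLS)",
    params=(
        ParamSpec("method", "enumeration", "FBP", "reconstruction algorithm",
                  tomo.RECON_METHODS),
        ParamSpec("grid_size", "integer", 64, "output image side, pixels"),
        ParamSpec("iterations", "integer", 20,
                  "iteration count (iterative methods)"),
        ParamSpec("relaxation", "float", 0.0,
                  "relaxation factor; 0 = method default"),
        ParamSpec("filter", "enumeration", "ramlak", "FBP filter",
                  tomo.FBP_FILTERS),
    ),
    run=_run_reconstruction,
    finalize=_finalize_reconstruction,
    requires_upstream=frozenset({"Sinogram"}),
    category="tomo",
)


# -- storage -----------------------------------------------------------------

def _init_storage(params, ctx):
    from .sources import ResultWriter

    writer = ResultWriter(params["path"], fmt=params["format"],
                          chunk_size=params["chunk_size"])
    writer.write_params(ctx.get("graph_params", {}))
    return {"writer": writer}


def _run_storage(state, inputs, params):
    record = {}
    for b in inputs:
        value = b.data if b.data_kind in ("curve", "scalar", "cake") else None
        if value is not None or b.out_params:
            record[b.producer] = (value, b.out_params)
    if record:
        state["writer"].append(record)
    return ResultBundle(data=None, data_kind="none")


def _finalize_storage(state, inputs, params):
    writer = state["writer"]
    for b in inputs:
        if b is not None and b.data is not None:
            writer.write_final(b.producer, b.data)
    writer.close()
    return None


DATA_STORAGE = NodeType(
    function_text="Data Storage",
    function_tip="Chunk-buffered persistence of upstream results plus all "
                 "workflow parameters (HDF5 or TXT)",
    params=(
        ParamSpec("path", "io", "results.h5", "output file or directory"),
        ParamSpec("format", "enumeration", "hdf5", "storage format",
                  ("hdf5", "txt")),
        ParamSpec("chunk_size", "integer", 100,
                  "frames buffered between flushes"),
    ),
    arity=(1, 8),
    init=_init_storage,
    run=_run_storage,
    finalize=_finalize_storage,
    category="sink",
)


BUILTIN_NODE_TYPES: tuple[NodeType, ...] = (
    DATA_SOURCE,
    IMPORT_CALIBRATION,
    IMPORT_MASK,
    THRESHOLD_MASK,
    BACKGROUND_SUBTRACTION,
    AZIMUTHAL_INTEGRATION,
    RADIAL_INTEGRATION,
    INTEGRATION_2D,
    ROI_INTENSITY,
    SINGLE_PEAK_FITTING,
    GUINIER_OPERATION,
    POROD_OPERATION,
    INTEGRAL_INVARIANT,
    T_PARAMETER,
    SINOGRAM,
    RECONSTRUCTION,
    DATA_STORAGE,
)


def builtin_registry() -> NodeRegistry:
    """A fresh registry pre-loaded with every built-in node type."""
    registry = NodeRegistry()
    for nt in BUILTIN_NODE_TYPES:
        registry.register(nt, origin="builtin")
    return registry
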