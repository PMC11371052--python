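"""Frame ingestion (HDF5, TIFF series, TXT, ZMQ streams) and result persistence.

All sources yield :class:`Frame` objects with strictly increasing indices so
that every downstream node sees the same stream regardless of transport —
the same logical stack delivered from an HDF5 file, a TIFF series or a ZMQ
replay produces identical workflow outputs.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import pickle
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import h5py
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "StreamEndpoint",
    "END_OF_STREAM_KEY",
    "iter_hdf5",
    "iter_tif",
    "iter_txt",
    "iter_zmq",
    "natural_sort",
    "encode_message",
    "decode_message",
    "ResultWriter",
    "write_results",
    "read_results",
]

#: reserved key marking the end-of-stream sentinel message on ZMQ transports
END_OF_STREAM_KEY = "__end_of_stream__"


@dataclass
class Frame:
    """One detector image plus acquisition metadata."""

    image: np.ndarray
    index: int
    coords: dict = field(default_factory=dict)   # scan-axis name -> position
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"frame image must be 2-D, got shape {self.image.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError(f"frame {self.index}: image contains non-finite counts")


@dataclass(frozen=True)
class StreamEndpoint:
    """A ZMQ stream address: host, port and the message key holding the image."""

    address: str
    port: int
    data_key: str

    def __post_init__(self) -> None:
        if not (1 <= self.port <= 65535):
            raise ValueError(f"port {self.port} outside [1, 65535]")
        if not self.data_key:
            raise ValueError("data_key must be non-empty")

    @property
    def url(self) -> str:
        return f"tcp://{self.address}:{self.port}"


def _check_stream(frames: Iterable[Frame]) -> Iterator[Frame]:
    """Enforce constant image shape and increasing indices within a stream."""
    shape = None
    last = -1
    for fr in frames:
        if shape is None:
            shape = fr.image.shape
        elif fr.image.shape != shape:
            raise ValueError(
                f"frame {fr.index}: shape {fr.image.shape} differs from stream shape {shape}")
        if fr.index <= last:
            raise ValueError(f"frame indices must be strictly increasing "
                             f"(got {fr.index} after {last})")
        last = fr.index
        yield fr


# -- file sources ------------------------------------------------------------

def _hdf5_dataset_paths(h5: h5py.File) -> list[str]:
    found = []
    h5.visititems(lambda name, obj: found.append(name)
                  if isinstance(obj, h5py.Dataset) else None)
    return found


def iter_hdf5(path, dataset_path: str,
              coords_datasets: Optional[dict[str, str]] = None) -> Iterator[Frame]:
    """Stream frames from an HDF5 dataset.

    A 3-D dataset is a frame stack along its first axis; a 2-D dataset is a
    single frame.  ``coords_datasets`` optionally maps a scan-axis name to a
    1-D dataset of per-frame positions (e.g. rotation angle, translation).
    """
    with h5py.File(path, "r") as h5:
        if dataset_path not in h5:
            raise KeyError(
                f"{path}: no dataset {dataset_path!r}; available datasets: "
                f"{_hdf5_dataset_paths(h5)}")
        dset = h5[dataset_path]
        if dset.ndim == 2:
            stack = np.asarray(dset)[None, ...]
        elif dset.ndim == 3:
            stack = dset
        else:
            raise ValueError(f"{path}:{dataset_path}: expected rank 2 or 3, "
                             f"got rank {dset.ndim}")
        coord_arrays = {}
        for name, dpath in (coords_datasets or {}).items():
            if dpath not in h5:
                raise KeyError(f"{path}: no coords dataset {dpath!r}")
            coord_arrays[name] = np.asarray(h5[dpath])
        def gen():
            for i in range(stack.shape[0]):
                coords = {k: float(v[i]) for k, v in coord_arrays.items()}
                yield Frame(np.asarray(stack[i]), index=i, coords=coords,
                            meta={"source": str(path), "dataset": dataset_path})
        yield from _check_stream(gen())


def natural_sort(names: Iterable[str]) -> list[str]:
    """Sort so that embedded integers compare numerically (img2 < img10)."""
    def key(name: str):
        return [int(tok) if tok.isdigit() else tok.lower()
                for tok in re.split(r"(\d+)", name)]
    return sorted(names, key=key)


def iter_tif(paths_or_glob) -> Iterator[Frame]:
    """Stream frames from TIFF files in natural-sort order of their names.

    Multi-page TIFFs expand in page order; images are read as grayscale 2-D.
    """
    if isinstance(paths_or_glob, (str, Path)):
        paths = _glob.glob(str(paths_or_glob))
        if not paths:
            raise FileNotFoundError(f"no TIFF files match {paths_or_glob!r}")
    else:
        paths = [str(p) for p in paths_or_glob]
        if not paths:
            raise FileNotFoundError("empty TIFF file list")
    def gen():
        index = 0
        for p in natural_sort(paths):
            try:
                data = tifffile.imread(p)
            except Exception as exc:
                raise IOError(f"cannot read TIFF file {p}: {exc}") from exc
            pages = data[None, ...] if data.ndim == 2 else data
            for page in pages:
                yield Frame(np.asarray(page), index=index, meta={"file": p})
                index += 1
    yield from _check_stream(gen())


def iter_txt(paths_or_glob, delimiter=None) -> Iterator[Frame]:
    """Stream frames from delimited text arrays (one file per frame).

    Whitespace- or comma-delimited; ``#``-prefixed lines are headers.
    """
    if isinstance(paths_or_glob, (str, Path)):
        paths = _glob.glob(str(paths_or_glob))
        if not paths:
            raise FileNotFoundError(f"no TXT files match {paths_or_glob!r}")
    else:
        paths = [str(p) for p in paths_or_glob]
    def gen():
        for i, p in enumerate(natural_sort(paths)):
            try:
                arr = np.loadtxt(p, delimiter=delimiter, comments="#", ndmin=2)
            except Exception as exc:
                raise IOError(f"cannot read TXT array {p}: {exc}") from exc
            yield Frame(arr, index=i, meta={"file": p})
    yield from _check_stream(gen())


# -- ZMQ streaming -----------------------------------------------------------

def encode_message(payload: dict) -> bytes:
    """Default message codec (self-describing binary mapping)."""
    return pickle.dumps(payload, protocol=pickle.HIGHEST_PROTOCOL)


def decode_message(raw: bytes) -> dict:
    obj = pickle.loads(raw)
    if not isinstance(obj, dict):
        raise ValueError("stream message did not decode to a key-value mapping")
    return obj


def iter_zmq(endpoint: StreamEndpoint,
             decoder: Callable[[bytes], dict] = decode_message,
             timeout_s: float = 30.0) -> Iterator[Frame]:
    """Consume frames from a ZMQ PULL socket until the end-of-stream sentinel.

    Each message must decode to a mapping; the entry under
    ``endpoint.data_key`` becomes the frame image, any ``coords`` entry
    becomes the frame coords, and all remaining entries go to ``meta``.
    Messages missing the data key (or failing to decode) are skipped with a
    warning.  The stream ends on a sentinel message carrying
    :data:`END_OF_STREAM_KEY`, or after ``timeout_s`` seconds of silence.
    """
    import zmq

    ctx = zmq.Context.instance()
    sock = ctx.socket(zmq.PULL)
    sock.connect(endpoint.url)
    poller = zmq.Poller()
    poller.register(sock, zmq.POLLIN)
    index = 0
    def gen():
        nonlocal index
        try:
            while True:
                events = dict(poller.poll(timeout=int(timeout_s * 1000)))
                if sock not in events:
                    logger.warning("ZMQ stream %s idle for %.1fs; closing",
                                   endpoint.url, timeout_s)
                    return
                raw = sock.recv()
                try:
                    msg = decoder(raw)
                except Exception as exc:
                    warnings.warn(f"undecodable stream message skipped: {exc}",
                                  stacklevel=2)
                    continue
                if msg.get(END_OF_STREAM_KEY):
                    return
                if endpoint.data_key not in msg:
                    warnings.warn(
                        f"stream message without data key {endpoint.data_key!r} "
                        f"skipped (keys: {sorted(msg)})", stacklevel=2)
                    continue
                image = np.asarray(msg[endpoint.data_key])
                coords = dict(msg.get("coords", {}))
                meta = {k: v for k, v in msg.items()
                        if k not in (endpoint.data_key, "coords")}
                yield Frame(image, index=index, coords=coords, meta=meta)
                index += 1
        finally:
            sock.close(linger=0)
    yield from _check_stream(gen())


# -- result persistence ------------------------------------------------------

def _sanitize(name: str) -> str:
    return re.sub(r"[^\w.+-]", "_", str(name))


def _record_array(value) -> np.ndarray:
    """Convert one per-frame record to a numeric array for storage."""
    from .reduction import Curve  # local import to avoid cycles

    if isinstance(value, Curve):
        cols = [value.x, value.y] + ([value.yerr] if value.yerr is not None else [])
        return np.stack(cols, axis=0)
    if np.isscalar(value) or isinstance(value, (int, float, np.generic)):
        return np.asarray(float(value))
    return np.asarray(value, dtype=float)


class ResultWriter:
    """Chunk-buffered writer for per-frame workflow results.

    ``fmt='hdf5'`` stores one appendable dataset per node under
    ``/results``, end-of-stream outputs under ``/final``, numeric out_params
    under ``/out_params`` and all node initialization parameters as JSON in
    ``/parameters``.  ``fmt='txt'`` writes a directory of delimited tables
    (one per node) with ``#`` headers and a ``parameters.txt`` file.
    Records are buffered and flushed every ``chunk_size`` frames and once at
    the end; the final contents are independent of the chunk size.
    """

    def __init__(self, path, fmt: str = "hdf5", chunk_size: int = 100):
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if fmt not in ("hdf5", "txt"):
            raise ValueError(f"unknown storage format {fmt!r}")
        self.path = Path(path)
        self.fmt = fmt
        self.chunk_size = chunk_size
        self._buffer: dict[str, list[np.ndarray]] = {}
        self._out_buffer: dict[str, list[dict]] = {}
        self._pending = 0
        self._n_written = 0
        self._params_json: Optional[str] = None
        self._closed = False
        if fmt == "hdf5":
            self._h5 = h5py.File(self.path, "w")
        else:
            self.path.mkdir(parents=True, exist_ok=True)
            self._h5 = None

    # -- public API ---------------------------------------------------------
    def write_params(self, params: dict) -> None:
        """Persist the per-node initialization parameters (JSON-serializable)."""
        self._params_json = json.dumps(params, indent=2, sort_keys=True, default=str)
        if self._h5 is not None:
            if "parameters" in self._h5:
                del self._h5["parameters"]
            self._h5.create_dataset("parameters", data=self._params_json)
        else:
            (self.path / "parameters.txt").write_text(self._params_json + "\n")

    def append(self, node_results: dict) -> None:
        """Buffer one frame's results: mapping node_id -> (value, out_params)."""
        for node_id, (value, out_params) in node_results.items():
            if value is not None:
                self._buffer.setdefault(node_id, []).append(_record_array(value))
            if out_params:
                self._out_buffer.setdefault(node_id, []).append(dict(out_params))
        self._pending += 1
        if self._pending >= self.chunk_size:
            self.flush()

    def write_final(self, node_id: str, value) -> None:
        """Persist an end-of-stream output (sinogram, reconstruction, ...)."""
        arr = _record_array(value)
        if self._h5 is not None:
            grp = self._h5.require_group("final")
            name = _sanitize(node_id)
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=arr)
        else:
            fname = self.path / f"{_sanitize(node_id)}.final.txt"
            with open(fname, "w") as fh:
                fh.write(f"# final output of {node_id}, shape {arr.shape}\n")
                np.savetxt(fh, np.atleast_2d(arr.reshape(-1, arr.shape[-1])
                                             if arr.ndim > 1 else arr), fmt="%.17g")

    def flush(self) -> None:
        try:
            for node_id, records in self._buffer.items():
                self._flush_node(node_id, records)
            for node_id, records in self._out_buffer.items():
                self._flush_out_params(node_id, records)
        except OSError as exc:
            raise IOError(
                f"sink write failure after {self._n_written} persisted frames "
                f"({self._pending} buffered lost): {exc}") from exc
        self._buffer.clear()
        self._out_buffer.clear()
        self._n_written += self._pending
        self._pending = 0
        if self._h5 is not None:
            self._h5.flush()

    def close(self) -> None:
        if self._closed:
            return
        self.flush()
        if self._h5 is not None:
            self._h5.close()
        self._closed = True

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- internals ----------------------------------------------------------
    def _flush_node(self, node_id: str, records: list[np.ndarray]) -> None:
        shape = records[0].shape
        uniform = [r if r.shape == shape else _pad_to(r, shape) for r in records]
        block = np.stack(uniform, axis=0)
        if self._h5 is not None:
            grp = self._h5.require_group("results")
            name = _sanitize(node_id)
            if name not in grp:
                grp.create_dataset(name, data=block,
                                   maxshape=(None,) + shape, chunks=True)
            else:
                dset = grp[name]
                n0 = dset.shape[0]
                dset.resize(n0 + block.shape[0], axis=0)
                dset[n0:] = block
        else:
            fname = self.path / f"{_sanitize(node_id)}.txt"
            new = not fname.exists()
            with open(fname, "a") as fh:
                if new:
                    fh.write(f"# per-frame results of {node_id}; "
                             f"record shape {shape}\n")
                for rec in uniform:
                    flat = rec.reshape(1, -1) if rec.ndim == 0 else \
                        rec.reshape(-1, rec.shape[-1]) if rec.ndim > 1 else rec[None, :]
                    np.savetxt(fh, flat, fmt="%.17g")
                    if rec.ndim > 1:
                        fh.write("\n")   # blank line separates multi-row records

    def _flush_out_params(self, node_id: str, records: list[dict]) -> None:
        keys = sorted({k for r in records for k in r
                       if isinstance(r.get(k), (int, float, np.floating, np.integer))})
        if not keys:
            return
        table = np.array([[float(r.get(k, np.nan)) for k in keys] for r in records])
        if self._h5 is not None:
            grp = self._h5.require_group("out_params").require_group(_sanitize(node_id))
            for j, k in enumerate(keys):
                col = table[:, j]
                if k not in grp:
                    grp.create_dataset(k, data=col, maxshape=(None,), chunks=True)
                else:
                    dset = grp[k]
                    n0 = dset.shape[0]
                    dset.resize(n0 + col.size, axis=0)
                    dset[n0:] = col
        else:
            fname = self.path / f"{_sanitize(node_id)}.out.txt"
            new = not fname.exists()
            with open(fname, "a") as fh:
                if new:
                    fh.write("# " + " ".join(keys) + "\n")
                np.savetxt(fh, table, fmt="%.17g")


def _pad_to(rec: np.ndarray, shape: tuple) -> np.ndarray:
    """Pad/truncate a record to the layout of the first record (NaN fill)."""
    warnings.warn("record shape varies within one node's stream; "
                  "padding with NaN to the first record's shape", stacklevel=3)
    out = np.full(shape, np.nan)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(rec.shape, shape))
    if rec.ndim == len(shape):
        out[sl] = rec[sl]
    return out


def write_results(records: dict, path, fmt: str = "hdf5",
                  params: Optional[dict] = None) -> None:
    """One-shot persistence of ``node_id -> list of per-frame values``."""
    with ResultWriter(path, fmt=fmt, chunk_size=max(1, max(
            (len(v) for v in records.values()), default=1))) as writer:
        if params is not None:
            writer.write_params(params)
        n = max((len(v) for v in records.values()), default=0)
        for i in range(n):
            writer.append({nid: (vals[i], None) for nid, vals in records.items()
                           if i < len(vals)})


def read_results(path, fmt: str = "hdf5") -> dict:
    """Read back per-frame result arrays written by :class:`ResultWriter`."""
    out = {}
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            for name, dset in h5.get("results", {}).items():
                out[name] = np.asarray(dset)
    else:
        for fname in Path(path).glob("*.txt"):
            if fname.name in ("parameters.txt",) or fname.name.endswith(".out.txt"):
                continue
            header = ""
            with open(fname) as fh:
                first = fh.readline()
                if first.startswith("#"):
                    header = first
            raw = np.loadtxt(fname, comments="#", ndmin=2)
            m = re.search(r"record shape \(([\d, ]*)\)", header)
            if m and m.group(1).strip():
                shape = tuple(int(s) for s in m.group(1).split(",") if s.strip())
                out[fname.stem] = raw.reshape((-1,) + shape) if shape else raw.ravel()
            else:
                out[fname.stem] = raw.ravel() if raw.shape[1] == 1 else raw
    return out
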