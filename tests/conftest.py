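"""Shared fixtures: registries, calibration files, in-memory source nodes."""

from __future__ import annotations

import numpy as np
import pytest

from saxsflow import builtin_registry
from saxsflow.engine import NodeType, ParamSpec, ResultBundle
from saxsflow.sources import Frame
from saxsflow import simulate as sim


CAL_TEXT = """# synthetic geometry
wavelength_A: 1.54
distance_mm: 1000
center_row: {cr}
center_col: {cc}
pixel_size_row_mm: 0.172
pixel_size_col_mm: 0.172
"""


@pytest.fixture
def registry():
    return builtin_registry()


@pytest.fixture
def cal():
    return sim.default_calibration()


@pytest.fixture
def cal_file(tmp_path):
    """Write a native-dialect calibration file; returns a factory(path, center)."""
    def make(center_row=127.5, center_col=127.5, name="cal.txt"):
        p = tmp_path / name
        p.write_text(CAL_TEXT.format(cr=center_row, cc=center_col))
        return str(p)
    return make


def array_source_type(frames: list[Frame], name: str = "Test Source") -> NodeType:
    """A source node type replaying an in-memory frame list (test helper)."""
    return NodeType(
        function_text=name,
        function_tip="in-memory frame source for tests",
        params=(ParamSpec("n", "integer", len(frames), "frame count"),),
        arity=(0, 0),
        open_stream=lambda params: iter(frames[: params["n"]]),
    )


def record_node_type(log: list, name: str = "Record") -> NodeType:
    """A passthrough node that records (node_id, frame_index) on every run."""
    def init(params, ctx):
        return {"nid": ctx["node_id"]}

    def run(state, inputs, params):
        frame = inputs[0].context.get("frame")
        idx = frame.index if frame is not None else None
        log.append((state["nid"], idx))
        return ResultBundle(data=float(len(log)), data_kind="scalar")

    return NodeType(function_text=name, function_tip="execution recorder",
                    arity=(1, 8), init=init, run=run)


def scalar_frames(values, shape=(4, 4)):
    """Frames of constant value, one per entry of ``values``."""
    return [Frame(np.full(shape, float(v)), index=i)
            for i, v in enumerate(values)]
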