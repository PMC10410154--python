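"""State-aware computational graph export and reference runtime.

A network running in external iteration is compiled to a single-timestep
dataflow graph.  Tensors that must survive the timestep boundary (membrane
potentials, the readout accumulator) become load/save node pairs keyed by
unique state identifiers (UUIDs); each load is associated with a constant
initializer node that provides the reset value.  Neuron arithmetic is
lowered to two built-in ops mirroring hardware primitives:

* ``cmp_and_fire`` — threshold comparison and spike generation,
* ``reset_with_decay`` — membrane reset (hard or soft) followed by decay,

so that load -> add(input current) -> cmp_and_fire -> reset_with_decay ->
save reproduces one LIF step exactly.  The reference runtime iterates
timesteps, binding loads from the state store and writing saves back; a
reset command restores every state from its initializer.  Graph execution
is bitwise identical to direct external-iteration execution; the builtins
are inference-only (export refuses a network flagged as training).

Serialization is versioned JSON with initializer/weight arrays inlined as
base64.
"""

from __future__ import annotations

import base64
import json
import uuid
from dataclasses import dataclass, field

import numpy as np

from ._tensor import conv2d_forward, linear_forward
from .blocks import ConvBlock, FCBlock
from .errors import GraphError
from .network import Network, _LinearHead, _PopulationHead

__all__ = ["StateGraph", "export_graph", "run_graph", "serialize", "deserialize"]

SCHEMA_VERSION = 1

_OPS = (
    "input", "const", "load", "save", "conv2d", "linear", "batchnorm",
    "relu", "flatten", "add", "div", "group_mean", "cmp_and_fire",
    "reset_with_decay", "output",
)


@dataclass
class StateGraph:
    """Single-timestep dataflow graph with explicit state bindings."""

    nodes: list = field(default_factory=list)  # {id, op, inputs, attrs}
    states: list = field(default_factory=list)  # {state_id, load, save, init}
    inputs: list = field(default_factory=list)  # node ids fed per timestep
    outputs: list = field(default_factory=list)  # node ids read out
    schema_version: int = SCHEMA_VERSION

    def node(self, op: str, inputs=(), **attrs) -> str:
        nid = f"n{len(self.nodes)}"
        self.nodes.append(
            {"id": nid, "op": op, "inputs": list(inputs), "attrs": attrs}
        )
        return nid

    def add_state(self, shape) -> tuple[str, str]:
        """Create an initializer + load node for a fresh state id; returns
        (state_id, load node id).  The save node is bound later."""
        sid = str(uuid.uuid4())
        init = self.node("const", fill=0.0, shape=list(shape))
        load = self.node("load", state_id=sid)
        self.states.append({"state_id": sid, "load": load, "save": None,
                            "init": init})
        return sid, load

    def bind_save(self, sid: str, value_node: str):
        save = self.node("save", inputs=[value_node], state_id=sid)
        for st in self.states:
            if st["state_id"] == sid:
                if st["save"] is not None:
                    raise GraphError(f"state {sid} already has a save node")
                st["save"] = save
                return
        raise GraphError(f"unknown state id {sid}")

    def validate(self):
        ids = [n["id"] for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise GraphError("duplicate node ids")
        byid = {n["id"]: n for n in self.nodes}
        for n in self.nodes:
            if n["op"] not in _OPS:
                raise GraphError(f"unknown op {n['op']!r}")
            for i in n["inputs"]:
                if i not in byid:
                    raise GraphError(f"node {n['id']} references unknown {i}")
        seen = set()
        for st in self.states:
            sid = st["state_id"]
            if sid in seen:
                raise GraphError(f"state id {sid} bound twice")
            seen.add(sid)
            for key in ("load", "save", "init"):
                if st[key] not in byid:
                    raise GraphError(f"state {sid}: missing {key} node")
            if byid[st["load"]]["op"] != "load" or byid[st["save"]]["op"] != "save":
                raise GraphError(f"state {sid}: wrong load/save op kinds")
            if byid[st["init"]]["op"] != "const":
                raise GraphError(f"state {sid}: initializer must be const")
        load_ids = {n["attrs"]["state_id"] for n in self.nodes if n["op"] == "load"}
        save_ids = {n["attrs"]["state_id"] for n in self.nodes if n["op"] == "save"}
        if load_ids != seen or save_ids != seen:
            raise GraphError("load/save state ids do not match the bindings")
        self._toposort()  # raises on cycles
        return self

    def _toposort(self) -> list:
        order, mark = [], {}
        byid = {n["id"]: n for n in self.nodes}

        def visit(nid):
            if mark.get(nid) == 2:
                return
            if mark.get(nid) == 1:
                raise GraphError("graph contains a cycle within a timestep")
            mark[nid] = 1
            for i in byid[nid]["inputs"]:
                visit(i)
            mark[nid] = 2
            order.append(nid)

        for n in self.nodes:
            visit(n["id"])
        return [byid[i] for i in order]


def _expand(arr, nd):
    """Broadcast a per-channel parameter against [B, C, *spatial]."""
    arr = np.asarray(arr)
    if arr.ndim == 0:
        return arr
    return arr.reshape((arr.shape[0],) + (1,) * (nd - 2))


def export_graph(net: Network) -> StateGraph:
    """Compile a network into a single-timestep state-aware graph."""
    if net.training:
        raise GraphError(
            "builtin neuron ops are inference-only: network is flagged "
            "for training"
        )
    if net.plan.has_temporal_transforms:
        raise GraphError("per-block temporal transforms cannot be exported")
    g = StateGraph()
    cur = g.node("input")
    g.inputs.append(cur)
    for blk in net.blocks:
        if blk.lifplus is not None and not blk.lifplus.is_default:
            raise GraphError(
                "only default LIF/LIAF dynamics lower to the builtin ops"
            )
        if isinstance(blk, ConvBlock):
            cur = g.node(
                "conv2d", [cur], w=blk.w.data, b=blk.b.data,
                stride=list(blk.cfg.stride), padding=blk.cfg.padding,
            )
            state_shape = (blk.cfg.out_channels,) + blk._spatial
        elif isinstance(blk, FCBlock):
            cur = g.node("flatten", [cur])
            cur = g.node("linear", [cur], w=blk.w.data, b=blk.b.data)
            state_shape = (blk.cfg.out_channels,)
        else:
            raise GraphError(f"unsupported block {type(blk).__name__}")
        if blk.norm is not None:
            bn = blk.norm
            cur = g.node(
                "batchnorm", [cur], gamma=bn.gamma.data, beta=bn.beta.data,
                mean=bn.running_mean, var=bn.running_var, eps=bn.eps,
            )
        if blk.neuron is not None:
            p = blk.neuron
            sid, load = g.add_state(state_shape)
            vm = g.node("add", [cur, load])
            fire = g.node("cmp_and_fire", [vm], v_th=p.v_th)
            vnew = g.node(
                "reset_with_decay", [fire, vm], alpha=p.alpha, beta=p.beta,
                v_th=p.v_th, v_reset=p.v_reset, reset_mode=p.reset_mode,
            )
            g.bind_save(sid, vnew)
            cur = fire if p.fire_mode == "spike" else g.node("relu", [vnew])
    agg = net.plan.aggregation
    if agg in ("sum", "mean", "accumulator"):
        sid, load = g.add_state(net.out_shape)
        cur = g.node("add", [cur, load])
        g.bind_save(sid, cur)
        if agg == "mean":
            cur = g.node("div", [cur], divisor=float(net.plan.t_total))
    head = net.head
    if isinstance(head, _LinearHead):
        cur = g.node("flatten", [cur])
        cur = g.node("linear", [cur], w=head.w.data, b=head.b.data)
    elif isinstance(head, _PopulationHead):
        cur = g.node("flatten", [cur])
        cur = g.node("group_mean", [cur], n_categories=head.n_classes,
                     n_per_category=head.n)
    out = g.node("output", [cur])
    g.outputs.append(out)
    return g.validate()


def _eval_node(n, vals, store, batch):
    op, a = n["op"], n["attrs"]
    x = [vals[i] for i in n["inputs"]]
    if op == "input":
        raise GraphError("input node evaluated without a bound frame")
    if op == "const":
        return np.full([batch] + list(a["shape"]), float(a["fill"]))
    if op == "load":
        return store[a["state_id"]]
    if op == "save":
        store[a["state_id"]] = x[0]
        return x[0]
    if op == "conv2d":
        out, _ = conv2d_forward(x[0], a["w"], a["b"], tuple(a["stride"]),
                                a["padding"])
        return out
    if op == "linear":
        return linear_forward(x[0], a["w"], a["b"])
    if op == "flatten":
        return x[0].reshape(x[0].shape[0], -1) if x[0].ndim > 2 else x[0]
    if op == "batchnorm":
        nd = x[0].ndim
        pshape = (1, -1) + (1,) * (nd - 2)
        mu = np.asarray(a["mean"]).reshape(pshape)
        var = np.asarray(a["var"]).reshape(pshape)
        xn = (x[0] - mu) / np.sqrt(var + a["eps"])
        return xn * np.asarray(a["gamma"]).reshape(pshape) + np.asarray(
            a["beta"]
        ).reshape(pshape)
    if op == "relu":
        return np.maximum(x[0], 0.0)
    if op == "add":
        return x[0] + x[1]
    if op == "div":
        return x[0] / float(a["divisor"])
    if op == "group_mean":
        b = x[0].shape[0]
        grouped = x[0].reshape(b, a["n_categories"], a["n_per_category"])
        return grouped.sum(axis=2) / float(a["n_per_category"])
    if op == "cmp_and_fire":
        v_th = _expand(a["v_th"], x[0].ndim)
        return np.greater_equal(x[0], v_th).astype(x[0].dtype)
    if op == "reset_with_decay":
        f, v_m = x
        nd = v_m.ndim
        alpha = _expand(a["alpha"], nd)
        beta = _expand(a["beta"], nd)
        v_th = _expand(a["v_th"], nd)
        v_reset = _expand(a["v_reset"], nd)
        if a["reset_mode"] == "hard":
            r = f * v_reset + (1.0 - f) * v_m
        else:
            r = f * (v_m - v_th) + (1.0 - f) * v_m
        return alpha * r + beta
    if op == "output":
        return x[0]
    raise GraphError(f"unknown op {op!r}")


def run_graph(g: StateGraph, frames, reset_between_samples: bool = True):
    """Execute the graph timestep by timestep on an ST tensor [B, T, ...].

    Returns the last timestep's output (None for an empty time axis).  With
    ``reset_between_samples`` every state is restored from its initializer
    before the first frame.
    """
    g.validate()
    order = g._toposort()
    byid = {n["id"]: n for n in g.nodes}
    frames = np.asarray(frames)
    if frames.shape[1:2] == (0,):
        return None
    batch = frames.shape[0]
    store = getattr(g, "_store", {})
    if reset_between_samples or not store:
        store = {}
        for st in g.states:
            init = byid[st["init"]]["attrs"]
            store[st["state_id"]] = np.full(
                [batch] + list(init["shape"]), float(init["fill"])
            )
    g._store = store
    out = None
    for t in range(frames.shape[1]):
        vals = {g.inputs[0]: frames[:, t]}
        for n in order:
            if n["id"] in vals:
                continue
            vals[n["id"]] = _eval_node(n, vals, store, batch)
        out = vals[g.outputs[0]]
    return out


# ---------------------------------------------------------------------------
# serialization


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {
            "__ndarray__": True,
            "dtype": str(obj.dtype),
            "shape": list(obj.shape),
            "data": base64.b64encode(np.ascontiguousarray(obj).tobytes()).decode(),
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not serializable: {type(obj)}")


def _decode_attrs(attrs):
    out = {}
    for k, v in attrs.items():
        if isinstance(v, dict) and v.get("__ndarray__"):
            out[k] = np.frombuffer(
                base64.b64decode(v["data"]), dtype=v["dtype"]
            ).reshape(v["shape"])
        else:
            out[k] = v
    return out


def serialize(g: StateGraph) -> str:
    """Lossless JSON text form of the graph (arrays inline as base64)."""
    doc = {
        "schema_version": g.schema_version,
        "nodes": g.nodes,
        "states": g.states,
        "inputs": g.inputs,
        "outputs": g.outputs,
    }
    return json.dumps(doc, default=_encode, indent=1)


def deserialize(text: str) -> StateGraph:
    """Parse and validate a serialized graph; raises GraphError on a schema
    version mismatch or any structural inconsistency (e.g. tampered ids)."""
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise GraphError(
            f"schema version {doc.get('schema_version')} != {SCHEMA_VERSION}"
        )
    g = StateGraph(
        nodes=[
            {**n, "attrs": _decode_attrs(n["attrs"])} for n in doc["nodes"]
        ],
        states=doc["states"],
        inputs=doc["inputs"],
        outputs=doc["outputs"],
    )
    return g.validate()
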