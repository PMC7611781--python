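"""Event-driven finite-state-machine trigger network.

Synchronizes electro-mechanical activation between the 0D chamber models
and the 3D electrophysiology: an autorhythmic clock (the sino-atrial node)
fires at a prescribed cycle length; reactive excitable units (RA, LA, the
atrial and ventricular sides of the AV node, the ventricular His exits)
re-fire incoming triggers after prescribed inter-node delays unless they
are inside their effective refractory period (ERP), in which case the
trigger is absorbed.  Bindings attach fired nodes to 0D wall activation
clocks or to 3D fascicle stimulation sets.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FsmNode", "FsmNetwork", "TriggerSchedule", "standard_heart_network"]


@dataclass
class FsmNode:
    name: str
    kind: str = "excitable"  # "auto" or "excitable"
    cycle_length: float = 0.0  # ms, auto nodes
    t0: float = 0.0  # ms, first firing of auto nodes
    erp: float = 350.0  # ms, excitable nodes


@dataclass
class FsmNetwork:
    """Trigger graph: nodes, delayed edges, and wall/fascicle bindings."""

    nodes: dict[str, FsmNode] = field(default_factory=dict)
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    bindings: dict[str, list[str]] = field(default_factory=dict)

    def add_node(self, node: FsmNode) -> None:
        if node.kind == "auto" and node.cycle_length <= 0:
            raise ValueError(f"auto node {node.name!r} needs a positive cycle length")
        if node.kind == "excitable" and node.erp <= 0:
            raise ValueError(f"excitable node {node.name!r} needs a positive ERP")
        self.nodes[node.name] = node

    def add_edge(self, src: str, dst: str, delay: float) -> None:
        if delay < 0:
            raise ValueError("FSM edge delays must be >= 0")
        self.edges.append((src, dst, delay))

    def bind(self, node: str, target: str) -> None:
        self.bindings.setdefault(node, []).append(target)

    def schedule(self, t_end: float) -> dict[str, np.ndarray]:
        """Deterministic firing times per node up to ``t_end`` (ms)."""
        out_edges: dict[str, list[tuple[str, float]]] = {}
        for s, d, dly in self.edges:
            out_edges.setdefault(s, []).append((d, dly))
        fired: dict[str, list[float]] = {n: [] for n in self.nodes}
        last_fire = {n: -np.inf for n in self.nodes}
        heap: list[tuple[float, int, str]] = []
        seq = 0
        for n in self.nodes.values():
            if n.kind == "auto":
                t = n.t0
                while t <= t_end:
                    heapq.heappush(heap, (t, seq, n.name))
                    seq += 1
                    t += n.cycle_length
        while heap:
            t, _, name = heapq.heappop(heap)
            if t > t_end:
                continue
            node = self.nodes[name]
            if node.kind == "excitable" and t < last_fire[name] + node.erp:
                continue  # absorbed within refractory period
            last_fire[name] = t
            fired[name].append(t)
            for dst, dly in out_edges.get(name, []):
                heapq.heappush(heap, (t + dly, seq, dst))
                seq += 1
        return {n: np.asarray(v) for n, v in fired.items()}

    def wall_trigger_times(self, t_end: float) -> "TriggerSchedule":
        """Firing times grouped by bound target (wall / fascicle tag)."""
        fires = self.schedule(t_end)
        times: dict[str, np.ndarray] = {}
        for node, targets in self.bindings.items():
            for tgt in targets:
                prev = times.get(tgt, np.empty(0))
                times[tgt] = np.sort(np.concatenate([prev, fires[node]]))
        return TriggerSchedule(times)


@dataclass
class TriggerSchedule:
    """Trigger times per target; provides the per-wall activation clock."""

    times: dict[str, np.ndarray]

    def clock(self, target: str, t: float) -> float:
        """Time since the most recent trigger of ``target`` (inf if none)."""
        tt = self.times.get(target)
        if tt is None or len(tt) == 0:
            return np.inf
        i = np.searchsorted(tt, t, side="right") - 1
        return np.inf if i < 0 else t - tt[i]

    def last_trigger(self, target: str, t: float) -> float:
        tt = self.times.get(target)
        if tt is None or len(tt) == 0:
            return -np.inf
        i = np.searchsorted(tt, t, side="right") - 1
        return -np.inf if i < 0 else float(tt[i])

    def events_in(self, t0: float, t1: float) -> np.ndarray:
        """Distinct trigger times in (t0, t1), for integrator event landing."""
        if not self.times:
            return np.empty(0)
        allt = np.unique(np.concatenate(list(self.times.values())))
        return allt[(allt > t0) & (allt < t1)]


def standard_heart_network(
    cycle_length: float = 585.0,
    t0_ra: float = 0.0,
    aa_delay: float = 20.0,
    av_delay: float = 100.0,
    vv_delay: float = 0.0,
    erp: float = 350.0,
) -> FsmNetwork:
    """The standard sinus-rhythm trigger topology (times in ms).

    SA fires RA at the cycle length; LA follows RA after the inter-atrial
    delay; the AV node relays RA to the ventricular His exits after the AV
    delay; the RV fires ``vv_delay`` after (positive) or before (negative)
    the LV.
    """
    net = FsmNetwork()
    net.add_node(FsmNode("sa", kind="auto", cycle_length=cycle_length, t0=t0_ra))
    for name in ("ra", "la", "av_a", "av_v", "lv_his", "rv_his"):
        net.add_node(FsmNode(name, kind="excitable", erp=erp))
    net.add_edge("sa", "ra", 0.0)
    net.add_edge("ra", "la", aa_delay)
    net.add_edge("ra", "av_a", 0.0)
    net.add_edge("av_a", "av_v", av_delay)
    net.add_edge("av_v", "lv_his", max(0.0, -vv_delay))
    net.add_edge("av_v", "rv_his", max(0.0, vv_delay))
    net.bind("ra", "ra")
    net.bind("la", "la")
    net.bind("lv_his", "lv")
    net.bind("rv_his", "rv")
    return net
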