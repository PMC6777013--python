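"""Leave-one-out robustness of a configured system.

Each scenario deletes one node (with its incident edges) from the network,
drops it from every input column and output row of the configuration
(columns/rows left empty are dropped, not reassigned: the damaged system is
tested as-is), and re-runs the graph-theoretic structural controllability
and observability tests on the (N-1)-state system.  A node is critical if
its removal makes the system structurally uncontrollable or unobservable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import pandas as pd

from .graph_core import DirectedNetwork, _sort_key
from .graph_core import (
    structural_controllability_test,
    structural_observability_test,
)
from .mapping import InputConfiguration, OutputConfiguration, build_model

Node = Hashable


@dataclass
class RobustnessReport:
    """Per-scenario outcomes and aggregate robustness of a configuration."""

    outcomes: pd.DataFrame  # index: removed node; controllable/observable bool cols
    input_robust_count: int
    output_robust_count: int
    input_robust_fraction: float
    output_robust_fraction: float
    critical_nodes_control: set[Node]
    critical_nodes_observe: set[Node]

    @property
    def n_scenarios(self) -> int:
        return len(self.outcomes)


def _remove_node(net: DirectedNetwork, v: Node) -> DirectedNetwork:
    labels = [u for u in net.labels if u != v]
    edges = {(a, b) for a, b in net.edges if a != v and b != v}
    return DirectedNetwork(labels, edges)


def _drop_from_assignment(assignment: dict[Node, int], v: Node) -> dict[Node, int]:
    """Remove node v; re-index the surviving columns densely, preserving order."""
    kept = {u: k for u, k in assignment.items() if u != v}
    live_cols = sorted(set(kept.values()))
    remap = {c: i for i, c in enumerate(live_cols)}
    return {u: remap[k] for u, k in kept.items()}


def leave_one_out(net: DirectedNetwork,
                  input_cfg: InputConfiguration,
                  output_cfg: OutputConfiguration) -> RobustnessReport:
    """Remove each node in turn and re-test structural controllability and
    observability of the damaged (N-1)-state system."""
    if net.n_nodes <= 1:
        raise ValueError("leave-one-out needs at least two nodes")
    rows = []
    for v in sorted(net.labels, key=_sort_key):
        damaged = _remove_node(net, v)
        in_assign = _drop_from_assignment(input_cfg.assignment, v)
        out_assign = _drop_from_assignment(output_cfg.assignment, v)
        if not in_assign:
            ctrl = False
        else:
            cfg_in = InputConfiguration(driver_nodes=set(in_assign),
                                        assignment=in_assign,
                                        method=input_cfg.method)
            # observability side irrelevant for the controllability verdict;
            # build with a throwaway full-sensing row if outputs vanished
            dummy_out = out_assign or {u: 0 for u in damaged.labels[:1]}
            cfg_out = OutputConfiguration(sensor_nodes=set(dummy_out),
                                          assignment=_dense(dummy_out),
                                          method=output_cfg.method)
            ctrl = structural_controllability_test(
                build_model(damaged, cfg_in, cfg_out))
        if not out_assign:
            obs = False
        else:
            cfg_out = OutputConfiguration(sensor_nodes=set(out_assign),
                                          assignment=out_assign,
                                          method=output_cfg.method)
            dummy_in = in_assign or {u: 0 for u in damaged.labels[:1]}
            cfg_in = InputConfiguration(driver_nodes=set(dummy_in),
                                        assignment=_dense(dummy_in),
                                        method=input_cfg.method)
            obs = structural_observability_test(
                build_model(damaged, cfg_in, cfg_out))
        rows.append({"removed": v,
                     "controllable_after_removal": ctrl,
                     "observable_after_removal": obs})
    outcomes = pd.DataFrame(rows).set_index("removed")
    n = net.n_nodes
    in_count = int(outcomes["controllable_after_removal"].sum())
    out_count = int(outcomes["observable_after_removal"].sum())
    return RobustnessReport(
        outcomes=outcomes,
        input_robust_count=in_count,
        output_robust_count=out_count,
        input_robust_fraction=round(in_count / n, 4),
        output_robust_fraction=round(out_count / n, 4),
        critical_nodes_control={
            v for v, ok in outcomes["controllable_after_removal"].items() if not ok},
        critical_nodes_observe={
            v for v, ok in outcomes["observable_after_removal"].items() if not ok},
    )


def _dense(assignment: dict[Node, int]) -> dict[Node, int]:
    live = sorted(set(assignment.values()))
    remap = {c: i for i, c in enumerate(live)}
    return {u: remap[k] for u, k in assignment.items()}


def critical_nodes(report: RobustnessReport) -> tuple[set[Node], set[Node]]:
    """(control-critical, observation-critical) node sets; by definition
    ``|critical| + robust count = N`` on each side."""
    return set(report.critical_nodes_control), set(report.critical_nodes_observe)
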