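"""Build input (B) and output (C) patterns that make a network's state-space
model structurally controllable and observable.

The minimal driver set from maximum matching guarantees a dilation-free
matching but not accessibility: a source component of the SCC condensation
that contains no driver is unreachable from every input.  Two strategies
repair this:

* ``path_finding`` attaches one representative node of each such critical
  source component to a new dedicated input column;
* ``signal_sharing`` adds the representative to the first existing input
  column, sharing that signal.

When no critical source component exists the two strategies coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .graph_core import (
    DirectedNetwork,
    StateSpaceModel,
    _sort_key,
    maximum_matching,
    minimal_driver_nodes,
    minimal_sensor_nodes,
    source_components,
)

Node = Hashable

METHODS = ("path_finding", "signal_sharing")


@dataclass
class InputConfiguration:
    """Assignment of actuated nodes to input columns of B.

    ``assignment`` maps each actuated node to a 0-based input column index;
    with ``path_finding`` the map is injective (one dedicated input per
    node), with ``signal_sharing`` a column may actuate several nodes.
    """

    driver_nodes: set[Node]
    assignment: dict[Node, int]
    method: str = "path_finding"

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("configuration must actuate at least one node")
        cols = set(self.assignment.values())
        if cols != set(range(len(cols))):
            raise ValueError("input columns must be consecutive 0-based indices")

    @property
    def n_inputs(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def actuated_nodes(self) -> set[Node]:
        return set(self.assignment)


@dataclass
class OutputConfiguration:
    """Dual of :class:`InputConfiguration` for the rows of C."""

    sensor_nodes: set[Node]
    assignment: dict[Node, int]
    method: str = "path_finding"

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("configuration must sense at least one node")
        rows = set(self.assignment.values())
        if rows != set(range(len(rows))):
            raise ValueError("output rows must be consecutive 0-based indices")

    @property
    def n_outputs(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def sensed_nodes(self) -> set[Node]:
        return set(self.assignment)


def _critical_sources(net: DirectedNetwork, base: set[Node]) -> list[Node]:
    """Smallest-label representative of each source component without a
    base driver, in ascending order of that representative."""
    reps = [min(comp, key=_sort_key)
            for comp in source_components(net) if not (comp & base)]
    return sorted(reps, key=_sort_key)


def map_inputs(net: DirectedNetwork, method: str = "path_finding") -> InputConfiguration:
    """Place inputs so the resulting model is structurally controllable.

    The base actuated set is the minimal driver set; every critical source
    component additionally gets one representative actuated, on a new
    dedicated column (``path_finding``) or sharing input column 0
    (``signal_sharing``).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    base = minimal_driver_nodes(net)
    ordered = sorted(base, key=_sort_key)
    assignment = {v: k for k, v in enumerate(ordered)}
    for rep in _critical_sources(net, base):
        if method == "path_finding":
            assignment[rep] = len(set(assignment.values()))
        else:
            assignment[rep] = 0
    return InputConfiguration(driver_nodes=base, assignment=assignment, method=method)


def map_outputs(net: DirectedNetwork, method: str = "path_finding") -> OutputConfiguration:
    """Dual of :func:`map_inputs` on the reversed network."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cfg = map_inputs(net.reverse(), method)
    return OutputConfiguration(sensor_nodes=cfg.driver_nodes,
                               assignment=cfg.assignment, method=method)


def build_model(net: DirectedNetwork,
                input_cfg: InputConfiguration,
                output_cfg: OutputConfiguration) -> StateSpaceModel:
    """Assemble the state-space sparsity patterns.

    ``A`` is the transpose of the network adjacency pattern; ``B[v][k] = 1``
    iff the input configuration assigns node v to column k; ``C`` dual;
    ``D`` zero.
    """
    n = net.n_nodes
    for v in list(input_cfg.assignment) + list(output_cfg.assignment):
        if v not in net:
            raise ValueError(f"configuration references unknown node {v!r}")
    A = net.adjacency_matrix().T
    B = np.zeros((n, input_cfg.n_inputs), dtype=np.int8)
    for v, k in input_cfg.assignment.items():
        B[net.index(v), k] = 1
    C = np.zeros((output_cfg.n_outputs, n), dtype=np.int8)
    for v, k in output_cfg.assignment.items():
        C[k, net.index(v)] = 1
    return StateSpaceModel(A, B, C, labels=list(net.labels))


def map_system(net: DirectedNetwork, method: str = "path_finding") -> StateSpaceModel:
    """One-call convenience: place inputs and outputs, build the model."""
    return build_model(net, map_inputs(net, method), map_outputs(net, method))
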