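"""Read and write directed networks in standard interchange formats.

Supported formats: dense adjacency matrices (comma- or whitespace-separated,
``M[i][j] != 0`` meaning edge i -> j, optional header row + label column),
two-column edge lists (TSV/whitespace, source target per line), Matrix
Market coordinate files, and GraphML.  Labels are kept as strings for file
formats that carry them; plain matrices without headers get labels 1..N.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import io as scipy_io
from scipy import sparse

from .graph_core import DirectedNetwork

FORMATS = ("adjacency-csv", "edgelist-tsv", "matrix-market", "graphml")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_adjacency(path: Path) -> DirectedNetwork:
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty file")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    sep = "," if "," in lines[0] else None
    rows = [[tok.strip() for tok in ln.split(sep)] for ln in lines]
    has_header = not all(_is_number(tok) for tok in rows[0])
    labels = None
    if has_header:
        header = rows[0]
        body = rows[1:]
        if not body:
            raise ValueError(f"{path}: header without matrix body")
        if len(body[0]) == len(header) + 1:
            # header lists N labels; body rows carry a leading label column
            labels = [r[0] for r in body]
            body = [r[1:] for r in body]
        elif header[0] == "" or (len(body[0]) == len(header)
                                 and not _is_number(body[0][0])):
            # corner cell before the header labels, or non-numeric row labels
            labels = [r[0] for r in body]
            body = [r[1:] for r in body]
        else:
            labels = header
    else:
        body = rows
    matrix = np.array([[float(tok) for tok in r] for r in body])
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: adjacency matrix must be square, got {matrix.shape}")
    if labels is None:
        labels = list(range(1, matrix.shape[0] + 1))
    return DirectedNetwork.from_adjacency(matrix, labels)


def _read_edgelist(path: Path) -> DirectedNetwork:
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty file")
    edges = []
    nodes: list[str] = []
    seen = set()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed edge list line {ln!r}")
        u, v = parts[0], parts[1]
        for w in (u, v):
            if w not in seen:
                seen.add(w)
                nodes.append(w)
        edges.append((u, v))
    return DirectedNetwork(nodes, edges)


def _read_matrix_market(path: Path) -> DirectedNetwork:
    m = scipy_io.mmread(str(path))
    m = sparse.coo_matrix(m)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: adjacency matrix must be square, got {m.shape}")
    return DirectedNetwork.from_adjacency(m)


def _read_graphml(path: Path) -> DirectedNetwork:
    g = nx.read_graphml(str(path))
    if not g.is_directed():
        g = g.to_directed()
    return DirectedNetwork(list(g.nodes()), list(g.edges()))


_READERS = {
    "adjacency-csv": _read_adjacency,
    "edgelist-tsv": _read_edgelist,
    "matrix-market": _read_matrix_market,
    "graphml": _read_graphml,
}


def read_network(path: str | Path, format: str = "edgelist-tsv") -> DirectedNetwork:
    """Read a directed network from *path* in the given *format*."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    net = _READERS[format](path)
    if net.n_nodes == 0:
        raise ValueError(f"{path}: empty network")
    return net


def write_network(net: DirectedNetwork, path: str | Path,
                  format: str = "edgelist-tsv") -> None:
    """Write *net* to *path*; round-trips losslessly with :func:`read_network`
    (labels become strings in label-carrying formats)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "adjacency-csv":
        m = net.adjacency_matrix()
        header = "," + ",".join(str(v) for v in net.labels)
        lines = [header]
        for i, v in enumerate(net.labels):
            lines.append(str(v) + "," + ",".join(str(int(x)) for x in m[i]))
        path.write_text("\n".join(lines) + "\n")
    elif format == "edgelist-tsv":
        lines = [f"{u}\t{v}" for u, v in
                 sorted((str(a), str(b)) for a, b in net.edges)]
        path.write_text("\n".join(lines) + "\n")
    elif format == "matrix-market":
        coo = sparse.coo_matrix(net.adjacency_matrix())
        scipy_io.mmwrite(str(path), coo, field="pattern")
    else:
        nx.write_graphml(net.to_networkx(), str(path))
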