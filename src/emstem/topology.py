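"""Circuit topologies for coupled EMT--stemness gene regulatory networks.

A circuit is a signed directed graph: nodes are gene products (transcription
factors, microRNA families collapsed to single species) and edges are
transcriptional/post-transcriptional activations or inhibitions.  Topologies
are read and written in the RACIPE ``.topo`` dialect: whitespace-delimited
``Source Target Type`` lines with ``Type`` 1 = activation, 2 = inhibition, and
an optional header line.

Six circuits are bundled: the core coupled EMT--stemness network (``base``,
miR-200/ZEB toggle + LIN28/let-7 toggle, coupled by the mutual microRNA
repressions miR-200 -| LIN28 and let-7 -| ZEB), a hypothetical ``uncoupled``
variant lacking both coupling links, and four variants adding one phenotypic
stability factor (PSF) each: ``grhl2``, ``grhl2_kd`` (GRHL2 without its
activation of miR-200), ``ovol``, and ``nrf2``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

ACTIVATION = 1
INHIBITION = -1

_TYPE_TO_SIGN = {1: ACTIVATION, 2: INHIBITION}
_SIGN_TO_TYPE = {ACTIVATION: 1, INHIBITION: 2}

#: The six circuits shipped with the package.
BUILTIN_CIRCUITS = ("base", "uncoupled", "grhl2", "grhl2_kd", "ovol", "nrf2")

#: Features used for phenotype clustering (the two coupled toggle switches).
CORE_NODES = ("miR200", "ZEB", "LIN28", "let7")

#: All nodes of the base circuit, in canonical state-vector order.
BASE_NODES = ("miR200", "ZEB", "SNAIL", "LIN28", "let7", "NFkB")


class TopologyError(ValueError):
    """Malformed ``.topo`` input or invalid circuit definition."""


@dataclass(frozen=True)
class Edge:
    """A signed regulatory link ``source -> target``.

    ``sign`` is :data:`ACTIVATION` (+1) or :data:`INHIBITION` (-1).
    Self-edges (``source == target``) are allowed.
    """

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise TopologyError(
                f"edge {self.source}->{self.target}: sign must be "
                f"{ACTIVATION} (activation) or {INHIBITION} (inhibition), got {self.sign}"
            )

    @property
    def is_activation(self) -> bool:
        return self.sign == ACTIVATION

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        arrow = "->" if self.is_activation else "-|"
        return f"{self.source}{arrow}{self.target}"


@dataclass(frozen=True)
class NetworkTopology:
    """A named circuit: ordered nodes plus signed directed edges.

    Node order is fixed and determines the layout of every state vector,
    parameter array, and solution-table column downstream.
    """

    name: str
    nodes: Tuple[str, ...]
    edges: Tuple[Edge, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise TopologyError(f"unknown node {node!r} in circuit {self.name!r}") from None

    def incoming(self, node: str) -> Tuple[Edge, ...]:
        """Edges targeting ``node``, in edge-list order."""
        return tuple(e for e in self.edges if e.target == node)

    def find_edge(self, source: str, target: str) -> Optional[Edge]:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def edge_index(self, source: str, target: str) -> int:
        for i, e in enumerate(self.edges):
            if e.source == source and e.target == target:
                return i
        raise TopologyError(f"no edge {source}->{target} in circuit {self.name!r}")

    def edge_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(src, dst, sign)`` integer arrays in edge-list order."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        src = np.array([idx[e.source] for e in self.edges], dtype=np.int64)
        dst = np.array([idx[e.target] for e in self.edges], dtype=np.int64)
        sign = np.array([e.sign for e in self.edges], dtype=np.int64)
        return src, dst, sign

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"NetworkTopology({self.name!r}: {self.n_nodes} nodes, {self.n_edges} edges)"


def loads_topology(text: str, name: str = "circuit") -> NetworkTopology:
    """Parse ``.topo`` text. Nodes are inferred in first-appearance order."""
    nodes: List[str] = []
    edges: List[Edge] = []
    seen_pairs = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if lineno == 1 and [f.lower() for f in fields[:3]] == ["source", "target", "type"]:
            continue  # tolerated header
        if len(fields) != 3:
            raise TopologyError(
                f"line {lineno}: expected 3 whitespace-delimited fields, got {len(fields)}: {raw!r}"
            )
        source, target, type_code = fields
        try:
            code = int(type_code)
        except ValueError:
            raise TopologyError(f"line {lineno}: Type must be an integer, got {type_code!r}") from None
        if code not in _TYPE_TO_SIGN:
            raise TopologyError(f"line {lineno}: unknown Type code {code} (expected 1 or 2)")
        for n in (source, target):
            if n not in nodes:
                nodes.append(n)
        if (source, target) in seen_pairs:
            raise TopologyError(f"line {lineno}: duplicate edge {source}->{target}")
        seen_pairs.add((source, target))
        edges.append(Edge(source, target, _TYPE_TO_SIGN[code]))
    if not edges:
        raise TopologyError("no edges found (empty topology)")
    return NetworkTopology(name=name, nodes=tuple(nodes), edges=tuple(edges))


def load_topology(path: os.PathLike | str, name: Optional[str] = None) -> NetworkTopology:
    """Load a circuit from a ``.topo`` file.

    The circuit name defaults to the file stem.  Round-trips with
    :func:`save_topology` up to header canonicalization.
    """
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return loads_topology(text, name=name)


def dumps_topology(t: NetworkTopology) -> str:
    """Serialize to canonical ``.topo`` text (header always written)."""
    lines = ["Source Target Type"]
    for e in t.edges:
        lines.append(f"{e.source} {e.target} {_SIGN_TO_TYPE[e.sign]}")
    return "\n".join(lines) + "\n"


def save_topology(t: NetworkTopology, path: os.PathLike | str) -> None:
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(dumps_topology(t))


def builtin_circuit(name: str) -> NetworkTopology:
    """Return one of the six bundled circuits by name.

    Valid names: ``base``, ``uncoupled``, ``grhl2``, ``grhl2_kd``, ``ovol``,
    ``nrf2``.  Node order is the canonical one (miR200, ZEB, SNAIL, LIN28,
    let7, NFkB, then the PSF node if present).
    """
    if name not in BUILTIN_CIRCUITS:
        raise TopologyError(
            f"unknown builtin circuit {name!r}; valid names: {', '.join(BUILTIN_CIRCUITS)}"
        )
    text = (resources.files("emstem") / "circuits" / f"{name}.topo").read_text(encoding="utf-8")
    return loads_topology(text, name=name)


def validate_topology(t: NetworkTopology) -> List[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    diagnostics: List[str] = []
    if len(set(t.nodes)) != len(t.nodes):
        dupes = sorted({n for n in t.nodes if t.nodes.count(n) > 1})
        diagnostics.append(f"duplicate node names: {', '.join(dupes)}")
    if not t.edges:
        diagnostics.append("no edges")
    declared = set(t.nodes)
    seen_pairs = set()
    for e in t.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in declared:
                diagnostics.append(f"unknown node {endpoint!r} referenced by edge {e}")
        pair = (e.source, e.target)
        if pair in seen_pairs:
            diagnostics.append(f"duplicate edge {e.source}->{e.target}")
        seen_pairs.add(pair)
    return diagnostics
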