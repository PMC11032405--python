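"""ASCII DIMACS clique-format reader/writer with a vertex-weight dialect.

The classic format: comment lines ``c ...``, one problem line
``p edge <n> <m>`` (``p col`` accepted as a synonym), and edge lines
``e <i> <j>`` with 1-based endpoints. Vertex weights use ``v <i> <w>``
lines, the convention circulating with weighted-clique benchmark sets;
files without ``v`` lines are valid and every weight defaults to 1.
"""

from __future__ import annotations

import io
from typing import TextIO, Union

from .graph import WeightedGraph, build_graph


class DimacsParseError(ValueError):
    """Malformed DIMACS input; message names the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_dimacs(source: Union[str, TextIO]) -> WeightedGraph:
    """Parse a DIMACS clique file into a :class:`WeightedGraph`.

    Accepts a string or a text stream. Vertex ids are converted to the
    internal 0-based convention; duplicate edge lines (either orientation)
    are ignored. Vertices without a ``v`` line get weight 1.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    n = None
    declared_m = None
    edges: list[tuple[int, int]] = []
    weights: dict[int, int] = {}
    for lineno, raw in enumerate(source, start=1):
        tokens = raw.split()
        if not tokens or tokens[0] == "c":
            continue
        kind = tokens[0]
        if kind == "p":
            if n is not None:
                raise DimacsParseError(lineno, "duplicate problem line")
            if len(tokens) != 4 or tokens[1] not in ("edge", "col"):
                raise DimacsParseError(
                    lineno, f"expected 'p edge <n> <m>', got {raw.strip()!r}"
                )
            try:
                n = int(tokens[2])
                declared_m = int(tokens[3])
            except ValueError:
                raise DimacsParseError(lineno, "non-integer counts on problem line")
            if n < 1:
                raise DimacsParseError(lineno, f"vertex count must be >= 1, got {n}")
        elif kind == "e":
            if n is None:
                raise DimacsParseError(lineno, "edge line before problem line")
            if len(tokens) != 3:
                raise DimacsParseError(lineno, f"malformed edge line {raw.strip()!r}")
            try:
                i, j = int(tokens[1]), int(tokens[2])
            except ValueError:
                raise DimacsParseError(lineno, "non-integer edge endpoint")
            if not (1 <= i <= n and 1 <= j <= n):
                raise DimacsParseError(
                    lineno, f"edge endpoint out of range 1..{n}: e {i} {j}"
                )
            if i == j:
                raise DimacsParseError(lineno, f"self-loop on vertex {i}")
            edges.append((i - 1, j - 1))
        elif kind == "v":
            if n is None:
                raise DimacsParseError(lineno, "weight line before problem line")
            if len(tokens) != 3:
                raise DimacsParseError(lineno, f"malformed weight line {raw.strip()!r}")
            try:
                i, w = int(tokens[1]), int(tokens[2])
            except ValueError:
                raise DimacsParseError(lineno, "non-integer weight line field")
            if not 1 <= i <= n:
                raise DimacsParseError(lineno, f"weight vertex out of range 1..{n}")
            if w < 1:
                raise DimacsParseError(lineno, f"weight must be >= 1, got {w}")
            if i - 1 in weights:
                raise DimacsParseError(lineno, f"duplicate weight line for vertex {i}")
            weights[i - 1] = w
        else:
            raise DimacsParseError(lineno, f"unknown line type {kind!r}")
    if n is None:
        raise DimacsParseError(0, "missing problem line")
    weight_vec = [weights.get(v, 1) for v in range(n)]
    return build_graph(n, edges, weight_vec)


def write_dimacs(G: WeightedGraph, stream: Union[TextIO, None] = None) -> str:
    """Serialize a graph: problem line, ``e`` lines (i < j), ``v`` lines.

    ``read_dimacs(write_dimacs(G))`` reproduces (n, edge set, weights)
    exactly.
    """
    out = io.StringIO()
    edges = list(G.edges())
    out.write(f"p edge {G.n} {len(edges)}\n")
    for i, j in edges:
        out.write(f"e {i + 1} {j + 1}\n")
    for v in range(G.n):
        out.write(f"v {v + 1} {G.weights[v]}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
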