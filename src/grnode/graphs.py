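"""Signed directed graphs over genes.

A gene regulatory graph at the coarsest level of abstraction is a directed
graph on genes ``1..n`` whose edges carry a sign: ``+1`` for activation,
``-1`` for repression.  This module provides the in-memory data model and a
plain-text edge-list format (``source<TAB>target<TAB>sign``) used everywhere
else in the package.

Gene indices are 1-based throughout, matching the standard set notation
``[n] = {1, ..., n}`` used for regulatory networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "SignedDigraph",
    "read_signed_graph",
    "write_signed_graph",
    "flowering_graph",
    "flowering_graph_minus",
    "repressilator_graph",
]

_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1,
    "-": -1, "-1": -1,
    "−": -1, "−1": -1,  # unicode minus
}


@dataclass(frozen=True)
class SignedDigraph:
    """A directed graph on genes ``1..n_vertices`` with signed edges.

    Parameters
    ----------
    n_vertices
        Number of genes (vertices).
    sign
        Mapping ``(i, j) -> {+1, -1}`` over the edge set; an edge ``(i, j)``
        means gene *i* regulates gene *j*.
    labels
        Optional gene names keyed by 1-based index.
    """

    n_vertices: int
    sign: Mapping[tuple[int, int], int]
    labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError("graph must have at least one vertex")
        object.__setattr__(self, "sign", dict(self.sign))
        object.__setattr__(self, "labels", dict(self.labels))
        for (i, j), b in self.sign.items():
            if i == j:
                raise ValueError(f"self-loop on gene {i} is not allowed")
            for v in (i, j):
                if not (1 <= v <= self.n_vertices):
                    raise ValueError(
                        f"edge ({i}, {j}) references gene {v} outside "
                        f"[1, {self.n_vertices}]"
                    )
            if b not in (1, -1):
                raise ValueError(f"edge ({i}, {j}) has invalid sign {b!r}")

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self.sign)

    @property
    def n_edges(self) -> int:
        return len(self.sign)

    def regulators(self, j: int) -> set[int]:
        """Set of transcription factors of gene *j*: ``{i : (i, j) in E}``."""
        if not (1 <= j <= self.n_vertices):
            raise ValueError(f"gene index {j} outside [1, {self.n_vertices}]")
        return {i for (i, jj) in self.sign if jj == j}

    def targets(self, i: int) -> set[int]:
        """Genes regulated by gene *i*."""
        if not (1 <= i <= self.n_vertices):
            raise ValueError(f"gene index {i} outside [1, {self.n_vertices}]")
        return {j for (ii, j) in self.sign if ii == i}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return (
            self.n_vertices == other.n_vertices
            and dict(self.sign) == dict(other.sign)
        )

    def __hash__(self) -> int:
        return hash((self.n_vertices, frozenset(self.sign.items())))


def regulators(g: SignedDigraph, j: int) -> set[int]:
    """Module-level alias for :meth:`SignedDigraph.regulators`."""
    return g.regulators(j)


def _parse_sign(token: str, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[token.strip()]
    except KeyError:
        raise ValueError(f"line {lineno}: malformed sign token {token!r}") from None


def read_signed_graph(path: str | Path) -> SignedDigraph:
    """Read a signed edge list.

    The format is TSV with columns ``source``, ``target``, ``sign`` and an
    optional fourth column naming the source gene.  Sign tokens ``+``, ``+1``
    and ``1`` map to ``+1``; ``-`` and ``-1`` map to ``-1``.  An optional
    header line ``#n=<int>`` declares the vertex count (otherwise the largest
    index seen is used).  Duplicate edges with conflicting signs and
    self-loops are errors.
    """
    path = Path(path)
    sign: dict[tuple[int, int], int] = {}
    labels: dict[int, str] = {}
    declared_n: int | None = None
    max_seen = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    declared_n = int(body[2:])
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated columns")
            i, j = int(parts[0]), int(parts[1])
            b = _parse_sign(parts[2], lineno)
            if i == j:
                raise ValueError(f"line {lineno}: self-loop on gene {i}")
            if (i, j) in sign and sign[(i, j)] != b:
                raise ValueError(
                    f"line {lineno}: duplicate edge ({i}, {j}) with conflicting sign"
                )
            sign[(i, j)] = b
            if len(parts) >= 4 and parts[3].strip():
                labels[i] = parts[3].strip()
            max_seen = max(max_seen, i, j)
    n = declared_n if declared_n is not None else max_seen
    if n < 1:
        raise ValueError(f"{path}: no vertices (empty file without '#n=' header)")
    return SignedDigraph(n_vertices=n, sign=sign, labels=labels)


def write_signed_graph(g: SignedDigraph, path: str | Path) -> None:
    """Write a graph in the edge-list format read by :func:`read_signed_graph`.

    ``read_signed_graph(write_signed_graph(g)) == g`` for every valid graph.
    """
    path = Path(path)
    lines = [f"#n={g.n_vertices}"]
    for (i, j) in sorted(g.sign):
        b = "+1" if g.sign[(i, j)] > 0 else "-1"
        name = g.labels.get(i, "")
        lines.append(f"{i}\t{j}\t{b}" + (f"\t{name}" if name else ""))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Built-in case-study graphs
# ---------------------------------------------------------------------------

#: Gene order of the five-gene soybean flowering network.
FLOWERING_GENES = {1: "E1", 2: "COL1a", 3: "FT4", 4: "FT2a", 5: "AP1a"}


def flowering_graph() -> SignedDigraph:
    """Five-gene core soybean flowering network, COL1a activating E1.

    Edges: E1 -> COL1a (+), E1 -> FT4 (+), COL1a -> E1 (+), COL1a -> FT4 (+),
    COL1a -| FT2a (-), FT4 -| AP1a (-), FT2a -> AP1a (+).
    """
    return SignedDigraph(
        n_vertices=5,
        sign={
            (1, 2): 1, (1, 3): 1, (2, 1): 1, (2, 3): 1,
            (2, 4): -1, (3, 5): -1, (4, 5): 1,
        },
        labels=FLOWERING_GENES,
    )


def flowering_graph_minus() -> SignedDigraph:
    """Flowering-network variant with COL1a repressing E1 (edge 2->1 is -)."""
    g = flowering_graph()
    sign = dict(g.sign)
    sign[(2, 1)] = -1
    return SignedDigraph(n_vertices=5, sign=sign, labels=FLOWERING_GENES)


def repressilator_graph() -> SignedDigraph:
    """Five-gene repressilator: 3 -| 1 -| 2 -| 5 -| 4 -| 3 (all repressing)."""
    return SignedDigraph(
        n_vertices=5,
        sign={(3, 1): -1, (1, 2): -1, (4, 3): -1, (5, 4): -1, (2, 5): -1},
    )
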