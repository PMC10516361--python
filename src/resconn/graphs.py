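"""Unipartite/bipartite connection graph templates and their realization.

A protein sequence of length ``L`` is viewed as a graph whose vertices are
residue positions (1-based).  Around a residue of interest, or around each
member of a residue pair of interest, a window of half-width ``w`` defines a
region of ``2w + 1`` residues.  Connections between two residues of the same
region are *local* residue-residue connections (LocRRCs); connections between
a residue of one region and a residue of the other region are *global*
residue-residue connections (GlobRRCs).

Which of the possible connections are realized is governed by a graph
template.  Bipartite templates (``patch``, ``memconp``, ``cross``, or custom)
are sets of integer offset pairs ``(a, b)``: for a central pair ``(p, q)``
the realized connection is ``(p + a, q + b)``.  Unipartite templates are
sets of ordered window-slot pairs in ``0 .. 2w``; the ``complete`` template
connects every ordered pair of distinct slots.

Connections whose ends fall outside ``1 .. L`` are kept with a ``None``
placeholder end, so every realized list has a fixed, template-determined
length -- convenient for fixed-width feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

#: Placeholder for a connection end that falls outside the sequence.
OUT_OF_RANGE = None

Offset = Tuple[int, int]
End = Optional[int]
Connection = Tuple[End, End]

#: The helix-packing bipartite template: offsets between two face-to-face
#: transmembrane helices used in helix-helix contact prediction, with the
#: heptad-like periodicity of an alpha-helix (steps of 1, 3 and 4 positions).
MEMCONP_OFFSETS: Tuple[Offset, ...] = (
    (0, 0), (0, 1), (0, -1), (0, 3), (0, -3), (0, 4), (0, -4),
    (1, 0), (-1, 0), (3, 0), (-3, 0),
    (3, 4), (-3, 4), (3, -4), (-3, -4),
    (4, 0), (-4, 0), (4, 3), (-4, 3), (4, -3), (-4, -3),
    (4, 4), (-4, 4), (4, -4), (-4, -4),
)


@dataclass(frozen=True)
class BipartiteGraphSpec:
    """A bipartite connection template given as offsets around a central pair.

    ``offsets`` is an ordered, duplicate-free tuple of ``(a, b)`` integer
    pairs; realizing the template at central pair ``(p, q)`` yields the
    connections ``(p + a, q + b)`` in offset order.  ``t`` is the edge count.
    """

    name: str
    offsets: Tuple[Offset, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) == 0:
            raise ValueError("a bipartite graph needs at least one offset")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("duplicate offsets in bipartite graph spec")

    @property
    def t(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class UnipartiteGraphSpec:
    """A unipartite template as ordered pairs of window-slot coordinates.

    Slots index the window positions ``0 .. 2w`` around a central residue
    (slot ``w`` is the center).  Self-edges are rejected.
    """

    name: str
    slot_edges: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        for si, sj in self.slot_edges:
            if si == sj:
                raise ValueError(f"self-edge ({si}, {sj}) not allowed")
        if len(set(self.slot_edges)) != len(self.slot_edges):
            raise ValueError("duplicate slot edges in unipartite graph spec")


@dataclass(frozen=True)
class ConnectionList:
    """Realized connections for one central residue or central pair.

    ``center`` is either a single 1-based residue index or a ``(p, q)``
    pair; ``connections`` is the ordered tuple of realized ``(i, j)``
    connections, with ``None`` marking an out-of-range end.
    """

    center: Union[int, Tuple[int, int]]
    connections: Tuple[Connection, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.connections)

    def __iter__(self):
        return iter(self.connections)


def make_patch(w: int) -> BipartiteGraphSpec:
    """Square patch template: all offsets ``(a, b)`` with ``|a|, |b| <= w``.

    The realized connections cover a ``(2w+1) x (2w+1)`` square of the
    contact map centered on the pair of interest; ``t = (2w+1)**2``.
    Offsets are ordered lexicographically.
    """
    if w < 0:
        raise ValueError(f"window half-width must be >= 0, got {w}")
    offsets = tuple(
        (a, b) for a in range(-w, w + 1) for b in range(-w, w + 1)
    )
    return BipartiteGraphSpec(name="patch", offsets=offsets)


def make_memconp() -> BipartiteGraphSpec:
    """The fixed 25-offset helix-packing template (see ``MEMCONP_OFFSETS``)."""
    return BipartiteGraphSpec(name="memconp", offsets=MEMCONP_OFFSETS)


def make_cross(w: int) -> BipartiteGraphSpec:
    """Cross template: the central row plus central column of a patch.

    Offsets ``(a, 0)`` for ``|a| <= w`` and ``(0, b)`` for ``|b| <= w``,
    deduplicated at the center; ``t = 4w + 1``.
    """
    if w < 0:
        raise ValueError(f"window half-width must be >= 0, got {w}")
    offsets = [(a, 0) for a in range(-w, w + 1)]
    offsets += [(0, b) for b in range(-w, w + 1) if b != 0]
    offsets.sort()
    return BipartiteGraphSpec(name="cross", offsets=tuple(offsets))


def complete_unipartite(w: int) -> UnipartiteGraphSpec:
    """Fully connected unipartite template over the ``2w + 1`` window slots.

    All ordered pairs of distinct slots, sorted by ``(slot_i, slot_j)``:
    ``(2w)(2w+1)`` edges.  With ``w = 0`` the window holds only the center
    and the edge set is empty.
    """
    if w < 0:
        raise ValueError(f"window half-width must be >= 0, got {w}")
    n = 2 * w + 1
    edges = tuple(
        (i, j) for i in range(n) for j in range(n) if i != j
    )
    return UnipartiteGraphSpec(name="complete", slot_edges=edges)


def _clip(pos: int, L: int) -> End:
    return pos if 1 <= pos <= L else OUT_OF_RANGE


def build_globrrcs(
    pair: Tuple[int, int],
    graph: BipartiteGraphSpec,
    L: int,
) -> ConnectionList:
    """Realize a bipartite template at a central residue pair.

    Every offset ``(a, b)`` yields the connection ``(p + a, q + b)``; ends
    outside ``1 .. L`` become placeholders, and a connection whose two ends
    resolve to the same residue (possible only for near-degenerate pairs)
    is emitted fully placeholdered, so the result always has ``graph.t``
    entries in template order.
    """
    p, q = pair
    if not (1 <= p < q <= L):
        raise ValueError(f"central pair {pair} not within 1..{L} with p < q")
    conns = []
    for a, b in graph.offsets:
        i, j = _clip(p + a, L), _clip(q + b, L)
        if i is not OUT_OF_RANGE and i == j:
            # both windows hit the same residue: no self-connection
            conns.append((OUT_OF_RANGE, OUT_OF_RANGE))
        else:
            conns.append((i, j))
    return ConnectionList(center=(p, q), connections=tuple(conns))


def build_locrrcs(
    center: int,
    w: int,
    graph: UnipartiteGraphSpec,
    L: int,
) -> ConnectionList:
    """Realize a unipartite template in the window around one residue.

    Window slot ``s`` (``0 .. 2w``) maps to residue ``center - w + s``;
    slot edges become residue connections, with out-of-range slots as
    placeholders.  For the complete template the list has ``(2w)(2w+1)``
    entries.
    """
    if not (1 <= center <= L):
        raise ValueError(f"center {center} not within 1..{L}")
    if w < 0:
        raise ValueError(f"window half-width must be >= 0, got {w}")
    n_slots = 2 * w + 1
    conns = []
    for si, sj in graph.slot_edges:
        if not (0 <= si < n_slots and 0 <= sj < n_slots):
            raise ValueError(
                f"slot edge ({si}, {sj}) outside window slots 0..{n_slots - 1}"
            )
        conns.append((_clip(center - w + si, L), _clip(center - w + sj, L)))
    return ConnectionList(center=center, connections=tuple(conns))


def enumerate_pairs(L: int, min_sep: int = 1) -> list[Tuple[int, int]]:
    """All residue pairs ``(p, q)`` with ``q - p >= min_sep``, in (p, q) order.

    At ``min_sep = 1`` this is every unordered pair: ``L(L-1)/2`` of them.
    """
    if L < 2:
        raise ValueError(f"sequence length must be >= 2, got {L}")
    if min_sep < 1:
        raise ValueError(f"minimum separation must be >= 1, got {min_sep}")
    return [(p, q) for p in range(1, L + 1) for q in range(p + min_sep, L + 1)]


def load_graph_config(
    path: Union[str, Path],
    kind: str = "bipartite",
    name: str = "custom",
) -> Union[BipartiteGraphSpec, UnipartiteGraphSpec]:
    """Load a custom graph template from a plain-text config.

    One pair per line, whitespace-separated: ``a b`` offsets for a
    bipartite template or ``slot_i slot_j`` coordinates for a unipartite
    one.  ``#`` starts a comment; blank lines are ignored.
    """
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two integers, got {raw!r}")
        try:
            pairs.append((int(fields[0]), int(fields[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field in {raw!r}") from exc
    if kind == "bipartite":
        return BipartiteGraphSpec(name=name, offsets=tuple(pairs))
    if kind == "unipartite":
        return UnipartiteGraphSpec(name=name, slot_edges=tuple(pairs))
    raise ValueError(f"unknown graph kind {kind!r}")
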