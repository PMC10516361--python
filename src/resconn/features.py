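"""Correlation-matrix lookup, feature assignment and the cumuCC score.

The feature source is a symmetric per-pair score table (typically
coevolutionary couplings such as FreeContact/EVfold output).  It is held as
a hash table keyed on the unordered residue-index pair, so a single lookup
costs O(1) and assigning features to ``n`` centers under a fixed graph
template costs O(n) in the number of lookups.

Two assignment routes are provided with identical contracts:

* :func:`assign_hash` generates each center's connections on the fly and
  looks the values up directly -- no whole-corpus connection object exists.
* :func:`assign_materialized` first builds the full 3D connection object
  (centers x connections x 2 ends), then performs the same lookups.  It is
  the slower reference route; the two must agree element-wise.

:func:`cumucc` computes a per-residue cumulative correlation coefficient:
the sum of the globally top-``k`` pair scores that involve the residue,
normalized by the matrix mean over all unordered pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from resconn.graphs import (
    BipartiteGraphSpec,
    ConnectionList,
    UnipartiteGraphSpec,
    build_globrrcs,
    build_locrrcs,
)

logger = logging.getLogger(__name__)


class CorrelationMatrix:
    """Symmetric L x L residue-pair score table with O(1) keyed lookup.

    Scores are stored once per unordered pair ``(i, j)``, ``i < j``; access
    is symmetric and absent pairs (including the diagonal) read as 0.0.
    ``lookups`` counts calls to :meth:`value`, which lets scaling tests
    count operations instead of timing them.
    """

    def __init__(self, L: int, values: Optional[dict[Tuple[int, int], float]] = None):
        if L < 1:
            raise ValueError(f"sequence length must be >= 1, got {L}")
        self.L = L
        self._values: dict[Tuple[int, int], float] = {}
        self.lookups = 0
        if values:
            for (i, j), v in values.items():
                self.set(i, j, v)

    def _key(self, i: int, j: int) -> Tuple[int, int]:
        if not (1 <= i <= self.L and 1 <= j <= self.L):
            raise ValueError(f"pair ({i}, {j}) outside 1..{self.L}")
        return (i, j) if i < j else (j, i)

    def set(self, i: int, j: int, score: float) -> None:
        if i == j:
            raise ValueError(f"diagonal entry ({i}, {i}) not storable")
        self._values[self._key(i, j)] = float(score)

    def value(self, i: int, j: int) -> float:
        """Symmetric O(1) lookup; diagonal and absent pairs are 0.0."""
        self.lookups += 1
        if i == j:
            return 0.0
        return self._values.get(self._key(i, j), 0.0)

    def items(self) -> Iterable[Tuple[Tuple[int, int], float]]:
        return self._values.items()

    def __len__(self) -> int:
        return len(self._values)


def load_correlation_matrix(
    path: Union[str, Path],
    L: int,
    score_column: int = 0,
) -> CorrelationMatrix:
    """Read a whitespace-delimited pair-score file into a matrix.

    Two dialects are auto-detected by column count: 3-column ``i j score``
    and 5+-column FreeContact-style ``i aa_i j aa_j score...``.
    ``score_column`` selects among multiple score columns (0-based within
    the score block).  Duplicate pairs keep the last value with a warning;
    1-based indices outside ``1..L`` and self-pairs are format errors.
    """
    matrix = CorrelationMatrix(L)
    seen: set[Tuple[int, int]] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
        if len(fields) >= 5:
            i_str, j_str, scores = fields[0], fields[2], fields[4:]
        else:
            i_str, j_str, scores = fields[0], fields[1], fields[2:]
        try:
            i, j = int(i_str), int(j_str)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer residue index") from exc
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"{path}:{lineno}: index pair ({i}, {j}) outside 1..{L}")
        if i == j:
            raise ValueError(f"{path}:{lineno}: self-pair ({i}, {i}) rejected")
        if score_column >= len(scores):
            raise ValueError(f"{path}:{lineno}: score column {score_column} missing")
        try:
            score = float(scores[score_column])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
        key = (i, j) if i < j else (j, i)
        if key in seen:
            logger.warning("%s:%d: duplicate pair %s, keeping last value", path, lineno, key)
        seen.add(key)
        matrix.set(i, j, score)
    return matrix


@dataclass
class FeatureTable:
    """Rectangular feature matrix: one row per center, one column per edge."""

    centers: list
    values: np.ndarray
    placeholder_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-dimensional")
        if self.values.shape[0] != len(self.centers):
            raise ValueError("row count must equal number of centers")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        ncols = self.values.shape[1]
        cols = [f"f_{k:03d}" for k in range(ncols)]
        df = pd.DataFrame(self.values, columns=cols)
        first = self.centers[0] if self.centers else None
        if isinstance(first, tuple):
            df.insert(0, "q", [c[1] for c in self.centers])
            df.insert(0, "p", [c[0] for c in self.centers])
        else:
            df.insert(0, "residue", list(self.centers))
        return df

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


GraphSpec = Union[BipartiteGraphSpec, UnipartiteGraphSpec]


def _realize(center, graph: GraphSpec, w: int, L: int) -> ConnectionList:
    if isinstance(graph, BipartiteGraphSpec):
        return build_globrrcs(center, graph, L)
    return build_locrrcs(center, w, graph, L)


def _n_columns(graph: GraphSpec) -> int:
    if isinstance(graph, BipartiteGraphSpec):
        return graph.t
    return len(graph.slot_edges)


def _check_centers(centers: Sequence, matrix: CorrelationMatrix) -> None:
    for c in centers:
        hi = max(c) if isinstance(c, tuple) else c
        if hi > matrix.L:
            raise ValueError(
                f"center {c} implies sequence length > matrix dimension {matrix.L}"
            )


def assign_hash(
    centers: Sequence,
    graph: GraphSpec,
    matrix: CorrelationMatrix,
    placeholder_value: float = 0.0,
    w: int = 0,
) -> FeatureTable:
    """Assign matrix values to each center's connections by direct lookup.

    Connections are generated per center and consumed immediately; no
    intermediate object holding all centers' connections is built.  The
    lookup count therefore grows linearly in the number of centers for a
    fixed graph template.
    """
    _check_centers(centers, matrix)
    ncols = _n_columns(graph)
    out = np.empty((len(centers), ncols), dtype=float)
    for r, center in enumerate(centers):
        for k, (i, j) in enumerate(_realize(center, graph, w, matrix.L)):
            if i is None or j is None:
                out[r, k] = placeholder_value
            else:
                out[r, k] = matrix.value(i, j)
    return FeatureTable(centers=list(centers), values=out,
                        placeholder_value=placeholder_value)


def assign_materialized(
    centers: Sequence,
    graph: GraphSpec,
    matrix: CorrelationMatrix,
    placeholder_value: float = 0.0,
    w: int = 0,
) -> FeatureTable:
    """Reference assignment route through a fully materialized 3D object.

    Builds the complete centers x connections x 2 structure first, then
    walks it performing the same lookups as :func:`assign_hash`.  Exists to
    cross-check the direct route (and to measure its overhead); outputs are
    element-wise identical by contract.
    """
    _check_centers(centers, matrix)
    ncols = _n_columns(graph)
    # full 3D connection object: [center][edge] -> (i, j)
    corpus = [list(_realize(center, graph, w, matrix.L)) for center in centers]
    out = np.empty((len(centers), ncols), dtype=float)
    for r, conns in enumerate(corpus):
        for k, (i, j) in enumerate(conns):
            if i is None or j is None:
                out[r, k] = placeholder_value
            else:
                out[r, k] = matrix.value(i, j)
    return FeatureTable(centers=list(centers), values=out,
                        placeholder_value=placeholder_value)


@dataclass
class CumuCCResult:
    """Per-residue cumulative correlation coefficients.

    ``scores[R - 1]`` is residue R's share of the top-``k_used`` pair
    scores divided by the normalization constant ``c`` (the matrix mean
    over all unordered pairs).
    """

    scores: np.ndarray
    k_used: int
    c: float


def cumucc(
    matrix: CorrelationMatrix,
    L: Optional[int] = None,
    ratio: float = 1.0,
    per_residue: bool = False,
) -> CumuCCResult:
    """Cumulative correlation coefficient of every residue.

    ``k = max(1, floor(ratio * L))``, capped at the pair count
    ``L(L-1)/2``.  The ``k`` highest-scoring unordered pairs are selected
    globally (ties broken by ascending ``(i, j)``); residue R's raw score
    ``CC_R`` is the sum of selected-pair scores over pairs containing R,
    and the reported score is ``CC_R / c`` with ``c`` the mean matrix value
    over all ``L(L-1)/2`` unordered pairs (diagonal excluded).

    With ``per_residue=True`` the selection is instead the ``k`` highest
    partner scores of each residue separately (a non-default variant).

    Raises if ``c == 0`` (normalization undefined, e.g. all-zero matrix).
    """
    if L is None:
        L = matrix.L
    if not (2 <= L <= matrix.L):
        raise ValueError(f"L must be in 2..{matrix.L}, got {L}")
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    n_pairs = L * (L - 1) // 2
    k_used = min(max(1, math.floor(ratio * L)), n_pairs)

    stored = {ij: v for ij, v in matrix.items() if ij[1] <= L}
    total = sum(stored.values())
    c = total / n_pairs
    if c == 0:
        raise ZeroDivisionError(
            "normalization constant c is 0 (matrix sums to zero)"
        )

    cc = np.zeros(L, dtype=float)
    if per_residue:
        partners: list[list[float]] = [[] for _ in range(L)]
        for (i, j), v in stored.items():
            partners[i - 1].append(v)
            partners[j - 1].append(v)
        k_res = min(k_used, L - 1)
        for r in range(L):
            vals = sorted(partners[r], reverse=True)[:k_res]
            cc[r] = sum(vals)
    else:
        # explicit zero entries matter for top-k when scores are negative,
        # so rank over all unordered pairs, absent ones at 0.0
        ranked = sorted(
            ((i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)),
            key=lambda ij: (-stored.get(ij, 0.0), ij),
        )
        for i, j in ranked[:k_used]:
            v = stored.get((i, j), 0.0)
            cc[i - 1] += v
            cc[j - 1] += v
    return CumuCCResult(scores=cc / c, k_used=k_used, c=c)
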