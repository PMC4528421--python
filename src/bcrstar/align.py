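"""Affine-gap local alignment (Smith-Waterman, three-matrix Gotoh DP).

Scoring: ``match`` (> 0) for identical bases, ``mismatch`` (< 0) otherwise;
a gap of length k costs ``gap_open + k * gap_extend``.  Traceback is
deterministic: on ties the diagonal move is preferred over the vertical
(query-consuming) move over the horizontal, and the best cell with the
smallest (i, j) is used as the local end point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

NEG = -10 ** 9


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment: score, half-open intervals, and aligned columns.

    ``pairs`` is a list of (query_index, reference_index) with ``None`` on
    the gapped side of a column.
    """

    score: float
    query_interval: tuple[int, int]
    reference_interval: tuple[int, int]
    pairs: tuple[tuple[int | None, int | None], ...]

    @property
    def n_matches(self) -> int:
        return sum(1 for q, r in self.pairs if q is not None and r is not None)


@njit(cache=True)
def _fill(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = q.shape[0], r.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # horizontal: gap in query
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # vertical: gap in reference
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            F[i, j] = f if f > fo else fo
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


_fill_py = _fill.py_func if _HAVE_NUMBA else _fill


def smith_waterman_affine(
    query: str,
    reference: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``reference``.

    Returns the empty alignment with score 0 when no positive-scoring cell
    exists.  Sequences must be non-empty.
    """
    if not query or not reference:
        raise ValueError("smith_waterman_affine requires non-empty sequences")
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    H, E, F = _fill(q, r, match, mismatch, gap_open, gap_extend)
    score = int(H.max())
    if score == 0:
        return AlignmentResult(0.0, (0, 0), (0, 0), ())
    flat = int(np.argmax(H))  # first maximum in row-major order: smallest (i, j)
    i, j = divmod(flat, H.shape[1])
    pairs: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = match if q[i - 1] == r[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            pairs.append((i - 1, None))
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
        else:  # E
            pairs.append((None, j - 1))
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
    pairs.reverse()
    qpos = [p[0] for p in pairs if p[0] is not None]
    rpos = [p[1] for p in pairs if p[1] is not None]
    return AlignmentResult(
        score=float(score),
        query_interval=(qpos[0], qpos[-1] + 1),
        reference_interval=(rpos[0], rpos[-1] + 1),
        pairs=tuple(pairs),
    )
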