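"""Global pairwise alignment with linear gap costs.

Needleman–Wunsch with a deterministic traceback (diagonal preferred over
vertical over horizontal on score ties) so that repeated runs produce
byte-identical alignments.  The dynamic program is vectorised row-wise:
the horizontal (left) dependency under a linear gap penalty reduces to a
running maximum of ``score - column * gap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PairwiseAlignment:
    """An aligned pair of sequences (gap character '-')."""

    a: str
    b: str
    score: float

    def identity(self, exclude_terminal_gaps: bool = True) -> float:
        """Fraction of identical columns.

        With ``exclude_terminal_gaps`` the denominator omits leading and
        trailing gap overhangs (the convention used for redundancy
        clustering); internal gap columns always count as mismatches.
        """
        cols = list(zip(self.a, self.b))
        lo, hi = 0, len(cols)
        if exclude_terminal_gaps:
            while lo < hi and ("-" in cols[lo]):
                if cols[lo][0] != "-" and cols[lo][1] != "-":
                    break
                lo += 1
            while hi > lo and (cols[hi - 1][0] == "-" or cols[hi - 1][1] == "-"):
                hi -= 1
        span = cols[lo:hi]
        if not span:
            return 0.0
        matches = sum(1 for x, y in span if x == y and x != "-")
        return matches / len(span)


def _eq(x: float, y: float, tol: float = 1e-9) -> bool:
    """Score equality with a tolerance: the vectorised recurrence and the
    traceback recompute the same sums in different orders, so exact float
    comparison would silently break the tie-break into spurious gaps."""
    return abs(x - y) <= tol * max(1.0, abs(x), abs(y))


def _score_matrix(a: str, b: str, match: float, mismatch: float,
                  gap: float) -> np.ndarray:
    m, n = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)
    H = np.empty((m + 1, n + 1))
    H[0, :] = np.arange(n + 1) * gap
    H[:, 0] = np.arange(m + 1) * gap
    jg = np.arange(1, n + 1) * gap
    for i in range(1, m + 1):
        diag = H[i - 1, :-1] + sub[i - 1]
        up = H[i - 1, 1:] + gap
        v = np.maximum(diag, up)
        # resolve left-dependency: H[i,j] = max(v[j], H[i,j-1] + gap)
        t = np.maximum.accumulate(np.concatenate(([H[i, 0]], v - jg)))
        H[i, 1:] = t[1:] + jg
    return H


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                 gap: float = -1.0) -> PairwiseAlignment:
    """Optimal global alignment of two same-moltype sequences.

    Ties are broken deterministically: diagonal, then up (gap in ``b``),
    then left.  Two empty sequences give the empty alignment.
    """
    if not a and not b:
        return PairwiseAlignment("", "", 0.0)
    if not a:
        return PairwiseAlignment("-" * len(b), b, gap * len(b))
    if not b:
        return PairwiseAlignment(a, "-" * len(a), gap * len(a))
    H = _score_matrix(a, b, match, mismatch, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if _eq(here, H[i - 1, j - 1] + s):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and _eq(here, H[i - 1, j] + gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(H[len(a), len(b)]))


def pairwise_identity(a: str, b: str, **kwargs) -> float:
    """Global-alignment identity excluding terminal gap overhangs."""
    return global_align(a, b, **kwargs).identity()


def align_with_matrix(sub: np.ndarray, gap: float) -> tuple[str, float]:
    """Global DP over a precomputed position-by-position score matrix.

    ``sub[i, j]`` scores pairing position i of the first profile with
    position j of the second.  Returns the traceback as a string of ops
    ('D' diagonal, 'U' up / gap in second, 'L' left / gap in first) and
    the optimal score.  Tie-break order matches :func:`global_align`.
    """
    m, n = sub.shape
    H = np.empty((m + 1, n + 1))
    H[0, :] = np.arange(n + 1) * gap
    H[:, 0] = np.arange(m + 1) * gap
    jg = np.arange(1, n + 1) * gap
    for i in range(1, m + 1):
        v = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap)
        t = np.maximum.accumulate(np.concatenate(([H[i, 0]], v - jg)))
        H[i, 1:] = t[1:] + jg
    ops: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if (i > 0 and j > 0
                and _eq(H[i, j], H[i - 1, j - 1] + sub[i - 1, j - 1])):
            ops.append("D")
            i -= 1
            j -= 1
        elif i > 0 and _eq(H[i, j], H[i - 1, j] + gap):
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    return "".join(reversed(ops)), float(H[m, n])
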