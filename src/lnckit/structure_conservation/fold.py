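"""Maximum-score nested RNA folding by dynamic programming.

A deliberately simple energy surrogate: pair scores GC=3, AU=2, GU=1
(others unpairable), hairpin loop constraint j - i > min_loop, energy =
-(total pair score).  The same dynamic program also folds consensus
column-score matrices for alignments.

The O(n^3) fill is JIT-compiled with numba when available; a pure-Python
fallback keeps results identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
N_CODES = 5  # 4 bases + everything else (gap/N)

# 5x5 numeric pair-score table indexed by base codes
PAIR_TABLE = np.zeros((N_CODES, N_CODES))
for (a, b), v in PAIR_SCORES.items():
    PAIR_TABLE[_CODE[a], _CODE[b]] = v

_EQ_TOL = 1e-9


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; non-ACGU(T) characters get code 4."""
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def pair_score_matrix(seq: str) -> np.ndarray:
    code = encode(seq)
    return PAIR_TABLE[code[:, None], code[None, :]]


@dataclass
class SecondaryStructure:
    """A nested set of base pairs with its (surrogate) energy."""

    pairs: list[tuple[int, int]]
    length: int
    energy: float  # -(pair score sum); <= 0
    single_row_fallback: bool = field(default=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _fill_python(s: np.ndarray, min_loop: int) -> np.ndarray:
    n = s.shape[0]
    M = np.zeros((n + 2, n + 1))
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = M[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if s[i, k] > 0:
                    v = s[i, k] + M[i + 1, k - 1] + (M[k + 1, j] if k < j else 0.0)
                    if v > best:
                        best = v
            M[i, j] = best
    return M

try:  # optional acceleration; results identical to the Python fill
    from numba import njit

    _fill_numba = njit(cache=True)(_fill_python)
except Exception:  # pragma: no cover - numba not installed
    _fill_numba = None


def _fill(s: np.ndarray, min_loop: int) -> np.ndarray:
    if _fill_numba is not None:
        return _fill_numba(s, min_loop)
    return _fill_python(s, min_loop)


def _traceback(M: np.ndarray, s: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    """Deterministic traceback preferring a pair at the smallest i, then the
    largest j for that i."""
    n = s.shape[0]
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n > 0 else []
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        best = M[i, j]
        if best <= _EQ_TOL:
            continue
        paired = False
        for k in range(j, i + min_loop, -1):
            if s[i, k] <= 0:
                continue
            v = s[i, k] + M[i + 1, k - 1] + (M[k + 1, j] if k < j else 0.0)
            if abs(v - best) <= _EQ_TOL:
                pairs.append((i, k))
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    pairs.sort()
    return pairs


def fold_matrix(s: np.ndarray, min_loop: int = 3) -> SecondaryStructure:
    """Fold an arbitrary non-negative column-pair score matrix."""
    n = s.shape[0]
    if n <= min_loop + 1:
        return SecondaryStructure([], n, 0.0)
    s = np.ascontiguousarray(s, dtype=np.float64)
    M = _fill(s, min_loop)
    pairs = _traceback(M, s, min_loop)
    return SecondaryStructure(pairs, n, -float(M[0, n - 1]))


def fold(sequence: str, min_loop: int = 3) -> SecondaryStructure:
    """Best nested structure of a single sequence (T treated as U)."""
    if len(sequence) < 5:
        return SecondaryStructure([], len(sequence), 0.0)
    return fold_matrix(pair_score_matrix(sequence), min_loop)


def consensus_score_matrix(rows: list[str], covariation_bonus: float = 1.0) -> np.ndarray:
    """Column-pair scores for an alignment: mean per-row pair score (gaps
    score 0) plus a covariation bonus for row pairs showing a compensatory
    double substitution that preserves pairability.

    The bonus is averaged over row pairs (full bonus when every row pair is
    compensatory) so the consensus energy stays on the scale of a single
    row's energy regardless of alignment depth.
    """
    codes = np.vstack([encode(r) for r in rows])
    m, n = codes.shape
    base = np.zeros((n, n))
    pairable = []
    for r in range(m):
        tab = PAIR_TABLE[codes[r][:, None], codes[r][None, :]]
        base += tab
        pairable.append(tab > 0)
    base /= m
    bonus = np.zeros((n, n))
    n_row_pairs = m * (m - 1) // 2
    for r in range(m):
        for q in range(r + 1, m):
            diff = codes[r] != codes[q]
            both_diff = diff[:, None] & diff[None, :]
            bonus += (both_diff & pairable[r] & pairable[q]) * covariation_bonus
    return base + bonus / max(1, n_row_pairs)


def consensus_fold(
    rows: list[str],
    min_loop: int = 3,
    covariation_bonus: float = 1.0,
) -> tuple[SecondaryStructure, float]:
    """Consensus structure and energy of aligned rows (all-gap columns must
    already be dropped by the caller via :func:`drop_allgap_columns`).

    A single row falls back to plain folding, flagged on the structure.
    """
    if not rows:
        raise ValueError("no rows to fold")
    if len(rows) == 1:
        st = fold(rows[0], min_loop)
        st.single_row_fallback = True
        return st, st.energy
    s = consensus_score_matrix(rows, covariation_bonus)
    st = fold_matrix(s, min_loop)
    return st, st.energy


def drop_allgap_columns(rows: list[str]) -> list[str]:
    if not rows:
        return rows
    keep = [i for i in range(len(rows[0])) if any(r[i] not in "-." for r in rows)]
    return ["".join(r[i] for i in keep) for r in rows]
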