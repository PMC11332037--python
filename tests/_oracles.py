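"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (python loops, direct definitions) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_crqa(matrix: np.ndarray, min_diag: int = 2, min_vert: int = 2):
    """RR/DET/LAM by direct O(N^2) scanning of the binary matrix."""
    m = np.asarray(matrix, dtype=bool)
    n_rows, n_cols = m.shape
    n_rec = int(m.sum())
    rr = n_rec / (n_rows * n_cols)
    if n_rec == 0:
        return rr, float("nan"), float("nan")

    diag_points = 0
    for k in range(-(n_rows - 1), n_cols):
        line = [m[i, i + k] for i in range(max(0, -k), min(n_rows, n_cols - k))]
        diag_points += _points_in_long_runs(line, min_diag)

    vert_points = 0
    for j in range(n_cols):
        vert_points += _points_in_long_runs(list(m[:, j]), min_vert)

    return rr, diag_points / n_rec, vert_points / n_rec


def _points_in_long_runs(line, min_len: int) -> int:
    total = 0
    run = 0
    for v in line + [False]:
        if v:
            run += 1
        else:
            if run >= min_len:
                total += run
            run = 0
    return total


def naive_leave_one_out_outliers(data: np.ndarray, n_sd: float) -> np.ndarray:
    """Trial flags from direct leave-one-trial-out pooled mean/SD."""
    n = data.shape[0]
    flags = np.zeros(n, dtype=bool)
    for t in range(n):
        others = np.concatenate([data[i] for i in range(n) if i != t])
        mu = others.mean()
        sd = others.std(ddof=1)
        if any(abs(x - mu) > n_sd * sd for x in data[t]):
            flags[t] = True
    return flags


def pearson_by_hand(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def chi2_by_hand(table) -> float:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = rows[i] * cols[j] / n
            chi2 += (table[i, j] - expected) ** 2 / expected
    return chi2


def ols_by_hand(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normal-equations coefficients (X includes the intercept column)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def sequence_rules_hold(seq) -> bool:
    """Independent restatement of the cue-sequence pseudorandomisation rules."""
    seq = list(seq)
    if len(seq) != 12 or sorted(set(seq)) != ["NT", "Tx"]:
        return False
    if seq.count("Tx") != 6:
        return False
    longest = 1
    cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        longest = max(longest, cur)
    if longest > 3:
        return False
    if not (2 <= seq[:6].count("Tx") <= 4 and 2 <= seq[6:].count("Tx") <= 4):
        return False
    for lab in ("Tx", "NT"):
        same = sum(a == lab and b == lab for a, b in zip(seq, seq[1:]))
        diff = sum(a == lab and b != lab for a, b in zip(seq, seq[1:]))
        if abs(same - diff) > 1:
            return False
    return True
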