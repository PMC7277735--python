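"""RNA secondary structure by base-pair maximization (Nussinov).

Canonical Watson-Crick pairs plus G:U wobble, minimum hairpin loop of 3
unpaired bases.  This is a combinatorial surrogate for thermodynamic
folding: adequate for deciding whether a candidate precursor can form a
stem-loop at all, not for energy estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass
class Structure:
    """Folded structure: dot-bracket string and a position -> partner map
    (0-based, both directions)."""

    sequence: str
    dotbracket: str
    pairs: dict[int, int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def fold(sequence: str, min_loop: int = 3) -> Structure:
    """Maximize base pairs with a minimum hairpin loop size.

    O(n^3) dynamic program with a numpy-vectorized inner maximization;
    traceback recovers one optimal structure (ties broken toward the
    leftmost bifurcation).
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return Structure(sequence=seq, dotbracket="", pairs={})
    dp = np.zeros((n, n), dtype=np.int32)
    # partners[j]: sorted positions k < j that can pair with j
    partners: list[np.ndarray] = []
    for j in range(n):
        ks = [k for k in range(j - min_loop) if can_pair(seq[k], seq[j])]
        partners.append(np.array(ks, dtype=np.int64))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            ks = partners[j]
            ks = ks[ks >= i]
            if ks.size:
                left = np.where(ks > i, dp[i, np.maximum(ks - 1, 0)], 0)
                vals = left + dp[ks + 1, j - 1] + 1
                m = int(vals.max())
                if m > best:
                    best = m
            dp[i, j] = best
    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in partners[j]:
            if k < i:
                continue
            left = dp[i, k - 1] if k > i else 0
            if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                pairs[int(k)] = j
                pairs[j] = int(k)
                if k > i:
                    stack.append((i, int(k) - 1))
                stack.append((int(k) + 1, j - 1))
                break
    db = "".join(
        "(" if (i in pairs and pairs[i] > i) else (")" if i in pairs else ".")
        for i in range(n)
    )
    return Structure(sequence=seq, dotbracket=db, pairs=pairs)
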