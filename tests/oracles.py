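"""Independent brute-force oracles shared across test modules."""

from __future__ import annotations

import numpy as np


def spearman_oracle(x, y) -> float:
    """Spearman via explicit average ranks + Pearson (NaN if degenerate)."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])
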