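"""Independent reference implementations used only to check the package.

These deliberately share no code with issalign: the aligner oracle is a
plain-Python three-state recurrence over dictionaries, and the composition
oracle is a quadratic double loop.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score_oracle(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Best local alignment score under affine gaps (open charged on the
    first gapped residue), by explicit three-state recurrence."""
    n, m = len(a), len(b)
    M = {}  # best alignment ending in a match at (i, j)
    X = {}  # ending with a gap in b (consumes a[i-1])
    Y = {}  # ending with a gap in a (consumes b[j-1])
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(
                0.0,
                M.get((i - 1, j - 1), NEG),
                X.get((i - 1, j - 1), NEG),
                Y.get((i - 1, j - 1), NEG),
            )
            M[(i, j)] = prev + score_fn(a[i - 1], b[j - 1])
            X[(i, j)] = max(
                M.get((i - 1, j), NEG) - gap_open,
                X.get((i - 1, j), NEG) - gap_extend,
            )
            Y[(i, j)] = max(
                M.get((i, j - 1), NEG) - gap_open,
                Y.get((i, j - 1), NEG) - gap_extend,
            )
            best = max(best, M[(i, j)])
    return int(best)


def compose_pairs_oracle(pairs1, pairs2):
    """Brute-force relational composition by double loop."""
    out = []
    for i, j in pairs1:
        for j2, k in pairs2:
            if j == j2:
                out.append((i, k))
    return sorted(out)


def random_monotone_pairs(rng, max_index: int, max_size: int):
    """A random strictly-monotone pairing inside [0, max_index)^2."""
    size = int(rng.integers(0, max_size + 1))
    if size == 0:
        return tuple()
    size = min(size, max_index)
    xs = sorted(rng.choice(max_index, size=size, replace=False).tolist())
    ys = sorted(rng.choice(max_index, size=size, replace=False).tolist())
    return tuple(zip(xs, ys))
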