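"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: full-matrix dynamic programming,
exhaustive enumeration.  None of it shares code with the package.
"""

from __future__ import annotations

import itertools


def levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def best_anchor_placement(window: str, anchor: str) -> tuple[int, int]:
    """Brute-force semi-global minimum: for every end position, the minimum
    Levenshtein distance of the anchor against any window substring ending
    there.  Returns (min distance, smallest end achieving it)."""
    per_end = [
        min(levenshtein(anchor, window[start:end]) for start in range(end + 1))
        for end in range(len(window) + 1)
    ]
    m = min(per_end)
    return m, per_end.index(m)


def enumerate_heaviest_path(graph) -> str:
    """All start→end paths of a PoaGraph; pick maximum total edge weight,
    ties by lexicographically smallest node-id tuple.  Exponential; only for
    tiny graphs."""
    best: tuple[int, tuple[int, ...]] | None = None

    def walk(node: int, weight: int, path: tuple[int, ...]) -> None:
        nonlocal best
        if node == graph.END:
            key = (-weight, path)
            if best is None or key < (-best[0], best[1]):
                best = (weight, path)
            return
        for succ in graph.succ[node]:
            walk(succ, weight + graph.edges[(node, succ)], path + (succ,))

    walk(graph.START, 0, ())
    assert best is not None
    return "".join(graph.bases[n] for n in best[1] if graph.bases[n] is not None)
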