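"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
arithmetic, without calling the implementation paths they check.
"""

import itertools

import numpy as np


def brute_force_match(cortical, thalamic):
    """Best injective assignment of thalamic to cortical events.

    Enumerates every injective partial assignment over pairs with strictly
    positive overlap and returns ``(matched_count, total_overlap)`` of the
    assignment that maximizes matched count first, then total overlap.
    """
    ov = np.zeros((len(cortical), len(thalamic)))
    for i, c in enumerate(cortical):
        for j, t in enumerate(thalamic):
            ov[i, j] = max(
                0.0, min(c.offset_s, t.offset_s) - max(c.onset_s, t.onset_s)
            )
    best = (0, 0.0)
    nc, nt = ov.shape
    for k in range(min(nc, nt) + 1):
        for rows in itertools.combinations(range(nc), k):
            for cols in itertools.permutations(range(nt), k):
                if all(ov[r, c] > 0 for r, c in zip(rows, cols)):
                    total = sum(ov[r, c] for r, c in zip(rows, cols))
                    if (k, total) > best:
                        best = (k, total)
    return best


def random_disjoint_intervals(rng, n_max, span=20.0):
    """Sorted, pairwise-disjoint random intervals inside [0, span]."""
    n = int(rng.integers(0, n_max + 1))
    points = np.sort(rng.uniform(0, span, size=2 * n))
    return [(points[2 * i], points[2 * i + 1]) for i in range(n)]
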