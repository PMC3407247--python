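"""Shared brute-force BH oracle used by unit and acceptance tests."""

import numpy as np


def brute_force_bh_reference(p):
    """Double-loop Benjamini-Hochberg step-up q-values, from the definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        best = 1.0
        for rank, j in enumerate(order, start=1):
            if rank >= pos:
                best = min(best, m * p[j] / rank)
        q[i] = best
    return np.array(q)
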