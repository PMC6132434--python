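"""Slow reference implementations used to validate the fast production code.

These are deliberately naive: correctness is argued from the rule's
definition, not from efficiency.  They back the property tests and the
acceptance checks; they are never used on the production path.
"""

from __future__ import annotations

import numpy as np


def _nonwear_mask_bruteforce(counts, min_window, max_interrupt):
    """O(n^2) window enumeration for the non-wear rule.

    Marks epoch t non-wear iff some window [i, j] contains t with
    j - i + 1 >= min_window, at most max_interrupt non-zero epochs, and
    zero epochs at both i and j.  For each zero start i the scan walks
    right until the interruption budget is exhausted; every admissible
    window from i is a prefix of the maximal one, so marking the maximal
    window marks their union.
    """
    n = counts.shape[0]
    mask = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        if counts[i] > 0:
            continue
        interrupts = 0
        best = -1
        for j in range(i, n):
            if counts[j] > 0:
                interrupts += 1
                if interrupts > max_interrupt:
                    break
            elif j - i + 1 >= min_window:
                best = j
        if best >= 0:
            for t in range(i, best + 1):
                mask[t] = True
    return mask


try:  # optional JIT: the rule check is O(n^2) and runs on thousands of series
    from numba import njit

    _nonwear_mask_bruteforce_fast = njit(cache=False)(_nonwear_mask_bruteforce)
except Exception:  # pragma: no cover - numba present in the supported env
    _nonwear_mask_bruteforce_fast = _nonwear_mask_bruteforce


def nonwear_mask_oracle(counts, min_window: int = 60,
                        max_interrupt: int = 2) -> np.ndarray:
    """Brute-force non-wear mask (independent oracle for ``nonwear_mask``)."""
    counts = np.ascontiguousarray(counts, dtype=np.int64)
    return np.asarray(_nonwear_mask_bruteforce_fast(counts, min_window, max_interrupt))
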