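"""Bonferroni and Benjamini-Hochberg adjusted p-values.

Both adjustments take an explicit number of tests ``m_tests``, which may
exceed the number of supplied p-values: p-values omitted from a report are
assumed nonsignificant, so they inflate the multiplier but never change the
step-up minimum.  In the pipeline ``m_tests`` is always the size of the SNP
set tested in that run, not merely the rows reported.
"""

from __future__ import annotations

import numpy as np


def _validate(p_values: np.ndarray, m_tests: int) -> None:
    if np.any((p_values < 0) | (p_values > 1)) or np.any(np.isnan(p_values)):
        raise ValueError("p-values must lie in [0, 1]")
    if m_tests < len(p_values):
        raise ValueError(
            f"m_tests ({m_tests}) must be at least the number of supplied "
            f"p-values ({len(p_values)})"
        )
    if m_tests < 1:
        raise ValueError("m_tests must be positive")


def bonferroni(p_values, m_tests: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m_tests) elementwise."""
    p = np.asarray(p_values, dtype=float)
    _validate(p, m_tests)
    return np.minimum(1.0, p * m_tests)


def bh_adjust(p_values, m_tests: int) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending; adjusted(i) = min over j >= i of p(j) * m_tests / j,
    capped at 1, mapped back to the input order.  Adjusted values are a
    monotone nondecreasing function of rank.
    """
    p = np.asarray(p_values, dtype=float)
    _validate(p, m_tests)
    if len(p) == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    scaled = p[order] * m_tests / ranks
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty_like(adjusted_sorted)
    adjusted[order] = adjusted_sorted
    return adjusted
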