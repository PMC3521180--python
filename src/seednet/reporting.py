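"""Small arithmetic helpers for network-size reports.

These back the summary tables comparing networks before and after paralogous
expansion (percentage increases, fold changes) and gene-coverage shares.
"""

from __future__ import annotations

__all__ = ["percent_increase", "fold_change", "percent_of"]


def percent_increase(before: float, after: float) -> float:
    """Relative growth from ``before`` to ``after`` in percent."""
    if before == 0:
        raise ValueError("percent_increase undefined for before == 0")
    return (after - before) / before * 100.0


def fold_change(before: float, after: float) -> float:
    """``after`` over ``before``."""
    if before == 0:
        raise ValueError("fold_change undefined for before == 0")
    return after / before


def percent_of(part: float, whole: float) -> float:
    """``part`` as a percentage of ``whole``."""
    if whole == 0:
        raise ValueError("percent_of undefined for whole == 0")
    return part / whole * 100.0
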