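"""Identity calls from coordination differences.

A variant that is over-coordinated relative to the index (positive mean
cumulative-coordination difference over the signal window, default 5-7 A)
leans agonist-like; under-coordination leans antagonist-like.  Magnitude
orders functional strength; differences below the tolerance are
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .paircorr import CoordinationDelta, _window_bins

OVER = "over_coordinated"
UNDER = "under_coordinated"
INDETERMINATE = "indeterminate"

_CLASS_ORDER = {OVER: 0, INDETERMINATE: 1, UNDER: 2}

DEFAULT_WINDOW = (5.0, 7.0)
DEFAULT_TOLERANCE = 0.05


@dataclass
class IdentityCall:
    variant_label: str
    index_label: str
    delta_at_limit: float  # mean delta over the window (coordination units)
    call: str
    magnitude: float
    window: tuple[float, float] = DEFAULT_WINDOW
    tolerance: float = DEFAULT_TOLERANCE


def call_identity(
    delta: CoordinationDelta,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tolerance: float = DEFAULT_TOLERANCE,
) -> IdentityCall:
    """Classify a coordination-difference curve over the signal window."""
    r1, r2 = window
    if not (0.0 <= r1 < r2):
        raise ValueError(f"bad window {window}")
    mask = _window_bins(delta.r_grid, delta.bin_size, r1, r2)
    if not mask.any():
        raise ValueError(
            f"window {window} lies outside the computed grid "
            f"(max {delta.r_grid[-1] + delta.bin_size / 2:.2f} A)"
        )
    value = float(np.mean(delta.delta[mask]))
    magnitude = abs(value)
    if magnitude < tolerance:
        call = INDETERMINATE
    elif value > 0:
        call = OVER
    else:
        call = UNDER
    return IdentityCall(
        variant_label=delta.variant_label,
        index_label=delta.index_label,
        delta_at_limit=value,
        call=call,
        magnitude=magnitude,
        window=(float(r1), float(r2)),
        tolerance=tolerance,
    )


def rank_variants(calls: Iterable[IdentityCall]) -> list[IdentityCall]:
    """Stable order: over-coordinated first, then indeterminate, then
    under-coordinated; within a class by descending magnitude, ties by label."""
    calls = list(calls)
    if not calls:
        raise ValueError("no identity calls to rank")
    return sorted(
        calls, key=lambda c: (_CLASS_ORDER[c.call], -c.magnitude, c.variant_label)
    )
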