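"""Top-decile activity extraction and per-arm summary statistics.

A sample pair's activity is the sum of the two arms' magnitudes at that
instant; the 10% of pairs with the largest sums — roughly the most active
2.5 h of a 24 h recording, not necessarily contiguous — form the extraction
set. Each arm's mean over that set is its recorded acceleration value, and
the normalized left/right difference gives the asymmetry index whose sign
marks the weaker side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bilateral import BilateralSession
from .errors import ParameterError, ShapeError


@dataclass(frozen=True)
class ActivitySummary:
    """Per-session activity summary over the top-decile extraction set.

    ``asymmetry_index`` is ``(right - left) / (right + left)`` of the
    selected-set means: negative when the left arm moves more, positive when
    the right arm does, so its sign points at the weaker side.
    """

    patient_id: str
    session: str
    mean_left: float
    mean_right: float
    mean_affected: float
    mean_unaffected: float
    n_selected: int
    fraction: float
    selected_duration_s: float
    asymmetry_index: float


def pair_activity(left, right) -> np.ndarray:
    """Element-wise bilateral sum; higher sum = more activity at that instant."""
    lv = np.asarray(getattr(left, "values", left), dtype=float)
    rv = np.asarray(getattr(right, "values", right), dtype=float)
    if lv.shape != rv.shape:
        raise ShapeError(f"arm lengths differ: {lv.shape} vs {rv.shape}")
    return lv + rv


def select_top_fraction(activity: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Indices of the ``ceil(fraction * n)`` largest activity values.

    Ties at the threshold are broken toward the earlier timestamp. Returns a
    sorted index array of exactly ``k`` entries.
    """
    activity = np.asarray(activity, dtype=float)
    n = len(activity)
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    if n < 1:
        raise ShapeError("activity series is empty")
    k = math.ceil(fraction * n)
    # Stable sort on descending activity keeps original order among ties,
    # which is exactly the earliest-timestamp tie-break.
    order = np.argsort(-activity, kind="stable")
    return np.sort(order[:k])


def summarize_session(session: BilateralSession, fraction: float = 0.10) -> ActivitySummary:
    """Means of each arm over the top-``fraction`` most active sample pairs.

    Leading filter-transient samples are excluded from the candidate pool;
    ``n_selected == ceil(fraction * n_candidates)``.
    """
    start = min(session.n_transient, len(session) - 1)
    lv = session.left.values[start:]
    rv = session.right.values[start:]
    idx = select_top_fraction(pair_activity(lv, rv), fraction)
    mean_left = float(np.mean(lv[idx]))
    mean_right = float(np.mean(rv[idx]))
    total = mean_left + mean_right
    asym = 0.0 if total == 0 else (mean_right - mean_left) / total
    if session.affected_side == "left":
        mean_aff, mean_unaff = mean_left, mean_right
    else:
        mean_aff, mean_unaff = mean_right, mean_left
    return ActivitySummary(
        patient_id=session.patient_id,
        session=session.session,
        mean_left=mean_left,
        mean_right=mean_right,
        mean_affected=mean_aff,
        mean_unaffected=mean_unaff,
        n_selected=len(idx),
        fraction=fraction,
        selected_duration_s=len(idx) / session.left.rate_hz,
        asymmetry_index=asym,
    )
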