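"""Cohort-level statistics: descriptives, session deltas, rank correlations.

The cohort table is a tidy :class:`pandas.DataFrame` with one row per
patient-session carrying the activity summary columns (``mean_left``,
``mean_right``, ``mean_affected``, ``mean_unaffected``, ``asymmetry_index``,
``n_selected``) alongside the clinical scores (``mas``, ``mal_aou``,
``mal_qom``) and metadata (``patient_id``, ``session``, ``affected_side``).

Spearman's rank correlation is used throughout because the clinical scales
are ordinal and heavily tied: ranks use the mid-rank convention, rho is the
Pearson correlation of the rank vectors, and the two-sided p-value comes
from exact permutation enumeration for n ≤ 9 and the t approximation
``t = rho * sqrt((n-2)/(1-rho²))`` with n−2 degrees of freedom otherwise.
No multiple-testing correction is applied across the nine cells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activity import ActivitySummary
from .errors import DegenerateError, EmptyError, ShapeError
from .raw_io import CohortRow

log = logging.getLogger(__name__)

SCORE_COLUMNS = ("mas", "mal_aou", "mal_qom")
DESCRIPTIVE_COLUMNS = SCORE_COLUMNS + ("mean_affected",)

#: Largest n for which the permutation null is enumerated exactly.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: str
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" | "t-approximation"


def cohort_table(
    summaries: list[ActivitySummary], rows: list[CohortRow]
) -> pd.DataFrame:
    """Join activity summaries with clinical metadata into the cohort table."""
    meta = {(r.patient_id, r.session): r for r in rows}
    records = []
    for s in summaries:
        r = meta[(s.patient_id, s.session)]
        records.append(
            {
                "patient_id": s.patient_id,
                "session": s.session,
                "affected_side": r.affected_side,
                "mean_left": s.mean_left,
                "mean_right": s.mean_right,
                "mean_affected": s.mean_affected,
                "mean_unaffected": s.mean_unaffected,
                "n_selected": s.n_selected,
                "asymmetry_index": s.asymmetry_index,
                "mas": r.scores.mas,
                "mal_aou": r.scores.mal_aou,
                "mal_qom": r.scores.mal_qom,
            }
        )
    return pd.DataFrame.from_records(records)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float((rx @ ry) / denom)


def spearman_rho(x, y, variable_pair: str = "x vs y") -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ShapeError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ShapeError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateError(f"{variable_pair}: constant input, rank variance is zero")
    rx = sps.rankdata(x)  # average ranks on ties
    ry = sps.rankdata(y)
    rho = _rank_pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        p = _t_approximation_p(rho, n)
        method = "t-approximation"
    return CorrelationResult(variable_pair, rho, p, n, method)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all n! permutations of the y ranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _t_approximation_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def cohort_descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles (linear-interpolation rule) per session.

    Returns a frame indexed by (variable, session) with columns
    ``median``, ``q1``, ``q3``, ``n``.
    """
    records = []
    for session, group in table.groupby("session", sort=True):
        if group.empty:
            raise EmptyError(f"no rows for session {session}")
        for var in DESCRIPTIVE_COLUMNS:
            vals = group[var].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            records.append(
                {
                    "variable": var,
                    "session": session,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "n": len(vals),
                }
            )
    if not records:
        raise EmptyError("empty cohort table")
    return pd.DataFrame.from_records(records).set_index(["variable", "session"])


DELTA_COLUMNS = ("mean_affected",) + SCORE_COLUMNS


def delta_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient T2 − T1 differences; positive = improvement.

    Patients missing either session are excluded with a logged warning,
    mirroring a completers-only analysis.
    """
    out = []
    for pid, group in table.groupby("patient_id", sort=True):
        sessions = set(group["session"])
        if sessions != {"T1", "T2"}:
            log.warning("patient %s excluded from deltas: sessions %s", pid, sorted(sessions))
            continue
        t1 = group[group["session"] == "T1"].iloc[0]
        t2 = group[group["session"] == "T2"].iloc[0]
        row = {"patient_id": pid}
        for var in DELTA_COLUMNS:
            row[f"delta_{var}"] = float(t2[var]) - float(t1[var])
        out.append(row)
    return pd.DataFrame.from_records(
        out, columns=["patient_id"] + [f"delta_{v}" for v in DELTA_COLUMNS]
    )


def run_correlation_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """The 3 × 3 grid: affected-arm acceleration vs each score at T1, T2, Δ.

    Returns a tidy frame with columns ``score``, ``contrast``, ``rho``,
    ``p_value``, ``n``, ``method``. A degenerate cell (constant input) is
    reported with NaN rho/p rather than aborting the grid.
    """
    deltas = delta_table(table)
    records = []
    for score in SCORE_COLUMNS:
        for contrast in ("T1", "T2", "delta"):
            if contrast == "delta":
                x = deltas["delta_mean_affected"].to_numpy()
                y = deltas[f"delta_{score}"].to_numpy()
            else:
                sub = table[table["session"] == contrast]
                x = sub["mean_affected"].to_numpy()
                y = sub[score].to_numpy()
            label = f"mean_affected vs {score} ({contrast})"
            try:
                res = spearman_rho(x, y, variable_pair=label)
                rec = {
                    "score": score,
                    "contrast": contrast,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                    "method": res.method,
                }
            except DegenerateError as exc:
                log.warning("degenerate correlation cell %s: %s", label, exc)
                rec = {
                    "score": score,
                    "contrast": contrast,
                    "rho": np.nan,
                    "p_value": np.nan,
                    "n": len(x),
                    "method": "degenerate",
                }
            records.append(rec)
    return pd.DataFrame.from_records(records)
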