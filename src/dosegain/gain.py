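"""Paired prone/supine gain analysis.

The prone setup provides a *dosimetric gain* for a patient when it reduces
the penalty score, i.e. when ``delta = prone - supine < 0``; ties count as
no gain.  Three assessments are provided: an aggregate paired t-test of the
mean scores, the per-patient gain proportion with its exact (Clopper-
Pearson) binomial confidence interval, and the bullet-arrow chart data —
patients sorted by supine score, with an arrow from the supine bullet to the
prone arrowhead showing direction and magnitude of the change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, EmptySubgroupError


def pair_scores(penalties: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long penalty table into one row per patient.

    Input columns: ``patient_id, setup, score`` (as produced by
    ``penalty.score_cohort``).  Output columns: ``patient_id, supine_score,
    prone_score, delta`` with ``delta = prone - supine``.
    """
    wide = penalties.pivot_table(
        index="patient_id", columns="setup", values="score", sort=False
    )
    wide = wide.dropna(subset=["prone", "supine"])
    out = pd.DataFrame(
        {
            "patient_id": wide.index,
            "supine_score": wide["supine"].to_numpy(),
            "prone_score": wide["prone"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["delta"] = out["prone_score"] - out["supine_score"]
    return out


def paired_t(supine: np.ndarray, prone: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on deltas; returns (t, two-sided p)."""
    supine = np.asarray(supine, dtype=float)
    prone = np.asarray(prone, dtype=float)
    if supine.shape != prone.shape or supine.ndim != 1:
        raise ValueError("supine and prone must be equal-length 1-D arrays")
    if supine.size < 2:
        raise DegenerateTestError("paired t-test needs at least two pairs")
    deltas = prone - supine
    if np.ptp(deltas) == 0:
        raise DegenerateTestError("all paired differences identical: t undefined")
    res = stats.ttest_rel(prone, supine)
    return float(res.statistic), float(res.pvalue)


def exact_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Proportion with Clopper-Pearson (exact binomial) confidence interval.

    Returns ``(proportion, low, high)`` on the 0-1 scale; the interval is
    derived from Beta quantiles, with low = 0 at zero successes and high = 1
    at n successes.
    """
    successes, n = int(successes), int(n)
    if n < 1 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts: {successes}/{n}")
    ci = stats.binomtest(successes, n).proportion_ci(
        confidence_level=level, method="exact"
    )
    return successes / n, float(ci.low), float(ci.high)


@dataclass(frozen=True)
class GainSummary:
    """Cohort-level gain assessment for one weight set / subgroup."""

    n: int
    n_gain: int
    proportion: float
    ci_low: float
    ci_high: float
    mean_supine: float
    mean_prone: float
    t_statistic: float | None
    t_p_value: float | None
    median_supine: float
    range_supine: tuple[float, float]
    median_prone: float
    range_prone: tuple[float, float]
    median_delta: float
    range_delta: tuple[float, float]
    level: float = 0.95

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "n_gain": self.n_gain,
            "proportion": self.proportion,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "mean_supine": self.mean_supine,
            "mean_prone": self.mean_prone,
            "t_statistic": self.t_statistic,
            "t_p_value": self.t_p_value,
            "median_supine": self.median_supine,
            "range_supine": list(self.range_supine),
            "median_prone": self.median_prone,
            "range_prone": list(self.range_prone),
            "median_delta": self.median_delta,
            "range_delta": list(self.range_delta),
            "level": self.level,
        }
        return d


def count_gains(
    pairs: pd.DataFrame,
    subgroup: Callable[[pd.DataFrame], np.ndarray] | None = None,
    level: float = 0.95,
) -> GainSummary:
    """Count patients gaining from prone and attach the exact binomial CI.

    ``subgroup`` is an optional boolean predicate over the pairs table (e.g.
    ``lambda p: p.supine_score >= 2``).  A gain is a strictly negative delta;
    ties are conservatively counted as no gain.
    """
    if pairs.empty:
        raise EmptySubgroupError("empty pair list")
    if subgroup is not None:
        mask = np.asarray(subgroup(pairs), dtype=bool)
        pairs = pairs.loc[mask]
        if pairs.empty:
            raise EmptySubgroupError("subgroup predicate selected no patients")
    deltas = pairs["delta"].to_numpy(dtype=float)
    supine = pairs["supine_score"].to_numpy(dtype=float)
    prone = pairs["prone_score"].to_numpy(dtype=float)
    n = int(deltas.size)
    n_gain = int(np.sum(deltas < 0))
    proportion, lo, hi = exact_binomial_ci(n_gain, n, level)
    try:
        t_stat, t_p = paired_t(supine, prone)
    except DegenerateTestError:
        t_stat, t_p = None, None
    return GainSummary(
        n=n,
        n_gain=n_gain,
        proportion=proportion,
        ci_low=lo,
        ci_high=hi,
        mean_supine=float(np.mean(supine)),
        mean_prone=float(np.mean(prone)),
        t_statistic=t_stat,
        t_p_value=t_p,
        median_supine=float(np.median(supine)),
        range_supine=(float(np.min(supine)), float(np.max(supine))),
        median_prone=float(np.median(prone)),
        range_prone=(float(np.min(prone)), float(np.max(prone))),
        median_delta=float(np.median(deltas)),
        range_delta=(float(np.min(deltas)), float(np.max(deltas))),
        level=level,
    )


def two_proportion_test(
    g1: tuple[int, int], g2: tuple[int, int], method: str = "fisher"
) -> float:
    """Two-sided comparison of two binomial proportions.

    ``g1`` and ``g2`` are (successes, n).  Default is Fisher's exact test on
    the 2x2 table; ``method='chi2'`` uses the chi-square test with
    continuity correction.
    """
    (k1, n1), (k2, n2) = g1, g2
    if n1 < 1 or n2 < 1 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("invalid group counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if method == "fisher":
        return float(stats.fisher_exact(table).pvalue)
    if method == "chi2":
        return float(stats.chi2_contingency(table)[1])
    raise ValueError(f"unknown method {method!r}")


def bullet_arrow(pairs: pd.DataFrame) -> pd.DataFrame:
    """Bullet-arrow chart records: patients sorted by supine score.

    Each record carries the rank (1-based after sorting supine ascending),
    the supine bullet, the prone arrowhead, and the arrow direction:
    ``down`` for a gain (delta < 0), ``up`` for a worse prone plan, ``none``
    for a tie.  The output is canonical — independent of the input order.
    """
    if pairs.empty:
        raise EmptySubgroupError("empty pair list")
    ordered = pairs.sort_values(
        ["supine_score", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    delta = ordered["delta"].to_numpy(dtype=float)
    direction = np.where(delta < 0, "down", np.where(delta > 0, "up", "none"))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "patient_id": ordered["patient_id"],
            "supine_score": ordered["supine_score"],
            "prone_score": ordered["prone_score"],
            "delta": delta,
            "direction": direction,
        }
    )
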