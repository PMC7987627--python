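"""Univariable screening of patient characteristics against the penalty change.

For each characteristic ``x`` the penalty difference ``delta = prone -
supine`` is regressed on ``x`` with a Huber robust linear fit (M-estimation,
tuning constant 1.345, MAD scale, iteratively reweighted least squares) so
that a handful of gross outlier patients cannot dominate the slope.
Nonlinearity is screened with a one-term fractional polynomial (FP1): the
best power among {-2, -1, -0.5, 0 (log), 0.5, 1, 2, 3} is compared to the
null and to the straight line in a closed test sequence.

A characteristic is flagged significant when |coefficient / SD| > 1.96.
Where the fitted line crosses zero, ``cutoff = -intercept / coefficient``
gives the value of the characteristic at which the predicted gain changes
sign: with a negative slope, patients above the cutoff are predicted to gain
from the prone setup (``greater_better``); with a positive slope, those
below it (``less_better``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CodingError,
    InsufficientDataError,
    RankDeficiencyError,
    TransformError,
)

logger = logging.getLogger(__name__)

SIGNIFICANCE_Z = 1.96
#: below this |coefficient/SD| the slope is too flat for a meaningful cutoff
NI_Z = 0.5

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


# ---------------------------------------------------------------------------
# feature derivation and coding
# ---------------------------------------------------------------------------

def derive_features(records: pd.DataFrame) -> pd.DataFrame:
    """Add pendulousness and breast/body features to a characteristics table.

    * ``depth_ratio`` = prone / supine breast depth (undefined at zero
      supine depth);
    * ``depth_diff`` = prone - supine breast depth (mm);
    * ``breast_volume_per_weight`` = ipsilateral breast volume / body weight
      (mL/kg).

    Missing inputs propagate to missing features without touching the rest.
    """
    out = records.copy()

    def col(name: str) -> pd.Series:
        if name in out:
            return pd.to_numeric(out[name], errors="coerce")
        return pd.Series(np.nan, index=out.index, dtype=float)

    sup = col("breast_depth_supine")
    pro = col("breast_depth_prone")
    out["depth_ratio"] = pro / sup.where(sup > 0)
    out["depth_diff"] = pro - sup
    wt = col("weight")
    out["breast_volume_per_weight"] = col("breast_volume_left") / wt.where(wt > 0)
    return out


def dummy_code(
    values: Sequence, reference, levels: Sequence | None = None
) -> np.ndarray:
    """Binary-code a categorical: 0 for the reference level, 1 otherwise.

    ``levels`` declares the admitted level set (defaults to the observed
    values plus the reference); an unseen level raises.  Missing values stay
    missing.
    """
    arr = pd.Series(values)
    declared = set(levels) if levels is not None else set(arr.dropna()) | {reference}
    if reference not in declared:
        raise CodingError(f"reference level {reference!r} not in declared levels")
    unseen = set(arr.dropna()) - declared
    if unseen:
        raise CodingError(f"unseen categorical level(s): {sorted(unseen)}")
    out = np.where(arr.isna(), np.nan, (arr != reference).astype(float))
    return out.astype(float)


# ---------------------------------------------------------------------------
# robust linear fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Univariable robust-fit summary for one characteristic."""

    name: str
    intercept: float
    coefficient: float
    coefficient_sd: float
    n: int
    significant: bool
    cutoff: float | None = None
    direction: str | None = None  # greater_better | less_better
    unit: str = ""
    group: str = ""
    nonlinear: bool | None = None
    fp_power: float | None = None

    @property
    def z(self) -> float:
        if self.coefficient_sd == 0:
            return math.inf if self.coefficient != 0 else 0.0
        return self.coefficient / self.coefficient_sd


def robust_fit(
    x: Sequence[float],
    y: Sequence[float],
    *,
    name: str = "x",
    unit: str = "",
    min_n: int = 10,
) -> RegressionResult:
    """Huber M-estimated line ``y = intercept + coefficient * x``.

    Complete-case analysis: rows with a missing value in either variable are
    dropped.  Settings follow the standard robust-regression defaults:
    Huber psi with tuning constant 1.345, scale from the median absolute
    deviation, IRLS to 1e-8 on the coefficients, at most 50 iterations.  The
    coefficient SD comes from the robust covariance of the final fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < min_n:
        raise InsufficientDataError(
            f"{name}: only {n} complete cases (need >= {min_n})"
        )
    if np.ptp(x) == 0:
        raise RankDeficiencyError(f"{name}: predictor is constant")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    fit = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=50)
    intercept, coefficient = (float(v) for v in fit.params)
    sd = float(fit.bse[1])
    significant = sd > 0 and abs(coefficient / sd) > SIGNIFICANCE_Z
    result = RegressionResult(
        name=name,
        intercept=intercept,
        coefficient=coefficient,
        coefficient_sd=sd,
        n=n,
        significant=significant,
        unit=unit,
    )
    return cutoff_from_fit(result, x_range=(float(np.min(x)), float(np.max(x))))


def cutoff_from_fit(
    result: RegressionResult,
    x_range: tuple[float, float] | None = None,
) -> RegressionResult:
    """Attach the prone-better cutoff ``-intercept/coefficient`` to a fit.

    The cutoff is where the predicted penalty difference changes sign.  A
    negative slope means larger values favor prone (``greater_better``); a
    positive slope the reverse.  The cutoff is not identifiable (left as
    None) when the slope is too flat (|coefficient/SD| < 0.5) or when the
    sign change falls outside the observed data range.
    """
    coef, sd = result.coefficient, result.coefficient_sd
    if coef == 0 or (sd > 0 and abs(coef / sd) < NI_Z):
        return replace(result, cutoff=None, direction=None)
    cutoff = -result.intercept / coef
    direction = "greater_better" if coef < 0 else "less_better"
    if x_range is not None and not (x_range[0] <= cutoff <= x_range[1]):
        return replace(result, cutoff=None, direction=direction)
    return replace(result, cutoff=float(cutoff), direction=direction)


def round_printed(value: float, decimals: int = 0) -> float:
    """Round half away from zero at the given number of decimals."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


# ---------------------------------------------------------------------------
# fractional polynomial (FP1) nonlinearity screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FPResult:
    """Outcome of the FP1 closed-test selection."""

    form: str  # null | linear | fp1
    power: float | None
    p_overall: float  # best FP1 vs null (2 df)
    p_nonlinear: float  # best FP1 vs linear (1 df)
    shift: float  # offset added to x before power transforms


def _fp_shift(x: np.ndarray) -> float:
    """Standard origin shift making x strictly positive for power transforms."""
    xmin = float(np.min(x))
    if xmin > 0:
        return 0.0
    diffs = np.diff(np.unique(x))
    step = float(np.min(diffs)) if diffs.size else 1.0
    return -xmin + step


def _deviance(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = y.size
    return n * math.log(rss / n)


def fp_transform(x: np.ndarray, power: float) -> np.ndarray:
    """Single fractional-polynomial transform; power 0 is the natural log."""
    return np.log(x) if power == 0 else x ** power


def fp_select(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
) -> FPResult:
    """Choose among {null, straight line, best FP1 power} by closed testing.

    The best single power is picked by deviance over :data:`FP_POWERS`; a
    first test against the intercept-only model on 2 degrees of freedom
    (one for the power selection, one for the slope) guards the family
    type-I error, then the best power is tested against the straight line on
    1 degree of freedom.  Nonlinearity is reported only when both tests
    reject at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise InsufficientDataError(f"only {x.size} complete cases for FP screen")
    if np.ptp(x) == 0:
        raise RankDeficiencyError("predictor is constant")
    shift = _fp_shift(x)
    xs = x + shift
    if np.min(xs) <= 0:
        raise TransformError("predictor not positive after standard shift")
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    dev_null = n * math.log(rss0 / n)
    devs = {p: _deviance(fp_transform(xs, p), y) for p in FP_POWERS}
    best = min(devs, key=lambda p: devs[p])
    p_overall = float(stats.chi2.sf(dev_null - devs[best], 2))
    p_nonlinear = float(stats.chi2.sf(devs[1.0] - devs[best], 1))
    if p_overall > alpha:
        form, power = "null", None
    elif p_nonlinear > alpha:
        form, power = "linear", 1.0
    else:
        form, power = "fp1", best
    return FPResult(
        form=form,
        power=power,
        p_overall=p_overall,
        p_nonlinear=p_nonlinear,
        shift=shift,
    )


# ---------------------------------------------------------------------------
# whole-table screening
# ---------------------------------------------------------------------------

#: (column, report label, unit, group, numeric-or-(reference, positive-level))
SCREEN_PLAN: tuple[tuple, ...] = (
    ("depth_ratio", "Breast depth ratio prone/supine", "ratio", "pendulousness", None),
    ("depth_diff", "Breast depth difference prone-supine", "mm", "pendulousness", None),
    ("breast_depth_prone", "Breast depth prone", "mm", "pendulousness", None),
    ("breast_volume_per_weight", "Breast volume/body weight ratio", "mL/kg", "breast_body", None),
    ("tumor_location", "Lower inner quadrant vs not", "binary", "tumor_location", ("not_liq", "lower_inner")),
    ("breast_volume_left", "Left breast volume supine", "mL", "breast_size", None),
    ("breast_volume_right", "Right breast volume supine", "mL", "breast_size", None),
    ("breast_depth_supine", "Breast depth supine", "mm", "breast_size", None),
    ("weight", "Weight", "kg", "body_size", None),
    ("bmi", "Body mass index", "kg/m2", "body_size", None),
    ("heart_volume", "Heart volume supine", "mL", "body_size", None),
    ("height", "Height", "cm", "body_size", None),
    ("lung_volume_right", "Right lung volume supine", "L", "dibh", None),
    ("lung_volume_total", "Total lung volume supine", "L", "dibh", None),
    ("lung_volume_left", "Left lung volume supine", "L", "dibh", None),
    ("age", "Age", "years", "dibh", None),
    ("lad_chest_distance", "LAD-chest wall distance", "mm", "dibh", None),
    ("couch", "Couch type Varian vs Bionix", "binary", "other", ("bionix", "varian")),
    ("preference", "Preference prone vs else", "binary", "other", ("else", "prone")),
    ("prone_score", "Prone penalty score", "%dose", "post_dosimetry", None),
    ("supine_score", "Supine penalty score", "%dose", "post_dosimetry", None),
)


def _screen_column(records: pd.DataFrame, column: str, coding) -> np.ndarray:
    if coding is None:
        return pd.to_numeric(records.get(column), errors="coerce").to_numpy(dtype=float)
    reference, positive = coding
    raw = records.get(column)
    if raw is None:
        return np.full(len(records), np.nan)
    collapsed = raw.where(raw.isna(), np.where(raw == positive, positive, reference))
    return dummy_code(collapsed, reference, levels={reference, positive})


def screen_all(
    records: pd.DataFrame,
    *,
    alpha: float = 0.05,
    run_fp: bool = True,
    exclude: Sequence | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Univariable screen of every characteristic against ``delta_penalty``.

    ``records`` is one row per patient with the characteristics columns, the
    paired penalty scores (``prone_score``, ``supine_score``) and
    ``delta_penalty``.  Returns one ordered row per characteristic with the
    robust fit, the significance flag, the cutoff and, when ``run_fp``, the
    FP1 nonlinearity verdict.  Characteristics with too few complete cases
    are skipped with a warning.  ``exclude`` drops the listed patient ids
    first (outlier sensitivity analysis).
    """
    records = derive_features(records)
    if exclude:
        records = records[~records["patient_id"].isin(set(exclude))]
    y = pd.to_numeric(records["delta_penalty"], errors="coerce").to_numpy(dtype=float)
    rows = []
    for column, label, unit, group, coding in SCREEN_PLAN:
        x = _screen_column(records, column, coding)
        try:
            res = robust_fit(x, y, name=label, unit=unit, min_n=min_n)
        except (InsufficientDataError, RankDeficiencyError) as exc:
            logger.warning("skipping %s: %s", label, exc)
            continue
        res = replace(res, group=group)
        if coding is not None:
            # a 0/1 predictor has no meaningful sign-change threshold
            res = replace(res, cutoff=None)
        fp_form, fp_power = None, None
        if run_fp and coding is None:
            try:
                fp = fp_select(x[~(np.isnan(x) | np.isnan(y))],
                               y[~(np.isnan(x) | np.isnan(y))], alpha=alpha)
                fp_form, fp_power = fp.form, fp.power
            except (InsufficientDataError, RankDeficiencyError, TransformError):
                pass
        rows.append(
            {
                "characteristic": res.name,
                "group": group,
                "n": res.n,
                "intercept": res.intercept,
                "coefficient": res.coefficient,
                "coefficient_sd": res.coefficient_sd,
                "significant": res.significant,
                "cutoff": res.cutoff,
                "direction": res.direction,
                "unit": res.unit,
                "fp_form": fp_form,
                "fp_power": fp_power,
            }
        )
    return pd.DataFrame(rows)
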