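"""Loewe-additivity synergy scoring of drug-combination matrices.

A combination experiment measures cell viability on a dose grid of two
drugs including both monotherapy margins and the untreated control.
Viability is normalized to the untreated-control mean and converted to
inhibition (100 - viability%).  Each monotherapy is summarized by a
four-parameter logistic (4PL) curve

    y(d) = L + (U - L) / (1 + (ec50 / d)^h)

with asymptotes L <= U clamped to [0, 100].  The Loewe-expected effect
of a dose pair (d1, d2) is the effect level y solving

    d1 / D1(y) + d2 / D2(y) = 1,

where Di(y) is the monotherapy dose of drug i producing effect y
(the inverse 4PL); the equation is solved by bisection.  Under this
reference a drug "combined" with itself is exactly additive (zero
synergy).  The synergy surface is delta = observed - expected inhibition
(percentage points) per non-margin dose pair; the reported summary is
the 75th percentile of delta over the dose range, with a two-sided
bootstrap p-value from resampling replicate wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: curves spanning less than this inhibition range are treated as flat
FLAT_RANGE = 5.0


@dataclass
class DoseResponseCurve:
    """Fitted 4PL monotherapy curve on the inhibition scale (0..100)."""

    lower: float
    upper: float
    ec50: float
    hill: float
    flat: bool = False
    flat_level: float = 0.0

    def response(self, dose: float) -> float:
        if self.flat:
            return self.flat_level
        if dose <= 0:
            return self.lower if self.hill > 0 else self.upper
        return self.lower + (self.upper - self.lower) / (
            1.0 + (self.ec50 / dose) ** self.hill)

    def inverse(self, effect: float) -> float:
        """Dose producing ``effect``; inf/0 outside the achievable range."""
        if self.flat:
            return np.inf
        lo, hi = min(self.lower, self.upper), max(self.lower, self.upper)
        if effect <= lo:
            return 0.0 if self.hill > 0 else np.inf
        if effect >= hi:
            return np.inf if self.hill > 0 else 0.0
        ratio = (effect - self.lower) / (self.upper - effect)
        return self.ec50 * ratio ** (1.0 / self.hill)


def _4pl(d, lower, upper, ec50, hill):
    with np.errstate(over="ignore", divide="ignore"):
        return lower + (upper - lower) / (1.0 + (ec50 / np.maximum(d, 1e-12))
                                          ** hill)


def fit_4pl(doses: np.ndarray, inhibition: np.ndarray) -> DoseResponseCurve:
    """Least-squares 4PL fit of monotherapy inhibition data.

    Requires >= 4 distinct doses including 0.  Asymptotes are bounded to
    [0, 100]; the Hill slope is sign-free (a warning is logged when the
    fitted response decreases with dose).  When the observed response
    range is below ``FLAT_RANGE`` percentage points the curve is flagged
    flat and summarized by its mean response.
    """
    doses = np.asarray(doses, dtype=float)
    inhibition = np.asarray(inhibition, dtype=float)
    if not np.all(np.isfinite(doses)):
        raise ValueError("non-finite dose")
    if len(np.unique(doses)) < 4 or 0.0 not in doses:
        raise ValueError("need >= 4 distinct doses including 0")
    span = np.nanmax(inhibition) - np.nanmin(inhibition)
    if span < FLAT_RANGE:
        return DoseResponseCurve(0.0, 0.0, 1.0, 1.0, flat=True,
                                 flat_level=float(np.nanmean(inhibition)))
    pos = doses > 0
    ec50_guess = float(np.median(doses[pos]))
    p0 = [max(float(np.nanmin(inhibition)), 0.0),
          min(float(np.nanmax(inhibition)), 100.0), ec50_guess, 1.0]
    bounds = ([0.0, 0.0, 1e-9, -20.0], [100.0, 100.0, 1e9, 20.0])
    params, _ = curve_fit(_4pl, doses, inhibition, p0=p0, bounds=bounds,
                          maxfev=20000)
    lower, upper, ec50, hill = params
    if lower > upper:
        lower, upper, hill = upper, lower, -hill
    if hill < 0:
        logger.warning("fitted inhibition decreases with dose")
    return DoseResponseCurve(float(lower), float(upper), float(ec50),
                             float(hill))


def loewe_expected(curve1: DoseResponseCurve, curve2: DoseResponseCurve,
                   d1: float, d2: float, tol: float = 1e-6) -> float:
    """Loewe-additivity expected inhibition at the dose pair (d1, d2).

    Margins reduce to the monotherapy response; a flat (inactive) curve
    contributes nothing, so the expected effect is that of the active
    drug alone.  If the additivity equation has no root in the
    achievable effect range the expected value is clamped to the nearer
    bound.
    """
    if curve1.flat and curve2.flat:
        return max(curve1.flat_level, curve2.flat_level)
    if d1 <= 0 or curve1.flat:
        return curve2.response(d2) if not curve2.flat \
            else curve1.response(d1)
    if d2 <= 0 or curve2.flat:
        return curve1.response(d1)

    def f(y: float) -> float:
        D1, D2 = curve1.inverse(y), curve2.inverse(y)
        term1 = d1 / D1 if D1 > 0 else np.inf
        term2 = d2 / D2 if D2 > 0 else np.inf
        return term1 + term2 - 1.0

    y_lo = max(min(curve1.lower, curve1.upper),
               min(curve2.lower, curve2.upper))
    y_hi = min(max(curve1.lower, curve1.upper),
               max(curve2.lower, curve2.upper))
    if y_hi <= y_lo:
        return float(np.clip(max(curve1.response(d1), curve2.response(d2)),
                             y_lo, y_hi) if y_hi > y_lo else y_lo)
    eps = (y_hi - y_lo) * 1e-9
    a, b = y_lo + eps, y_hi - eps
    fa, fb = f(a), f(b)
    if fa < 0:  # even the smallest effect over-satisfies: clamp low
        return float(a)
    if fb > 0:  # doses exceed what the curves can express: clamp high
        return float(b)
    while b - a > tol:
        mid = 0.5 * (a + b)
        if f(mid) > 0:
            a = mid
        else:
            b = mid
    return float(0.5 * (a + b))


def _normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Viability as % of the untreated-control mean; adds inhibition."""
    ctrl = matrix[(matrix["dose_a"] == 0) & (matrix["dose_b"] == 0)]
    if len(ctrl) == 0:
        raise ValueError("matrix lacks the (0, 0) untreated control")
    ctrl_mean = ctrl["viability_percent"].mean()
    out = matrix.copy()
    out["viability_norm"] = 100.0 * out["viability_percent"] / ctrl_mean
    out["inhibition"] = 100.0 - out["viability_norm"]
    return out


def _delta_surface(matrix: pd.DataFrame) -> pd.DataFrame:
    """Observed-minus-expected inhibition per non-margin dose pair."""
    a_margin = matrix[matrix["dose_b"] == 0]
    b_margin = matrix[matrix["dose_a"] == 0]
    if a_margin["dose_a"].nunique() < 4 or b_margin["dose_b"].nunique() < 4:
        raise ValueError("missing or short monotherapy margin")
    curve_a = fit_4pl(a_margin["dose_a"].to_numpy(),
                      a_margin["inhibition"].to_numpy())
    curve_b = fit_4pl(b_margin["dose_b"].to_numpy(),
                      b_margin["inhibition"].to_numpy())
    combo = matrix[(matrix["dose_a"] > 0) & (matrix["dose_b"] > 0)]
    rows = []
    for (da, db), grp in combo.groupby(["dose_a", "dose_b"], sort=True):
        expected = loewe_expected(curve_a, curve_b, da, db)
        rows.append({"dose_a": da, "dose_b": db,
                     "observed": grp["inhibition"].mean(),
                     "expected": expected,
                     "delta": grp["inhibition"].mean() - expected})
    return pd.DataFrame(rows)


def synergy_score(matrix: pd.DataFrame, n_boot: int = 1000,
                  seed: int = 0) -> dict:
    """Score one drug-pair combination matrix for Loewe synergy.

    ``matrix`` is the long table for a single drug pair (columns dose_a,
    dose_b, replicate, viability_percent) including both margins and the
    untreated control.  Returns the delta surface, its 75th-percentile
    summary (percentage points of inhibition above additivity) and a
    two-sided bootstrap p-value from resampling replicate wells.
    """
    norm = _normalize(matrix)
    surface = _delta_surface(norm)
    summary = float(np.percentile(surface["delta"], 75))
    rng = np.random.default_rng(seed)
    groups = [grp.index.to_numpy() for _, grp
              in norm.groupby(["dose_a", "dose_b"], sort=True)]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(g, size=len(g), replace=True)
                               for g in groups])
        resampled = norm.loc[take]
        try:
            boot[b] = float(np.percentile(
                _delta_surface(resampled)["delta"], 75))
        except (RuntimeError, ValueError):
            boot[b] = np.nan
    boot = boot[np.isfinite(boot)]
    if len(boot):
        p_le = (1.0 + np.sum(boot <= 0)) / (len(boot) + 1.0)
        p_ge = (1.0 + np.sum(boot >= 0)) / (len(boot) + 1.0)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = np.nan
    return {"surface": surface, "summary": summary, "p_value": p,
            "n_boot": int(len(boot))}
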