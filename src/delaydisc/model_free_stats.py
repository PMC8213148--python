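"""Model-agnostic analyses of intertemporal choice data.

Two tracks, matched to the two task designs:

* seconds-scale grid data: the per-subject proportion of larger-later
  choices, arcsine-square-root transformed, compared between groups with
  Welch's unequal-variance t test;
* days-scale titration data: per-delay indifference points (the LL amount
  at which a subject is equally likely to take either option), normalized
  into an empirical discounting curve, summarized by the trapezoid area
  under the curve (AUC in [0, 1]; smaller = steeper discounting).

Also provides the Pearson chi-square test (no continuity correction) used
for 2x2 demographic contingency tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import chi2_contingency, ttest_ind

from .choice_models import Trial

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndifferenceCurve:
    """Normalized empirical discounting curve for one subject.

    ``points`` are (x, y) pairs with x = delay / max delay in (0, 1] strictly
    increasing and y = normalized subjective value in [0, 1]; an anchor
    (0, 1) is prepended by :func:`auc`.
    """

    points: Tuple[Tuple[float, float], ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("curve x values must be strictly increasing")
        if any(not (0.0 <= p[1] <= 1.0) for p in self.points):
            raise ValueError("curve y values must lie in [0, 1]")


def proportion_ll(trials: Sequence[Trial]) -> float:
    """Fraction of answered trials on which the larger-later option was chosen."""
    choices = [t.choice for t in trials if t.choice is not None]
    if not choices:
        raise ValueError("no trials with recorded choices")
    return float(np.mean(choices))


def arcsin_transform(p: float) -> float:
    """Variance-stabilizing arcsine-square-root transform of a proportion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    return math.asin(math.sqrt(p))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]
            ) -> Tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate variances with unequal means")
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2x2(counts) -> Tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction: (chi2, df, p)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def _logistic_indifference(amounts: np.ndarray, choices: np.ndarray,
                           lo: float, hi: float) -> float:
    """MLE of a rising logistic P(LL | amount) with positive slope; returns
    the amount at P = 0.5, clipped to [lo, hi]."""
    ss_max = amounts[choices == 0].max() if np.any(choices == 0) else None
    ll_min = amounts[choices == 1].min() if np.any(choices == 1) else None
    # complete separation (or one-sided behavior): midpoint-of-switch fallback
    if ss_max is None:
        return lo
    if ll_min is None:
        return hi
    if ss_max < ll_min:
        logger.info("complete separation; using midpoint of switch interval")
        return float(np.clip(0.5 * (ss_max + ll_min), lo, hi))

    def nll_at(x0: float) -> Tuple[float, float]:
        # profile the slope at fixed crossing point x0
        def nll(log_slope: float) -> float:
            p = expit(math.exp(log_slope) * (amounts - x0))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -float(np.sum(choices * np.log(p) + (1 - choices) * np.log1p(-p)))

        r = minimize_scalar(nll, bounds=(-8.0, 8.0), method="bounded")
        return float(r.fun), float(r.x)

    grid = np.linspace(lo, hi, 61)
    nlls = [nll_at(x0)[0] for x0 in grid]
    return float(grid[int(np.argmin(nlls))])


def estimate_indifference_points(trials: Sequence[Trial],
                                 delays: Sequence[float]) -> Dict[float, float]:
    """Per-delay LL amount at which the subject is indifferent (P(LL) = 0.5).

    Fits a monotone logistic of choice on LL amount within each delay;
    under complete separation falls back to the midpoint between the
    highest always-SS and lowest always-LL amount. Estimates are clipped to
    the observed amount range.
    """
    out: Dict[float, float] = {}
    for d in delays:
        sub = [t for t in trials if t.ll_delay == d and t.choice is not None]
        amounts = np.array([t.ll_amount for t in sub], dtype=float)
        if len(sub) < 4 or np.unique(amounts).size < 2:
            raise ValueError(f"need >= 4 choice trials with varying LL amounts at delay {d}")
        choices = np.array([t.choice for t in sub], dtype=float)
        out[float(d)] = _logistic_indifference(amounts, choices,
                                               float(amounts.min()), float(amounts.max()))
    return out


def indifference_curve(indiff_points: Dict[float, float], ss_amount: float,
                       max_delay: float, subject_id: str = "") -> IndifferenceCurve:
    """Normalize indifference points into an empirical discounting curve.

    x = delay / max_delay; y = ss_amount / indifference LL amount, i.e. the
    relative subjective value of one currency unit at that delay (1 at
    delay 0 by construction, smaller with steeper discounting).
    """
    pts = []
    for d in sorted(indiff_points):
        y = ss_amount / indiff_points[d]
        pts.append((d / max_delay, float(np.clip(y, 0.0, 1.0))))
    return IndifferenceCurve(points=tuple(pts), subject_id=subject_id)


def auc(curve: IndifferenceCurve) -> float:
    """Trapezoid area under the normalized discounting curve, in [0, 1].

    An anchor point (0, 1) — full value at zero delay — is prepended; the
    area is the sum over consecutive points of (x2 - x1) * (y1 + y2) / 2.
    """
    pts = list(curve.points)
    if not pts:
        raise ValueError("empty curve")
    if pts[0][0] <= 0.0:
        raise ValueError("curve x values must be positive (anchor is added here)")
    if pts[-1][0] > 1.0:
        raise ValueError("curve x values must not exceed 1 (delay / max delay)")
    pts = [(0.0, 1.0)] + pts
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def subject_summary(trials: Sequence[Trial], delays: Sequence[float] | None = None,
                    compute_auc: bool = False, subject_id: str = "") -> Dict[str, float]:
    """Per-subject model-free summary: proportion LL, its arcsine transform,
    and (for titration designs) per-delay indifference points and AUC."""
    p = proportion_ll(trials)
    out: Dict[str, float] = {"proportion_ll": p, "arcsin_prop_ll": arcsin_transform(p)}
    if compute_auc:
        if delays is None:
            delays = sorted({t.ll_delay for t in trials})
        points = estimate_indifference_points(trials, delays)
        ss_amount = trials[0].ss_amount
        curve = indifference_curve(points, ss_amount, max(delays), subject_id)
        out["auc"] = auc(curve)
        for d, v in points.items():
            out[f"indiff[{d:g}]"] = v
    return out
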