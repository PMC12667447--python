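"""Four-parameter logistic (4PL) viability curves and IC50 estimation.

Model: response(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill) with
top > bottom and hill > 0, so viability falls with dose and the response
at d = ic50 is the midpoint (top + bottom) / 2.  Fitting is least squares
with quartile-based initialization and a small multi-start over IC50 and
Hill-slope guesses; the IC50 is optimized on the log scale to keep it
positive and make the fit equivariant under dose-unit changes.  An IC50
landing outside the tested dose range is reported as range-censored
("> max dose" / "< min dose"), not as a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

N_STARTS = 5


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    responses: np.ndarray
    top: float
    bottom: float
    ic50: float  # point estimate, or the range bound when censored
    hill: float
    ic50_censored: Literal["exact", "above_range", "below_range"]
    rss: float

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(dose, dtype=float), self.top, self.bottom,
                        self._ic50_fit, self.hill)

    _ic50_fit: float = 0.0  # uncensored fitted value backing predict()


def _four_pl(d: np.ndarray, top: float, bottom: float, ic50: float,
             hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(d) - np.log(ic50))))


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> DoseResponseCurve:
    """Fit a 4PL curve by multi-start least squares.

    Requires >= 5 distinct positive doses and finite responses.  Raises if
    no start converges to a valid fit (top > bottom, finite parameters).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must align")
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    if len(np.unique(d)) < 5:
        raise ValueError("need >= 5 distinct doses")

    # flat response: amplitude unidentifiable, IC50 beyond the tested range
    if np.ptp(y) < 1e-6 * (abs(float(np.mean(y))) + 1.0):
        m = float(np.mean(y))
        return DoseResponseCurve(d, y, m, m, float(d.max()), 1.0, "above_range",
                                 float(np.sum((y - m) ** 2)), _ic50_fit=np.inf)

    logd = np.log(d)
    top0 = float(np.quantile(y, 0.95))
    bot0 = float(np.quantile(y, 0.05))
    if top0 <= bot0:
        top0, bot0 = bot0 + 1.0, bot0
    mid = (top0 + bot0) / 2.0
    # dose whose response is nearest the midpoint seeds log-IC50
    lic0 = float(logd[np.argmin(np.abs(y - mid))])
    starts = [
        (top0, bot0, lic0, 0.0),                       # hill = 1
        (top0, bot0, float(logd.min()), 0.0),
        (top0, bot0, float(logd.max()), 0.0),
        (top0, bot0, float(np.median(logd)), np.log(0.5)),
        (top0, bot0, float(np.median(logd)), np.log(2.0)),
    ][:N_STARTS]

    def resid(theta: np.ndarray) -> np.ndarray:
        top, bottom, lic, lh = theta
        return _four_pl(d, top, bottom, np.exp(lic), np.exp(lh)) - y

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, np.asarray(x0), method="lm", max_nfev=5000)
        except Exception:
            continue
        if not np.isfinite(sol.x).all():
            continue
        rss = float(np.sum(sol.fun**2))
        top, bottom = float(sol.x[0]), float(sol.x[1])
        if top <= bottom:
            continue
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            "4PL fit failed to converge from all starts; "
            f"response range {float(np.ptp(y)):.3g} over {len(d)} doses"
        )
    rss, (top, bottom, lic, lh) = best[0], best[1]
    ic50 = float(np.exp(lic))
    hill = float(np.exp(lh))
    censored: Literal["exact", "above_range", "below_range"] = "exact"
    reported = ic50
    if ic50 > d.max():
        censored, reported = "above_range", float(d.max())
    elif ic50 < d.min():
        censored, reported = "below_range", float(d.min())
    return DoseResponseCurve(d, y, float(top), float(bottom), reported, hill,
                             censored, rss, _ic50_fit=ic50)


@dataclass
class FoldChange:
    """IC50 fold change of a drug alone vs in combination.

    ``value`` is ic50_alone / ic50_combo; when the alone arm is
    above-range censored the value is a lower bound (``censored`` = True,
    rendered as e.g. "> 2.89").
    """

    value: float
    censored: bool = False

    def __str__(self) -> str:
        return (">" if self.censored else "") + format(self.value, ".4g")


def fold_change(alone: DoseResponseCurve, combo: DoseResponseCurve) -> FoldChange:
    """IC50 fold reduction achieved by the combination.

    Both curves exact: the plain ratio.  Alone censored above range: a
    lower bound using the range bound.  A combo censored above range leaves
    the fold change undefined.
    """
    if combo.ic50_censored == "above_range":
        raise ValueError("fold change undefined: combination IC50 above tested range")
    if alone.ic50_censored == "above_range":
        return FoldChange(alone.ic50 / combo.ic50, censored=True)
    if alone.ic50_censored != "exact" or combo.ic50_censored != "exact":
        raise ValueError("fold change needs exact or above-range-alone IC50s")
    return FoldChange(alone.ic50 / combo.ic50)
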