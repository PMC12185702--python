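"""Four-parameter logistic dose-response fitting and drug classification.

The 4PL model is ``y = bottom + (top - bottom) / (1 + (x / IC50)^h)``: ``top``
is the response at vanishing dose, ``bottom`` the plateau at saturating dose,
and the fitted curve passes through ``(top + bottom) / 2`` at ``x = IC50``.
Fitting is least squares with multi-start over a log-spaced IC50 grid.

Single-dose screens are summarised per drug by the relative metabolic
activity alone (A) and after 24 h MEK-inhibitor pre-treatment (T), both
against matched controls (= 1), and classified into growth-promoting /
cytotoxic x MAPK-dependent / -independent, or ineffective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import four_pl

CLASSES = (
    "ineffective",
    "MAPK-independent growth-promoting",
    "MAPK-dependent growth-promoting",
    "MAPK-dependent cytotoxic",
    "MAPK-independent cytotoxic",
)


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, x):
        return four_pl(x, self.top, self.bottom, self.ic50, self.hill)


def fit_4pl(doses, responses, n_starts: int = 12) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start over a log-spaced IC50 grid.

    Requires >= 4 distinct doses and non-constant responses.  The best
    converged start (lowest residual sum of squares) is returned.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.allclose(y, y[0]):
        raise ValueError("responses do not vary: curve unidentifiable")
    lo, hi = x.min(), x.max()
    top0, bot0 = float(y[np.argmin(x)]), float(y[np.argmax(x)])
    best = None
    for ic0 in np.geomspace(lo, hi, n_starts):
        for h0 in (0.8, 1.5):
            sign = 1.0 if top0 >= bot0 else -1.0
            p0 = (max(top0, bot0), min(top0, bot0), ic0, sign * h0)
            try:
                popt, _ = curve_fit(
                    four_pl, x, y, p0=p0, maxfev=4000,
                    bounds=([-np.inf, -np.inf, lo / 1e3, -10.0],
                            [np.inf, np.inf, hi * 1e3, 10.0]))
            except RuntimeError:
                continue
            rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return DoseResponseFit(top0, bot0, float(np.sqrt(lo * hi)), 1.0,
                               float(np.sum((y - y.mean()) ** 2)), False)
    (top, bottom, ic50, hill), rss = best
    if hill < 0:  # canonical orientation: top = low-dose asymptote
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(float(top), float(bottom), float(ic50),
                           float(hill), rss, True)


def ic50_fold(ic50_a: float, ic50_b: float) -> float:
    """Fold change ``b / a`` (how many-fold larger condition b's IC50 is)."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_b / ic50_a


def mean_ic50_fold(ic50s_a, ic50s_b) -> float:
    """Mean fold across paired models = arithmetic mean of per-model ratios."""
    return float(np.mean([ic50_fold(a, b) for a, b in zip(ic50s_a, ic50s_b)]))


def classify_drug(A: float, T: float, delta: float = 0.2) -> str:
    """Classify a single-dose screen result (control = 1).

    ``A`` is the relative metabolic activity of the drug alone, ``T`` after
    MEKi pre-treatment.  ``delta`` bounds the "marginal effect" band:
    ineffective when both A and T sit within 1 +/- delta; growth-promoting
    when A > 1 + delta (MAPK-dependent if the effect disappears under
    pre-treatment); cytotoxic when A < 1 - delta (MAPK-dependent if
    pre-treatment rescues the cells).  A drug inert on its own
    (|A - 1| <= delta) is called ineffective regardless of T, which makes
    the rule a total partition of the (A, T) plane.
    """
    if A < 0 or T < 0:
        raise ValueError("activities must be non-negative")
    if abs(A - 1.0) <= delta:
        return "ineffective"
    if A > 1.0 + delta:
        return ("MAPK-independent growth-promoting" if T > 1.0 + delta
                else "MAPK-dependent growth-promoting")
    # A < 1 - delta
    return ("MAPK-independent cytotoxic" if T < 1.0 - delta
            else "MAPK-dependent cytotoxic")
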