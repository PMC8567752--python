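"""Semi-quantitative perfusion features derived from a fitted Brix curve.

All landmarks are evaluated on the fitted model, not on raw samples:

* ``PE``  — peak enhancement, the maximum of E(t) over the acquisition window
* ``TTP`` — time to peak, the corresponding t in seconds
* ``wash_in`` / ``wash_out`` — maximum / minimum of dE/dt over the window
* ``AUC`` — the initial area under the enhancement curve, integrated in
  closed form over a fixed early window (60 s by default)

For 0 < k_el < k_ep the peak is at the closed form
``ln(k_ep/k_el)/(k_ep - k_el)`` and the derivative's only interior stationary
point sits at twice that value; with k_el <= 0 the curve increases
monotonically and peaks at the window end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brix import BrixParams, brix_derivative, brix_enhancement, DEGENERATE_RTOL

__all__ = [
    "CurveFeatures",
    "compute_ttp_pe",
    "compute_washin_washout",
    "compute_auc",
    "compute_features",
    "DEFAULT_AUC_WINDOW",
]

DEFAULT_AUC_WINDOW = 60.0  # s after bolus arrival


@dataclass(frozen=True)
class CurveFeatures:
    PE: float
    TTP: float
    AUC: float
    wash_in: float
    wash_out: float
    window_end: float


def _peak_time(kep: float, kel: float) -> float:
    """Unclipped peak location of E for k_el > 0 (degenerate: 1/k_ep)."""
    if abs(kep - kel) < DEGENERATE_RTOL * abs(kep):
        return 1.0 / kep
    return float(np.log(kep / kel) / (kep - kel))


def compute_ttp_pe(params: BrixParams, window_end: float) -> tuple[float, float]:
    """Time to peak (s) and peak enhancement over [0, window_end].

    k_el <= 0 means enhancement never falls within the window, so the peak is
    taken at the window end.
    """
    if window_end <= 0:
        raise ValueError("window_end must be positive")
    if params.kel <= 0:
        ttp = window_end
    else:
        ttp = min(_peak_time(params.kep, params.kel), window_end)
    return ttp, float(brix_enhancement(ttp, params))


def compute_washin_washout(params: BrixParams, window_end: float) -> tuple[float, float]:
    """Max (wash-in) and min (wash-out) of dE/dt over [0, window_end].

    dE/dt has at most one interior stationary point, so the extrema are found
    among {0, that point, window_end}.
    """
    if window_end <= 0:
        raise ValueError("window_end must be positive")
    kep, kel = params.kep, params.kel
    candidates = [0.0, window_end]
    if abs(kep - kel) < DEGENERATE_RTOL * abs(kep):
        t_stat = 2.0 / kep
    elif kel == 0.0:
        # E'(t) = A*kep*exp(-kep t): strictly decreasing, no stationary point
        t_stat = np.inf
    else:
        # solve E''(t)=0: kep^2 exp(-kep t) = kel^2 exp(-kel t)
        t_stat = float(np.log(kep**2 / kel**2) / (kep - kel))
    if 0.0 < t_stat < window_end:
        candidates.append(t_stat)
    vals = [float(brix_derivative(t, params)) for t in candidates]
    return max(vals), min(vals)


def compute_auc(params: BrixParams, auc_window: float = DEFAULT_AUC_WINDOW) -> float:
    """Closed-form integral of E over [0, auc_window] (enhancement * s)."""
    if auc_window <= 0:
        raise ValueError("auc_window must be positive")
    A, kep, kel, T = params.A, params.kep, params.kel, auc_window
    if abs(kep - kel) < DEGENERATE_RTOL * abs(kep):
        # integral of A*kep*t*exp(-kep t)
        return float(A * (1.0 - np.exp(-kep * T) * (1.0 + kep * T)) / kep)
    term_ep = (1.0 - np.exp(-kep * T)) / kep
    term_el = (1.0 - np.exp(-kel * T)) / kel
    return float(A * kep / (kel - kep) * (term_ep - term_el))


def compute_features(
    params: BrixParams,
    window_end: float,
    auc_window: float = DEFAULT_AUC_WINDOW,
) -> CurveFeatures:
    """All semi-quantitative features for one fitted curve.

    ``window_end`` should be the last normalized timestamp of the patient's
    curve (the acquisition window on the bolus-arrival clock).
    """
    ttp, pe = compute_ttp_pe(params, window_end)
    win, wout = compute_washin_washout(params, window_end)
    auc = compute_auc(params, auc_window)
    return CurveFeatures(PE=pe, TTP=ttp, AUC=auc, wash_in=win, wash_out=wout,
                         window_end=window_end)
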