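"""Four-parameter log-logistic (4PL) dose-response fitting and hit confirmation.

The confirmation stage re-tests candidate compounds over a wide dose range on
both lines, fits

    v(x) = bottom + (top - bottom) / (1 + (x / ic50)^h)

to percent viability on log-dose, and calls collateral sensitivity when the
IC50 fold-change ic50_resistant / ic50_sensitive drops below the reciprocal
of a configurable resistance-ratio threshold. IC50 here is the relative IC50
(the curve's inflection), which stays well defined when the maximal effect
is partial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import LINE_RESISTANT, LINE_SENSITIVE

__all__ = [
    "DoseResponseFit",
    "ConfirmationResult",
    "four_pl",
    "fit_4pl",
    "resistance_ratio",
    "confirm_hits",
]

#: fits with a top-bottom span below this (percentage points) carry no dose
#: information and are reported unconverged ("non-toxic").
MIN_EFFECT_SPAN = 5.0


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate the 4PL curve at ``dose`` (same units as ``ic50``)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters for one compound x line series."""

    compound_id: str
    line: str
    bottom: float
    top: float
    ic50: float
    hill_slope: float
    rss: float
    converged: bool
    message: str = ""


@dataclass
class ConfirmationResult:
    """Outcome of the dose-range follow-up for one candidate compound."""

    compound_id: str
    ic50_sensitive: Optional[float]
    ic50_resistant: Optional[float]
    resistance_ratio: Optional[float]
    confirmed_collateral: bool
    testable: bool = True
    message: str = ""


def _fit_once(logx, y, p0, bounds):
    def model(lx, bottom, top, logic50, h):
        return bottom + (top - bottom) / (1.0 + np.exp(h * (lx - logic50)))

    popt, _ = curve_fit(
        model, logx, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
    )
    resid = y - model(logx, *popt)
    return popt, float(resid @ resid)


def fit_4pl(
    doses: Sequence[float],
    viabilities: Sequence[float],
    compound_id: str = "",
    line: str = "",
) -> DoseResponseFit:
    """Least-squares 4PL fit on log-dose with multi-start initialization.

    Initial top/bottom come from the per-dose-mean extremes, the Hill slope
    starts at 1, and the IC50 is started from the dose nearest half-range
    plus two additional log-spaced starts across the tested range; the best
    residual sum of squares wins. The fit is reported unconverged — with the
    parameters still populated where meaningful — when the optimizer fails,
    the fitted IC50 leaves the tested dose range, or the fitted span is too
    small to evidence any dose effect (flat, "non-toxic" series).
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if doses.shape != y.shape:
        raise ValueError("doses and viabilities must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (log-dose fit)")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses")

    logx = np.log(doses)
    # per-dose means guide the initial guesses
    order = np.argsort(doses)
    uniq, inv = np.unique(doses[order], return_inverse=True)
    means = np.bincount(inv, weights=y[order]) / np.bincount(inv)
    top0, bot0 = float(means.max()), float(means.min())
    half = 0.5 * (top0 + bot0)
    ic50_data = uniq[int(np.argmin(np.abs(means - half)))]
    lo, hi = float(np.log(uniq[0])), float(np.log(uniq[-1]))
    starts = [float(np.log(ic50_data))] + list(np.linspace(lo, hi, 4)[1:3])

    bounds = (
        [-50.0, -50.0, lo - 3.0, 0.05],
        [max(200.0, y.max() + 50.0), max(200.0, y.max() + 50.0), hi + 3.0, 20.0],
    )
    best = None
    for s in starts:
        try:
            popt, rss = _fit_once(logx, y, [bot0, top0, s, 1.0], bounds)
        except (RuntimeError, ValueError):
            continue
        if best is None or rss < best[1]:
            best = (popt, rss)

    if best is None:
        return DoseResponseFit(
            compound_id, line, np.nan, np.nan, np.nan, np.nan, np.nan, False, "optimizer failed"
        )
    (bottom, top, logic50, h), rss = best
    if bottom > top:  # canonicalize: top is the high-viability asymptote
        bottom, top, h = top, bottom, -h
    ic50 = float(np.exp(logic50))
    # the fitted effect must clear both the minimum span and 3x the residual
    # noise, else a flat noisy series "converges" by chasing noise
    resid_sd = np.sqrt(rss / max(y.size - 4, 1))
    converged, message = True, ""
    if top - bottom < max(MIN_EFFECT_SPAN, 3.0 * resid_sd):
        converged, message = False, "no dose effect (non-toxic over tested range)"
    elif not (uniq[0] <= ic50 <= uniq[-1]):
        converged, message = False, "fitted IC50 outside tested dose range"
    elif h <= 0:
        converged, message = False, "non-monotone fit"
    return DoseResponseFit(
        compound_id=compound_id,
        line=line,
        bottom=float(bottom),
        top=float(top),
        ic50=ic50,
        hill_slope=float(h),
        rss=rss,
        converged=converged,
        message=message,
    )


def resistance_ratio(
    fit_resistant: DoseResponseFit, fit_sensitive: DoseResponseFit
) -> Optional[float]:
    """IC50 fold-change ic50_resistant / ic50_sensitive.

    Large ratios mean the mutation protects (resistance phenotype); ratios
    far below 1 mean the mutation sensitizes (collateral sensitivity).
    Undefined (None) when either fit did not converge.
    """
    if not (fit_resistant.converged and fit_sensitive.converged):
        return None
    return fit_resistant.ic50 / fit_sensitive.ic50


def fit_dose_response_table(dr: pd.DataFrame) -> list[DoseResponseFit]:
    """Fit every compound x line series of a long-format dose-response table."""
    fits = []
    for (cid, line), sub in dr.groupby(["compound_id", "line"], sort=True):
        fits.append(
            fit_4pl(sub["dose_nM"].to_numpy(), sub["viability_pct"].to_numpy(), cid, line)
        )
    return fits


def confirm_hits(
    candidates: Sequence[str],
    dose_response: pd.DataFrame,
    ratio_threshold: float = 10.0,
) -> list[ConfirmationResult]:
    """Confirm candidate hits from their wide-dose-range series on both lines.

    A candidate is confirmed collateral-sensitive iff both line fits converge
    and ic50_resistant / ic50_sensitive < 1 / ratio_threshold. Candidates
    missing a series for either line are marked untestable. The full table is
    returned regardless of confirmation outcome.
    """
    results = []
    for cid in candidates:
        sub = dose_response[dose_response["compound_id"] == cid]
        fits = {}
        for line in (LINE_SENSITIVE, LINE_RESISTANT):
            s = sub[sub["line"] == line]
            if s.empty:
                fits[line] = None
            else:
                fits[line] = fit_4pl(
                    s["dose_nM"].to_numpy(), s["viability_pct"].to_numpy(), cid, line
                )
        if fits[LINE_SENSITIVE] is None or fits[LINE_RESISTANT] is None:
            results.append(
                ConfirmationResult(cid, None, None, None, False, testable=False,
                                   message="missing dose-response series for a line")
            )
            continue
        fs, fr = fits[LINE_SENSITIVE], fits[LINE_RESISTANT]
        ratio = resistance_ratio(fr, fs)
        confirmed = ratio is not None and ratio < 1.0 / ratio_threshold
        results.append(
            ConfirmationResult(
                compound_id=cid,
                ic50_sensitive=fs.ic50 if fs.converged else None,
                ic50_resistant=fr.ic50 if fr.converged else None,
                resistance_ratio=ratio,
                confirmed_collateral=bool(confirmed),
                message="" if ratio is not None else "unconverged fit on at least one line",
            )
        )
    return results
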