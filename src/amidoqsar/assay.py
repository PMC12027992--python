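"""Enzyme-inhibition arithmetic: % inhibition, bands, occupancy, IC50.

The screen measures residual hydrolytic activity of human DPP III (0.75 nM,
Arg-Arg-2-naphthylamide substrate) in the presence of 30 µM inhibitor.
Percent inhibition compares inhibited to control activity; compounds are
classed into five inhibition bands; per-substituent-group potency is
summarised as a relative occupancy; dose–response series are fitted with a
log-logistic curve to estimate IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize

__all__ = [
    "InhibitionBand",
    "percent_inhibition",
    "classify_band",
    "relative_occupancy",
    "DoseResponse",
    "Ic50Fit",
    "fit_ic50",
]


class InhibitionBand(str, Enum):
    """Inhibition bands partitioning [0, 100], lower bound inclusive."""

    strong = "strong"      # >= 90
    high = "high"          # >= 80, < 90
    moderate = "moderate"  # >= 50, < 80
    mild = "mild"          # >= 20, < 50
    weak = "weak"          # < 20


_BAND_EDGES = (
    (90.0, InhibitionBand.strong),
    (80.0, InhibitionBand.high),
    (50.0, InhibitionBand.moderate),
    (20.0, InhibitionBand.mild),
)


def percent_inhibition(control_activity: float, inhibited_activity: float) -> float:
    """% inh. = (control − inhibited) / control × 100.

    Negative values (apparent activation) are returned unclipped but
    trigger a warning.
    """
    if control_activity <= 0:
        raise ValueError("control activity must be positive")
    pct = (control_activity - inhibited_activity) / control_activity * 100.0
    if pct < 0:
        warnings.warn(
            f"negative % inhibition ({pct:.2f}): apparent activation",
            stacklevel=2,
        )
    return pct


def classify_band(pct_inh: float) -> InhibitionBand:
    """Map a % inhibition to its band (thresholds 90/80/50/20, inclusive)."""
    for lower, band in _BAND_EDGES:
        if pct_inh >= lower:
            return band
    return InhibitionBand.weak


def relative_occupancy(compound_set, group: str) -> float:
    """Σ % inh. over a substituent group, relative to 100 per compound.

    Equivalently the group mean % inhibition divided by 100; reported
    rounded to two decimals.
    """
    members = compound_set.group(group)
    total = sum(r.pct_inh_30uM for r in members)
    return round(total / (100.0 * len(members)), 2)


@dataclass(frozen=True)
class DoseResponse:
    """Inhibitor dose–response series (concentrations in µM)."""

    concentrations: tuple
    pct_inh: tuple
    replicates: int = 3

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        p = np.asarray(self.pct_inh, dtype=float)
        if c.shape != p.shape:
            raise ValueError("concentrations and pct_inh differ in length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")

    @property
    def conc(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    @property
    def response(self) -> np.ndarray:
        return np.asarray(self.pct_inh, dtype=float)


@dataclass(frozen=True)
class Ic50Fit:
    """Result of a log-logistic dose–response fit."""

    ic50_uM: float
    hill_slope: float
    residual_sse: float
    converged: bool
    bottom: float = 0.0
    top: float = 100.0
    message: str = ""

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        frac = 1.0 / (1.0 + (self.ic50_uM / c) ** self.hill_slope)
        return self.bottom + (self.top - self.bottom) * frac


def _two_pl(logc, log_ic50, hill):
    return 100.0 / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))


def _four_pl(logc, log_ic50, hill, bottom, top):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))


def fit_ic50(dr: DoseResponse, model: str = "2pl") -> Ic50Fit:
    """Least-squares IC50 from % inhibition vs concentration.

    ``model="2pl"`` (default) fixes the asymptotes at 0 and 100 — the
    natural choice since % inhibition is already normalised to the control —
    and fits log10(IC50) and the Hill slope.  ``model="4pl"`` frees both
    asymptotes.  A flat response is rejected; optimisation failures return
    ``converged=False`` with the optimizer message.
    """
    c = dr.conc
    y = dr.response
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.ptp(y) < 1e-12:
        raise ValueError("flat dose-response: IC50 is unidentifiable")
    logc = np.log10(c)
    # start at the concentration closest to half-maximal response
    guess_log_ic50 = logc[np.argmin(np.abs(y - 50.0))]
    try:
        if model == "2pl":
            popt, _ = optimize.curve_fit(
                _two_pl, logc, y, p0=[guess_log_ic50, 1.0], maxfev=20000
            )
            log_ic50, hill = popt
            bottom, top = 0.0, 100.0
            resid = y - _two_pl(logc, *popt)
        elif model == "4pl":
            popt, _ = optimize.curve_fit(
                _four_pl,
                logc,
                y,
                p0=[guess_log_ic50, 1.0, float(y.min()), float(y.max())],
                maxfev=20000,
            )
            log_ic50, hill, bottom, top = popt
            resid = y - _four_pl(logc, *popt)
        else:
            raise ValueError(f"unknown model {model!r} (use '2pl' or '4pl')")
    except RuntimeError as exc:  # curve_fit non-convergence
        return Ic50Fit(
            ic50_uM=float("nan"),
            hill_slope=float("nan"),
            residual_sse=float("nan"),
            converged=False,
            message=str(exc),
        )
    return Ic50Fit(
        ic50_uM=float(10.0**log_ic50),
        hill_slope=float(hill),
        residual_sse=float(np.sum(resid**2)),
        converged=True,
        bottom=float(bottom),
        top=float(top),
    )
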