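"""Quantitative assay computations: Hill dose-response, -ddCt, growth rules.

``fit_hill`` fits a decreasing Hill curve ``OD(c) = top / (1 + (c/ic50)**hill)``
to endpoint optical densities along a compound gradient; the minimal
inhibitory concentration (MIC) is defined as the fitted IC50.  ``ddct``
computes relative expression as -ddCt against an internal reference gene.
``growth_endpoint`` and ``final_od`` implement the plate-reader endpoint
and background conventions: the endpoint is when the no-plant control
reaches 90% of its saturation OD, and the background of a well is its
fifth-lowest measurement (plant material absorbance decays over time, so
the first reading would over-subtract).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HillFit",
    "GrowthCurve",
    "hill_curve",
    "fit_hill",
    "ddct",
    "growth_endpoint",
    "final_od",
]


def hill_curve(dose, top, ic50, hill):
    """Decreasing Hill function with the lower asymptote fixed at 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return top / (1.0 + ratio)


@dataclass
class HillFit:
    """A fitted decreasing Hill dose-response curve.

    ``mic`` equals ``ic50`` by definition; ``conf_int`` holds Wald 95%
    intervals per coefficient.
    """

    top: float
    ic50: float
    hill: float
    conf_int: pd.DataFrame  # rows: top, ic50, hill; columns: low, high
    rss: float
    identifiable: bool

    @property
    def mic(self) -> float:
        return self.ic50

    def predict(self, dose) -> np.ndarray:
        return hill_curve(dose, self.top, self.ic50, self.hill)


def fit_hill(doses, od, confidence: float = 0.95) -> HillFit:
    """Least-squares fit of the decreasing Hill model.

    Initialization: top at the maximum OD, IC50 at the dose whose mean OD
    is closest to half-maximum, Hill slope 1; all parameters bounded
    positive.  The fit is flagged non-identifiable when the data show no
    decrease from the lowest to the highest dose.
    """
    doses = np.asarray(doses, dtype=float)
    od = np.asarray(od, dtype=float)
    if doses.shape != od.shape:
        raise ValueError("doses and od must have equal length")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if (od < 0).any():
        raise ValueError("od values must be non-negative")

    by_dose = pd.Series(od).groupby(pd.Series(doses)).mean()
    top0 = float(od.max())
    half = top0 / 2.0
    positive = by_dose.index[by_dose.index > 0]
    ic50_0 = float(positive[np.argmin(np.abs(by_dose.loc[positive] - half))])
    identifiable = bool(by_dose.iloc[-1] < by_dose.iloc[0])

    popt, pcov = optimize.curve_fit(
        hill_curve,
        doses,
        od,
        p0=[top0 if top0 > 0 else 1.0, ic50_0, 1.0],
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        maxfev=10_000,
    )
    resid = od - hill_curve(doses, *popt)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    se = np.sqrt(np.diag(pcov))
    conf = pd.DataFrame(
        {"low": popt - z * se, "high": popt + z * se},
        index=["top", "ic50", "hill"],
    )
    return HillFit(
        top=float(popt[0]),
        ic50=float(popt[1]),
        hill=float(popt[2]),
        conf_int=conf,
        rss=float((resid**2).sum()),
        identifiable=identifiable,
    )


def ddct(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> tuple[float, float]:
    """Relative expression as -ddCt and fold change.

    ``-ddCt = (Ct_target,control - Ct_ref,control)
            - (Ct_target,treated - Ct_ref,treated)``; fold = 2**(-ddCt).
    """
    for ct in (ct_target_treated, ct_reference_treated, ct_target_control, ct_reference_control):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    minus_ddct = (ct_target_control - ct_reference_control) - (
        ct_target_treated - ct_reference_treated
    )
    return minus_ddct, float(2.0**minus_ddct)


@dataclass
class GrowthCurve:
    """An OD600 time series for one well."""

    times: np.ndarray
    od: np.ndarray
    well: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if len(self.times) and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


def growth_endpoint(control: GrowthCurve, saturation_fraction: float = 0.9) -> float:
    """First time the no-plant control reaches 90% of its saturation OD."""
    if not 0 < saturation_fraction <= 1:
        raise ValueError("saturation_fraction must be in (0, 1]")
    if len(control.od) == 0:
        raise ValueError("empty growth curve")
    if len(control.od) > 1 and (np.diff(control.od) < 0).all():
        raise ValueError("control curve is monotone decreasing; no growth to saturate")
    threshold = saturation_fraction * control.od.max()
    idx = int(np.argmax(control.od >= threshold))
    return float(control.times[idx])


def final_od(sample: GrowthCurve, endpoint: float) -> float:
    """Background-corrected final OD of one well.

    The OD at the last measured time at or before ``endpoint``, minus the
    well's background, defined as its fifth-smallest measurement.
    """
    if len(sample.od) < 5:
        raise ValueError("need at least 5 measurements to define background")
    at_or_before = np.flatnonzero(sample.times <= endpoint)
    if len(at_or_before) == 0:
        raise ValueError("endpoint precedes the first measurement")
    end_od = float(sample.od[at_or_before[-1]])
    background = float(np.sort(sample.od)[4])
    return end_od - background
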