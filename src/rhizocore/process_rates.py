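"""Soil functional-potential measurements from raw assay data.

Slope-based potential nitrification (PNR) and denitrification enzyme
activity (DEA), spectrophotometric RubisCO activity, and qPCR absolute
quantification with standard-curve QC gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeries",
    "RateEstimate",
    "StandardCurve",
    "RubisCOAssay",
    "linear_rate",
    "qpcr_standard_curve",
    "qpcr_quantify",
    "rubisco_activity",
    "DEA_N_POINTS",
]

#: DEA uses the latest four sampling times when more are supplied
DEA_N_POINTS = 4

#: NADH molar extinction coefficient at 340 nm (mM^-1 cm^-1)
EPSILON_NADH_MM = 6.22

#: NADH oxidized per CO2 fixed in the coupled RubisCO assay
NADH_PER_CO2 = 2.0


@dataclass
class TimeSeries:
    """One sample's assay time course (times in hours, strictly increasing)."""

    sample_id: str
    times: np.ndarray
    values: np.ndarray
    assay: str = "PNR"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2:
            raise ValueError("a time series needs at least 2 points")
        if self.times.size != self.values.size:
            raise ValueError("times and values must be the same length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.assay not in ("PNR", "DEA"):
            raise ValueError("assay must be 'PNR' or 'DEA'")


@dataclass
class RateEstimate:
    slope: float
    stderr: float
    n_points: int


@dataclass
class StandardCurve:
    """qPCR dilution-series fit: Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    qc_pass: bool
    flags: list[str]


@dataclass
class RubisCOAssay:
    """A340 time courses for sample and blank (no-RuBP) reactions.

    Times in minutes; NADH oxidation makes absorbance decline, so the
    reaction rate is the negated regression slope.
    """

    times_min: np.ndarray
    sample_a340: np.ndarray
    blank_a340: np.ndarray
    volume_l: float
    path_cm: float = 1.0
    dry_mass_kg: float = 1.0
    extract_fraction: float = 1.0
    epsilon_mm: float = EPSILON_NADH_MM
    nadh_per_co2: float = NADH_PER_CO2

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.sample_a340 = np.asarray(self.sample_a340, dtype=float)
        self.blank_a340 = np.asarray(self.blank_a340, dtype=float)
        if self.times_min.size < 2:
            raise ValueError("need at least 2 absorbance readings")
        if self.sample_a340.size != self.times_min.size:
            raise ValueError("sample readings must match times")
        if self.blank_a340.size != self.times_min.size:
            raise ValueError("blank readings must match times")
        if min(self.volume_l, self.path_cm, self.dry_mass_kg) <= 0:
            raise ValueError("volume, path and dry mass must be positive")
        if not 0 < self.extract_fraction <= 1:
            raise ValueError("extract_fraction must lie in (0, 1]")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    fit = stats.linregress(x, y)
    se = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    return float(fit.slope), se


def linear_rate(ts: TimeSeries, n_points: int | None = None) -> RateEstimate:
    """OLS slope of value on time, with its standard error.

    DEA series are trimmed to the latest :data:`DEA_N_POINTS` sampling
    times when more are supplied; PNR uses all points. ``n_points``
    overrides the trim for either assay.
    """
    t, y = ts.times, ts.values
    if n_points is None and ts.assay == "DEA":
        n_points = DEA_N_POINTS
    if n_points is not None:
        if n_points < 2:
            raise ValueError("n_points must be >= 2")
        t, y = t[-n_points:], y[-n_points:]
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points")
    slope, se = _ols_slope(t, y)
    return RateEstimate(slope=slope, stderr=se, n_points=len(t))


def qpcr_standard_curve(log10_copies: np.ndarray, cq: np.ndarray) -> StandardCurve:
    """Fit Cq on log10(copies); efficiency = 10^(-1/slope) - 1.

    QC flags fire when r_squared <= 0.98 or efficiency < 0.85 (85%).
    A positive slope means an inverted dilution series and raises.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    if np.ptp(x) < 2:
        raise ValueError("dilution series must span >= 2 log10 units")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("positive slope: inverted dilution series")
    efficiency = 10 ** (-1 / fit.slope) - 1
    r2 = float(fit.rvalue**2)
    flags = []
    if r2 <= 0.98:
        flags.append(f"r_squared {r2:.4f} <= 0.98")
    if efficiency < 0.85:
        flags.append(f"efficiency {efficiency:.3f} < 0.85")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency=float(efficiency),
        qc_pass=not flags,
        flags=flags,
    )


def qpcr_quantify(
    cq: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    soil_mass_g: float = 1.0,
    allow_failed_curve: bool = False,
) -> float:
    """Absolute quantification: copies per g dry soil from a Cq value.

    copies per reaction = 10^((cq - intercept) / slope), scaled by the
    dilution factor and normalized per gram of soil in the reaction.
    Quantifying against a failed curve requires ``allow_failed_curve``.
    """
    if not curve.qc_pass and not allow_failed_curve:
        raise ValueError(f"standard curve failed QC: {curve.flags}")
    if soil_mass_g <= 0 or dilution_factor <= 0:
        raise ValueError("dilution factor and soil mass must be positive")
    copies_rxn = 10 ** ((cq - curve.intercept) / curve.slope)
    return copies_rxn * dilution_factor / soil_mass_g


def rubisco_activity(assay: RubisCOAssay) -> float:
    """RubisCO activity in nmol CO2 min^-1 per kg dry soil.

    rate = (decline_sample - decline_blank) / (eps * path)   [mM NADH/min]
    converted via the reaction volume to nmol NADH/min, divided by the
    NADH:CO2 stoichiometry, the soil dry mass and the extract fraction.
    Negative activities (blank faster than sample) clamp to 0 with a
    warning. Offset shifts of all readings cancel (slope-based).
    """
    s_slope, _ = _ols_slope(assay.times_min, assay.sample_a340)
    b_slope, _ = _ols_slope(assay.times_min, assay.blank_a340)
    decline = (-s_slope) - (-b_slope)  # A340 units per minute
    rate_mm_min = decline / (assay.epsilon_mm * assay.path_cm)
    nmol_min = rate_mm_min * assay.volume_l * 1e6  # mM * L = mmol -> nmol
    activity = nmol_min / (
        assay.nadh_per_co2 * assay.dry_mass_kg * assay.extract_fraction
    )
    if activity < 0:
        warnings.warn("blank rate exceeds sample rate; activity clamped to 0")
        return 0.0
    return float(activity)
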