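"""Rates and comparisons from batch-cultivation time series.

Specific growth rate μ is the slope of a least-squares line through
ln(CDW) versus time; interval-specific exchange rates use the
logarithmic-mean biomass X̄ = (X₂−X₁)/ln(X₂/X₁), which is exact for
exponential segments.  Depletion times come from linear interpolation
of the first downward threshold crossing.  Cross-strain production is
compared on biomass-normalized titers evaluated at equal time after
phosphate depletion, mirroring the physiological (switch-aligned)
time axis used to pair strains with different growth rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "TimeSeries",
    "RateEstimate",
    "estimate_growth_rate",
    "detect_depletion",
    "specific_rates",
    "production_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class TimeSeries:
    """One replicate's cultivation measurements on a common time grid.

    ``cdw`` is cell dry weight in g·L⁻¹; ``concentrations`` maps
    compound names to per-time values (mmol·L⁻¹; mg·L⁻¹ for pigments
    and germicidins); ``co2`` is the volume-corrected respiration rate.
    """

    strain_id: str
    times: np.ndarray  # h, strictly increasing
    cdw: np.ndarray
    concentrations: Dict[str, np.ndarray] = field(default_factory=dict)
    co2: Optional[np.ndarray] = None
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cdw = np.asarray(self.cdw, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, values in list(self.concentrations.items()):
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"length mismatch for {name!r}")
            self.concentrations[name] = arr
        if self.co2 is not None:
            self.co2 = np.asarray(self.co2, dtype=float)
        if self.cdw.shape != self.times.shape:
            raise ValueError("cdw length mismatch")


@dataclass
class RateEstimate:
    strain_id: str
    mu: Optional[float] = None  # h^-1
    mu_window: Optional[Tuple[float, float]] = None
    mu_r2: Optional[float] = None
    q: Dict[str, np.ndarray] = field(default_factory=dict)  # per-interval rates
    interval_times: Optional[np.ndarray] = None  # interval midpoints, h
    depletion: Dict[str, Optional[float]] = field(default_factory=dict)
    uptake_ratio: Optional[np.ndarray] = None  # glucose:glutamate per interval


def _loglinear_fit(times: np.ndarray, cdw: np.ndarray) -> Tuple[float, float]:
    """Slope of ln(cdw) vs time and the fit R² (1.0 for 2 points)."""
    y = np.log(cdw)
    slope, intercept = np.polyfit(times, y, 1)
    pred = slope * times + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def estimate_growth_rate(
    ts: TimeSeries,
    window: Optional[Tuple[float, float]] = None,
    depletion_compound: str = "phosphate",
    depletion_threshold: float = 0.0,
) -> RateEstimate:
    """μ from a log-linear fit of CDW over an exponential window.

    With an explicit ``window`` (t_start, t_end) the fit uses all
    points inside it (≥ 3 required).  Otherwise the window is chosen
    automatically: among prefixes of at least 4 points ending no later
    than the earliest depletion event (growth is still exponential at
    the depletion time itself), the one maximizing R² wins.
    """
    if window is not None:
        mask = (ts.times >= window[0]) & (ts.times <= window[1])
        if mask.sum() < 3:
            raise ValueError("growth window must contain at least 3 points")
        if np.any(ts.cdw[mask] <= 0):
            raise ValueError("non-positive CDW inside growth window")
        mu, r2 = _loglinear_fit(ts.times[mask], ts.cdw[mask])
        t_sel = ts.times[mask]
        return RateEstimate(ts.strain_id, mu=mu, mu_window=(t_sel[0], t_sel[-1]), mu_r2=r2)

    t_dep = None
    if depletion_compound in ts.concentrations:
        t_dep = detect_depletion(ts, depletion_compound, depletion_threshold)
    limit = len(ts.times) if t_dep is None else int(np.searchsorted(ts.times, t_dep, "right"))
    best: Optional[Tuple[float, float, int]] = None
    for end in range(4, max(limit, 4) + 1):
        seg_t, seg_x = ts.times[:end], ts.cdw[:end]
        if np.any(seg_x <= 0):
            raise ValueError("non-positive CDW inside growth window")
        mu, r2 = _loglinear_fit(seg_t, seg_x)
        # ties (e.g. noise-free data, R² = 1 everywhere) go to the longest prefix
        if best is None or r2 >= best[1] - 1e-12:
            best = (mu, r2, end)
    if best is None:
        raise ValueError("too few points for automatic growth window")
    mu, r2, end = best
    return RateEstimate(ts.strain_id, mu=mu, mu_window=(ts.times[0], ts.times[end - 1]), mu_r2=r2)


def detect_depletion(ts: TimeSeries, compound: str, threshold: float = 0.0) -> Optional[float]:
    """Linearly interpolated time of the first downward threshold crossing.

    Returns None when the compound never reaches the threshold.  If the
    trace chatters around the threshold the first crossing is taken and
    a warning logged.
    """
    if compound not in ts.concentrations:
        raise KeyError(f"compound {compound!r} not tracked")
    values = ts.concentrations[compound]
    crossing = None
    n_crossings = 0
    for i in range(len(values) - 1):
        if values[i] > threshold >= values[i + 1]:
            n_crossings += 1
            if crossing is None:
                frac = (values[i] - threshold) / (values[i] - values[i + 1])
                crossing = float(ts.times[i] + frac * (ts.times[i + 1] - ts.times[i]))
    if values[0] <= threshold:
        return float(ts.times[0])
    if n_crossings > 1:
        logger.warning("%s/%s: %d threshold crossings; using the first",
                       ts.strain_id, compound, n_crossings)
    return crossing


def _log_mean(x1: float, x2: float) -> float:
    if x1 <= 0 or x2 <= 0:
        raise ValueError("log-mean biomass requires positive CDW")
    if math.isclose(x1, x2):
        return 0.5 * (x1 + x2)
    return (x2 - x1) / math.log(x2 / x1)


def specific_rates(
    ts: TimeSeries,
    glucose: str = "glucose",
    glutamate: str = "glutamate",
) -> RateEstimate:
    """Per-interval specific exchange rates q = ΔC / (Δt · X̄).

    X̄ is the log-mean CDW over the interval; consumption is negative.
    Also reports the glucose:glutamate uptake-rate ratio per interval
    (NaN where glutamate uptake vanishes).
    """
    if len(ts.times) < 2:
        raise ValueError("need at least two time points for interval rates")
    dt = np.diff(ts.times)
    if np.any(dt == 0):
        raise ValueError("zero-length interval")
    xbar = np.array([_log_mean(ts.cdw[i], ts.cdw[i + 1]) for i in range(len(dt))])
    q: Dict[str, np.ndarray] = {}
    for name, conc in ts.concentrations.items():
        q[name] = np.diff(conc) / (dt * xbar)
    mids = 0.5 * (ts.times[:-1] + ts.times[1:])
    est = RateEstimate(ts.strain_id, q=q, interval_times=mids)
    if glucose in q and glutamate in q:
        with np.errstate(divide="ignore", invalid="ignore"):
            est.uptake_ratio = np.where(q[glutamate] != 0, q[glucose] / q[glutamate], np.nan)
    for name in ts.concentrations:
        est.depletion[name] = detect_depletion(ts, name)
    return est


def production_comparison(
    ts_ref: TimeSeries,
    ts_alt: TimeSeries,
    compound: str,
    align_by: str = "depletion",
    align_compound: str = "phosphate",
    align_threshold: float = 0.0,
) -> float:
    """Percent reduction of biomass-normalized titer, depletion-aligned.

    Both series' titers (concentration / CDW) are evaluated at the same
    time after their own phosphate depletion — the latest such time
    observed in both — and the reduction is 100·(1 − alt/ref).
    Identical series give 0 %; a unit change applied to both series
    cancels.
    """
    if align_by != "depletion":
        raise ValueError(f"unsupported alignment {align_by!r}")
    for ts in (ts_ref, ts_alt):
        if compound not in ts.concentrations:
            raise KeyError(f"compound {compound!r} missing in {ts.strain_id}")
    t_ref = detect_depletion(ts_ref, align_compound, align_threshold)
    t_alt = detect_depletion(ts_alt, align_compound, align_threshold)
    if t_ref is None or t_alt is None:
        raise ValueError("depletion-aligned comparison needs a depletion event in both series")
    delta = min(ts_ref.times[-1] - t_ref, ts_alt.times[-1] - t_alt)
    if delta < 0:
        raise ValueError("no overlap after depletion alignment")

    def titer(ts: TimeSeries, at: float) -> float:
        conc = float(np.interp(at, ts.times, ts.concentrations[compound]))
        cdw = float(np.interp(at, ts.times, ts.cdw))
        return conc / cdw

    ref = titer(ts_ref, t_ref + delta)
    alt = titer(ts_alt, t_alt + delta)
    if ref == 0:
        raise ValueError("reference titer is zero at the aligned time")
    return 100.0 * (1.0 - alt / ref)
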