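"""Non-compartmental analysis of plasma concentration-time data, HPLC-style
calibration quantification, and biodistribution fold ratios.

Times are minutes throughout; concentrations ng/mL. Window AUCs use the
linear trapezoid rule divided by 60, so AUCs are reported in ng/mL·h while
timepoints stay in minutes (the convention of the tables this mirrors).
Apparent clearance CL/F = dose / AUC_total, with F the unobserved
bioavailable fraction. Distribution (alpha) and elimination (beta) rate
constants come from least-squares slopes of log10 concentration against
time, multiplied by 2.303 to return to base e; half-life = ln 2 / rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpec, NoDecayPhase, UndefinedPK

__all__ = [
    "PlasmaSeries",
    "PKParameters",
    "CalibrationCurve",
    "trapezoid_auc",
    "nca",
    "phase_rates",
    "auto_phase_windows",
    "half_life",
    "fold_ratio",
    "fit_calibration",
    "quantify",
    "cohort_summary",
]

LOG10_TO_LN = 2.303  # printed convention for converting log10 slopes


@dataclass
class PlasmaSeries:
    """Concentration-time series for one animal.

    ``t_adm`` is the end of the administration (infusion) window in minutes.
    Concentrations below the quantification limit should be passed as NaN
    (missing), not zero; they are dropped from regressions and interpolated
    across for AUCs.
    """

    times: np.ndarray  # min, strictly increasing
    concentrations: np.ndarray  # ng/mL
    t_adm: float = 24.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise InvalidSpec("times and concentrations must be 1D and congruent")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidSpec("times must be strictly increasing")
        if self.times[0] < 0:
            raise InvalidSpec("times must start at or after 0")
        finite = np.isfinite(self.concentrations)
        if np.any(self.concentrations[finite] < 0):
            raise InvalidSpec("concentrations must be non-negative")
        if not (self.times[0] <= self.t_adm <= self.times[-1]):
            raise InvalidSpec("t_adm must lie within the sampled span")

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations with missing (NaN) samples dropped."""
        ok = np.isfinite(self.concentrations)
        return self.times[ok], self.concentrations[ok]


@dataclass
class PKParameters:
    tmax_min: float
    cmax_ng_ml: float
    auc_administration: float  # ng/mL·h
    auc_post_administration: float  # ng/mL·h
    auc_total: float  # ng/mL·h
    cl_f: float  # (mg)/(ng/mL)/h; apparent clearance, F unobserved
    dose_mg: float
    alpha: float | None = None  # 1/min
    beta: float | None = None  # 1/min
    t_half_alpha_min: float | None = None
    t_half_beta_min: float | None = None

    def as_dict(self) -> dict:
        return {
            "tmax_min": self.tmax_min,
            "cmax_ng_ml": self.cmax_ng_ml,
            "auc_administration": self.auc_administration,
            "auc_post_administration": self.auc_post_administration,
            "auc_total": self.auc_total,
            "t_half_alpha_min": self.t_half_alpha_min,
            "t_half_beta_min": self.t_half_beta_min,
            "cl_f": self.cl_f,
        }


@dataclass
class CalibrationCurve:
    """Peak-area-ratio (analyte / internal standard) vs nominal concentration."""

    slope: float
    intercept: float
    r_squared: float
    mode: str = "linear"  # linear | single-point

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidSpec("calibration slope must be positive")
        if self.mode == "single-point" and self.intercept != 0.0:
            raise InvalidSpec("single-point calibration has zero intercept")
        if self.mode not in ("linear", "single-point"):
            raise InvalidSpec(f"unknown calibration mode: {self.mode}")


# ---------------------------------------------------------------------------
# AUC


def trapezoid_auc(series: PlasmaSeries, t_start: float, t_end: float) -> float:
    """Linear-trapezoid AUC over [t_start, t_end], ng/mL·h.

    Endpoints not on the sampling grid are linearly interpolated; missing
    samples are interpolated across.
    """
    if t_end <= t_start:
        raise InvalidSpec("t_end must exceed t_start")
    t_obs, c_obs = series.observed()
    if len(t_obs) < 2:
        raise UndefinedPK("too few observed samples for an AUC")
    if t_start < t_obs[0] - 1e-9 or t_end > t_obs[-1] + 1e-9:
        raise InvalidSpec("AUC window must lie within the sampled span")
    inner = (t_obs > t_start) & (t_obs < t_end)
    t = np.concatenate([[t_start], t_obs[inner], [t_end]])
    c = np.interp(t, t_obs, c_obs)
    return float(np.trapezoid(c, t)) / 60.0


# ---------------------------------------------------------------------------
# phase rates / half-lives


def half_life(rate_per_min: float) -> float:
    """ln 2 / rate, minutes."""
    if rate_per_min <= 0:
        raise InvalidSpec("rate must be positive")
    return float(np.log(2.0) / rate_per_min)


def _log_slope_rate(series: PlasmaSeries, window: tuple[float, float]) -> float:
    lo, hi = window
    t_obs, c_obs = series.observed()
    sel = (t_obs >= lo) & (t_obs <= hi) & (c_obs > 0)
    if sel.sum() < 3:
        raise InvalidSpec("each phase window needs >= 3 positive samples")
    t, c = t_obs[sel], c_obs[sel]
    slope = np.polyfit(t, np.log10(c), 1)[0]
    rate = -slope * LOG10_TO_LN
    if rate <= 0:
        raise NoDecayPhase(f"no decaying segment in window [{lo}, {hi}] min")
    return float(rate)


def phase_rates(
    series: PlasmaSeries,
    alpha_window: tuple[float, float],
    beta_window: tuple[float, float],
    strip: bool = False,
) -> tuple[float, float]:
    """Distribution and elimination rate constants (1/min) from log10-slope
    regressions over the two post-administration windows.

    With ``strip=True`` the terminal fit is back-extrapolated and subtracted
    from the distribution-window samples before the alpha regression (the
    method of residuals). The plain two-window procedure biases alpha low
    whenever the terminal phase still contributes early; stripping removes
    that bias at the cost of assuming the terminal fit extrapolates.
    """
    beta = _log_slope_rate(series, beta_window)
    if not strip:
        return _log_slope_rate(series, alpha_window), beta
    lo, hi = beta_window
    t_obs, c_obs = series.observed()
    sel_b = (t_obs >= lo) & (t_obs <= hi) & (c_obs > 0)
    coef_b = np.polyfit(t_obs[sel_b], np.log10(c_obs[sel_b]), 1)
    a_lo, a_hi = alpha_window
    sel_a = (t_obs >= a_lo) & (t_obs <= a_hi) & (c_obs > 0)
    resid = c_obs[sel_a] - 10.0 ** np.polyval(coef_b, t_obs[sel_a])
    keep = resid > 0
    if keep.sum() < 3:
        raise NoDecayPhase("fewer than 3 positive residuals in the distribution window")
    slope = np.polyfit(t_obs[sel_a][keep], np.log10(resid[keep]), 1)[0]
    alpha = -slope * LOG10_TO_LN
    if alpha <= 0:
        raise NoDecayPhase("residuals do not decay in the distribution window")
    return float(alpha), beta


def auto_phase_windows(series: PlasmaSeries) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default split of the post-administration span into an early
    (distribution) and late (elimination) window.

    The breakpoint is chosen among post-administration sample times to
    minimize the total SSE of the two log10-linear fits, requiring >= 3
    positive samples on each side.
    """
    t_obs, c_obs = series.observed()
    post = (t_obs >= series.t_adm) & (c_obs > 0)
    t, c = t_obs[post], np.log10(c_obs[post])
    if len(t) < 6:
        raise InvalidSpec("need >= 6 positive post-administration samples to auto-split")
    best = None
    for k in range(3, len(t) - 2):
        sse = 0.0
        for tt, cc in ((t[:k], c[:k]), (t[k - 1 :], c[k - 1 :])):
            coef = np.polyfit(tt, cc, 1)
            sse += float(((np.polyval(coef, tt) - cc) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, k)
    k = best[1]
    return (float(t[0]), float(t[k - 1])), (float(t[k - 1]), float(t[-1]))


# ---------------------------------------------------------------------------
# NCA


def nca(
    series: PlasmaSeries,
    dose_mg: float = 40.0,
    phase_windows: tuple[tuple[float, float], tuple[float, float]] | str | None = "auto",
    assume_c0_zero: bool = True,
) -> PKParameters:
    """Full non-compartmental summary of one series.

    Cmax/Tmax from the observed samples (ties broken to the earliest time);
    AUCs over [first time, t_adm] and [t_adm, last time] by linear trapezoid;
    AUC_total is their sum by construction; CL/F = dose / AUC_total. When
    ``assume_c0_zero`` and sampling starts after 0, a C(0) = 0 anchor is
    prepended before integration (the infusion starts from zero). Phase
    windows may be explicit, "auto" (SSE-minimizing split), or None to skip
    the biexponential fit.
    """
    if dose_mg <= 0:
        raise InvalidSpec("dose must be positive")
    t_obs, c_obs = series.observed()
    if len(t_obs) == 0 or np.all(c_obs == 0):
        raise UndefinedPK("all-zero or empty series")
    work = series
    if assume_c0_zero and t_obs[0] > 0:
        work = PlasmaSeries(
            np.concatenate([[0.0], series.times]),
            np.concatenate([[0.0], series.concentrations]),
            t_adm=series.t_adm,
        )
    imax = int(np.argmax(c_obs))  # argmax returns the earliest maximum
    w_obs = work.observed()
    auc_adm = trapezoid_auc(work, w_obs[0][0], series.t_adm)
    auc_post = trapezoid_auc(work, series.t_adm, w_obs[0][-1])
    auc_total = auc_adm + auc_post
    alpha = beta = th_a = th_b = None
    if phase_windows is not None:
        windows = auto_phase_windows(series) if phase_windows == "auto" else phase_windows
        alpha, beta = phase_rates(series, *windows)
        th_a, th_b = half_life(alpha), half_life(beta)
    return PKParameters(
        tmax_min=float(t_obs[imax]),
        cmax_ng_ml=float(c_obs[imax]),
        auc_administration=auc_adm,
        auc_post_administration=auc_post,
        auc_total=auc_total,
        cl_f=dose_mg / auc_total,
        dose_mg=dose_mg,
        alpha=alpha,
        beta=beta,
        t_half_alpha_min=th_a,
        t_half_beta_min=th_b,
    )


def fold_ratio(a: float, b: float, decimals: int = 1) -> float:
    """a / b, reported to one decimal by convention."""
    if b <= 0:
        raise InvalidSpec("fold ratio denominator must be positive")
    return round(a / b, decimals)


# ---------------------------------------------------------------------------
# calibration / quantification


def fit_calibration(
    nominal_conc: Sequence[float],
    area_ratio: Sequence[float],
    mode: str = "linear",
    weighting: str | None = "1/x2",
) -> CalibrationCurve:
    """Least-squares line (or single-point proportionality) of area ratio vs
    nominal concentration.

    ``weighting='1/x2'`` (default) applies the bioanalytical convention of
    1/x^2 weights, which keeps back-calculation accuracy roughly uniform
    across a wide standard range when the detector noise is multiplicative;
    pass None for ordinary least squares.
    """
    x = np.asarray(nominal_conc, dtype=float)
    y = np.asarray(area_ratio, dtype=float)
    if mode == "single-point":
        if len(x) != 1:
            raise InvalidSpec("single-point calibration takes exactly one standard")
        return CalibrationCurve(slope=float(y[0] / x[0]), intercept=0.0, r_squared=1.0, mode=mode)
    if len(x) < 2:
        raise InvalidSpec("linear calibration needs >= 2 standards")
    if weighting == "1/x2":
        if np.any(x <= 0):
            raise InvalidSpec("1/x2 weighting requires positive standards")
        w = 1.0 / x  # polyfit takes sqrt-weights
    elif weighting is None:
        w = None
    else:
        raise InvalidSpec(f"unknown weighting: {weighting}")
    slope, intercept = np.polyfit(x, y, 1, w=w)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(slope=float(slope), intercept=float(intercept), r_squared=r2, mode="linear")


def quantify(
    peak_area_ratio: float,
    curve: CalibrationCurve,
    tissue_mass_mg: float | None = None,
) -> tuple[float, bool]:
    """Back-calculate concentration from a peak-area ratio.

    linear mode: (ratio - intercept) / slope; single-point: ratio / slope.
    Negative back-calculations clip to 0 with the flag set. With
    ``tissue_mass_mg`` the result is normalized per mg of tissue.
    """
    if peak_area_ratio < 0:
        raise InvalidSpec("peak-area ratio must be >= 0")
    if curve.mode == "single-point":
        conc = peak_area_ratio / curve.slope
    else:
        conc = (peak_area_ratio - curve.intercept) / curve.slope
    clipped = conc < 0
    conc = max(conc, 0.0)
    if tissue_mass_mg is not None:
        if tissue_mass_mg <= 0:
            raise InvalidSpec("tissue mass must be positive")
        conc = conc / tissue_mass_mg
    return float(conc), bool(clipped)


# ---------------------------------------------------------------------------
# cohort summaries


def cohort_summary(per_animal: list[PKParameters]) -> pd.DataFrame:
    """Mean ± SD across animals, computed per animal then averaged (the
    structure of a cohort PK table). Returns columns: parameter, mean, sd, n."""
    if not per_animal:
        raise InvalidSpec("empty cohort")
    rows = []
    keys = per_animal[0].as_dict().keys()
    for key in keys:
        vals = np.asarray([p.as_dict()[key] for p in per_animal], dtype=float)
        ok = np.isfinite(vals)
        rows.append(
            {
                "parameter": key,
                "mean": float(vals[ok].mean()) if ok.any() else np.nan,
                "sd": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
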