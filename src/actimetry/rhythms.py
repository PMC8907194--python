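"""Biological-rhythm statistics for binned activity series.

Implements the chronobiology toolbox around a count series x_i per bin:

- **Chi-square periodogram** (folded-profile statistic): for a candidate
  period of P bins the series is truncated to K complete cycles (N = K*P
  samples) and folded into a K x P array with column means M_h and grand
  mean M; the power is ``Q_P = N * sum_h (M_h - M)^2 / sum_i (x_i - M)^2``,
  compared against a chi-squared quantile with P - 1 degrees of freedom.
- **Lomb-Scargle periodogram**: classical variance-normalized least-squares
  spectral power (with the tau phase offset), usable with gaps; per-period
  significance from the false-alarm relation ``p = 1 - (1 - e^-z)^m``.
- **Cosinor acrophase**: single-component cosinor fit by closed-form least
  squares, refined by the extended (anti-logistic / sigmoidally squared)
  cosine model, yielding the acrophase and the activity phase relative to
  lights-on.
- **Nonparametric circadian indices**: inter-daily stability (IS),
  intra-daily variability (IV) on hourly bins, and relative amplitude
  RA = (M10 - L5)/(M10 + L5) from the average daily profile.
- **Detrended fluctuation analysis** (DFA, first order): scaling exponent
  of log fluctuation amplitude versus log time-scale; ~0.5 for white noise
  up to ~1.5 for Brownian-like, excessively regular patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats
from scipy.special import expit

from .errors import ParameterError, RangeError
from .monitor_io import AnnotatedSeries


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _series_values(series, bin_h: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (time_hours, counts, bin_h) from an AnnotatedSeries or array."""
    if isinstance(series, AnnotatedSeries):
        bh = series.bin_seconds / 3600.0
        if series.light_cycle is not None:
            t = series.zeitgeber_hours
        else:
            t = series.hours_from_start
        return t, np.asarray(series.counts, dtype=float), bh
    x = np.asarray(series, dtype=float)
    if bin_h is None:
        raise ParameterError("bin_h is required for plain-array input")
    return np.arange(len(x)) * bin_h, x, bin_h


@dataclass
class Periodogram:
    """Tested periods, powers, and per-period significance threshold."""

    method: str
    periods_h: np.ndarray
    power: np.ndarray
    significance_level: np.ndarray
    peak_period_h: float
    alpha: float

    def _peak_index(self) -> int:
        return int(np.argmin(np.abs(self.periods_h - self.peak_period_h)))

    @property
    def peak_power(self) -> float:
        if np.isnan(self.peak_period_h):
            return float("nan")
        return float(self.power[self._peak_index()])

    @property
    def peak_significant(self) -> bool:
        if np.isnan(self.peak_period_h):
            return False
        i = self._peak_index()
        return bool(self.power[i] > self.significance_level[i])


# ---------------------------------------------------------------------------
# chi-square periodogram
# ---------------------------------------------------------------------------

def chi_square_periodogram(
    series,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    step_h: float | None = None,
    alpha: float = 0.05,
    bin_h: float | None = None,
) -> Periodogram:
    """Chi-square (folded profile) periodogram on an evenly binned series.

    Candidate periods are whole multiples of the bin size covering
    ``period_range_h`` (the folding statistic is only defined for whole-bin
    periods); ``step_h`` further thins the grid when coarser than one bin.

    The power is normalized so that an exactly P-periodic series scores
    Q_P = P; the classical folded-profile statistic is K * Q_P (K complete
    cycles), so the significance line — the chi-squared quantile with P - 1
    degrees of freedom at level ``alpha``, Bonferroni-corrected across the
    grid — is divided by K to keep the test decision identical to the
    classical one.  Because both the expected power and the line grow with
    P under pure noise, the peak is the period with the largest *excess*
    power over its significance line (raw argmax is biased toward long
    periods).  Requires at least two complete cycles of the shortest
    candidate period.
    """
    _, x, bh = _series_values(series, bin_h)
    if np.isnan(x).any():
        raise ParameterError("chi-square periodogram needs complete data (impute first)")
    n = len(x)
    lo, hi = period_range_h
    p_lo = max(2, int(np.ceil(lo / bh - 1e-9)))
    p_hi = int(np.floor(hi / bh + 1e-9))
    if step_h is not None and step_h > bh:
        stride = max(1, int(round(step_h / bh)))
    else:
        stride = 1
    p_bins = np.arange(p_lo, p_hi + 1, stride)
    p_bins = p_bins[n // p_bins >= 2]
    if p_bins.size == 0:
        raise RangeError(
            f"series of {n} bins holds fewer than 2 complete cycles of the "
            f"shortest candidate period ({lo} h)"
        )

    m_grid = len(p_bins)
    powers = np.empty(m_grid)
    ks = n // p_bins
    sig = stats.chi2.ppf(1 - alpha / m_grid, p_bins - 1) / ks
    degenerate = False
    for j, P in enumerate(p_bins):
        K = n // P
        N = K * P
        xt = x[:N]
        M = xt.mean()
        denom = ((xt - M) ** 2).sum()
        if denom == 0:
            powers[j] = np.nan
            degenerate = True
            continue
        col_means = xt.reshape(K, P).mean(axis=0)
        powers[j] = N * ((col_means - M) ** 2).sum() / denom
    if degenerate:
        warnings.warn("constant series: chi-square power undefined", stacklevel=2)

    periods_h = p_bins * bh
    excess = powers - sig
    peak = (
        float(periods_h[np.nanargmax(excess)])
        if not np.all(np.isnan(powers)) else float("nan")
    )
    return Periodogram("chi_square", periods_h, powers, sig, peak, alpha)


# ---------------------------------------------------------------------------
# Lomb-Scargle periodogram
# ---------------------------------------------------------------------------

def lomb_scargle_periodogram(
    series,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    n_periods: int = 512,
    alpha: float = 0.05,
    bin_h: float | None = None,
) -> Periodogram:
    """Classical normalized Lomb-Scargle periodogram; gaps (NaN) allowed.

    Power is the Scargle least-squares spectral power divided by the sample
    variance, so the single-frequency false-alarm probability of a power z
    is ``e^-z``; the per-period significance line solves
    ``1 - (1 - e^-z)^m = alpha`` with m = ``n_periods`` independent
    frequencies (a conservative count).
    """
    t, x, _ = _series_values(series, bin_h)
    keep = ~np.isnan(x)
    t, x = t[keep], x[keep]
    if len(x) < 3:
        raise ParameterError("Lomb-Scargle needs at least 3 observations")
    lo, hi = period_range_h
    if not lo < hi:
        raise ParameterError("period range must satisfy lo < hi")
    periods_h = np.linspace(lo, hi, n_periods)
    var = x.var(ddof=1)
    z_alpha = -np.log1p(-(1 - alpha) ** (1.0 / n_periods))
    sig = np.full(n_periods, z_alpha)
    if var == 0:
        warnings.warn("constant series: Lomb-Scargle power undefined", stacklevel=2)
        power = np.full(n_periods, np.nan)
        return Periodogram("lomb_scargle", periods_h, power, sig, float("nan"), alpha)
    omega = 2 * np.pi / periods_h
    raw = signal.lombscargle(t, x - x.mean(), omega)
    power = raw / var
    peak = float(periods_h[np.nanargmax(power)])
    return Periodogram("lomb_scargle", periods_h, power, sig, peak, alpha)


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

def _wrap_half(x: float, period: float) -> float:
    """Wrap into (-period/2, period/2]."""
    w = np.mod(x, period)
    if w > period / 2:
        w -= period
    return float(w)


def cosinor_phase(
    series,
    cycle_h: float = 24.0,
    lights_on_zt: float = 0.0,
    bin_h: float | None = None,
) -> dict:
    """Acrophase and activity phase from the (extended) cosinor model.

    Stage 1 fits ``y = mesor + A cos(2 pi (t - phi)/cycle_h)`` by closed-form
    least squares on sine/cosine regressors.  Stage 2 refines with the
    anti-logistic transform of the cosine,
    ``y = min + amp * sigma(beta * (cos(2 pi (t - phi)/cycle_h) - alpha))``
    with the logistic function sigma, which accommodates the square-ish
    on/off profiles typical of activity data; if the nonlinear fit fails the
    stage-1 estimates are returned with ``converged = False``.

    The acrophase is the zeitgeber time of the model peak in
    ``[0, cycle_h)``; the activity phase is the acrophase minus the
    lights-on time, wrapped to ``(-cycle_h/2, cycle_h/2]``.
    """
    t, y, bh = _series_values(series, bin_h)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if t[-1] - t[0] < 2 * cycle_h - bh:
        raise ParameterError("cosinor needs at least 2 full cycles of data")

    w = 2 * np.pi / cycle_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    (mesor, a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    amplitude = float(np.hypot(a, b))
    phi1 = float(np.mod(np.arctan2(b, a) / w, cycle_h))

    def model(tt, mn, amp, beta, alph, phi):
        return mn + amp * expit(beta * (np.cos(w * (tt - phi)) - alph))

    p0 = [mesor - amplitude, 2 * amplitude, 2.0, 0.0, phi1]
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 0.0, 1e-3, -1.0, -np.inf],
                    [np.inf, np.inf, 60.0, 1.0, np.inf]),
            maxfev=20000,
        )
        phi2 = float(np.mod(popt[4], cycle_h))
        fitted = model(t, *popt)
        extended = {
            "min": float(popt[0]), "amp": float(popt[1]),
            "beta": float(popt[2]), "alpha": float(popt[3]), "phi": phi2,
        }
    except (RuntimeError, ValueError):
        converged = False
        phi2 = phi1
        fitted = X @ np.array([mesor, a, b])
        extended = {}

    acrophase = phi2 if converged else phi1
    rss = float(((y - fitted) ** 2).sum())
    return {
        "acrophase_h": acrophase,
        "activity_phase_h": _wrap_half(acrophase - lights_on_zt, cycle_h),
        "amplitude": amplitude,
        "mesor": float(mesor),
        "stage1_acrophase_h": phi1,
        "extended": extended,
        "converged": converged,
        "rss": rss,
    }


# ---------------------------------------------------------------------------
# nonparametric circadian indices
# ---------------------------------------------------------------------------

def nonparametric_stats(series, cycle_h: float = 24.0, bin_h: float | None = None) -> dict:
    """IS, IV, RA, M10 and L5 from hourly-binned counts.

    The series is re-binned to 1-hour bins (IV is defined between
    consecutive hours) and truncated to complete cycles of ``p = cycle_h``
    hourly values.  With n hourly values x_i, hour-of-cycle means xbar_h and
    grand mean xbar::

        IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)
        IV = n * sum_{i>=2} (x_i - x_{i-1})^2 / ((n-1) * sum_i (x_i - xbar)^2)

    M10 / L5 are the max / min means over cyclic sliding windows of 10 h /
    5 h on the average daily profile (counts per hour); ties break to the
    earliest onset.  RA = (M10 - L5)/(M10 + L5).
    """
    if isinstance(series, AnnotatedSeries):
        from .preprocess import bin_counts

        if abs(series.bin_seconds - 3600.0) > 1e-9:
            series = bin_counts(series, 60.0)
        x = np.asarray(series.counts, dtype=float)
    else:
        x = np.asarray(series, dtype=float)  # assumed hourly already
    if np.isnan(x).any():
        raise ParameterError("nonparametric stats need complete data (impute first)")
    p = int(round(cycle_h))
    if abs(cycle_h - p) > 1e-9:
        raise ParameterError("cycle_h must be a whole number of hours")
    K = len(x) // p
    if K < 2:
        raise ParameterError("need at least 2 complete cycles of hourly data")
    x = x[: K * p]
    n = len(x)
    xbar = x.mean()
    total_ss = ((x - xbar) ** 2).sum()
    if total_ss == 0:
        warnings.warn("constant series: IS/IV/RA undefined", stacklevel=2)
        return {k: float("nan") for k in
                ("IS", "IV", "RA", "M10", "L5", "M10_onset_h", "L5_onset_h")}
    profile = x.reshape(K, p).mean(axis=0)
    IS = n * ((profile - xbar) ** 2).sum() / (p * total_ss)
    IV = n * (np.diff(x) ** 2).sum() / ((n - 1) * total_ss)

    def _window_means(width: int) -> np.ndarray:
        ext = np.concatenate([profile, profile[: width - 1]])
        return np.convolve(ext, np.ones(width) / width, mode="valid")[:p]

    m10 = _window_means(min(10, p))
    l5 = _window_means(min(5, p))
    M10, M10_onset = float(m10.max()), int(np.argmax(m10))
    L5, L5_onset = float(l5.min()), int(np.argmin(l5))
    RA = (M10 - L5) / (M10 + L5) if (M10 + L5) > 0 else float("nan")
    return {
        "IS": float(IS), "IV": float(IV), "RA": float(RA),
        "M10": M10, "L5": L5,
        "M10_onset_h": float(M10_onset), "L5_onset_h": float(L5_onset),
    }


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa(
    series,
    scale_range: tuple[int, int] | None = None,
    n_scales: int = 20,
    bin_h: float | None = 1.0,
) -> dict:
    """First-order DFA scaling exponent of a count series.

    The integrated profile ``y(k) = sum_{i<=k}(x_i - xbar)`` is split into
    non-overlapping windows of n samples (taken both from the start and
    from the end of the series, so trailing samples contribute), a straight
    line is removed per window, and ``F(n)`` is the RMS residual.  The
    scaling exponent is the least-squares slope of ``log F(n)`` versus
    ``log n`` over ``n_scales`` log-spaced scales in ``scale_range``
    (default [4, N/4]).
    """
    if isinstance(series, AnnotatedSeries):
        x = np.asarray(series.counts, dtype=float)
    else:
        x = np.asarray(series, dtype=float)
    if np.isnan(x).any():
        raise ParameterError("DFA needs complete data (impute first)")
    N = len(x)
    n_min, n_max = scale_range if scale_range is not None else (4, N // 4)
    if n_min < 4 or n_max > N // 4 or n_min >= n_max:
        raise ParameterError(
            f"scale range [{n_min}, {n_max}] outside the valid [4, {N // 4}]"
        )
    scales = np.unique(
        np.round(np.geomspace(n_min, n_max, n_scales)).astype(int)
    )
    y = np.cumsum(x - x.mean())
    F = np.empty(len(scales))
    for j, n in enumerate(scales):
        F[j] = _fluctuation(y, int(n))
    slope = np.polyfit(np.log(scales), np.log(F), 1)[0]
    return {
        "scaling_exponent": float(slope),
        "scales": scales,
        "fluctuation_F": F,
    }


def _fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS linear-detrended residual over forward + backward windows of n."""
    N = len(profile)
    n_win = N // n
    xs = np.arange(n, dtype=float)
    A = np.column_stack([xs, np.ones(n)])
    pinv = np.linalg.pinv(A)

    def _rms2(seg: np.ndarray) -> np.ndarray:
        V = seg.reshape(n_win, n)
        resid = V - (A @ (pinv @ V.T)).T
        return (resid ** 2).mean(axis=1)

    fwd = _rms2(profile[: n_win * n])
    bwd = _rms2(profile[N - n_win * n:])
    return float(np.sqrt(np.concatenate([fwd, bwd]).mean()))
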