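"""Ensemble spectral estimation for single-cell FRET ratio time series.

The power spectral density of each cell is estimated over non-overlapping
T-frame segments (default T = 400) as s(f_k) = |R̂_k|² / (T·R̄²), k = 1..T/2,
where R̂ is the discrete Fourier transform of the segment and R̄ its mean;
segments are averaged per cell, then over cells, with the SEM taken across
cells.  The DC bin is excluded throughout, so all derived quantities refer to
fluctuations of the mean-normalized ratio R/R̄.  The autocorrelation function
is the inverse DFT of the ensemble PSD (Wiener-Khinchin); correlation times
come from an exponential fit whose default variant propagates the exponential
model through the same DC-excluded segment estimator as the data, removing
the finite-segment bias that otherwise shortens fitted times when the
correlation time is not small compared to T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "EnsemblePSD",
    "AcfFit",
    "VarianceEstimate",
    "ActivitySortResult",
    "compute_psd",
    "psd_to_acf",
    "expected_segment_acf",
    "fit_correlation_time",
    "parseval_variance",
    "estimate_lambda",
    "filter_unresponsive",
    "sort_by_activity",
]


@dataclass
class EnsemblePSD:
    """Cell-averaged one-sided PSD on the grid f_k = k/(T·Δt), k=1..T/2."""

    freq: np.ndarray
    s: np.ndarray
    sem: np.ndarray
    T: int
    n_cells: int
    n_segments_per_cell: float
    mean_sq_ratio: float = 1.0  # ensemble <R̄²>, used to de-normalize variances

    def two_sided_sum(self, values=None) -> float:
        """Σ over all nonzero DFT bins (bins below Nyquist counted twice)."""
        v = self.s if values is None else np.asarray(values)
        w = np.full(len(v), 2.0)
        if self.T % 2 == 0:
            w[-1] = 1.0  # Nyquist bin appears once
        return float(np.sum(w * v))


@dataclass
class AcfFit:
    lag: np.ndarray
    C: np.ndarray
    C0: float = np.nan
    tau0: float = np.nan
    r2: float = np.nan
    failed: bool = False
    T: int | None = None  # segment length the ACF was estimated with


@dataclass
class VarianceEstimate:
    var_ratio: float
    var_activity: float
    lambda_used: float
    floored_mass: float = 0.0  # variance removed by flooring negative bins


@dataclass
class ActivitySortResult:
    bins: list                 # list of dicts: n, A, psd (EnsemblePSD), size
    n_values: tuple
    scaling_slope: float = np.nan
    scaling_intercept: float = np.nan
    scaling_r2: float = np.nan
    excluded_cells: list = field(default_factory=list)


def _trace_ratio(trace):
    return np.asarray(getattr(trace, "ratio", trace), dtype=float)


def _trace_time(trace, n):
    t = getattr(trace, "time", None)
    return np.arange(n, dtype=float) if t is None else np.asarray(t, float)


def _iter_traces(ensemble):
    return list(getattr(ensemble, "traces", ensemble))


def compute_psd(ensemble, segment_length: int = 400, window=None,
                detrend: bool = False) -> EnsemblePSD:
    """Estimate the ensemble PSD from an iterable of traces.

    ``window`` optionally restricts the analysis to [t0, t1) seconds; each
    trace must contain at least one full segment inside it.  ``detrend``
    removes a linear trend per segment (off by default; drift is normally
    handled by noise-PSD subtraction instead).
    """
    T = int(segment_length)
    freq = np.arange(1, T // 2 + 1) / T  # Δt = 1 s acquisition
    per_cell = []
    rbar_sq = []
    n_segs = []
    for trace in _iter_traces(ensemble):
        r = _trace_ratio(trace)
        t = _trace_time(trace, len(r))
        if np.any(np.abs(np.diff(t) - (t[1] - t[0])) > 1e-9):
            raise ValueError("non-uniform time grid")
        if window is not None:
            mask = (t >= window[0]) & (t < window[1])
            r = r[mask]
        n_full = len(r) // T
        if n_full < 1:
            raise ValueError("analysis window shorter than one segment")
        segs = []
        for j in range(n_full):
            seg = r[j * T:(j + 1) * T].astype(float)
            if detrend:
                seg = seg - np.polyval(np.polyfit(np.arange(T), seg, 1),
                                       np.arange(T)) + seg.mean()
            rbar = seg.mean()
            rhat = np.fft.rfft(seg)
            segs.append(np.abs(rhat[1:T // 2 + 1]) ** 2 / (T * rbar ** 2))
            rbar_sq.append(rbar ** 2)
        per_cell.append(np.mean(segs, axis=0))
        n_segs.append(n_full)
    per_cell = np.asarray(per_cell)
    n_cells = per_cell.shape[0]
    s = per_cell.mean(axis=0)
    sem = (per_cell.std(axis=0, ddof=1) / math.sqrt(n_cells)
           if n_cells > 1 else np.zeros_like(s))
    return EnsemblePSD(freq=freq, s=s, sem=sem, T=T, n_cells=n_cells,
                       n_segments_per_cell=float(np.mean(n_segs)),
                       mean_sq_ratio=float(np.mean(rbar_sq)))


def psd_to_acf(psd: EnsemblePSD) -> AcfFit:
    """Autocorrelation function as the inverse DFT of the (DC-excluded) PSD.

    C(0) equals the total normalized variance (1/T)·Σ_{k≠0} s_k including the
    shot-noise contribution.
    """
    T = psd.T
    half = np.concatenate([[0.0], psd.s])  # DC bin zeroed
    C = np.fft.irfft(half, n=T)
    lag = np.arange(T, dtype=float)
    keep = T // 2 + 1  # circular symmetry beyond the half length
    return AcfFit(lag=lag[:keep], C=C[:keep], T=T)


def expected_segment_acf(tau: float, T: int) -> np.ndarray:
    """Expected DC-excluded circular sample ACF of a unit-variance process
    with C(t) = exp(−|t|/τ), observed in T-frame segments.

    Computed exactly: the expected periodogram is the DFT of the triangularly
    windowed autocovariance; zeroing its DC bin and inverting reproduces what
    the segment estimator does to the data.
    """
    d = np.arange(T)
    c = (1.0 - d / T) * np.exp(-d / tau)
    # E[s_k] = c0 + 2 Σ_{d>=1} c_d cos(2πkd/T)  (real part of the DFT trick)
    e = 2.0 * np.real(np.fft.fft(c)) - c[0]
    e[0] = 0.0  # DC excluded
    C = np.real(np.fft.ifft(e))
    return C[:T // 2 + 1]


def fit_correlation_time(acf: AcfFit, fit_range=None,
                         model: str = "debiased") -> AcfFit:
    """Fit C0·exp(−t/τ0) to the ACF for t > 0 (C(0) excluded so the white
    shot-noise spike does not bias the amplitude).

    model="exp" fits the bare exponential; the default "debiased" fits the
    same exponential family propagated through the segment estimator
    (see :func:`expected_segment_acf`), which is the consistent model for
    ACFs obtained via :func:`psd_to_acf`.  On non-decaying input the result
    is flagged ``failed`` with no silent τ.
    """
    lag = np.asarray(acf.lag, float)
    C = np.asarray(acf.C, float)
    T = acf.T or 2 * (len(C) - 1)
    if fit_range is None:
        fit_range = (0.0, T / 4.0)
    mask = (lag > fit_range[0]) & (lag <= fit_range[1]) & (lag > 0)
    if mask.sum() < 10:
        raise ValueError("need >= 10 lags in fit range")
    x, y = lag[mask], C[mask]

    out = AcfFit(lag=lag, C=C, T=acf.T)
    # quick sanity: require a positive, decaying early ACF
    head = y[: max(3, len(y) // 10)]
    if np.all(head <= 0) or y[0] <= 0:
        out.failed = True
        return out

    if model == "exp":
        def f(t, c0, tau):
            return c0 * np.exp(-t / tau)
    elif model == "debiased":
        def f(t, c0, tau):
            m = expected_segment_acf(tau, T)
            return c0 * np.interp(t, np.arange(len(m), dtype=float), m)
    else:
        raise ValueError(f"unknown model {model!r}")

    tau_guess = max(float(x[np.argmin(np.abs(y - y[0] / math.e))]), 1.0)
    try:
        popt, _ = curve_fit(f, x, y, p0=[float(y[0]), tau_guess],
                            bounds=([0.0, 1e-3], [np.inf, 100.0 * T]),
                            maxfev=10000)
    except (RuntimeError, ValueError):
        out.failed = True
        return out
    resid = y - f(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    out.C0, out.tau0, out.r2 = float(popt[0]), float(popt[1]), r2
    if r2 < 0.2 or out.C0 <= 0:
        out.failed = True
    return out


def parseval_variance(psd: EnsemblePSD, noise_psd: EnsemblePSD | None,
                      lam: float, denormalize: bool = True) -> VarianceEstimate:
    """Total fluctuation variance by summing the shot-corrected PSD
    (Parseval), ⟨ΔR²⟩, and the activity variance ⟨ΔA²⟩ = ⟨ΔR²⟩/λ².

    Negative per-bin differences are floored at zero (the floored mass is
    reported).  With ``denormalize`` the per-ensemble ⟨R̄²⟩ factors convert the
    mean-normalized spectra back to ratio units before differencing, so the
    result is the variance of R itself; without it the estimate is the
    variance of R/R̄ exactly as the DC-excluded Parseval sum gives it.
    """
    s = psd.s * (psd.mean_sq_ratio if denormalize else 1.0)
    if noise_psd is not None:
        if len(noise_psd.freq) != len(psd.freq) or not np.allclose(
                noise_psd.freq, psd.freq):
            raise ValueError("frequency grid mismatch")
        s_n = noise_psd.s * (noise_psd.mean_sq_ratio if denormalize else 1.0)
    else:
        s_n = np.zeros_like(s)
    diff = s - s_n
    floored = np.clip(-diff, 0.0, None)
    var_ratio = psd.two_sided_sum(np.clip(diff, 0.0, None)) / psd.T
    floored_mass = psd.two_sided_sum(floored) / psd.T
    return VarianceEstimate(var_ratio=var_ratio,
                            var_activity=var_ratio / lam ** 2,
                            lambda_used=lam, floored_mass=floored_mass)


# ---------------------------------------------------------------------------
# protocol-window utilities

VALVE_GUARD_S = 20.0  # data excluded around solution-exchange events


def _protocol_windows(ensemble, duration=None):
    proto = getattr(ensemble, "protocol", None)
    if proto is None:
        raise ValueError("ensemble carries no stimulation protocol")
    duration = duration or getattr(ensemble, "duration", None)
    return list(proto.windows(duration))


def _window_mean(trace, t0, t1, guard=VALVE_GUARD_S):
    r = _trace_ratio(trace)
    t = _trace_time(trace, len(r))
    mask = (t >= t0 + guard) & (t < t1 - guard)
    if not np.any(mask):
        raise ValueError("empty analysis window after guard trimming")
    return float(r[mask].mean())


def _windows_by_token(ensemble, token):
    return [(t0, t1) for lvl, t0, t1 in _protocol_windows(ensemble)
            if lvl == token]


def estimate_lambda(ensemble, buffer_token="buffer",
                    saturating_token="MeAsp 100 uM",
                    guard=VALVE_GUARD_S):
    """Conversion factor λ = mean over cells of (buffer-window mean ratio −
    saturating-window mean ratio); windows exclude ``guard`` seconds around
    valve events.  Buffer windows correspond to full activity for the
    adaptation-deficient reference strain; saturating stimulation drives the
    activity to zero."""
    bufs = _windows_by_token(ensemble, buffer_token)
    sats = _windows_by_token(ensemble, saturating_token)
    if not bufs or not sats:
        raise ValueError("protocol lacks buffer and/or saturating windows")
    lams = []
    for tr in _iter_traces(ensemble):
        r_buf = np.mean([_window_mean(tr, t0, t1, guard) for t0, t1 in bufs])
        r_sat = np.mean([_window_mean(tr, t0, t1, guard) for t0, t1 in sats])
        lams.append(r_buf - r_sat)
    return float(np.mean(lams))


def filter_unresponsive(ensemble, stim_window, ref_window,
                        population_response: float | None = None,
                        threshold: float = 0.1, guard=VALVE_GUARD_S):
    """Discard cells whose stimulus response is below ``threshold`` (10%) of
    the population response.  Returns (kept, discarded) trace lists.

    ``population_response`` is the reference ratio change (in the paper, from
    the confluent-population ROI); when None it defaults to the ensemble-mean
    response, which is only sensible for an ensemble known to respond."""
    traces = _iter_traces(ensemble)
    deltas = [
        _window_mean(tr, *ref_window, guard) - _window_mean(tr, *stim_window, guard)
        for tr in traces
    ]
    pop = float(np.mean(deltas)) if population_response is None \
        else float(population_response)
    if pop == 0:
        raise ValueError("population response magnitude is zero")
    kept, discarded = [], []
    for tr, d in zip(traces, deltas):
        (kept if abs(d) >= threshold * abs(pop) else discarded).append(tr)
    return kept, discarded


def per_cell_activity(trace, w_pre30, w_30, w_pre100, w_100, guard=VALVE_GUARD_S):
    """Pathway activity A = 1 − (R̄_pre,30 − R̄_30)/(R̄_pre,100 − R̄_100)
    from the two-step (sub-saturating then saturating) protocol windows."""
    num = _window_mean(trace, *w_pre30, guard) - _window_mean(trace, *w_30, guard)
    den = _window_mean(trace, *w_pre100, guard) - _window_mean(trace, *w_100, guard)
    if den <= 0:
        raise ValueError("non-positive saturating response; cell excluded")
    return 1.0 - num / den


def sort_by_activity(ensemble, n_values=(10, 9, 6, 5, 4),
                     segment_length: int = 400,
                     sub_token="MeAsp 30 uM", sat_token="MeAsp 100 uM",
                     buffer_token="buffer", low_freq_max: float = 0.01,
                     guard=VALVE_GUARD_S) -> ActivitySortResult:
    """Sort cells by inferred activity, estimate per-subpopulation PSDs in the
    sub-saturating window, and fit the low-frequency PSD against A(1−A).

    For each n in ``n_values`` the cells are split into n equally populated
    subpopulations (±1 cell); all (n, bin) points enter one regression of the
    mean low-frequency PSD on A(1−A)."""
    wins = _protocol_windows(ensemble)
    try:
        w_30 = next((t0, t1) for lvl, t0, t1 in wins if lvl == sub_token)
        w_100 = next((t0, t1) for lvl, t0, t1 in wins if lvl == sat_token)
        w_pre30 = next((t0, t1) for lvl, t0, t1 in wins
                       if lvl == buffer_token and t1 <= w_30[0])
        w_pre100 = next((t0, t1) for lvl, t0, t1 in wins
                        if lvl == buffer_token and t1 <= w_100[0])
    except StopIteration:
        raise ValueError("protocol lacks the required windows") from None

    acts, kept, excluded = [], [], []
    for tr in _iter_traces(ensemble):
        try:
            acts.append(per_cell_activity(tr, w_pre30, w_30, w_pre100, w_100,
                                          guard))
            kept.append(tr)
        except ValueError:
            excluded.append(tr)
    acts = np.asarray(acts)
    order = np.argsort(acts)

    psd_window = (w_30[0] + guard, w_30[1] - guard)
    bins = []
    xs, ys = [], []
    for n in n_values:
        for chunk in np.array_split(order, n):
            if len(chunk) == 0:
                continue
            sub = [kept[i] for i in chunk]
            psd = compute_psd(sub, segment_length, window=psd_window)
            a_mean = float(acts[chunk].mean())
            s_low = float(psd.s[psd.freq <= low_freq_max].mean())
            bins.append({"n": n, "A": a_mean, "psd": psd, "size": len(chunk),
                         "s_low": s_low})
            xs.append(a_mean * (1.0 - a_mean))
            ys.append(s_low)
    fit = linregress(xs, ys)
    return ActivitySortResult(bins=bins, n_values=tuple(n_values),
                              scaling_slope=float(fit.slope),
                              scaling_intercept=float(fit.intercept),
                              scaling_r2=float(fit.rvalue ** 2),
                              excluded_cells=excluded)
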