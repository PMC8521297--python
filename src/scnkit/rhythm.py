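"""Circadian rhythm quantification for bioluminescence / fluorescence traces.

The workhorse is an FFT-initialised nonlinear least-squares fit of a single
damped cosine,

    y(t) = c + A * exp(-lambda * t) * cos(2*pi*(t - phi) / tau),

exposed statsmodels-style: :class:`DampedCosineModel` is built from a trace
and its :meth:`~DampedCosineModel.fit` returns a :class:`RhythmFit` results
object carrying the estimates, their standard errors, the relative
amplitude error (RAE: half-width of the ~95% confidence interval of the
amplitude divided by the amplitude estimate), a goodness-of-fit statistic
(1 - SSR/SST) and the rhythmicity classification. An ROI is "initiated"
when the fitted period lies in [23.5, 34.5] h (inclusive) and RAE < 0.3
(strict).

Supporting operations cover detrending/smoothing (24-h baseline window,
2.5-h moving average), peak detection, Rayleigh phase-coherence statistics,
phase maps over ROI grids, treatment phase shifts, waveform (baseline /
amplitude / period) changes and phase-response-curve assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .containers import BioluminescenceTrace, ROIGrid

__all__ = [
    "RhythmFit",
    "DampedCosineModel",
    "PhaseMap",
    "detrend_and_smooth",
    "fit_rhythm",
    "classify_initiated",
    "rayleigh",
    "build_phase_map",
    "detect_peaks",
    "phase_shift",
    "waveform_changes",
    "WaveformChange",
    "assemble_prc",
    "map_ct",
]

#: Initiation criteria: fitted period within these bounds (inclusive) ...
PERIOD_BOUNDS_H: Tuple[float, float] = (23.5, 34.5)
#: ... and relative amplitude error strictly below this.
RAE_MAX: float = 0.3
#: Default period search window for the FFT initialisation and fit bounds.
PERIOD_WINDOW_H: Tuple[float, float] = (18.0, 40.0)
#: Default moving-average windows (hours).
BASELINE_WINDOW_H: float = 24.0
SMOOTH_WINDOW_H: float = 2.5

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class RhythmFit:
    """Results of a damped-cosine rhythm fit.

    ``phase_h`` is the time of the fitted cosine peak, reduced mod the
    period into [0, tau). A failed fit (no spectral peak in the period
    window, or optimisation failure) carries ``rae = inf`` and is never
    classified as initiated.
    """

    period_h: float
    phase_h: float
    amplitude: float
    damping: float
    baseline: float
    rae: float
    gof: float
    n_obs: int
    period_se: float = float("nan")
    amplitude_se: float = float("nan")
    success: bool = True
    label: str = "trace"

    @property
    def initiated(self) -> bool:
        return classify_initiated(self)

    def summary(self) -> str:
        rows = [
            ("period tau (h)", self.period_h, self.period_se),
            ("phase phi (h)", self.phase_h, float("nan")),
            ("amplitude A", self.amplitude, self.amplitude_se),
            ("damping lambda (/h)", self.damping, float("nan")),
            ("baseline c", self.baseline, float("nan")),
        ]
        lines = [
            f"Damped-cosine rhythm fit: {self.label}",
            "=" * 46,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
            "-" * 46,
        ]
        for name, est, se in rows:
            se_s = f"{se:>12.4f}" if np.isfinite(se) else f"{'':>12}"
            lines.append(f"{name:<22}{est:>12.4f}{se_s}")
        lines += [
            "-" * 46,
            f"RAE: {self.rae:.4f}   GOF (1-SSR/SST): {self.gof:.4f}   n = {self.n_obs}",
            f"initiated: {self.initiated} "
            f"(period in [{PERIOD_BOUNDS_H[0]}, {PERIOD_BOUNDS_H[1]}] h and RAE < {RAE_MAX})",
        ]
        return "\n".join(lines)

    @classmethod
    def failed(cls, n_obs: int, label: str = "trace") -> "RhythmFit":
        return cls(
            period_h=float("nan"),
            phase_h=float("nan"),
            amplitude=0.0,
            damping=0.0,
            baseline=float("nan"),
            rae=float("inf"),
            gof=0.0,
            n_obs=n_obs,
            success=False,
            label=label,
        )


def classify_initiated(
    fit: RhythmFit,
    period_bounds_h: Tuple[float, float] = PERIOD_BOUNDS_H,
    rae_max: float = RAE_MAX,
) -> bool:
    """Two-test rhythmicity call: period within bounds (inclusive) and RAE < max (strict)."""
    if not fit.success or not np.isfinite(fit.period_h):
        return False
    lo, hi = period_bounds_h
    return bool(lo <= fit.period_h <= hi and fit.rae < rae_max)


# ---------------------------------------------------------------------------
# Detrending and smoothing


def _centered_moving_average(y: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with edge truncation (min_periods=1)."""
    s = pd.Series(y)
    return s.rolling(window=window_samples, center=True, min_periods=1).mean().to_numpy()


def detrend_and_smooth(
    trace: BioluminescenceTrace,
    baseline_window_h: float = BASELINE_WINDOW_H,
    smooth_window_h: float = SMOOTH_WINDOW_H,
) -> BioluminescenceTrace:
    """Subtract a moving-average baseline, then smooth with a 2.5-h moving average.

    Both windows are centered; edges are handled by window truncation.
    """
    dt = trace.dt
    for name, w in (("baseline", baseline_window_h), ("smooth", smooth_window_h)):
        if w <= dt:
            raise ValueError(f"{name} window ({w} h) must exceed the sampling interval ({dt} h)")
        if w >= trace.duration_h:
            raise ValueError(f"{name} window ({w} h) must be shorter than the trace duration")

    def samples(w_h: float) -> int:
        n = max(1, int(round(w_h / dt)))
        return n if n % 2 == 1 else n + 1

    detrended = trace.signal - _centered_moving_average(trace.signal, samples(baseline_window_h))
    smoothed = _centered_moving_average(detrended, samples(smooth_window_h))
    return trace.replace_signal(smoothed)


# ---------------------------------------------------------------------------
# FFT-NLLS fit


class DampedCosineModel:
    """Damped-cosine rhythm model for a single trace (FFT-NLLS).

    Parameters are (baseline c, amplitude A, damping lambda, period tau,
    phase phi). The nonlinear least-squares fit is initialised from the
    dominant discrete-Fourier component whose period falls inside
    ``period_window_h``; if no spectral peak lies in the window the fit is
    reported as failed (``rae = inf``, not initiated).
    """

    n_params = 5

    def __init__(
        self,
        trace: BioluminescenceTrace,
        period_window_h: Tuple[float, float] = PERIOD_WINDOW_H,
    ):
        self.trace = trace
        self.period_window_h = (float(period_window_h[0]), float(period_window_h[1]))
        if self.period_window_h[0] <= 0 or self.period_window_h[0] >= self.period_window_h[1]:
            raise ValueError("period window must satisfy 0 < lo < hi")
        if trace.duration_h < 2 * self.period_window_h[0]:
            warnings.warn(
                "trace shorter than two putative periods; fit may be unidentifiable"
            )

    def _fft_start(self) -> Optional[np.ndarray]:
        t, y = self.trace.time_h, self.trace.signal
        dt = self.trace.dt
        yc = y - y.mean()
        spec = np.fft.rfft(yc)
        freqs = np.fft.rfftfreq(y.size, d=dt)
        lo, hi = self.period_window_h
        mask = (freqs > 0) & (freqs >= 1.0 / hi) & (freqs <= 1.0 / lo)
        if not mask.any():
            return None
        power = np.abs(spec) ** 2
        idx = np.flatnonzero(mask)[np.argmax(power[mask])]
        tau0 = 1.0 / freqs[idx]
        amp0 = 2.0 * np.abs(spec[idx]) / y.size
        # y ~ A cos(2 pi f t - theta) -> component phase theta = -angle(spec)
        theta0 = -np.angle(spec[idx])
        phi0 = (theta0 * tau0 / (2 * np.pi) + t[0]) % tau0
        return np.array([y.mean(), amp0, 0.0, tau0, phi0])

    @staticmethod
    def _predict(params: np.ndarray, t: np.ndarray) -> np.ndarray:
        c, A, lam, tau, phi = params
        return c + A * np.exp(-lam * t) * np.cos(2 * np.pi * (t - phi) / tau)

    def fit(self) -> RhythmFit:
        t, y = self.trace.time_h, self.trace.signal
        x0 = self._fft_start()
        if x0 is None:
            return RhythmFit.failed(y.size, self.trace.label)
        lo, hi = self.period_window_h
        bounds = (
            [-np.inf, 0.0, 0.0, lo, -np.inf],
            [np.inf, np.inf, 2.0, hi, np.inf],
        )
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(
                lambda p: self._predict(p, t) - y, x0, bounds=bounds, method="trf"
            )
        except Exception:
            return RhythmFit.failed(y.size, self.trace.label)
        if not res.success and not np.isfinite(res.cost):
            return RhythmFit.failed(y.size, self.trace.label)

        c, A, lam, tau, phi = res.x
        phi = phi % tau
        ssr = float(2 * res.cost)
        sst = float(((y - y.mean()) ** 2).sum())
        gof = 1.0 - ssr / sst if sst > 0 else 0.0

        dof = max(y.size - self.n_params, 1)
        s2 = ssr / dof
        try:
            JTJ = res.jac.T @ res.jac
            cov = s2 * np.linalg.pinv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except Exception:
            se = np.full(self.n_params, np.nan)
        amp_se, tau_se = se[1], se[3]
        rae = _Z95 * amp_se / A if (A > 0 and np.isfinite(amp_se)) else float("inf")
        return RhythmFit(
            period_h=float(tau),
            phase_h=float(phi),
            amplitude=float(A),
            damping=float(lam),
            baseline=float(c),
            rae=float(rae),
            gof=float(gof),
            n_obs=int(y.size),
            period_se=float(tau_se),
            amplitude_se=float(amp_se),
            success=True,
            label=self.trace.label,
        )


def fit_rhythm(
    trace: BioluminescenceTrace,
    period_window_h: Tuple[float, float] = PERIOD_WINDOW_H,
) -> RhythmFit:
    """Convenience wrapper: ``DampedCosineModel(trace, window).fit()``."""
    return DampedCosineModel(trace, period_window_h).fit()


# ---------------------------------------------------------------------------
# Circular statistics


def rayleigh(phases_h: Sequence[float], period_h: float) -> Tuple[float, float]:
    """Rayleigh test of phase coherence.

    Phases (hours) are mapped to angles ``theta = 2*pi*phase/period``; the
    mean resultant length is ``R = |sum exp(i theta)| / n`` (1 = perfect
    synchrony, 0 = uniform dispersion). The p-value uses the standard
    finite-n approximation (Zar, Biostatistical Analysis):
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` with ``Rn = n*R``.
    """
    phases = np.asarray(phases_h, float)
    if phases.size < 2:
        raise ValueError("Rayleigh test needs at least two phases")
    if period_h <= 0:
        raise ValueError("period must be positive")
    theta = 2 * np.pi * phases / period_h
    n = phases.size
    Rn = np.abs(np.exp(1j * theta).sum())
    R = Rn / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    return float(R), float(min(max(p, 0.0), 1.0))


def _circular_mean_angle(theta: np.ndarray) -> float:
    return float(np.angle(np.exp(1j * theta).sum()))


# ---------------------------------------------------------------------------
# Phase maps


@dataclass
class PhaseMap:
    """Per-ROI rhythm fits over a grid, with slice-level coherence summaries.

    ``table`` has one row per ROI (row, col, mean_signal, included, fit
    parameters, initiated flag and relative phase vs the slice circular
    mean phase); ``initiated_fraction`` counts initiated ROIs among those
    above the bulk-signal threshold.
    """

    table: pd.DataFrame
    initiated_fraction: float
    rayleigh_R: float
    rayleigh_p: float
    mean_period_h: float

    def plot(self, ax=None):
        """Relative-phase heat map (initiated ROIs; others masked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        nrow = int(self.table["row"].max()) + 1
        ncol = int(self.table["col"].max()) + 1
        img = np.full((nrow, ncol), np.nan)
        sub = self.table[self.table["initiated"]]
        img[sub["row"].to_numpy(int), sub["col"].to_numpy(int)] = sub["rel_phase_h"]
        pc = ax.imshow(img, cmap="twilight", origin="lower")
        ax.figure.colorbar(pc, ax=ax, label="relative phase (h)")
        ax.set_xlabel("column")
        ax.set_ylabel("row")
        ax.set_title(f"initiated fraction {self.initiated_fraction:.2f}, R = {self.rayleigh_R:.2f}")
        return ax


def build_phase_map(
    grid: ROIGrid,
    signal_threshold: float,
    baseline_window_h: float = BASELINE_WINDOW_H,
    smooth_window_h: float = SMOOTH_WINDOW_H,
    period_window_h: Tuple[float, float] = PERIOD_WINDOW_H,
) -> PhaseMap:
    """Fit and classify every ROI of a grid and assemble the phase map.

    ROIs whose mean raw signal falls below ``signal_threshold`` are treated
    as extra-SCN background and excluded. Included ROIs are detrended,
    smoothed, fitted and classified; phases of initiated ROIs are expressed
    relative to their circular mean, and the Rayleigh statistic is computed
    over the initiated phases.
    """
    if len(grid) == 0:
        raise ValueError("empty ROI grid")
    rows = []
    fits: List[Optional[RhythmFit]] = []
    for i, trace in enumerate(grid):
        r, c = grid.position(i)
        mean_sig = float(trace.signal.mean())
        included = mean_sig >= signal_threshold
        fit = None
        if included:
            fit = fit_rhythm(
                detrend_and_smooth(trace, baseline_window_h, smooth_window_h),
                period_window_h,
            )
        fits.append(fit)
        rows.append(
            {
                "row": r,
                "col": c,
                "roi": trace.label,
                "mean_signal": mean_sig,
                "included": included,
                "period_h": fit.period_h if fit else np.nan,
                "phase_h": fit.phase_h if fit else np.nan,
                "amplitude": fit.amplitude if fit else np.nan,
                "rae": fit.rae if fit else np.nan,
                "gof": fit.gof if fit else np.nan,
                "initiated": bool(fit.initiated) if fit else False,
            }
        )
    table = pd.DataFrame(rows)
    n_included = int(table["included"].sum())
    if n_included == 0:
        raise ValueError("all ROIs fall below the signal threshold")
    initiated = table["initiated"].to_numpy()
    frac = float(initiated.sum() / n_included)

    rel = np.full(len(table), np.nan)
    R, p, tau_bar = float("nan"), float("nan"), float("nan")
    init_idx = np.flatnonzero(initiated)
    if init_idx.size >= 1:
        taus = table.loc[init_idx, "period_h"].to_numpy()
        tau_bar = float(np.mean(taus))
        theta = 2 * np.pi * table.loc[init_idx, "phase_h"].to_numpy() / taus
        mean_theta = _circular_mean_angle(theta)
        wrapped = np.angle(np.exp(1j * (theta - mean_theta)))
        rel[init_idx] = wrapped * tau_bar / (2 * np.pi)
        if init_idx.size >= 2:
            R, p = rayleigh(theta * tau_bar / (2 * np.pi), tau_bar)
    table["rel_phase_h"] = rel
    return PhaseMap(
        table=table,
        initiated_fraction=frac,
        rayleigh_R=R,
        rayleigh_p=p,
        mean_period_h=tau_bar,
    )


# ---------------------------------------------------------------------------
# Peaks, phase shifts, waveform changes, PRC


def detect_peaks(
    trace: BioluminescenceTrace,
    prominence_frac: float = 0.2,
    min_separation_h: float = 16.0,
    refine: bool = True,
) -> np.ndarray:
    """Times (h) of local maxima in a detrended/smoothed trace.

    Peaks must have prominence >= ``prominence_frac`` of the signal range
    and be separated by >= ``min_separation_h``. The trace is padded below
    its minimum at both ends so maxima at the boundaries are detected too.
    With ``refine`` (default) interior peak times are localised to
    sub-sample precision by a least-squares parabola over a +-3 h window
    around each detected peak, which averages out residual noise.
    """
    y = trace.signal
    t = trace.time_h
    rng = float(y.max() - y.min())
    if rng == 0:
        return np.empty(0)
    pad = y.min() - rng
    ypad = np.concatenate([[pad], y, [pad]])
    dist = max(1, int(round(min_separation_h / trace.dt)))
    idx, _ = find_peaks(ypad, prominence=prominence_frac * rng, distance=dist)
    idx = idx - 1
    idx = idx[(idx >= 0) & (idx < y.size)]
    times = t[idx].astype(float)
    if refine:
        half_w = 3.0
        for k, i in enumerate(idx):
            sel = np.flatnonzero(np.abs(t - t[i]) <= half_w)
            if sel.size < 5:
                continue
            tt = t[sel] - t[i]
            a, b, _c = np.polyfit(tt, y[sel], 2)
            if a < 0:
                vertex = -b / (2 * a)
                if abs(vertex) <= half_w:
                    times[k] = t[i] + vertex
    return times


def phase_shift(
    trace: BioluminescenceTrace,
    treatment_time_h: Optional[float] = None,
    edge_exclusion_h: Optional[float] = None,
    **peak_kwargs,
) -> float:
    """Treatment-induced phase shift (h); positive = delay.

    Pre-treatment peaks (>= 3 required) define the free-running period and
    phase by a linear fit of peak time against cycle number; the expected
    continuation is extrapolated and the shift is the mean deviation
    (observed - expected) of the first three post-treatment peaks. Peaks
    within half a baseline window of either trace end are discarded (the
    moving-average edge truncation distorts them).
    """
    t_rx = treatment_time_h if treatment_time_h is not None else trace.treatment_time_h
    if t_rx is None:
        raise ValueError("treatment time required (argument or trace.treatment_time_h)")
    t = trace.time_h
    detr = detrend_and_smooth(trace)
    peaks = detect_peaks(detr, **peak_kwargs)
    edge = BASELINE_WINDOW_H / 2 if edge_exclusion_h is None else edge_exclusion_h
    # Trace ends and the zone around the treatment are edge-truncated /
    # mixed-regime territory for the moving-average baseline; peaks there
    # are filter artifacts rather than rhythm peaks.
    keep = (peaks >= t[0] + edge) & (peaks <= t[-1] - edge)
    keep &= np.abs(peaks - t_rx) >= edge
    peaks = peaks[keep]
    pre = peaks[peaks < t_rx]
    post = peaks[peaks >= t_rx]
    if pre.size < 3 or post.size < 3:
        raise ValueError(
            f"need >=3 peaks on each side of treatment (found {pre.size} pre, {post.size} post)"
        )
    k = np.arange(pre.size)
    period_pre, t0 = np.polyfit(k, pre, 1)
    shifts = []
    for tp in post[:3]:
        cycle = np.round((tp - t0) / period_pre)
        shifts.append(tp - (t0 + cycle * period_pre))
    return float(np.mean(shifts))


@dataclass
class WaveformChange:
    """Relative baseline/amplitude change and period change across a treatment."""

    delta_baseline_rel: float
    delta_amplitude_rel: float
    delta_period_h: float
    pre_cycle: Tuple[float, float]
    post_cycle: Tuple[float, float]


def waveform_changes(
    trace: BioluminescenceTrace,
    treatment_time_h: Optional[float] = None,
    period_window_h: Tuple[float, float] = PERIOD_WINDOW_H,
) -> WaveformChange:
    """Baseline, amplitude and period changes across a treatment.

    Cycles are delimited by troughs of the detrended trace; the comparison
    is the first full post-treatment cycle (anchored at the first
    post-treatment trough) against the last full pre-treatment cycle.
    Baseline is the cycle mean of the raw signal, amplitude is
    (peak - trough)/2 of the raw signal within the cycle, and the period
    change comes from damped-cosine fits of the detrended pre and post
    segments.
    """
    t_rx = treatment_time_h if treatment_time_h is not None else trace.treatment_time_h
    if t_rx is None:
        raise ValueError("treatment time required (argument or trace.treatment_time_h)")
    detr = detrend_and_smooth(trace)
    troughs = detect_peaks(detr.replace_signal(-detr.signal))
    pre_troughs = troughs[troughs < t_rx]
    post_troughs = troughs[troughs >= t_rx]
    if pre_troughs.size < 2 or post_troughs.size < 2:
        raise ValueError("need at least one full cycle on each side of treatment")
    pre_cycle = (float(pre_troughs[-2]), float(pre_troughs[-1]))
    post_cycle = (float(post_troughs[0]), float(post_troughs[1]))

    t, y = trace.time_h, trace.signal

    def cycle_stats(lo: float, hi: float) -> Tuple[float, float]:
        m = (t >= lo) & (t <= hi)
        seg = y[m]
        return float(seg.mean()), float((seg.max() - seg.min()) / 2)

    base_pre, amp_pre = cycle_stats(*pre_cycle)
    base_post, amp_post = cycle_stats(*post_cycle)
    if base_pre == 0 or amp_pre == 0:
        warnings.warn("pre-treatment baseline or amplitude is zero; relative change undefined")
    d_base = (base_post - base_pre) / base_pre if base_pre != 0 else float("nan")
    d_amp = (amp_post - amp_pre) / amp_pre if amp_pre != 0 else float("nan")

    def segment_fit(lo: float, hi: float) -> RhythmFit:
        m = (t >= lo) & (t <= hi)
        seg = BioluminescenceTrace(t[m], y[m], label=trace.label)
        return fit_rhythm(detrend_and_smooth(seg), period_window_h)

    fit_pre = segment_fit(t[0], t_rx)
    fit_post = segment_fit(t_rx, t[-1])
    d_period = fit_post.period_h - fit_pre.period_h
    return WaveformChange(
        delta_baseline_rel=d_base,
        delta_amplitude_rel=d_amp,
        delta_period_h=float(d_period),
        pre_cycle=pre_cycle,
        post_cycle=post_cycle,
    )


def assemble_prc(
    records: Iterable[Tuple[float, float]] | pd.DataFrame,
    bin_width_h: float = 3.0,
) -> pd.DataFrame:
    """Bin (treatment CT, phase shift) records into a phase-response curve.

    Bins are anchored at CT0 — [0, 3), [3, 6), ... — with CT values reduced
    mod 24 before binning. Returns per-bin mean, SEM and n (empty bins are
    reported with n = 0).
    """
    if isinstance(records, pd.DataFrame):
        ct = records.iloc[:, 0].to_numpy(float)
        shift = records.iloc[:, 1].to_numpy(float)
    else:
        arr = np.asarray(list(records), float)
        if arr.size == 0:
            ct, shift = np.empty(0), np.empty(0)
        else:
            ct, shift = arr[:, 0], arr[:, 1]
    if bin_width_h <= 0 or 24.0 % bin_width_h != 0:
        raise ValueError("bin width must be positive and divide 24 h")
    ct = np.mod(ct, 24.0)
    n_bins = int(24.0 / bin_width_h)
    which = np.floor(ct / bin_width_h).astype(int)
    rows = []
    for b in range(n_bins):
        vals = shift[which == b]
        rows.append(
            {
                "bin_start_ct": b * bin_width_h,
                "bin_end_ct": (b + 1) * bin_width_h,
                "mean_shift_h": float(vals.mean()) if vals.size else np.nan,
                "sem_h": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else (0.0 if vals.size == 1 else np.nan),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("bin_start_ct")


def map_ct(
    phase_h: float,
    reference_phase_h: float,
    reference_ct: float,
    period_h: float = 24.0,
    reference_period_h: Optional[float] = None,
) -> float:
    """Convert a fitted phase to circadian time via a reference oscillation.

    ``CT(x) = (reference_ct + (phase_x - phase_ref)) mod period``. Warns if
    the two fitted periods differ by more than 1 h (registration between
    reporters is then questionable).
    """
    if reference_period_h is not None and abs(period_h - reference_period_h) > 1.0:
        warnings.warn(
            f"periods differ by {abs(period_h - reference_period_h):.2f} h; "
            "CT registration may be unreliable"
        )
    return float(np.mod(reference_ct + (phase_h - reference_phase_h), period_h))
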