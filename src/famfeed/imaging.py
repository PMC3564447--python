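"""Ratiometric calcium-imaging pipeline.

Turns two-channel (cyan 480 nm / yellow 535 nm) fluorescence into the
fractional ratio change ΔR/R of a YC3.60-type FRET sensor, a 10 s-binned
time course, and a signed-area response statistic:

1. raw ratio ``R = (I_535 − I'_535)/(I_480 − I'_480) − 0.65`` where primes
   are background-ROI intensities and 0.65 corrects cyan→yellow
   bleed-through;
2. photobleach correction by a single-exponential least-squares fit to the
   raw ratio trace, ``ΔR/R = R / (A e^{−λt}) − 1``;
3. per-animal 10 s bin means, then equal-weight averaging across animals;
4. trapezoidal signed area of ΔR/R over the first 120 s of the stimulus.

The :class:`CalciumResponseModel` bundles steps 1–4 for one recording and
returns a :class:`CalciumResponseResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "TwoChannelRecording",
    "RatioTrace",
    "BleachFit",
    "BinnedResponse",
    "ResponseSummary",
    "extract_roi_trace",
    "compute_raw_ratio",
    "fit_photobleach",
    "correct_photobleach",
    "bin_timecourse",
    "average_binned",
    "signed_area",
    "compare_response_groups",
    "CalciumResponseModel",
    "CalciumResponseResults",
    "DEFAULT_BLEED",
]

#: fraction of the cyan signal that bleeds into the yellow channel
DEFAULT_BLEED = 0.65


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class TwoChannelRecording:
    """Per-frame ROI and background intensities of one recording.

    ``i_480``/``i_535`` are circular-ROI means centred on the neuron;
    ``bg_480``/``bg_535`` are the surrounding-annulus means.  Time is in
    seconds from acquisition start; ``stimulus_onset_s`` marks stimulus
    delivery on that clock.
    """

    time_s: np.ndarray
    i_480: np.ndarray
    i_535: np.ndarray
    bg_480: np.ndarray
    bg_535: np.ndarray
    stimulus_onset_s: float

    def __post_init__(self):
        arrays = [self.time_s, self.i_480, self.i_535, self.bg_480, self.bg_535]
        n = len(self.time_s)
        if n < 2:
            raise PipelineError("recording needs at least 2 frames")
        if any(len(a) != n for a in arrays):
            raise PipelineError("channel/background vectors must share one length")
        if not np.all(np.diff(self.time_s) > 0):
            raise PipelineError("time_s must be strictly increasing")
        if not (self.time_s[0] <= self.stimulus_onset_s <= self.time_s[-1]):
            raise PipelineError("stimulus_onset_s outside the recorded time span")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class RatioTrace:
    """Emission-ratio time series aligned to stimulus delivery (t = 0).

    ``stage`` is ``"raw"`` (R) or ``"corrected"`` (ΔR/R).  Figures in the
    field show 100× the corrected values as a percentage change.
    """

    time_s: np.ndarray
    values: np.ndarray
    stage: str

    def __post_init__(self):
        if len(self.time_s) != len(self.values):
            raise PipelineError("time and value vectors differ in length")
        if not np.all(np.diff(self.time_s) > 0):
            raise PipelineError("time_s must be strictly increasing")
        if self.stage not in ("raw", "corrected"):
            raise PipelineError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class BleachFit:
    """Single-exponential photobleach fit ``A exp(−λ t)`` to a raw ratio."""

    amplitude: float
    decay_rate: float  # 1/s, constrained >= 0: bleaching cannot brighten
    residual_rms: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.decay_rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class BinnedResponse:
    """Bin means of ΔR/R in half-open bins [lo, hi) anchored at t = 0."""

    bin_edges: np.ndarray  # length n_bins + 1
    means: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ResponseSummary:
    """Signed area of ΔR/R over a post-stimulus window (units: seconds,
    since ΔR/R is dimensionless)."""

    signed_area: float
    window: tuple[float, float]


# ---------------------------------------------------------------------------
# ROI extraction


def extract_roi_trace(
    stack: np.ndarray,
    center: tuple[float, float],
    roi_radius: float,
    bg_outer_radius: float,
    time_s: np.ndarray,
    stimulus_onset_s: float,
) -> TwoChannelRecording:
    """Extract ROI and background traces from a 2-channel image stack.

    ``stack`` has axes (frame, channel, y, x) with channel 0 = cyan
    (480 nm) and channel 1 = yellow (535 nm).  ``I`` is the mean over
    pixels whose centre lies within ``roi_radius`` of ``center`` (x, y,
    0-based); ``I'`` is the mean over the annulus
    ``roi_radius < d <= bg_outer_radius``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise PipelineError("stack must have axes (frame, channel=2, y, x)")
    if not (0 < roi_radius < bg_outer_radius):
        raise PipelineError("need 0 < roi_radius < bg_outer_radius")
    h, w = stack.shape[2], stack.shape[3]
    cx, cy = center
    if (cx - bg_outer_radius < -0.5 or cx + bg_outer_radius > w - 0.5
            or cy - bg_outer_radius < -0.5 or cy + bg_outer_radius > h - 0.5):
        raise PipelineError("background ROI exceeds frame bounds")

    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    disc = d2 <= roi_radius**2
    annulus = (d2 > roi_radius**2) & (d2 <= bg_outer_radius**2)
    if not disc.any():
        raise PipelineError("ROI disc contains no pixels")
    if not annulus.any():
        raise PipelineError("background annulus contains no pixels")

    i_cyan = stack[:, 0][:, disc].mean(axis=1)
    i_yellow = stack[:, 1][:, disc].mean(axis=1)
    bg_cyan = stack[:, 0][:, annulus].mean(axis=1)
    bg_yellow = stack[:, 1][:, annulus].mean(axis=1)
    return TwoChannelRecording(
        time_s=np.asarray(time_s, dtype=float),
        i_480=i_cyan,
        i_535=i_yellow,
        bg_480=bg_cyan,
        bg_535=bg_yellow,
        stimulus_onset_s=stimulus_onset_s,
    )


# ---------------------------------------------------------------------------
# ratio computation and photobleach correction


def compute_raw_ratio(rec: TwoChannelRecording, bleed: float = DEFAULT_BLEED) -> RatioTrace:
    """Background-subtracted emission ratio with bleed-through correction.

    ``R = (I_535 − I'_535) / (I_480 − I'_480) − bleed`` per frame; time is
    re-expressed relative to stimulus delivery.
    """
    denom = rec.i_480 - rec.bg_480
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise PipelineError(
            f"non-positive cyan signal (I_480 - I'_480) at frame {bad[0]}"
        )
    values = (rec.i_535 - rec.bg_535) / denom - bleed
    return RatioTrace(
        time_s=rec.time_s - rec.stimulus_onset_s, values=values, stage="raw"
    )


def fit_photobleach(trace: RatioTrace, prestim_only: bool = False) -> BleachFit:
    """Least-squares fit of ``A exp(−λ t)`` to a raw ratio trace.

    The fit covers the entire trace by default (``prestim_only=True``
    restricts it to frames before stimulus delivery).  λ is constrained
    non-negative; starting values come from a log-linear regression.
    """
    if trace.stage != "raw":
        raise PipelineError("photobleach fit expects a raw ratio trace")
    t = trace.time_s
    y = trace.values
    if prestim_only:
        keep = t < 0
        if keep.sum() < 5:
            raise PipelineError("fewer than 5 pre-stimulus frames to fit")
        t, y = t[keep], y[keep]
    if len(y) < 5:
        raise PipelineError("need at least 5 frames to fit the bleach curve")
    if np.any(y <= 0):
        raise PipelineError("raw ratio must be positive everywhere for the fit")

    # log-domain initialisation; slope clipped so the exponent cannot grow
    slope, intercept = np.polyfit(t, np.log(y), 1)
    lam0 = max(-slope, 0.0)
    a0 = float(np.exp(intercept + slope * 0.0)) if lam0 > 0 else float(np.exp(np.mean(np.log(y))))

    def model(tt, a, lam):
        return a * np.exp(-lam * tt)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[max(a0, 1e-12), lam0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy rarely fails here
        raise PipelineError(
            f"photobleach fit did not converge (initial A={a0:.4g}, "
            f"lambda={lam0:.4g}): {err}"
        ) from err
    a, lam = float(popt[0]), float(popt[1])
    rms = float(np.sqrt(np.mean((y - model(t, a, lam)) ** 2)))
    return BleachFit(amplitude=a, decay_rate=lam, residual_rms=rms)


def correct_photobleach(trace: RatioTrace, fit: BleachFit) -> RatioTrace:
    """Normalise a raw ratio by the fitted bleach curve: ΔR/R = R/fit − 1."""
    if trace.stage != "raw":
        raise PipelineError("correction expects a raw ratio trace")
    baseline = fit(trace.time_s)
    if np.any(baseline <= 0):
        raise PipelineError("fitted bleach curve is non-positive on the trace")
    return RatioTrace(
        time_s=trace.time_s, values=trace.values / baseline - 1.0, stage="corrected"
    )


# ---------------------------------------------------------------------------
# binning and the signed-area statistic


def bin_timecourse(trace: RatioTrace, bin_width_s: float = 10.0) -> BinnedResponse:
    """Mean ΔR/R in half-open ``[k·w, (k+1)·w)`` bins anchored at t = 0.

    Negative-k bins cover the pre-stimulus period.  Only bins containing
    at least one frame are reported.
    """
    if trace.stage != "corrected":
        raise PipelineError("binning expects a corrected (ΔR/R) trace")
    if bin_width_s <= 0:
        raise PipelineError("bin_width_s must be > 0")
    if len(trace.values) == 0:
        raise PipelineError("empty trace")
    idx = np.floor(trace.time_s / bin_width_s).astype(int)
    k_lo, k_hi = idx.min(), idx.max()
    ks = np.arange(k_lo, k_hi + 1)
    counts = np.bincount(idx - k_lo, minlength=len(ks))
    sums = np.bincount(idx - k_lo, weights=trace.values, minlength=len(ks))
    keep = counts >= 1
    ks = ks[keep]
    means = sums[keep] / counts[keep]
    edges = np.concatenate([ks, [ks[-1] + 1]]) * bin_width_s
    return BinnedResponse(bin_edges=edges.astype(float), means=means, counts=counts[keep])


def average_binned(responses: list[BinnedResponse]) -> BinnedResponse:
    """Equal-weight cross-animal average of per-animal bin means.

    Bins are matched by their edges; a bin is reported if at least one
    animal contributes to it, and each contributing animal counts once.
    """
    if not responses:
        raise PipelineError("no binned responses to average")
    per_bin: dict[tuple[float, float], list[float]] = {}
    for r in responses:
        for lo, hi, m in zip(r.bin_edges[:-1], r.bin_edges[1:], r.means):
            per_bin.setdefault((float(lo), float(hi)), []).append(float(m))
    keys = sorted(per_bin)
    edges = np.array([k[0] for k in keys] + [keys[-1][1]])
    means = np.array([np.mean(per_bin[k]) for k in keys])
    counts = np.array([len(per_bin[k]) for k in keys])
    return BinnedResponse(bin_edges=edges, means=means, counts=counts)


def signed_area(
    trace: RatioTrace, window: tuple[float, float] = (0.0, 120.0)
) -> ResponseSummary:
    """Trapezoidal signed area of ΔR/R over ``window`` (seconds after
    stimulus delivery).

    Integration runs on the native sampling grid; the window endpoints are
    included by linear interpolation when they fall between frames.  The
    recording may stop up to one frame interval short of the window end,
    in which case the integral runs to the last frame.  Negative
    excursions subtract.
    """
    if trace.stage != "corrected":
        raise PipelineError("signed area expects a corrected (ΔR/R) trace")
    lo, hi = float(window[0]), float(window[1])
    if not (lo >= 0 and hi > lo):
        raise PipelineError("window must satisfy 0 <= start < end")
    t, v = trace.time_s, trace.values
    dt = np.median(np.diff(t))
    if t[0] > lo or t[-1] < hi - dt:
        raise PipelineError(
            f"trace [{t[0]:.1f}, {t[-1]:.1f}] s does not span window [{lo}, {hi}] s"
        )
    hi_eff = min(hi, float(t[-1]))
    inside = (t > lo) & (t < hi_eff)
    tt = np.concatenate([[lo], t[inside], [hi_eff]])
    vv = np.concatenate([[np.interp(lo, t, v)], v[inside], [np.interp(hi_eff, t, v)]])
    return ResponseSummary(signed_area=float(np.trapezoid(vv, tt)), window=(lo, hi))


def compare_response_groups(areas_by_group: dict[str, list[float]]):
    """One-way ANOVA with Tukey HSD on per-animal signed areas by group.

    Thin delegate to :func:`famfeed.feeding.anova_tukey`, which documents
    the contract.
    """
    from .feeding import anova_tukey

    return anova_tukey(areas_by_group)


# ---------------------------------------------------------------------------
# model / results surface


class CalciumResponseModel:
    """End-to-end ΔR/R analysis of one two-channel recording.

    Parameters
    ----------
    recording : TwoChannelRecording
    bleed : float
        Cyan→yellow bleed-through fraction subtracted from the raw ratio.
    bin_width_s : float
        Width of the time-course bins, seconds.
    window : (float, float)
        Signed-area window in seconds after stimulus delivery.
    fit_prestim_only : bool
        Restrict the photobleach fit to pre-stimulus frames (default).
        Fitting the whole trace instead runs the exponential through the
        response itself and attenuates ΔR/R by roughly the fraction of
        the trace the response occupies; see the methods documentation.
    """

    def __init__(
        self,
        recording: TwoChannelRecording,
        bleed: float = DEFAULT_BLEED,
        bin_width_s: float = 10.0,
        window: tuple[float, float] = (0.0, 120.0),
        fit_prestim_only: bool = True,
    ):
        self.recording = recording
        self.bleed = bleed
        self.bin_width_s = bin_width_s
        self.window = window
        self.fit_prestim_only = fit_prestim_only

    def fit(self) -> "CalciumResponseResults":
        raw = compute_raw_ratio(self.recording, self.bleed)
        bleach = fit_photobleach(raw, prestim_only=self.fit_prestim_only)
        corrected = correct_photobleach(raw, bleach)
        binned = bin_timecourse(corrected, self.bin_width_s)
        summary = signed_area(corrected, self.window)
        return CalciumResponseResults(self, raw, bleach, corrected, binned, summary)


@dataclass(frozen=True)
class CalciumResponseResults:
    """Fitted quantities of a :class:`CalciumResponseModel`."""

    model: CalciumResponseModel
    raw_ratio: RatioTrace
    bleach_fit: BleachFit
    delta_r: RatioTrace
    binned: BinnedResponse
    response: ResponseSummary

    @property
    def signed_area(self) -> float:
        return self.response.signed_area

    def summary(self) -> str:
        m = self.model
        lines = [
            "Calcium response (ratiometric ΔR/R)",
            "===================================",
            f"frames                 {self.raw_ratio.values.size}",
            f"bleed-through          {m.bleed:.2f}",
            f"bleach fit A           {self.bleach_fit.amplitude:.5g}",
            f"bleach fit lambda      {self.bleach_fit.decay_rate:.5g} 1/s",
            f"bleach residual rms    {self.bleach_fit.residual_rms:.3g}",
            f"peak ΔR/R              {self.delta_r.values.max():.4f}",
            f"signed area {m.window[0]:g}-{m.window[1]:g} s   "
            f"{self.response.signed_area:.4f} s",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the binned ΔR/R time course (percent change)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(
            self.binned.bin_edges[:-1],
            100.0 * self.binned.means,
            where="post",
        )
        ax.axvline(0.0, linestyle="--", color="k")
        ax.set_xlabel("time after stimulus (s)")
        ax.set_ylabel("ΔR/R (%)")
        return ax
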