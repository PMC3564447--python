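"""Synthetic data generators for every input the pipeline consumes.

Three generators, each with a known ground truth so downstream stages can be
tested for parameter recovery:

* :func:`gen_imaging_recording` — two-channel (cyan/yellow) fluorescence
  traces from a YC3.60-style FRET sensor, with per-channel exponential
  photobleaching, additive background, cyan→yellow bleed-through and a
  stimulus-locked slow calcium transient.
* :func:`gen_feeding_dataset` — per-animal pharyngeal pump-count triplets
  (adults, 3 × 30 s) or pairs (L1 larvae, 2 × 55 s) around condition means.
* :func:`gen_cellcount_dataset` — serotonin-positive AIM/RIH cell counts in
  {0..3} per animal per condition per experiment.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .imaging import TwoChannelRecording

__all__ = [
    "ImagingSimParams",
    "GroundTruth",
    "FeedingDesign",
    "FeedingCondition",
    "CellCountDesign",
    "gen_imaging_recording",
    "gen_feeding_dataset",
    "gen_cellcount_dataset",
    "render_tiff_stack",
    "transient_kernel",
]

#: Conditions are coded by two letters: training food then test food
#: (H = E. coli HB101, D = Pseudomonas DA1878).
CONDITION_CODES = ("HH", "DH", "DD", "HD")


class SimulationParameterError(ValueError):
    """A simulation parameter violates its validity constraint."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise SimulationParameterError(f"{name}: {msg}")


@dataclass(frozen=True)
class ImagingSimParams:
    """Parameters of a simulated two-channel calcium-imaging recording.

    The forward model is

    .. math::

        S_c(t) = I_c \\, e^{-t/\\tau_c}, \\qquad
        S_y(t) = r(t) \\, I_c \\, e^{-t/\\tau_y},

    ``cyan = S_c + b_c + noise`` and
    ``yellow = S_y + 0.65 S_c + b_y + noise``, where the bleed-through term
    is a fixed fraction of the *cyan* signal and
    ``r(t) = r0 (1 + a k(t - onset))`` is the true sensor ratio with a
    smooth rise/decay kernel ``k`` normalised to peak 1.  With equal
    channel bleach constants the raw ratio
    ``(yellow - b_y)/(cyan - b_c) - 0.65`` recovers ``r(t)`` exactly;
    unequal constants produce the slow ratio drift that the photobleach
    correction removes.
    """

    duration_s: float = 200.0
    frame_rate_hz: float = 5.0
    stimulus_onset_s: float = 40.0
    baseline_ratio: float = 1.0
    transient_amplitude: float = 0.10
    transient_rise_s: float = 10.0
    transient_decay_s: float = 40.0
    bleach_tau_cyan_s: float = 600.0
    bleach_tau_yellow_s: float = 400.0
    cyan_baseline_intensity: float = 1000.0
    background_cyan: float = 50.0
    background_yellow: float = 50.0
    bleed_coefficient: float = 0.65
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.duration_s > 0, "duration_s", "must be > 0")
        _require(self.frame_rate_hz > 0, "frame_rate_hz", "must be > 0")
        if not (2.0 <= self.frame_rate_hz <= 10.0):
            warnings.warn(
                "frame_rate_hz outside the typical 2-10 Hz acquisition range",
                stacklevel=3,
            )
        _require(
            0 <= self.stimulus_onset_s < self.duration_s,
            "stimulus_onset_s",
            "must lie within [0, duration_s)",
        )
        _require(self.baseline_ratio > 0, "baseline_ratio", "must be > 0")
        _require(self.transient_amplitude >= 0, "transient_amplitude", "must be >= 0")
        _require(self.transient_rise_s > 0, "transient_rise_s", "must be > 0")
        _require(self.transient_decay_s > 0, "transient_decay_s", "must be > 0")
        _require(self.bleach_tau_cyan_s > 0, "bleach_tau_cyan_s", "must be > 0")
        _require(self.bleach_tau_yellow_s > 0, "bleach_tau_yellow_s", "must be > 0")
        _require(
            self.cyan_baseline_intensity > 0,
            "cyan_baseline_intensity",
            "must be > 0",
        )
        _require(self.background_cyan >= 0, "background_cyan", "must be >= 0")
        _require(self.background_yellow >= 0, "background_yellow", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel of a simulated recording, for recovery tests."""

    true_ratio_trace: np.ndarray
    true_signed_area: float
    baseline_ratio: float


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Smooth stimulus-locked kernel ``(1 - exp(-t/rise)) exp(-t/decay)``,
    normalised to peak 1, zero for ``t < 0``.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_s)) * np.exp(-np.maximum(t, 0) / decay_s), 0.0)
    # analytic peak location of (1-exp(-t/r))exp(-t/d)
    t_peak = rise_s * np.log(1.0 + decay_s / rise_s)
    peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    return k / peak


def gen_imaging_recording(
    params: ImagingSimParams,
) -> tuple[TwoChannelRecording, GroundTruth]:
    """Simulate a two-channel recording and its ground truth.

    Returns the recording (per-frame cyan/yellow ROI intensities plus
    constant background traces and stimulus onset) and a
    :class:`GroundTruth` holding the true sensor ratio ``r(t)`` and the
    trapezoidal signed area of ``r/r0 - 1`` over the first 120 s of the
    stimulus.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n = int(round(params.duration_s * params.frame_rate_hz))
    t = np.arange(n) / params.frame_rate_hz

    kern = transient_kernel(t - params.stimulus_onset_s, params.transient_rise_s, params.transient_decay_s)
    r = params.baseline_ratio * (1.0 + params.transient_amplitude * kern)

    s_cyan = params.cyan_baseline_intensity * np.exp(-t / params.bleach_tau_cyan_s)
    s_yellow = r * params.cyan_baseline_intensity * np.exp(-t / params.bleach_tau_yellow_s)

    cyan = s_cyan + params.background_cyan + rng.normal(0.0, params.noise_sd, n) if params.noise_sd else s_cyan + params.background_cyan
    yellow_noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else 0.0
    yellow = s_yellow + params.bleed_coefficient * s_cyan + params.background_yellow + yellow_noise

    rec = TwoChannelRecording(
        time_s=t,
        i_480=np.asarray(cyan, dtype=float),
        i_535=np.asarray(yellow, dtype=float),
        bg_480=np.full(n, params.background_cyan, dtype=float),
        bg_535=np.full(n, params.background_yellow, dtype=float),
        stimulus_onset_s=params.stimulus_onset_s,
    )

    # truth signed area: trapezoid of r/r0 - 1 over [onset, onset + 120]
    rel = t - params.stimulus_onset_s
    frac = r / params.baseline_ratio - 1.0
    end = min(120.0, rel[-1])
    mask = (rel >= 0) & (rel <= end)
    area = float(np.trapezoid(frac[mask], rel[mask]))
    truth = GroundTruth(true_ratio_trace=r, true_signed_area=area, baseline_ratio=params.baseline_ratio)
    return rec, truth


# ---------------------------------------------------------------------------
# feeding-rate data


@dataclass(frozen=True)
class FeedingCondition:
    """One experimental group of the feeding assay."""

    training_food: str
    test_food: str
    genotype: str
    mean_rate: float
    sd_rate: float
    n_animals: int

    @property
    def label(self) -> str:
        return f"{self.training_food}{self.test_food}"


@dataclass(frozen=True)
class FeedingDesign:
    """Design of a synthetic feeding-rate dataset.

    ``counting_mode`` is ``"adult"`` (three 30 s pump counts per animal,
    rates in pumps/min) or ``"l1"`` (two 55 s counts, rates reported as
    pumps per 55 s).
    """

    conditions: tuple[FeedingCondition, ...]
    counting_mode: str = "adult"
    seed: int = 0

    def validate(self) -> None:
        if self.counting_mode not in ("adult", "l1"):
            raise SimulationParameterError(
                f"counting_mode: unknown mode {self.counting_mode!r} (use 'adult' or 'l1')"
            )
        keys = [(c.genotype, c.label) for c in self.conditions]
        _require(len(keys) == len(set(keys)), "conditions", "labels must be unique")
        for c in self.conditions:
            _require(c.n_animals >= 1, "n_animals", "must be >= 1")
            _require(c.sd_rate >= 0, "sd_rate", "must be >= 0")
            _require(c.mean_rate >= 0, "mean_rate", "must be >= 0")


def _default_feeding_conditions() -> tuple[FeedingCondition, ...]:
    # familiar-food groups pump faster than novel-food groups; magnitudes
    # follow the wild-type adult range (~150-280 pumps/min)
    return tuple(
        FeedingCondition(cond[0], cond[1], "wt", mean, 20.0, 30)
        for cond, mean in zip(CONDITION_CODES, (265.0, 230.0, 255.0, 225.0))
    )


def default_feeding_design(seed: int = 0) -> FeedingDesign:
    """Four wild-type groups HH/DH/DD/HD with familiar > novel rates."""
    return FeedingDesign(conditions=_default_feeding_conditions(), seed=seed)


def gen_feeding_dataset(design: FeedingDesign) -> "pd.DataFrame":
    """Generate per-animal pump counts.

    Each animal's underlying rate is drawn from a normal truncated at 0;
    the matching total pump count is split across the counting windows by
    a symmetric multinomial so the windows vary naturally while the
    derived rate stays within rounding error of the draw.

    Returns a tidy DataFrame with columns ``animal_id, genotype,
    training_food, test_food, stage, window_s, count1..countK``.
    """
    import pandas as pd

    design.validate()
    rng = np.random.default_rng(design.seed)

    if design.counting_mode == "adult":
        n_windows, window_s, stage = 3, 30, "adult"
    else:
        n_windows, window_s, stage = 2, 55, "l1"

    rows = []
    aid = 0
    for cond in design.conditions:
        rates = rng.normal(cond.mean_rate, cond.sd_rate, cond.n_animals)
        rates = np.clip(rates, 0.0, None)
        for rate in rates:
            # expected pumps per window; adult rates are per minute
            per_window = rate * window_s / 60.0 if stage == "adult" else rate
            total = int(round(per_window * n_windows))
            counts = rng.multinomial(total, np.full(n_windows, 1.0 / n_windows))
            row = {
                "animal_id": f"a{aid:04d}",
                "genotype": cond.genotype,
                "training_food": cond.training_food,
                "test_food": cond.test_food,
                "stage": stage,
                "window_s": window_s,
            }
            row.update({f"count{i + 1}": int(c) for i, c in enumerate(counts)})
            rows.append(row)
            aid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serotonin-positive cell counts


@dataclass(frozen=True)
class CellCountDesign:
    """Design of a synthetic serotonin-positive cell-count dataset.

    ``expected_counts`` maps each condition (H and D starvation baselines;
    HH/DH/DD/HD refed groups) to the expected number of serotonin-positive
    AIM/RIH cells per animal, a value in [0, 3].  Counts are drawn as
    binomial(3, expected/3), the simplest family respecting the {0..3}
    support (two AIMs plus RIH).

    Defaults reproduce the study conditions: starvation baselines 2.06 (H)
    and 1.99 (D), a +0.7 cell increase after refeeding on familiar food and
    +0.1 on novel food, three independent experiments of 25 animals per
    condition.
    """

    n_experiments: int = 3
    n_animals: int = 25
    expected_counts: dict = field(
        default_factory=lambda: {
            "H": 2.06,
            "D": 1.99,
            "HH": 2.76,
            "DH": 2.09,
            "DD": 2.69,
            "HD": 2.16,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_experiments >= 1, "n_experiments", "must be >= 1")
        _require(self.n_animals >= 1, "n_animals", "must be >= 1")
        for cond, mu in self.expected_counts.items():
            if cond not in ("H", "D", "HH", "DH", "DD", "HD"):
                raise SimulationParameterError(f"expected_counts: unknown condition {cond!r}")
            _require(0.0 <= mu <= 3.0, f"expected_counts[{cond}]", "must lie in [0, 3]")


def null_cellcount_design(seed: int = 0) -> CellCountDesign:
    """Same design but with the familiarity effect removed (all refed
    groups get the novel-food increase)."""
    d = CellCountDesign(seed=seed)
    ec = dict(d.expected_counts)
    ec["HH"] = ec["H"] + 0.1
    ec["DD"] = ec["D"] + 0.1
    ec["DH"] = ec["D"] + 0.1
    ec["HD"] = ec["H"] + 0.1
    return replace(d, expected_counts=ec)


def gen_cellcount_dataset(design: CellCountDesign) -> "pd.DataFrame":
    """Generate per-animal serotonin-positive cell counts.

    Returns a tidy DataFrame with columns ``animal_id, condition,
    experiment, count`` where ``count`` is an integer in {0, 1, 2, 3}.
    """
    import pandas as pd

    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    aid = 0
    for exp in range(1, design.n_experiments + 1):
        for cond, mu in design.expected_counts.items():
            counts = rng.binomial(3, mu / 3.0, design.n_animals)
            for c in counts:
                rows.append(
                    {
                        "animal_id": f"c{aid:04d}",
                        "condition": cond,
                        "experiment": exp,
                        "count": int(c),
                    }
                )
                aid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TIFF rendering for the ROI-extraction path


def render_tiff_stack(
    rec: TwoChannelRecording,
    path,
    shape: tuple[int, int] = (64, 64),
    center: tuple[int, int] = (32, 32),
    spot_sigma: float = 3.0,
    roi_radius: float = 10.0,
) -> None:
    """Render a recording as a 2-channel multi-frame TIFF.

    The neuron is a Gaussian spot on a uniform background.  Per frame and
    channel the spot is scaled so that the mean over the disc of radius
    ``roi_radius`` equals the recording's ROI intensity, and the uniform
    background equals the recording's background intensity; extracting the
    trace with the same geometry therefore recovers the embedded
    intensities up to the Gaussian tail that leaks outside the disc
    (< 1 % for ``spot_sigma <= roi_radius / 3``).

    The stack is written as float32 with axes (frame, channel, y, x),
    channel 0 = cyan (480 nm), channel 1 = yellow (535 nm).
    """
    import tifffile

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    spot = np.exp(-d2 / (2.0 * spot_sigma**2))
    disc = d2 <= roi_radius**2
    spot_disc_mean = spot[disc].mean()

    frames = np.empty((len(rec.time_s), 2, h, w), dtype=np.float32)
    for ch, (sig, bg) in enumerate(
        [(rec.i_480, rec.bg_480), (rec.i_535, rec.bg_535)]
    ):
        # ROI mean = bg + scale * spot_disc_mean  ==>  scale
        scale = (sig - bg) / spot_disc_mean
        frames[:, ch] = bg[:, None, None] + scale[:, None, None] * spot[None, :, :]
    tifffile.imwrite(path, frames)
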