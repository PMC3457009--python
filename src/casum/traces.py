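"""Fluorescence time series: synthesis, ΔF/F extraction, paired pulses.

The peak ΔF/F readout is defined on a raw fluorescence trace as

    ΔF/F = (F_peak - F_baseline) / F_baseline

with ``F_baseline`` the mean fluorescence over the 500 ms window ending
at stimulus onset and ``F_peak`` the maximum over the 100 ms window
after onset.  Windows are half-open on the left: baseline covers
``(onset - 0.5 s, onset]`` and the peak window ``(onset, onset + 0.1 s]``.

Also here: the area under the ΔF/F curve in the post-stimulus window,
the paired-pulse facilitation ratio (second response measured after
subtracting the extrapolated single-exponential decay of the first),
and counting overlapping neurons from a depth-intensity profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

BASELINE_WINDOW_S = 0.5
PEAK_WINDOW_S = 0.1
DEFAULT_SINGLE_NEURON_WIDTH_UM = 30.0


@dataclass(frozen=True)
class FluorescenceTrace:
    """A sampled fluorescence series with a known stimulus onset."""

    samples: np.ndarray
    sampling_rate: float  # samples / s
    stim_onset: float     # s from trace start

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stim_onset < BASELINE_WINDOW_S:
            raise ValueError(
                f"stim_onset {self.stim_onset} s leaves no room for the "
                f"{BASELINE_WINDOW_S * 1e3:.0f} ms baseline window"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sampling_hz\t{self.sampling_rate}\n")
            fh.write(f"# stim_onset_s\t{self.stim_onset}\n")
            fh.write("time_s\tfluorescence\n")
            for t, f in zip(self.times, self.samples):
                fh.write(f"{t:.6f}\t{f:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FluorescenceTrace":
        meta: dict[str, float] = {}
        samples = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("\t")
                    meta[key.strip()] = float(val)
                elif not line.startswith("time_s"):
                    samples.append(float(line.split("\t")[1]))
        if "sampling_hz" not in meta or "stim_onset_s" not in meta:
            raise ValueError(f"{path}: missing sampling_hz / stim_onset_s header lines")
        return cls(
            samples=np.asarray(samples),
            sampling_rate=meta["sampling_hz"],
            stim_onset=meta["stim_onset_s"],
        )


def _window_indices(trace: FluorescenceTrace, start_s: float, end_s: float) -> np.ndarray:
    """Sample indices with start_s < t <= end_s (half-open on the left)."""
    t = trace.times
    return np.nonzero((t > start_s + 1e-12) & (t <= end_s + 1e-12))[0]


def _baseline(trace: FluorescenceTrace, onset: float) -> float:
    idx = _window_indices(trace, onset - BASELINE_WINDOW_S, onset)
    if len(idx) == 0:
        raise ValueError("no samples in the baseline window")
    fb = float(trace.samples[idx].mean())
    if fb <= 0:
        raise ValueError(f"baseline fluorescence {fb} is not positive")
    return fb


def compute_dff(trace: FluorescenceTrace) -> float:
    """Peak ΔF/F: (max over 100 ms post-onset - baseline) / baseline.

    Negative values are possible on noisy traces and are returned as-is;
    thresholding sub-detection responses to zero is downstream policy.
    """
    onset = trace.stim_onset
    peak_idx = _window_indices(trace, onset, onset + PEAK_WINDOW_S)
    if len(peak_idx) == 0:
        raise ValueError("no samples in the 100 ms post-stimulus window")
    fb = _baseline(trace, onset)
    fp = float(trace.samples[peak_idx].max())
    return (fp - fb) / fb


def compute_area(trace: FluorescenceTrace) -> float:
    """Trapezoidal area of ΔF/F over the 100 ms post-stimulus window (ΔF/F·s)."""
    onset = trace.stim_onset
    idx = _window_indices(trace, onset, onset + PEAK_WINDOW_S)
    if len(idx) < 2:
        raise ValueError("need at least two samples in the post-stimulus window")
    fb = _baseline(trace, onset)
    dff = (trace.samples[idx] - fb) / fb
    return float(np.trapezoid(dff, trace.times[idx]))


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceConfig:
    """Synthetic transient settings.

    The sampling rate default matches an EMCCD camera acquiring at
    122 Hz; the decay constant is a typical somatic calcium-indicator
    decay.  Baseline fluorescence is in camera units (arbitrary).
    """

    sampling_rate: float = 122.0
    baseline_level: float = 100.0
    baseline_duration: float = 1.0   # s of pre-stimulus baseline, >= 0.5
    post_duration: float = 1.0       # s after stimulus onset
    decay_tau: float = 0.4           # s, exponential decay of the transient
    noise_sd: float = 0.0            # white noise SD, camera units

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.baseline_duration < BASELINE_WINDOW_S:
            raise ValueError(
                f"baseline_duration must be >= {BASELINE_WINDOW_S} s for the ΔF/F window"
            )


def simulate_trace(
    peak: float,
    config: TraceConfig = TraceConfig(),
    seed: int | np.random.Generator = 0,
    extra_transients: list[tuple[float, float]] | None = None,
) -> FluorescenceTrace:
    """Noisy baseline plus a stimulus-locked exponential transient.

    The transient rises in a single sample to ``baseline * (1 + peak)``
    at the first sample after onset and decays exponentially, so
    running :func:`compute_dff` on a noise-free trace recovers ``peak``
    up to one sample of decay.  ``extra_transients`` adds further
    (onset_s, peak) events, e.g. for paired-pulse protocols.
    """
    cfg = config
    n = int(round((cfg.baseline_duration + cfg.post_duration) * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    onset = cfg.baseline_duration
    f = np.full(n, cfg.baseline_level, dtype=float)
    events = [(onset, peak)] + list(extra_transients or [])
    for ev_onset, ev_peak in events:
        rising = t > ev_onset + 1e-12
        dt = t[rising] - ev_onset
        f[rising] += cfg.baseline_level * ev_peak * np.exp(-dt / cfg.decay_tau)
    if cfg.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
            np.random.SeedSequence(seed)
        )
        f = f + rng.normal(0.0, cfg.noise_sd, size=n)
    return FluorescenceTrace(samples=f, sampling_rate=cfg.sampling_rate, stim_onset=onset)


# ---------------------------------------------------------------------------
# Paired-pulse facilitation
# ---------------------------------------------------------------------------


def paired_pulse_ratio(
    trace: FluorescenceTrace,
    onset1: float,
    onset2: float,
    decay_fit_window: float | None = None,
) -> float:
    """Facilitation ratio of a two-pulse protocol.

    Fits a single-exponential decay to the first response between its
    peak and the second onset, extrapolates it beyond ``onset2``,
    subtracts it from the trace, and returns the residual second peak
    ΔF/F divided by the first peak ΔF/F.  A ratio near 1 means the
    second pulse recruited an independent response (the cross-electrode
    expectation); same-electrode stimulation typically facilitates.
    """
    if onset2 <= onset1:
        raise ValueError("onset2 must be after onset1")
    fb = _baseline(trace, onset1)
    t = trace.times
    f = trace.samples

    idx1 = _window_indices(trace, onset1, onset1 + PEAK_WINDOW_S)
    idx1 = idx1[t[idx1] <= onset2]
    if len(idx1) == 0:
        raise ValueError("no samples between the two onsets")
    p1_i = idx1[np.argmax(f[idx1])]
    peak1 = (f[p1_i] - fb) / fb
    if peak1 <= 0:
        raise ValueError(f"first peak ΔF/F {peak1:.4f} is not positive")

    fit_end = onset2 if decay_fit_window is None else min(onset2, t[p1_i] + decay_fit_window)
    fit_idx = np.nonzero((t >= t[p1_i]) & (t <= fit_end + 1e-12))[0]
    if len(fit_idx) < 3:
        raise ValueError("too few samples between first peak and second onset to fit decay")
    dff = (f - fb) / fb

    def model(tt, amp, tau):
        return amp * np.exp(-(tt - t[p1_i]) / tau)

    try:
        popt, _ = curve_fit(
            model,
            t[fit_idx],
            dff[fit_idx],
            p0=(peak1, 0.3),
            bounds=([0.0, 1e-3], [np.inf, 10.0]),
            maxfev=2000,
        )
    except RuntimeError as exc:
        raise ValueError(f"decay fit failed: {exc}") from exc

    idx2 = _window_indices(trace, onset2, onset2 + PEAK_WINDOW_S)
    if len(idx2) == 0:
        raise ValueError("no samples in the second-pulse window")
    residual = dff[idx2] - model(t[idx2], *popt)
    peak2 = float(residual.max())
    return peak2 / peak1


# ---------------------------------------------------------------------------
# Overlap counting on depth-intensity profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity along imaging depth for one ROI of a z-stack."""

    depth_um: np.ndarray
    intensity: np.ndarray
    imaged_depth_um: float
    healthy_depth_um: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_um", np.asarray(self.depth_um, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if len(self.depth_um) != len(self.intensity):
            raise ValueError("depth and intensity must have equal lengths")
        if len(self.depth_um) and np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth positions must be strictly increasing")

    @classmethod
    def from_tsv(
        cls, path: str | Path, imaged_depth_um: float, healthy_depth_um: float
    ) -> "IntensityProfile":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(
            depth_um=data[:, 0],
            intensity=data[:, 1],
            imaged_depth_um=imaged_depth_um,
            healthy_depth_um=healthy_depth_um,
        )


def count_overlapping_neurons(
    profile: IntensityProfile,
    single_width_um: float = DEFAULT_SINGLE_NEURON_WIDTH_UM,
    prominence: float = 0.2,
) -> tuple[int, float]:
    """Estimate overlapping neurons from a depth-intensity profile.

    Within each contiguous bright region (intensity above ``prominence``
    x the profile maximum), the neuron count is the larger of the number
    of prominent local maxima and ``ceil(width / single_width_um)`` —
    a region narrower than one soma diameter counts as a single neuron
    however it is shaped.  The scaled count extrapolates to the healthy
    slice depth, ``count * healthy_depth_um / imaged_depth_um``.

    Returns ``(count, scaled_count)``; a flat profile gives ``(0, 0.0)``.
    """
    inten = profile.intensity
    if len(inten) == 0 or inten.max() <= 0 or np.ptp(inten) == 0:
        return 0, 0.0
    level = prominence * float(inten.max())
    above = inten > level
    # contiguous above-threshold regions
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    total = 0
    abs_prominence = prominence * float(inten.max())
    for s, e in zip(starts, ends):
        width = profile.depth_um[e - 1] - profile.depth_um[s]
        peaks, _ = find_peaks(inten[s:e], prominence=abs_prominence)
        n_peaks = max(len(peaks), 1)  # a plateau region is at least one neuron
        n_width = max(1, math.ceil(width / single_width_um)) if width > 0 else 1
        total += max(n_peaks, n_width)
    scaled = total * profile.healthy_depth_um / profile.imaged_depth_um
    return total, scaled
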