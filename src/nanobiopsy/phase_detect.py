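"""Detection of nanoinjection subphases and extraction signatures.

The injection quality control rests on three subphases visible in the
aqueous-barrel current: the hopping stop (current falls to the 99.5% set
point), the membrane touch (a ~2% step drop during the stepped descent)
and the vibrational noise picked up close to the coverslip.  A successful
membrane penetration shows all three, in that order; the band power of
the vibrational component relative to the quiet descent serves as the
spectral quality-control feature.

For the organic barrel, the extraction signature is the increase in hold
current magnitude after the electrowetting pulse, Delta-i_org, measured
as the difference of the medians of the two hold segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfilt, welch

from .sicm_model import InvalidParameterError
from .trace_sim import TraceChannel

__all__ = [
    "DetectionParams",
    "PhaseAnnotation",
    "QCResult",
    "ExtractionMeasurement",
    "PatternError",
    "estimate_baseline",
    "detect_phases",
    "welch_psd",
    "qc_classify",
    "measure_delta_i",
]


class PatternError(ValueError):
    """The trace does not contain the expected bias pattern."""


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the subphase detectors.

    ``touch_fraction`` sits midway between the baseline (1.0) and the
    expected ~2% touch drop (0.98) so the decision is not taken exactly at
    the post-drop level.  ``contact_floor`` of None means 3x the estimated
    white-noise standard deviation.  'Sustained' crossings must hold for
    ``sustain`` consecutive samples (1 ms at 10 kHz) to reject spikes.
    """

    setpoint_fraction: float = 0.995
    touch_fraction: float = 0.985
    vib_band: tuple = (50.0, 500.0)
    vib_ratio_threshold: float = 8.0
    contact_floor: Optional[float] = None
    baseline_window: float = 0.05
    sustain: int = 10
    smooth: int = 11


@dataclass
class PhaseAnnotation:
    """Detected subphase sample indices (None = not detected)."""

    hop_stop: Optional[int] = None
    membrane_touch: Optional[int] = None
    vibration_onset: Optional[int] = None
    substrate_contact: Optional[int] = None
    retraction: Optional[int] = None
    band_power_ratio: Optional[float] = None

    _ORDER = ("hop_stop", "membrane_touch", "vibration_onset", "substrate_contact", "retraction")

    def present(self) -> dict:
        return {k: getattr(self, k) for k in self._ORDER if getattr(self, k) is not None}

    def ordered(self) -> bool:
        vals = list(self.present().values())
        return all(b > a for a, b in zip(vals, vals[1:]))


@dataclass
class QCResult:
    """Injection success verdict: success iff hopping stop, membrane touch
    and vibration onset are all detected, in order."""

    success: bool
    reasons: list = field(default_factory=list)
    band_power_ratio: Optional[float] = None


@dataclass
class ExtractionMeasurement:
    """Hold-current medians around the electrowetting pulse (A)."""

    pre_hold: float
    post_hold: float
    delta_i: float
    hold_bias: Optional[float] = None


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _first_sustained(mask: np.ndarray, sustain: int) -> Optional[int]:
    """Index of the first run of ``sustain`` consecutive True values."""
    if len(mask) < sustain:
        return None
    counts = np.convolve(mask.astype(float), np.ones(sustain), mode="valid")
    hits = np.nonzero(counts >= sustain - 0.5)[0]
    return int(hits[0]) if len(hits) else None


def _constant_runs(x: np.ndarray, atol: float = 0.0) -> list:
    """Contiguous runs of (approximately) constant value: [(start, stop, value)]."""
    if len(x) == 0:
        return []
    change = np.nonzero(np.abs(np.diff(x)) > atol)[0] + 1
    bounds = np.concatenate([[0], change, [len(x)]])
    return [(int(a), int(b), float(x[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def estimate_baseline(trace: TraceChannel, window: float = 0.05) -> float:
    """Median current over the first ``window`` seconds at constant bias."""
    n_win = int(round(window * trace.sample_rate))
    if n_win < 1 or n_win > trace.n_samples:
        raise InvalidParameterError("baseline window must be shorter than the trace")
    seg_bias = trace.bias[:n_win]
    if np.ptp(seg_bias) > 0:
        raise InvalidParameterError("bias is not constant within the baseline window")
    return float(np.median(trace.current[:n_win]))


def _noise_sd(current: np.ndarray) -> float:
    """Robust white-noise sd from first differences (MAD-based)."""
    diffs = np.diff(current)
    if len(diffs) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)


def _detect_touch(
    mag: np.ndarray,
    position: Optional[np.ndarray],
    start: int,
    stop: int,
    params: DetectionParams,
) -> Optional[int]:
    """Step-aligned drop below touch_fraction x previous-dwell median."""
    if stop - start < 2 * params.sustain:
        return None
    if position is not None:
        seg = position[start:stop]
        dwells = [(a, b, v) for a, b, v in _constant_runs(seg) if b - a >= 2 * params.sustain]
        for prev, cur in zip(dwells[:-1], dwells[1:]):
            if cur[2] >= prev[2]:
                continue  # only descending steps
            base = float(np.median(mag[start + prev[0]:start + prev[1]]))
            level = float(np.median(mag[start + cur[0]:start + cur[1]]))
            if level < params.touch_fraction * base:
                window = mag[start + prev[1]:start + cur[1]]
                below = np.nonzero(window < params.touch_fraction * base)[0]
                if len(below):
                    return start + prev[1] + int(below[0])
                return start + cur[0]
        return None
    # no position channel: trailing-window local baseline
    lag = 20 * params.sustain
    for i in range(start + lag, stop - params.sustain):
        base = float(np.median(mag[i - lag:i]))
        if np.all(mag[i:i + params.sustain] < params.touch_fraction * base):
            return i
    return None


def _contrast_argmax(x: np.ndarray, lo: int, hi: int) -> Optional[int]:
    """L2 change-point: split of x[lo:hi] maximising t(n-t)(mean_l-mean_r)^2.

    Means are taken over the window only, so the estimate is local; returns
    the absolute split index (first sample of the right segment).
    """
    seg = x[lo:hi]
    n = len(seg)
    if n < 8:
        return None
    csum = np.cumsum(seg)
    total = csum[-1]
    t = np.arange(1, n)
    mean_l = csum[:-1] / t
    mean_r = (total - csum[:-1]) / (n - t)
    contrast = t * (n - t) * (mean_l - mean_r) ** 2
    return lo + int(np.argmax(contrast)) + 1


def _detect_vibration(
    current: np.ndarray,
    sample_rate: float,
    start: int,
    stop: int,
    params: DetectionParams,
) -> tuple:
    """Onset of band-limited excess power; returns (index or None, ratio)."""
    seg = current[start:stop]
    n = len(seg)
    if n < 40 * params.sustain:
        return None, None
    # causal IIR bandpass: no energy leaks backwards across the onset, so
    # the in-band power stays at the quiet floor until the true onset and
    # the known filter latency can be subtracted afterwards
    sos = butter(3, params.vib_band, btype="bandpass", fs=sample_rate, output="sos")
    bp = sosfilt(sos, seg - seg.mean())
    # drop the leading margin entirely: it may hold the bandpass transient
    # of the membrane-touch step, which would contaminate the means
    margin = min(300, n // 4)
    x = (bp * bp)[margin:]
    m = len(x)
    guard = min(100, m // 4)
    if m < 4 * guard or m < 4 * params.sustain:
        return None, None
    cp = _contrast_argmax(x, guard, m - guard)
    if cp is None:
        return None, None
    power_pre = float(np.mean(x[:cp]))
    power_post = float(np.mean(x[cp:]))
    if power_post <= 0:
        return None, None
    ratio = power_post / power_pre if power_pre > 0 else np.inf
    if ratio < params.vib_ratio_threshold:
        return None, ratio
    # the L2 change point fixes presence and the two power levels, but its
    # location is loose when the vibration occupies a short tail of the
    # region; with the levels known, the maximum-likelihood change point
    # for exponentially distributed instantaneous power is sharp:
    # onset = argmax_t sum_{i>=t} [x_i (1/p0 - 1/p1) - ln(p1/p0)]
    # the per-sample penalty is scaled with the decorrelation time of the
    # in-band power: the effective inclusion threshold must sit well above
    # the quiet-power tail (to resist early pulls from correlated noise
    # excursions) yet below typical in-band power lulls (to resist late
    # pushes), which a quarter of the decorrelation length achieves
    p0 = max(power_pre, power_post * 1e-9)
    p1 = power_post
    corr_len = max(1.0, sample_rate / (8.0 * (params.vib_band[1] - params.vib_band[0])))
    w = x * (1.0 / p0 - 1.0 / p1) - corr_len * np.log(p1 / p0)
    tail = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    coarse = int(np.argmax(tail))
    # refine to the first 'hot' sample near the coarse onset: vibration
    # power is far above the quiet floor from its very first sample, while
    # quiet-floor excursions above 15x the floor are ~1e-4 per sample
    lo, hi = max(coarse - 60, 0), min(coarse + 80, m)
    hot = np.nonzero(x[lo:hi] > 15.0 * p0)[0]
    onset = lo + int(hot[0]) if len(hot) else coarse
    # subtract the causal filter's energy-rise latency (10% point of the
    # cumulative impulse-response energy)
    imp = np.zeros(512)
    imp[0] = 1.0
    h2 = sosfilt(sos, imp) ** 2
    cum = np.cumsum(h2) / h2.sum()
    latency = int(np.searchsorted(cum, 0.10))
    onset = max(onset - latency, 0)
    return start + margin + onset, ratio


def detect_phases(trace: TraceChannel, params: DetectionParams = DetectionParams()) -> PhaseAnnotation:
    """Detect the injection subphases in an aqueous-barrel trace.

    Absent subphases are reported as None, never raised; present indices
    are guaranteed strictly increasing by construction (each detector
    searches after the previous subphase's region).
    """
    ann = PhaseAnnotation()
    n = trace.n_samples
    mag = np.abs(trace.current)
    smooth_mag = _moving_average(mag, params.smooth)

    # approach segment = leading run of the initial bias
    bias_runs = _constant_runs(trace.bias)
    approach_stop = bias_runs[0][1]
    n_win = min(int(round(params.baseline_window * trace.sample_rate)), approach_stop)
    if n_win < 2:
        return ann
    baseline = float(np.median(mag[:n_win]))
    sd = _noise_sd(trace.current[:n_win])

    # the feedback halts (and retracts) the moment the set point is hit,
    # so the crossing cannot persist; it is detected on a heavily smoothed
    # magnitude (the approach slope near the set point is shallow, so wide
    # smoothing buys noise rejection without biasing the crossing)
    approach_smooth = _moving_average(mag[:approach_stop], 5 * params.smooth - 4)
    below = np.nonzero(approach_smooth < params.setpoint_fraction * baseline)[0]
    if len(below):
        ann.hop_stop = int(below[0])

    if approach_stop >= n:  # truncated before the descent
        return ann
    descent_start = approach_stop

    floor = params.contact_floor if params.contact_floor is not None else 3.0 * sd
    contact = _first_sustained(mag[descent_start:] <= floor, params.sustain)
    if contact is not None:
        contact += descent_start
        ann.substrate_contact = contact
        rise = _first_sustained(mag[contact:] > floor, params.sustain)
        if rise is not None:
            ann.retraction = contact + rise
    pre_contact_stop = contact if contact is not None else n

    ann.membrane_touch = _detect_touch(mag, trace.position, descent_start, pre_contact_stop, params)

    vib_start = ann.membrane_touch if ann.membrane_touch is not None else descent_start
    # back the vibration region off the contact point so the bandpass
    # transient of the current collapsing to zero stays outside it
    vib_stop = pre_contact_stop - (150 if contact is not None else 0)
    vib_idx, ratio = _detect_vibration(
        trace.current, trace.sample_rate, vib_start, vib_stop, params
    )
    ann.band_power_ratio = ratio
    if vib_idx is not None and (ann.membrane_touch is None or vib_idx > ann.membrane_touch):
        ann.vibration_onset = vib_idx
    return ann


def welch_psd(
    segment: np.ndarray,
    sample_rate: float,
    window_len: int = 256,
    overlap: float = 0.5,
) -> tuple:
    """Averaged-periodogram power spectral density (A^2/Hz)."""
    segment = np.asarray(segment, dtype=float)
    if len(segment) < window_len:
        raise InvalidParameterError(
            f"segment of {len(segment)} samples shorter than window_len={window_len}"
        )
    freqs, power = welch(
        segment, fs=sample_rate, nperseg=window_len, noverlap=int(window_len * overlap)
    )
    return freqs, power


def qc_classify(annotation: PhaseAnnotation, band_power_ratio: Optional[float] = None) -> QCResult:
    """Injection success verdict from the detected subphases."""
    reasons = []
    for name in ("hop_stop", "membrane_touch", "vibration_onset"):
        if getattr(annotation, name) is None:
            reasons.append(f"{name} missing")
    if not reasons and not annotation.ordered():
        reasons.append("subphases mis-ordered")
    ratio = band_power_ratio if band_power_ratio is not None else annotation.band_power_ratio
    return QCResult(success=not reasons, reasons=reasons, band_power_ratio=ratio)


def measure_delta_i(trace_org: TraceChannel, settle_margin: float = 0.5) -> ExtractionMeasurement:
    """Delta-i_org from an organic-barrel hold/extract/hold trace.

    The pre- and post-extraction hold currents are medians of the two
    constant-bias hold segments, excluding ``settle_margin`` seconds at the
    start of each segment; ``delta_i = |post| - |pre|``.
    """
    runs = _constant_runs(trace_org.bias)
    if len(runs) != 3 or runs[0][2] != runs[2][2] or runs[0][2] == runs[1][2]:
        raise PatternError(
            "expected a hold -> extract -> hold bias pattern "
            f"(found {len(runs)} constant-bias segments)"
        )
    margin = int(round(settle_margin * trace_org.sample_rate))
    pre_a, pre_b, hold_bias = runs[0]
    post_a, post_b, _ = runs[2]
    if pre_b - pre_a <= margin or post_b - post_a <= margin:
        raise PatternError("hold segments shorter than the settling margin")
    pre = float(np.median(trace_org.current[pre_a + margin:pre_b]))
    post = float(np.median(trace_org.current[post_a + margin:post_b]))
    return ExtractionMeasurement(
        pre_hold=pre,
        post_hold=post,
        delta_i=abs(post) - abs(pre),
        hold_bias=hold_bias,
    )
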