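"""R-peak detection and heartbeat segmentation.

The detector follows the Hamilton QRS-detection recipe: bandpass the signal
to the QRS energy band (8–16 Hz), differentiate, rectify, smooth with an
80 ms moving average, then pick peaks of the resulting envelope against an
adaptive threshold that tracks running QRS-peak and noise-peak estimates,
with a 200 ms refractory period and a half-threshold search-back for long RR
gaps.  Detections are finally refined to the local maximum of the original
signal within ±40 ms.

Beats are cut as windows starting 240 ms before and ending 400 ms after each
R peak (82 samples at 128 Hz) and z-scored per segment (population standard
deviation), giving mean 0 and unit spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Stage settings of the envelope detector (Hamilton-style defaults)."""

    band: tuple[float, float] = (8.0, 16.0)
    ma_window_s: float = 0.080
    refractory_s: float = 0.200
    threshold_coeff: float = 0.3125  # position between noise and QRS estimates
    peak_memory: int = 8  # running-mean length for peak/noise estimates
    searchback_factor: float = 1.5  # RR gap (x mean RR) triggering search-back
    refine_window_s: float = 0.040


@dataclass
class RPeakSet:
    indices: np.ndarray
    fs: float
    detector_params: DetectorParams = field(default_factory=DetectorParams)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")
        self.indices = idx


@dataclass
class HeartbeatSegment:
    """Fixed-length beat window around an R peak."""

    samples: np.ndarray
    fs: float
    r_offset: int  # samples from window start to the R peak
    label: str | None = None
    mu: float = 0.0  # mean removed by z-scoring (mV)
    sigma: float = 1.0  # scale removed by z-scoring (mV)


def _envelope(x: np.ndarray, fs: float, p: DetectorParams) -> np.ndarray:
    sos = sps.butter(2, list(p.band), btype="band", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, x)
    d = np.abs(np.diff(f, prepend=f[0]))
    w = max(int(round(p.ma_window_s * fs)), 1)
    return np.convolve(d, np.ones(w) / w, mode="same")


def detect_rpeaks(x: np.ndarray, fs: float, params: DetectorParams = DetectorParams()) -> RPeakSet:
    """Detect R peaks with an adaptive-threshold envelope detector."""
    x = np.asarray(x, dtype=float)
    if fs < 64:
        raise ValueError("fs too low for QRS detection (< 64 Hz)")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    env = _envelope(x, fs, params)
    if np.max(env) <= 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs, detector_params=params)

    refractory = int(round(params.refractory_s * fs))
    floor = 0.1 * float(np.max(env))  # reject filter ringing on sparse signals
    cand, _ = sps.find_peaks(env, distance=max(refractory, 1), height=floor)
    if cand.size == 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs, detector_params=params)

    # adaptive threshold: running means of accepted QRS peaks and noise peaks
    init = env[: int(2 * fs)]
    qrs_hist = [float(np.max(init))]
    noise_hist = [float(np.mean(init))]
    accepted: list[int] = []
    thr_at_cand: list[float] = []
    for c in cand:
        spk = float(np.mean(qrs_hist[-params.peak_memory:]))
        npk = float(np.mean(noise_hist[-params.peak_memory:]))
        thr = npk + params.threshold_coeff * (spk - npk)
        thr_at_cand.append(thr)
        if env[c] > thr:
            accepted.append(int(c))
            qrs_hist.append(float(env[c]))
        else:
            noise_hist.append(float(env[c]))

    # search-back: revisit long RR gaps at half threshold
    if len(accepted) >= 2:
        rr = np.diff(accepted)
        mean_rr = float(np.mean(rr))
        extra: list[int] = []
        half_thr = 0.5 * float(np.median(thr_at_cand))
        for a, b, gap in zip(accepted[:-1], accepted[1:], rr):
            if gap > params.searchback_factor * mean_rr:
                inside = cand[(cand > a + refractory) & (cand < b - refractory)]
                for c in inside:
                    if env[c] > half_thr:
                        extra.append(int(c))
        accepted = sorted(set(accepted) | set(extra))

    # refine to the local maximum of the original signal within +-40 ms
    half = int(round(params.refine_window_s * fs))
    refined = []
    for c in accepted:
        lo, hi = max(c - half, 0), min(c + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    if refined.size:
        keep = np.concatenate([[True], np.diff(refined) >= refractory])
        refined = refined[keep]
    return RPeakSet(indices=refined, fs=fs, detector_params=params)


def segment_beats(
    x: np.ndarray,
    fs: float,
    rpeaks: RPeakSet | np.ndarray,
    pre_s: float = 0.240,
    post_s: float = 0.400,
    label: str | None = None,
) -> list[HeartbeatSegment]:
    """Cut [r - round(pre_s*fs), r + round(post_s*fs)) windows around R peaks.

    Beats whose window crosses the record boundary are dropped (and counted
    in a log line) rather than padded.
    """
    x = np.asarray(x, dtype=float)
    idx = rpeaks.indices if isinstance(rpeaks, RPeakSet) else np.asarray(rpeaks, dtype=int)
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    out: list[HeartbeatSegment] = []
    dropped = 0
    for r in idx:
        lo, hi = r - pre, r + post
        if lo < 0 or hi > len(x):
            dropped += 1
            continue
        out.append(HeartbeatSegment(samples=x[lo:hi].copy(), fs=fs, r_offset=pre, label=label))
    if dropped:
        logger.info("segment_beats: dropped %d boundary beats of %d", dropped, len(idx))
    return out


def zscore(segment: HeartbeatSegment) -> HeartbeatSegment:
    """Standardize a beat window to mean 0, population SD 1 (stored on it)."""
    s = np.asarray(segment.samples, dtype=float)
    mu = float(np.mean(s))
    sigma = float(np.std(s))  # population (N-denominator) convention
    if sigma == 0:
        raise ZeroDivisionError("degenerate beat: zero-variance segment cannot be z-scored")
    return HeartbeatSegment(
        samples=(s - mu) / sigma,
        fs=segment.fs,
        r_offset=segment.r_offset,
        label=segment.label,
        mu=mu,
        sigma=sigma,
    )
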