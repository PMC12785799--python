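"""CWT/SIFT feature images: the heartbeat-to-image representation.

A z-scored heartbeat becomes a 128x128x3 image:

* channel 1 — Mexican Hat CWT scalogram (scales 1..64), min-max normalized
  and bilinearly resized;
* channel 2 — Morlet CWT scalogram, same treatment;
* channel 3 — a keypoint-density map: a difference-of-Gaussians SIFT
  detector runs over the grayscale Morlet scalogram, each keypoint
  increments one cell of a 5x128 histogram, which is blurred with a 3x3
  Gaussian, min-max normalized and nearest-neighbor upsampled to 128x128.

The CWT is computed as a direct convolution of the signal with the sampled,
scaled mother wavelet, ``coef(s, u) = 1/sqrt(s) * sum_t x[t] psi((t-u)/s)``,
under symmetric boundary extension; the scalogram pixel is the coefficient
magnitude (the squared modulus is available by flag).  The SIFT stages are
the classical ones: incremental Gaussian scale space, DoG extrema over a
26-neighborhood, iterative quadratic (Taylor) refinement, contrast and
edge-ratio rejection, and gradient-histogram orientation assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from skimage.transform import resize as _skimage_resize

DEFAULT_SCALES = np.arange(1, 65)

#: Channel roles in storage order.
CHANNEL_ROLES = ("mexh-scalogram", "morl-scalogram", "sift-density")


# ---------------------------------------------------------------------------
# Continuous wavelet transform
# ---------------------------------------------------------------------------


@dataclass
class ScalogramImage:
    matrix: np.ndarray  # (n_scales, n_samples) nonnegative magnitudes
    wavelet_name: str
    scales: np.ndarray
    source_length: int


@lru_cache(maxsize=8)
def _wavelet_table(name: str) -> tuple[np.ndarray, np.ndarray, float]:
    wav = pywt.ContinuousWavelet(name)
    psi, grid = wav.wavefun(level=12)
    return np.asarray(psi, dtype=float), np.asarray(grid, dtype=float), float(wav.upper_bound)


def sampled_wavelet(name: str, scale: float) -> np.ndarray:
    """psi(n/s)/sqrt(s) on the integer grid covering the wavelet support."""
    psi, grid, ub = _wavelet_table(name)
    half = int(np.ceil(scale * ub))
    n = np.arange(-half, half + 1)
    return np.interp(n / scale, grid, psi, left=0.0, right=0.0) / np.sqrt(scale)


def cwt_scalogram(
    segment: np.ndarray,
    wavelet_name: str,
    scales: np.ndarray = DEFAULT_SCALES,
    squared: bool = False,
) -> ScalogramImage:
    """|CWT| magnitudes for every scale at every sample position.

    Boundary handling is symmetric extension; interior columns therefore
    agree with an infinite-signal convolution of the extended sequence.
    """
    if wavelet_name not in ("morl", "mexh"):
        raise ValueError(f"unknown wavelet {wavelet_name!r} (use 'morl' or 'mexh')")
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("segment must be 1-D with length >= 8")
    rows = []
    for s in scales:
        w = sampled_wavelet(wavelet_name, float(s))
        half = (len(w) - 1) // 2
        xp = np.pad(x, half, mode="symmetric")
        # correlation: coef[u] = sum_m x[u+m-half] w[m]
        coef = fftconvolve(xp, w[::-1], mode="valid")
        rows.append(coef)
    m = np.abs(np.asarray(rows))
    if squared:
        m = m**2
    return ScalogramImage(matrix=m, wavelet_name=wavelet_name,
                          scales=np.asarray(scales), source_length=len(x))


# ---------------------------------------------------------------------------
# Image utilities
# ---------------------------------------------------------------------------


@dataclass
class GrayImage:
    matrix: np.ndarray  # H x W in [0, 255]
    provenance: str = ""


def minmax01(m: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant array maps to all zeros."""
    m = np.asarray(m, dtype=float)
    lo, hi = float(np.min(m)), float(np.max(m))
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def to_gray(scalogram: ScalogramImage | np.ndarray, provenance: str = "") -> GrayImage:
    m = scalogram.matrix if isinstance(scalogram, ScalogramImage) else np.asarray(scalogram)
    if not np.all(np.isfinite(m)):
        raise ValueError("scalogram contains non-finite values")
    return GrayImage(matrix=minmax01(m) * 255.0, provenance=provenance)


def resize_image(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize; a same-size call is the identity."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if out_h <= 0 or out_w <= 0:
        raise ValueError("target size must be positive")
    if img.shape == (out_h, out_w):
        return img.copy()
    return _skimage_resize(img, (out_h, out_w), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# SIFT detector (DoG scale-space extrema)
# ---------------------------------------------------------------------------


@dataclass
class ScaleSpace:
    octaves: list[np.ndarray]  # per octave: (n_levels, H, W) Gaussian stack
    dog: list[np.ndarray]  # per octave: (n_levels - 1, H, W)
    k: float
    sigma0: float
    intervals: int


@dataclass
class Keypoint:
    x: float  # column, base-image pixels
    y: float  # row
    sigma: float  # detected scale (base-image units)
    response: float  # refined |D|
    orientation: float = 0.0  # degrees


#: Assumed blur of the input image, per the classical detector.
_INIT_SIGMA = 0.5


def build_scale_space(
    gray: GrayImage | np.ndarray,
    sigma0: float = 1.6,
    intervals: int = 3,
    octaves: int | None = None,
) -> ScaleSpace:
    """Incremental Gaussian pyramid plus DoG stacks.

    Each octave holds ``intervals + 3`` Gaussian levels with blur
    ``sigma0 * k**i`` (k = 2^(1/intervals)); the DoG stack is the difference
    of adjacent levels.  Spatial size halves per octave; no initial
    upsampling is applied (input images here are small).
    """
    img = gray.matrix if isinstance(gray, GrayImage) else np.asarray(gray, dtype=float)
    img = img / 255.0  # detector thresholds assume intensities in [0, 1]
    if min(img.shape) < 8:
        raise ValueError("image too small for a scale space (min dim < 8)")
    k = 2.0 ** (1.0 / intervals)
    n_levels = intervals + 3
    if octaves is None:
        octaves = 0
        h, w = img.shape
        while min(h, w) >= 8:
            octaves += 1
            h, w = h // 2, w // 2

    base = gaussian_filter(img, max(np.sqrt(max(sigma0**2 - _INIT_SIGMA**2, 0.0)), 1e-8))
    gauss_stacks, dog_stacks = [], []
    for _ in range(octaves):
        levels = [base]
        for i in range(1, n_levels):
            sig_prev = sigma0 * k ** (i - 1)
            sig_diff = sig_prev * np.sqrt(k**2 - 1.0)
            levels.append(gaussian_filter(levels[-1], sig_diff))
        stack = np.asarray(levels)
        gauss_stacks.append(stack)
        dog_stacks.append(stack[1:] - stack[:-1])
        base = stack[intervals][::2, ::2]
    return ScaleSpace(octaves=gauss_stacks, dog=dog_stacks, k=k,
                      sigma0=sigma0, intervals=intervals)


def _is_extremum_mask(dog: np.ndarray) -> np.ndarray:
    """Strict 26-neighborhood extrema of a (L, H, W) DoG stack (interior)."""
    c = dog[1:-1, 1:-1, 1:-1]
    gt = np.ones_like(c, dtype=bool)
    lt = np.ones_like(c, dtype=bool)
    for dl in (-1, 0, 1):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dl == dr == dc == 0:
                    continue
                nb = dog[1 + dl : dog.shape[0] - 1 + dl,
                         1 + dr : dog.shape[1] - 1 + dr,
                         1 + dc : dog.shape[2] - 1 + dc]
                gt &= c > nb
                lt &= c < nb
    return gt | lt


def _refine(dog: np.ndarray, l: int, r: int, c: int, max_iter: int = 5):
    """Quadratic (Taylor) sub-voxel refinement; returns None on failure.

    An extremum straddling a voxel boundary (offset oscillating around
    +-0.5) is accepted on the final iteration with the offset clipped,
    rather than discarded.
    """
    L, H, W = dog.shape
    for it in range(max_iter):
        d = dog
        g = 0.5 * np.array([
            d[l + 1, r, c] - d[l - 1, r, c],
            d[l, r + 1, c] - d[l, r - 1, c],
            d[l, r, c + 1] - d[l, r, c - 1],
        ])
        hll = d[l + 1, r, c] + d[l - 1, r, c] - 2 * d[l, r, c]
        hrr = d[l, r + 1, c] + d[l, r - 1, c] - 2 * d[l, r, c]
        hcc = d[l, r, c + 1] + d[l, r, c - 1] - 2 * d[l, r, c]
        hlr = 0.25 * (d[l + 1, r + 1, c] - d[l + 1, r - 1, c] - d[l - 1, r + 1, c] + d[l - 1, r - 1, c])
        hlc = 0.25 * (d[l + 1, r, c + 1] - d[l + 1, r, c - 1] - d[l - 1, r, c + 1] + d[l - 1, r, c - 1])
        hrc = 0.25 * (d[l, r + 1, c + 1] - d[l, r + 1, c - 1] - d[l, r - 1, c + 1] + d[l, r - 1, c - 1])
        hess = np.array([[hll, hlr, hlc], [hlr, hrr, hrc], [hlc, hrc, hcc]])
        try:
            off = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(off) < 0.5) or (it == max_iter - 1 and np.all(np.abs(off) < 1.0)):
            off = np.clip(off, -0.5, 0.5)
            d_ref = d[l, r, c] + 0.5 * float(g @ off)
            return l, r, c, off, d_ref, (hrr, hcc, hrc)
        l += int(round(off[0]))
        r += int(round(off[1]))
        c += int(round(off[2]))
        if not (1 <= l < L - 1 and 1 <= r < H - 1 and 1 <= c < W - 1):
            return None
    return None


def detect_keypoints(
    gray: GrayImage | np.ndarray,
    contrast_thr: float = 0.04,
    edge_thr: float = 10.0,
    sigma0: float = 1.6,
    intervals: int = 3,
    scale_space: ScaleSpace | None = None,
) -> list[Keypoint]:
    """DoG scale-space extrema with Taylor refinement and stability tests.

    A candidate survives when its refined |D| reaches ``contrast_thr``
    (image intensities taken in [0, 1]) and its spatial Hessian passes the
    edge-ratio test ``tr^2/det < (r+1)^2/r`` at ``r = edge_thr``.
    """
    ss = scale_space or build_scale_space(gray, sigma0=sigma0, intervals=intervals)
    kps: list[Keypoint] = []
    for o, dog in enumerate(ss.dog):
        if dog.shape[0] < 3 or min(dog.shape[1:]) < 3:
            continue
        mask = _is_extremum_mask(dog)
        # candidate prefilter scales with the contrast threshold (keeps the
        # threshold monotone: lowering it can only add keypoints)
        mask &= np.abs(dog[1:-1, 1:-1, 1:-1]) > 0.5 * contrast_thr
        for l, r, c in zip(*np.nonzero(mask)):
            res = _refine(dog, l + 1, r + 1, c + 1)
            if res is None:
                continue
            l2, r2, c2, off, d_ref, (hrr, hcc, hrc) = res
            if abs(d_ref) < contrast_thr:
                continue
            tr = hrr + hcc
            det = hrr * hcc - hrc**2
            if det <= 0 or tr**2 / det >= (edge_thr + 1.0) ** 2 / edge_thr:
                continue
            scale_mult = 2.0**o
            kps.append(
                Keypoint(
                    x=float((c2 + off[2]) * scale_mult),
                    y=float((r2 + off[1]) * scale_mult),
                    sigma=float(ss.sigma0 * ss.k ** (l2 + off[0]) * scale_mult),
                    response=float(abs(d_ref)),
                )
            )
    return kps


def assign_orientation(keypoint: Keypoint, scale_space: ScaleSpace) -> list[Keypoint]:
    """Dominant gradient orientation(s) from a 36-bin weighted histogram.

    Peaks within 80% of the maximum spawn duplicate keypoints; a flat
    neighborhood keeps a single keypoint with orientation 0.
    """
    o = int(np.clip(np.floor(np.log2(max(keypoint.sigma / scale_space.sigma0, 1e-9))), 0,
                    len(scale_space.octaves) - 1))
    stack = scale_space.octaves[o]
    sig_oct = keypoint.sigma / 2.0**o
    level = int(np.clip(round(np.log(max(sig_oct / scale_space.sigma0, 1e-9)) / np.log(scale_space.k)),
                        0, stack.shape[0] - 1))
    img = stack[level]
    r0 = int(round(keypoint.y / 2.0**o))
    c0 = int(round(keypoint.x / 2.0**o))
    sigma_w = 1.5 * sig_oct
    radius = max(int(round(3.0 * sigma_w)), 1)
    hist = np.zeros(36)
    H, W = img.shape
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = r0 + dr, c0 + dc
            if not (1 <= r < H - 1 and 1 <= c < W - 1):
                continue
            gx = img[r, c + 1] - img[r, c - 1]
            gy = img[r + 1, c] - img[r - 1, c]
            mag = np.hypot(gx, gy)
            theta = np.degrees(np.arctan2(gy, gx)) % 360.0
            wgt = np.exp(-(dr**2 + dc**2) / (2.0 * sigma_w**2))
            hist[int(theta // 10) % 36] += wgt * mag
    peak = hist.max()
    if peak <= 0:
        return [Keypoint(keypoint.x, keypoint.y, keypoint.sigma, keypoint.response, 0.0)]
    out = []
    for b in range(36):
        if hist[b] >= 0.8 * peak and hist[b] >= hist[(b - 1) % 36] and hist[b] >= hist[(b + 1) % 36]:
            out.append(Keypoint(keypoint.x, keypoint.y, keypoint.sigma,
                                keypoint.response, orientation=b * 10.0 + 5.0))
    return out or [Keypoint(keypoint.x, keypoint.y, keypoint.sigma, keypoint.response, 0.0)]


# ---------------------------------------------------------------------------
# Density map and fusion
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    counts: np.ndarray  # (5, 128)
    n_keypoints: int


@dataclass
class FeatureImage:
    channels: np.ndarray  # (128, 128, 3) in [0, 1]
    channel_roles: tuple[str, str, str] = CHANNEL_ROLES


def density_map(
    keypoints: list[Keypoint],
    src_h: int = 128,
    src_w: int = 128,
    target_h: int = 5,
    target_w: int = 128,
    mode: str = "point",
) -> DensityMap:
    """Histogram keypoint locations onto a ``target_h x target_w`` grid.

    ``mode='point'`` increments one cell per keypoint (the default);
    ``mode='disk'`` stamps a filled circle of radius ``round(scale)`` instead
    — an alternative reading of the attention-map construction.
    """
    counts = np.zeros((target_h, target_w))
    for kp in keypoints:
        row = min(int(kp.y * target_h / src_h), target_h - 1)
        col = min(int(kp.x * target_w / src_w), target_w - 1)
        row, col = max(row, 0), max(col, 0)
        if mode == "point":
            counts[row, col] += 1
        elif mode == "disk":
            rad = max(int(round(kp.sigma)), 0)
            rr, cc = np.ogrid[:target_h, :target_w]
            counts[(rr - row) ** 2 + (cc - col) ** 2 <= rad**2] += 1
        else:
            raise ValueError(f"unknown density mode {mode!r}")
    return DensityMap(counts=counts, n_keypoints=len(keypoints))


def finalize_sift_channel(dmap: DensityMap, out_h: int = 128, out_w: int = 128) -> np.ndarray:
    """3x3 Gaussian blur (sigma 1.0, symmetric borders), min-max
    normalization, then nearest-neighbor upsampling to ``out_h x out_w``."""
    blurred = gaussian_filter(dmap.counts, sigma=1.0, truncate=1.0, mode="reflect")
    norm = minmax01(blurred)
    h, w = norm.shape
    rows = (np.arange(out_h) * h) // out_h
    cols = (np.arange(out_w) * w) // out_w
    return norm[np.ix_(rows, cols)]


def fuse(
    segment,
    scales: np.ndarray = DEFAULT_SCALES,
    channel_order: tuple[str, str, str] = CHANNEL_ROLES,
    contrast_thr: float = 0.04,
    edge_thr: float = 10.0,
) -> FeatureImage:
    """Build the fused 128x128x3 feature image for one z-scored heartbeat.

    The SIFT channel is derived from the Morlet scalogram after grayscale
    normalization and resizing to 128x128, so keypoint coordinates live
    directly on the 128-wide grid that the density map subsamples.
    """
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    parts: dict[str, np.ndarray] = {}
    sc = {name: cwt_scalogram(x, name, scales) for name in ("mexh", "morl")}
    for name in ("mexh", "morl"):
        parts[f"{name}-scalogram"] = resize_image(minmax01(sc[name].matrix), 128, 128)

    gray = to_gray(parts["morl-scalogram"], provenance="morl scalogram 128x128")
    kps = detect_keypoints(gray, contrast_thr=contrast_thr, edge_thr=edge_thr)
    parts["sift-density"] = finalize_sift_channel(density_map(kps, 128, 128))

    img = np.stack([parts[role] for role in channel_order], axis=-1)
    return FeatureImage(channels=np.clip(img, 0.0, 1.0), channel_roles=channel_order)
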