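"""Synthetic single-lead ECG generator with exact R-peak ground truth.

Each heartbeat is modelled as a sum of Gaussian bumps (P, Q, R, S, T) whose
amplitude (mV), centre (ms relative to the R peak) and width (ms) are held in
a :class:`BeatTemplate`.  Ten class profiles carry caricatured morphology
differences (widened QRS for bundle-branch-block-like classes, depressed T
waves for infarct-like classes, ...) so that downstream feature extraction and
classification have separable structure to recover.  The profiles make no
clinical claim.

Records are quasi-periodic beat trains with RR intervals drawn from a
truncated normal distribution, corrupted (optionally) by baseline wander,
powerline interference and white noise.  True R-peak sample indices are
recorded exactly, which makes every later stage (detection, segmentation,
denoising) testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The ten supported class labels.
CLASS_LABELS = ("N", "MI", "VHD", "CAD", "CHF", "DY", "MYO", "HCM", "DCM", "BBB")

#: Minimum admissible RR interval (s); keeps adjacent 640 ms beat windows
#: from overlapping the neighbouring QRS complex.
RR_MIN_S = 0.4


@dataclass(frozen=True)
class BeatTemplate:
    """P-QRS-T morphology as Gaussian bumps.

    ``components`` maps a wave name to ``(amplitude_mv, center_ms, width_ms)``
    where the centre is relative to the R peak.
    """

    components: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (_, _, width) in self.components.items():
            if width <= 0:
                raise ValueError(f"component {name!r} has non-positive width")
        if self.components:
            amps = {k: abs(v[0]) for k, v in self.components.items()}
            if "R" in self.components and amps["R"] < max(amps.values()):
                raise ValueError("R component must have the largest |amplitude|")


@dataclass(frozen=True)
class ClassProfile:
    """Beat morphology plus rhythm statistics for one class."""

    class_label: str
    template: BeatTemplate
    rr_mean: float  # s
    rr_sd: float  # s

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be > 0")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + powerline + white noise."""

    baseline_amp: float = 0.1  # mV
    baseline_freq: float = 0.5  # Hz, low-frequency drift band
    powerline_amp: float = 0.05  # mV
    powerline_freq: float = 50.0  # Hz
    white_sd: float = 0.03  # mV

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not (0.1 <= self.baseline_freq <= 1.0):
            raise ValueError("baseline_freq must lie in [0.1, 1.0] Hz")


#: Convenience all-zero noise specification.
NO_NOISE = NoiseSpec(baseline_amp=0.0, powerline_amp=0.0, white_sd=0.0)


@dataclass
class SyntheticRecord:
    samples: np.ndarray  # mV
    fs: float  # Hz
    true_rpeaks: np.ndarray  # sample indices, strictly increasing
    label: str
    seed: int

    def __post_init__(self) -> None:
        rp = np.asarray(self.true_rpeaks)
        if rp.size and (np.any(np.diff(rp) <= 0) or rp[0] < 0 or rp[-1] >= len(self.samples)):
            raise ValueError("true_rpeaks must be strictly increasing and in bounds")


def _normal_template() -> BeatTemplate:
    return BeatTemplate(
        {
            "P": (0.15, -160.0, 22.0),
            "Q": (-0.12, -32.0, 9.0),
            "R": (1.10, 0.0, 13.0),
            "S": (-0.25, 30.0, 11.0),
            "T": (0.35, 185.0, 45.0),
        }
    )


def _variant(base: BeatTemplate, **overrides: tuple[float, float, float]) -> BeatTemplate:
    comps = dict(base.components)
    comps.update(overrides)
    return BeatTemplate(comps)


def default_profiles() -> dict[str, ClassProfile]:
    """Ten caricatured class morphologies.

    The perturbations echo textbook ECG signatures only loosely (wide QRS for
    BBB/DCM, inverted T for MI, tall R + deep S for HCM, tachycardic CHF,
    erratic rhythm for DY, ...); their purpose is pairwise-distinguishable
    mean beats, not physiological fidelity.
    """
    n = _normal_template()
    t = {
        "N": (n, 0.85, 0.04),
        "MI": (_variant(n, T=(-0.22, 190.0, 45.0), Q=(-0.30, -32.0, 12.0)), 0.85, 0.05),
        "VHD": (_variant(n, P=(0.30, -170.0, 32.0), R=(0.95, 0.0, 14.0)), 0.90, 0.05),
        "CAD": (_variant(n, S=(-0.45, 35.0, 18.0), T=(0.15, 190.0, 40.0)), 0.80, 0.05),
        "CHF": (_variant(n, R=(0.70, 0.0, 13.0), T=(0.20, 180.0, 40.0)), 0.60, 0.03),
        "DY": (_variant(n, P=(0.08, -150.0, 18.0)), 0.95, 0.22),
        "MYO": (_variant(n, T=(0.08, 185.0, 55.0), R=(0.90, 0.0, 15.0)), 0.88, 0.06),
        "HCM": (_variant(n, R=(1.60, 0.0, 13.0), S=(-0.60, 32.0, 13.0), Q=(-0.28, -34.0, 10.0)), 0.82, 0.04),
        "DCM": (_variant(n, R=(0.80, 0.0, 26.0), S=(-0.35, 45.0, 16.0)), 0.88, 0.05),
        "BBB": (_variant(n, R=(0.95, -12.0, 28.0), S=(-0.50, 42.0, 22.0), T=(0.25, 200.0, 50.0)), 0.85, 0.05),
    }
    return {lab: ClassProfile(lab, tpl, rr, sd) for lab, (tpl, rr, sd) in t.items()}


#: Per-class record proportions mirroring the heavily imbalanced source
#: distribution (majority:minority roughly 50:1).
DEFAULT_IMBALANCE = {
    "MI": 4614, "N": 1426, "CAD": 680, "CHF": 600, "BBB": 415,
    "DCM": 334, "DY": 334, "VHD": 185, "HCM": 108, "MYO": 93,
}


def make_beat(template: BeatTemplate, fs: float, window: float) -> np.ndarray:
    """Render one beat on a window of ``round(window*fs)`` samples.

    The R centre sits at the window midpoint; each component contributes a
    Gaussian bump ``a * exp(-(t-c)^2 / (2 w^2))``.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if window <= 0:
        raise ValueError("window must be > 0")
    n = int(round(window * fs))
    t_ms = (np.arange(n) - n // 2) / fs * 1000.0  # sample n//2 sits exactly at R
    out = np.zeros(n)
    for amp, center, width in template.components.values():
        out += amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return out


def _add_beats(t_s: np.ndarray, r_times: np.ndarray, template: BeatTemplate) -> np.ndarray:
    x = np.zeros_like(t_s)
    for r in r_times:
        dt_ms = (t_s - r) * 1000.0
        for amp, center, width in template.components.values():
            # skip far-away beats: bump support ~ 5 widths
            m = np.abs(dt_ms - center) < 6.0 * width
            x[m] += amp * np.exp(-0.5 * ((dt_ms[m] - center) / width) ** 2)
    return x


def synthesize_record(
    profile: ClassProfile,
    duration: float,
    fs: float,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
) -> SyntheticRecord:
    """Generate one labelled record with exact R-peak indices.

    RR intervals are drawn from a normal(rr_mean, rr_sd) truncated below at
    ``RR_MIN_S``.  Noise is added after beat placement.  Identical
    ``(profile, duration, fs, noise, seed)`` give bitwise-identical samples.
    """
    if duration < 2 * profile.rr_mean:
        raise ValueError("duration too short: need at least two RR intervals")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t_s = np.arange(n) / fs

    r_times = []
    t = 0.5 * profile.rr_mean
    margin = 0.45  # keep the final T wave inside the record
    while t < duration - margin:
        r_times.append(t)
        rr = profile.rr_mean + profile.rr_sd * rng.standard_normal()
        t += max(rr, RR_MIN_S)
    r_times = np.asarray(r_times)

    x = _add_beats(t_s, r_times, profile.template)
    if noise.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq * t_s + phase)
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t_s + phase)
    if noise.white_sd > 0:
        x = x + noise.white_sd * rng.standard_normal(n)

    rpeaks = np.round(r_times * fs).astype(int)
    rpeaks = rpeaks[(rpeaks >= 0) & (rpeaks < n)]
    return SyntheticRecord(samples=x, fs=fs, true_rpeaks=rpeaks, label=profile.class_label, seed=seed)


def make_dataset(
    profiles: dict[str, ClassProfile],
    counts_per_class: dict[str, int],
    duration: float = 10.0,
    fs: float = 128.0,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
) -> list[SyntheticRecord]:
    """Generate a labelled multi-class record collection.

    Per-record seeds derive from the master seed through a counter-based
    ``SeedSequence`` spawn key ``(class_index, replicate)``, so the records
    produced for one class do not depend on which other classes are requested.
    """
    for lab, cnt in counts_per_class.items():
        if lab not in profiles:
            raise ValueError(f"unknown class label {lab!r}")
        if cnt < 1:
            raise ValueError(f"count for class {lab!r} must be >= 1")
    records: list[SyntheticRecord] = []
    for lab in sorted(counts_per_class, key=CLASS_LABELS.index):
        ci = CLASS_LABELS.index(lab)
        for rep in range(counts_per_class[lab]):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, rep))
            rec_seed = int(ss.generate_state(1)[0] % (2**31))
            records.append(synthesize_record(profiles[lab], duration, fs, noise, rec_seed))
    return records
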