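"""Reading and writing single-lead ECG records.

Two on-disk formats are supported:

* **WFDB** — the PhysioNet waveform format: a text ``.hea`` header plus a
  binary ``.dat`` signal file.  Formats 16 (int16) and 32 (int32) with
  interleaved multiplexed samples are handled, with gain/baseline conversion
  to millivolts.  The writer defaults to format 32 with an automatic gain so
  that a write→read round trip is lossless to well below 1e-9 mV for
  physiological amplitude ranges.
* **CSV** — a plain two-line-header delimited fallback (one value per line).

Reading never resamples or filters; preprocessing is an explicit later stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import CLASS_LABELS

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`map_label` when no pattern matches.
UNMATCHED = "unmatched"


@dataclass
class EcgRecord:
    """A sampled single-lead ECG trace in mV."""

    samples: np.ndarray
    fs: float
    lead_name: str = "II"
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")


@dataclass
class LabelMap:
    """Ordered, case-insensitive substring patterns -> class label.

    First match wins.  Unmatched diagnoses map to :data:`UNMATCHED` and are
    logged, never silently dropped.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("label map must be non-empty")
        for pat, lab in self.pairs:
            if lab not in CLASS_LABELS:
                raise ValueError(f"pattern {pat!r} maps to unknown label {lab!r}")


#: Best-effort header-text patterns for the ten classes.  Order matters:
#: 'myocarditis' must precede 'myocardial', the named cardiomyopathies must
#: precede any bare 'cardiomyopathy' pattern.
DEFAULT_LABEL_MAP = LabelMap(
    [
        ("myocarditis", "MYO"),
        ("myocardial infarction", "MI"),
        ("infarct", "MI"),
        ("valvular", "VHD"),
        ("heart valve", "VHD"),
        ("coronary", "CAD"),
        ("heart failure", "CHF"),
        ("dysrhythmia", "DY"),
        ("arrhythmia", "DY"),
        ("hypertrophic cardiomyopathy", "HCM"),
        ("hypertrophy", "HCM"),
        ("dilated cardiomyopathy", "DCM"),
        ("bundle branch block", "BBB"),
        ("healthy", "N"),
        ("normal", "N"),
    ]
)


def map_label(diagnosis_text: str, label_map: LabelMap = DEFAULT_LABEL_MAP) -> str:
    """Map free-text diagnosis to a class label (or :data:`UNMATCHED`)."""
    low = diagnosis_text.lower()
    for pat, lab in label_map.pairs:
        if pat.lower() in low:
            return lab
    logger.info("diagnosis %r matched no label pattern", diagnosis_text)
    return UNMATCHED


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------

_DTYPES = {16: np.dtype("<i2"), 32: np.dtype("<i4")}


def _parse_gain(tok: str) -> tuple[float, int, str]:
    """Parse a 'gain(baseline)/units' token; returns (gain, baseline, units)."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline, units


def _read_wfdb(header: Path, lead_preference: str, strict: bool) -> EcgRecord:
    lines = [ln.strip() for ln in header.read_text().splitlines() if ln.strip()]
    body = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln.lstrip("#").strip() for ln in lines if ln.startswith("#")]
    rec_tok = body[0].split()
    name, nsig = rec_tok[0], int(rec_tok[1])
    fs = float(rec_tok[2]) if len(rec_tok) > 2 else 250.0
    nsamp = int(rec_tok[3]) if len(rec_tok) > 3 else 0
    sig_lines = body[1 : 1 + nsig]

    sigs = []
    for ln in sig_lines:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, 0, "mV")
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append({"file": tok[0], "fmt": fmt, "gain": gain,
                     "baseline": baseline, "units": units, "desc": desc})

    fmts = {s["fmt"] for s in sigs}
    if len(fmts) != 1 or fmts.pop() not in _DTYPES:
        raise IOError(f"{header}: unsupported or mixed WFDB signal formats")
    fmt = sigs[0]["fmt"]
    dat = header.with_name(sigs[0]["file"])
    if not dat.exists():
        raise IOError(f"signal file {dat} not found")
    raw = np.fromfile(dat, dtype=_DTYPES[fmt])
    if nsamp and raw.size < nsamp * nsig:
        raise IOError(f"{dat}: truncated signal file")
    raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)

    descs = [s["desc"] for s in sigs]
    if lead_preference in descs:
        idx = descs.index(lead_preference)
    elif strict:
        raise IOError(f"{header}: requested lead {lead_preference!r} absent (leads: {descs})")
    else:
        idx = 0
        warnings.warn(
            f"{header.name}: lead {lead_preference!r} absent; using {descs[0]!r}",
            stacklevel=3,
        )
    s = sigs[idx]
    samples = (raw[:, idx].astype(float) - s["baseline"]) / s["gain"]
    if s["units"].lower() in ("uv", "microvolts"):
        samples = samples / 1000.0

    label = None
    for c in comments:
        if c.lower().startswith("label:") and c.split(":", 1)[1].strip() in CLASS_LABELS:
            label = c.split(":", 1)[1].strip()
            break
        lab = map_label(c)
        if lab != UNMATCHED:
            label = lab
            break
    return EcgRecord(samples=samples, fs=fs, lead_name=s["desc"], label=label, source_id=name)


def _read_csv(path: Path) -> EcgRecord:
    meta: dict[str, str] = {}
    values: list[float] = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "=" in ln:
                k, v = ln.lstrip("#").split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        values.append(float(ln.split(",")[0]))
    if not values:
        raise IOError(f"{path}: no samples found")
    label = meta.get("label") or None
    return EcgRecord(
        samples=np.asarray(values),
        fs=float(meta.get("fs", 128.0)),
        lead_name=meta.get("lead", "II"),
        label=label if label in CLASS_LABELS else None,
        source_id=meta.get("source_id", path.stem),
    )


def read_record(path: str | Path, lead_preference: str = "II", strict: bool = False) -> EcgRecord:
    """Read a WFDB header (.hea) or delimited text (.csv/.txt) record.

    ``lead_preference`` names the desired signal description; if absent and
    ``strict`` is off, the first lead is returned with a warning.
    """
    path = Path(path)
    if path.suffix == "":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise IOError(f"no such record: {path}")
    if path.suffix == ".hea":
        return _read_wfdb(path, lead_preference, strict)
    return _read_csv(path)


def write_record(record: EcgRecord, path: str | Path, format: str = "wfdb") -> Path:
    """Write ``record``; returns the path to read back (``.hea`` or ``.csv``).

    WFDB output uses format 32 with the gain chosen to span the int32 range
    (``(2**31 - 1) / max|x|``), so the quantization error stays below 1e-9 mV
    for physiological amplitudes.
    """
    path = Path(path)
    if format == "csv":
        path = path.with_suffix(".csv")
        lines = [f"# fs = {record.fs!r}", f"# lead = {record.lead_name}"]
        if record.label:
            lines.append(f"# label = {record.label}")
        if record.source_id:
            lines.append(f"# source_id = {record.source_id}")
        lines += [repr(float(v)) for v in record.samples]
        path.write_text("\n".join(lines) + "\n")
        return path
    if format != "wfdb":
        raise ValueError(f"unknown format {format!r}")

    name = path.stem
    hea, dat = path.with_suffix(".hea"), path.with_suffix(".dat")
    max_abs = float(np.max(np.abs(record.samples))) or 1.0
    gain = min((2**31 - 1) / (max_abs * 1.0001), 1e15)
    adu = np.round(record.samples * gain)
    if np.any(np.abs(adu) >= 2**31):
        raise ValueError("signal amplitude overflows format 32 at chosen gain")
    header = [f"{name} 1 {record.fs!r} {len(record.samples)}",
              f"{name}.dat 32 {gain!r}(0)/mV 32 0 0 0 0 {record.lead_name}"]
    if record.label:
        header.append(f"# label: {record.label}")
    if record.source_id:
        header.append(f"# source: {record.source_id}")
    try:
        hea.write_text("\n".join(header) + "\n")
        adu.astype("<i4").tofile(dat)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot write record to {path}: {exc}") from exc
    return hea
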