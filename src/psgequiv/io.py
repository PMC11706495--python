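"""Readers and writers for the formats the pipeline consumes and produces.

Covers European Data Format (EDF / continuous EDF+) recordings, hypnogram
CSVs with lights-off/lights-on anchors and arousal events, environmental
logger CSVs, and tidy result tables.  Discontinuous EDF+ ("EDF+D") is
rejected: the recorder this pipeline targets exports plain continuous EDF.

EDF samples are stored as little-endian int16 with per-channel linear
physical/digital scaling; the codec here converts to and from microvolts
with that scaling, so a write-read round trip is exact to within one
digitization quantum.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, UnsupportedDialectError, ValidationError
from .hypnogram import EPOCH_SECONDS, Hypnogram

logger = logging.getLogger(__name__)

_EDF_HEADER_BYTES = 256
_EDF_SIGNAL_HEADER_BYTES = 256


def _normalize_label(label: str) -> str:
    """Case-insensitive electrode label, stripped of 'EEG '/'-Ref' decorations."""
    s = label.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    if s.upper().endswith("-REF"):
        s = s[:-4]
    return s.strip().upper()


@dataclass
class PsgRecording:
    """Multichannel PSG voltages in microvolts at a common sample rate."""

    channel_labels: list[str]
    sample_rate: float
    signals: np.ndarray  # shape (n_channels, n_samples), µV
    start_time: dt.datetime | None = None
    lights_off: dt.datetime | None = None
    lights_on: dt.datetime | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValidationError("channel_labels/signals length mismatch")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if (
            self.lights_off is not None
            and self.lights_on is not None
            and not self.lights_off < self.lights_on
        ):
            raise ValidationError("lights_off must precede lights_on")

    def channel(self, label: str) -> np.ndarray:
        """Samples for one channel, matched case-insensitively."""
        want = _normalize_label(label)
        for i, lab in enumerate(self.channel_labels):
            if _normalize_label(lab) == want:
                return self.signals[i]
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")


@dataclass
class DerivationSignal:
    """A referenced derivation such as F3-M2: active minus reference."""

    name: str
    samples: np.ndarray
    sample_rate: float


@dataclass
class EnvLog:
    """Environmental logger series for one night (missing values kept as NaN)."""

    frame: pd.DataFrame  # columns: timestamp, temperature_c, humidity_pct, sound_db, vibration
    night_id: str = ""
    place: str = ""
    timepoint: int = 0

    PARAMETERS = ("temperature_c", "humidity_pct", "sound_db", "vibration")


def derive(rec: PsgRecording, active: str, reference: str) -> DerivationSignal:
    """Pointwise difference active − reference, named '<active>-<reference>'."""
    a = rec.channel(active)
    r = rec.channel(reference)
    return DerivationSignal(
        name=f"{active}-{reference}", samples=a - r, sample_rate=rec.sample_rate
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _num(raw: bytes, start: int, length: int, name: str, cast=float):
    text = _field(raw, start, length)
    try:
        return cast(text)
    except ValueError:
        raise FormatError(f"EDF header field {name!r} is not numeric: {text!r}")


def read_edf(path: str | Path) -> PsgRecording:
    """Read a plain EDF or continuous EDF+ file into a :class:`PsgRecording`.

    Units are converted to physical values (µV for EEG channels) using the
    per-channel EDF scaling.  All channels must share one sampling rate.
    Raises :class:`FormatError` for malformed or truncated files and
    :class:`UnsupportedDialectError` for discontinuous EDF+ ("EDF+D").
    """
    raw = Path(path).read_bytes()
    if len(raw) < _EDF_HEADER_BYTES:
        raise FormatError("file shorter than the 256-byte EDF header")
    reserved = _field(raw, 192, 44)
    if reserved.startswith("EDF+D"):
        raise UnsupportedDialectError(
            "discontinuous EDF+ (EDF+D) recordings are not supported"
        )
    header_bytes = _num(raw, 184, 8, "header_bytes", int)
    n_records = _num(raw, 236, 8, "n_records", int)
    record_duration = _num(raw, 244, 8, "record_duration")
    ns = _num(raw, 252, 4, "n_signals", int)
    if ns <= 0:
        raise FormatError(f"EDF header field 'n_signals' must be positive, got {ns}")
    if header_bytes != _EDF_HEADER_BYTES + ns * _EDF_SIGNAL_HEADER_BYTES:
        raise FormatError(
            f"EDF header field 'header_bytes' ({header_bytes}) inconsistent "
            f"with {ns} signals"
        )
    if len(raw) < header_bytes:
        raise FormatError("file truncated inside the signal header")

    # Signal header layout: label 16, transducer 80, phys_dim 8, phys_min 8,
    # phys_max 8, dig_min 8, dig_max 8, prefilter 80, samples_per_record 8,
    # reserved 32.  Offsets are cumulative in units of ns.
    offsets = {"label": 0, "transducer": 16, "phys_dim": 96, "phys_min": 104,
               "phys_max": 112, "dig_min": 120, "dig_max": 128,
               "prefilter": 136, "n_samp": 216, "reserved": 224}

    def col(name: str, width: int, cast):
        base = _EDF_HEADER_BYTES + offsets[name] * ns
        out = []
        for i in range(ns):
            text = _field(raw, base + i * width, width)
            if cast is str:
                out.append(text)
            else:
                try:
                    out.append(cast(text))
                except ValueError:
                    raise FormatError(
                        f"EDF signal header field {name!r} for signal {i} "
                        f"is not numeric: {text!r}"
                    )
        return out

    labels = col("label", 16, str)
    phys_min = col("phys_min", 8, float)
    phys_max = col("phys_max", 8, float)
    dig_min = col("dig_min", 8, int)
    dig_max = col("dig_max", 8, int)
    n_samp = col("n_samp", 8, int)

    record_bytes = 2 * sum(n_samp)
    expected = header_bytes + n_records * record_bytes
    if len(raw) < expected:
        raise FormatError(
            f"file truncated: header promises {n_records} data records "
            f"({expected} bytes) but file has {len(raw)} bytes"
        )

    # Drop the EDF+ annotation channel if present; we only need signals.
    keep = [i for i, lab in enumerate(labels) if lab != "EDF Annotations"]
    data = np.frombuffer(
        raw[header_bytes : header_bytes + n_records * record_bytes],
        dtype="<i2",
    ).reshape(n_records, -1)
    starts = np.concatenate([[0], np.cumsum(n_samp)])
    signals = []
    for i in keep:
        dig = data[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        if dig_max[i] == dig_min[i]:
            raise FormatError(
                f"EDF signal header field 'dig_min/dig_max' degenerate "
                f"for signal {i}"
            )
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signals.append((dig - dig_min[i]) * gain + phys_min[i])
    rates = {n_samp[i] / record_duration for i in keep}
    if len(rates) != 1:
        raise FormatError(f"channels have differing sample rates: {sorted(rates)}")

    start_time = None
    try:
        d = _field(raw, 168, 8)
        t = _field(raw, 176, 8)
        day, mon, yr = (int(x) for x in d.split("."))
        hh, mm, ss = (int(x) for x in t.split("."))
        yr += 2000 if yr < 85 else 1900
        start_time = dt.datetime(yr, mon, day, hh, mm, ss)
    except (ValueError, IndexError):
        logger.warning("unparseable EDF start date/time %r %r", d, t)

    return PsgRecording(
        channel_labels=[labels[i] for i in keep],
        sample_rate=rates.pop(),
        signals=np.vstack(signals),
        start_time=start_time,
    )


def write_edf(rec: PsgRecording, path: str | Path) -> None:
    """Write a :class:`PsgRecording` as plain EDF (int16, 1-s data records).

    Per-channel physical ranges are set from the data so the digitization
    quantum is as small as int16 allows; trailing samples that do not fill a
    whole 1-s record are zero-padded (the reader returns them as written).
    """
    fs = rec.sample_rate
    if fs != int(fs):
        raise ValidationError("EDF writer requires an integer sample rate")
    fs = int(fs)
    n_ch, n = rec.signals.shape
    n_records = int(math.ceil(n / fs))
    start = rec.start_time or dt.datetime(2020, 1, 1, 23, 0, 0)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad(start.strftime("%d.%m.%y"), 8),
        pad(start.strftime("%H.%M.%S"), 8),
        pad(str(_EDF_HEADER_BYTES + n_ch * _EDF_SIGNAL_HEADER_BYTES), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])

    phys_min, phys_max, dig = [], [], []
    for ch in rec.signals:
        lo = float(np.nanmin(ch)) if n else -1.0
        hi = float(np.nanmax(ch)) if n else 1.0
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (hi - lo) / (32767 - (-32768))
        d = np.round((ch - lo) / gain) + (-32768)
        dig.append(np.clip(d, -32768, 32767).astype("<i2"))

    def num_field(x: float) -> str:
        s = f"{x:.6g}"
        return s[:8]

    cols = [
        [pad(lab, 16) for lab in rec.channel_labels],
        [pad("AgAgCl electrode", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(num_field(x), 8) for x in phys_min],
        [pad(num_field(x), 8) for x in phys_max],
        [pad("-32768", 8)] * n_ch,
        [pad("32767", 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(fs), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    sig_header = b"".join(b"".join(c) for c in cols)

    total = n_records * fs
    padded = np.zeros((n_ch, total), dtype="<i2")
    for i, d in enumerate(dig):
        padded[i, :n] = d
        if n < total:
            # pad with the digital value that maps to physical zero-ish (use dig_min-free midpoint of last sample)
            padded[i, n:] = d[-1] if n else 0
    records = padded.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig_header + records.tobytes())


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, arousal_path: str | Path | None = None) -> Hypnogram:
    """Read a hypnogram CSV (with '#lights_off='/'#lights_on=' header lines).

    Columns: ``epoch_index,stage,artifact_flag``.  Stage labels are validated
    against {W,N1,N2,N3,R} with the offending row reported; the epoch count
    must tile the lights-off -> lights-on interval exactly in 30-s epochs.
    Arousal events (``onset_seconds,duration_seconds``) are read from
    ``arousal_path`` when given.
    """
    lights = {}
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                lights[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = parts
                continue
            rows.append((lineno, parts))

    if header is None or header[:2] != ["epoch_index", "stage"]:
        raise FormatError(
            "hypnogram CSV must have columns epoch_index,stage[,artifact_flag]"
        )

    stages, flags = [], []
    from .hypnogram import STAGES

    for lineno, parts in rows:
        stage = parts[1]
        if stage not in STAGES:
            raise ValidationError(
                f"unknown stage label {stage!r} at line {lineno} of {path}"
            )
        stages.append(stage)
        flags.append(len(parts) > 2 and parts[2] in ("1", "True", "true"))

    lo = lights.get("lights_off")
    on = lights.get("lights_on")
    lights_off = lights_on = None
    if lo and on:
        lights_off = dt.datetime.fromisoformat(lo)
        lights_on = dt.datetime.fromisoformat(on)
        trt_s = (lights_on - lights_off).total_seconds()
        if trt_s <= 0:
            raise ValidationError("lights_off must precede lights_on")
        if abs(trt_s - len(stages) * EPOCH_SECONDS) > 1e-6:
            raise ValidationError(
                f"{len(stages)} epochs x 30 s does not cover the "
                f"lights interval of {trt_s:.0f} s"
            )

    arousals: list[tuple[float, float]] = []
    if arousal_path is not None:
        df = pd.read_csv(arousal_path, float_precision="round_trip")
        for col in ("onset_seconds", "duration_seconds"):
            if col not in df.columns:
                raise FormatError(f"arousal CSV missing column {col!r}")
        arousals = [
            (float(r.onset_seconds), float(r.duration_seconds))
            for r in df.itertuples()
        ]

    return Hypnogram(
        stages=stages,
        arousals=arousals,
        artifact_flags=flags,
        lights_off=lights_off,
        lights_on=lights_on,
    )


def write_hypnogram(
    hyp: Hypnogram, path: str | Path, arousal_path: str | Path | None = None
) -> None:
    """Write a hypnogram (and optionally its arousal events) as CSV."""
    with open(path, "w") as fh:
        if hyp.lights_off is not None:
            fh.write(f"#lights_off={hyp.lights_off.isoformat()}\n")
        if hyp.lights_on is not None:
            fh.write(f"#lights_on={hyp.lights_on.isoformat()}\n")
        fh.write("epoch_index,stage,artifact_flag\n")
        for i, (s, a) in enumerate(zip(hyp.stages, hyp.artifact_flags)):
            fh.write(f"{i},{s},{int(a)}\n")
    if arousal_path is not None:
        pd.DataFrame(
            hyp.arousals, columns=["onset_seconds", "duration_seconds"]
        ).to_csv(arousal_path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# Environment CSV
# ---------------------------------------------------------------------------

def read_env(path: str | Path, **meta) -> EnvLog:
    """Read an environmental logger CSV; keeps missing values as NaN.

    Timestamps must be strictly increasing; duplicates or reversals raise
    :class:`ValidationError`.  An empty data section yields an empty log with
    a logged warning.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    expected = ["timestamp", *EnvLog.PARAMETERS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"environment CSV missing columns {missing}")
    if len(df) == 0:
        logger.warning("environment CSV %s has an empty data section", path)
        return EnvLog(frame=df, **meta)
    ts = df["timestamp"]
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        bad = ts[ts.duplicated() | (ts.diff() <= pd.Timedelta(0))].iloc[0]
        raise ValidationError(
            f"environment timestamps not strictly increasing at {bad}"
        )
    return EnvLog(frame=df, **meta)


def write_env(log: EnvLog, path: str | Path) -> None:
    log.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path,
                  rounded_decimals: int = 3) -> list[Path]:
    """Write each result table as full-precision CSV plus a rounded view.

    Returns the list of files written.  A JSON companion carries every table
    for programmatic reuse.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    payload = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
        pr = outdir / f"{name}_rounded.csv"
        df.round(rounded_decimals).to_csv(pr, index=False)
        written.append(pr)
        payload[name] = json.loads(df.to_json(orient="records"))
    pj = outdir / "results.json"
    pj.write_text(json.dumps(payload, indent=1, default=str))
    written.append(pj)
    return written
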