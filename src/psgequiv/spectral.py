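"""EEG band-power pipeline: filtering, windowed FFT, SWA/SWE summaries.

The analysis chain mirrors standard sleep-EEG practice: referenced
derivations are band-pass filtered 0.3–35 Hz, each 30-s scored epoch is
covered by ten 4-s Hann-windowed FFT segments whose band powers are
averaged after natural-log transformation, and night-level summaries (NREM
mean SWA, N3 mean SWA, slow-wave energy) are taken over the non-artifact
epochs of the relevant stages.

Window layout
-------------
Ten 4-s windows with 1-s overlap cannot tile a 30-s epoch exactly; windows
start at 0, 3, 6, …, 27 s, so the tenth window extends 1 s into the next
epoch.  The final epoch of a record, which has no look-ahead second, falls
back to nine windows (recorded in ``n_windows_used``).

Band powers are sums of periodogram bins (0.25 Hz resolution) whose centre
frequency lies in the half-open interval [lo, hi), so the slow-oscillation
and delta bands partition slow-wave activity exactly: SO + delta = SWA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .hypnogram import Hypnogram
from .io import DerivationSignal

logger = logging.getLogger(__name__)

WINDOW_SECONDS = 4.0
WINDOW_STEP_SECONDS = 3.0  # 4-s windows overlapping by 1 s
WINDOWS_PER_EPOCH = 10
FREQ_RESOLUTION = 0.25  # Hz, from 4-s windows

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "so": (0.5, 1.0),
    "swa": (0.5, 4.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}


@dataclass
class BandTable:
    """Named frequency bands in Hz, half-open [lo, hi)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: lower {lo} !< upper {hi}")

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class EpochBandPower:
    """Per-band mean natural-log power (ln µV²) for one 30-s epoch."""

    epoch_index: int
    derivation: str
    values: dict[str, float]  # band -> mean ln power; NaN if no usable window
    n_windows_used: int
    artifact: bool = False


@dataclass
class SpectralSummary:
    """Night-level spectral summaries over non-artifact epochs (ln µV²)."""

    swa_mean_nrem: float
    swa_mean_n3: float
    swe: float
    band_means_nrem: dict[str, float]
    swe_convention: str = "linear_sum"
    n_epochs_nrem: int = 0
    n_epochs_n3: int = 0


def bandpass(sig: DerivationSignal, lo: float = 0.3, hi: float = 35.0) -> DerivationSignal:
    """Zero-phase band-pass 0.3–35 Hz (cascaded Butterworth, forward-backward).

    Requires ``sample_rate > 2*hi``.  Separate high- and low-pass sections
    (order 4 each, applied with ``sosfiltfilt``) give a monotone passband and
    ≥40 dB attenuation at 0.1 and 70 Hz.
    """
    fs = sig.sample_rate
    if fs <= 2 * hi:
        raise ValueError(f"sample rate {fs} Hz too low for {hi} Hz high cut")
    hp = sps.butter(4, lo, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(4, hi, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(hp, sig.samples)
    x = sps.sosfiltfilt(lp, x)
    return DerivationSignal(name=sig.name, samples=x, sample_rate=fs)


def window_psd(segment: np.ndarray, sample_rate: float = 500.0) -> tuple[np.ndarray, np.ndarray]:
    """Hann periodogram of one 4-s segment: (freqs, power per bin in µV²).

    The DC component is removed before windowing; normalization is such that
    the power of an in-band sinusoid of amplitude A, summed over its spectral
    neighbourhood, recovers A²/2 (window-power compensation).  Bin spacing is
    0.25 Hz for 4-s segments.
    """
    segment = np.asarray(segment, dtype=float)
    expected = int(round(WINDOW_SECONDS * sample_rate))
    if segment.shape != (expected,):
        raise ValueError(
            f"expected exactly {expected} samples (4 s at {sample_rate} Hz), "
            f"got {segment.shape}"
        )
    freqs, pxx = sps.periodogram(
        segment, fs=sample_rate, window="hann", detrend="constant",
        scaling="density",
    )
    return freqs, pxx * (freqs[1] - freqs[0])


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Sum of bin powers with centre frequency in [lo, hi)."""
    mask = (freqs >= lo) & (freqs < hi)
    return float(power[mask].sum())


def _epoch_window_starts(epoch_index: int, n_samples: int, fs: float) -> list[int]:
    """Sample offsets of the (up to ten) 4-s analysis windows of an epoch."""
    epoch_start = int(round(epoch_index * 30.0 * fs))
    wlen = int(round(WINDOW_SECONDS * fs))
    step = int(round(WINDOW_STEP_SECONDS * fs))
    starts = []
    for w in range(WINDOWS_PER_EPOCH):
        s = epoch_start + w * step
        if s + wlen <= n_samples:
            starts.append(s)
    return starts


def epoch_band_power(
    sig: DerivationSignal,
    epoch_index: int,
    bands: BandTable | None = None,
    artifact: bool = False,
) -> EpochBandPower:
    """Band powers for one 30-s epoch: mean over windows of ln(band power).

    Windows with nonpositive power in a band are excluded from that band's
    mean (and logged) rather than propagating −inf.  Artifact epochs carry no
    values.
    """
    bands = bands or BandTable()
    if artifact:
        return EpochBandPower(
            epoch_index=epoch_index, derivation=sig.name,
            values={b: math.nan for b in bands.names()},
            n_windows_used=0, artifact=True,
        )
    fs = sig.sample_rate
    starts = _epoch_window_starts(epoch_index, len(sig.samples), fs)
    if not starts:
        raise ValueError(f"signal too short for epoch {epoch_index}")
    wlen = int(round(WINDOW_SECONDS * fs))
    per_band_logs: dict[str, list[float]] = {b: [] for b in bands.names()}
    for s in starts:
        freqs, power = window_psd(sig.samples[s : s + wlen], fs)
        for name, (lo, hi) in bands.bands.items():
            p = band_power(freqs, power, lo, hi)
            if p > 0:
                per_band_logs[name].append(math.log(p))
            else:
                logger.debug(
                    "nonpositive %s power in window at sample %d of epoch %d; "
                    "window excluded from that band's mean", name, s, epoch_index,
                )
    values = {
        b: (float(np.mean(v)) if v else math.nan)
        for b, v in per_band_logs.items()
    }
    return EpochBandPower(
        epoch_index=epoch_index, derivation=sig.name, values=values,
        n_windows_used=len(starts), artifact=False,
    )


def score_derivation(
    sig: DerivationSignal,
    hyp: Hypnogram,
    bands: BandTable | None = None,
    prefilter: bool = True,
) -> list[EpochBandPower]:
    """Band powers for every epoch of a night, honouring artifact flags."""
    bands = bands or BandTable()
    if prefilter:
        sig = bandpass(sig)
    return [
        epoch_band_power(sig, i, bands, artifact=bool(hyp.artifact_flags[i]))
        for i in range(hyp.n_epochs)
    ]


def detect_artifacts_amplitude(
    sig: DerivationSignal, n_epochs: int, threshold_uv: float = 500.0
) -> np.ndarray:
    """Optional amplitude heuristic: flag epochs with any |x| > threshold.

    The primary artifact input is an explicit mask from visual inspection;
    this heuristic exists for synthetic pipelines and is off by default.
    """
    fs = sig.sample_rate
    n_per = int(round(30.0 * fs))
    flags = np.zeros(n_epochs, dtype=bool)
    for i in range(n_epochs):
        seg = sig.samples[i * n_per : (i + 1) * n_per]
        if seg.size and np.max(np.abs(seg)) > threshold_uv:
            flags[i] = True
    return flags


def summarize_spectra(
    per_epoch: list[EpochBandPower],
    hyp: Hypnogram,
    swe_convention: str = "linear_sum",
) -> SpectralSummary:
    """Night-level SWA/SWE and per-band NREM means from per-epoch powers.

    NREM means are over non-artifact N2+N3 epochs; the N3 mean over
    non-artifact N3 epochs.  Slow-wave energy is, under the default
    ``linear_sum`` convention, the sum of linear per-epoch SWA over those
    NREM epochs reported on the natural-log scale; ``log_sum`` instead sums
    the per-epoch log values directly.
    """
    if swe_convention not in ("linear_sum", "log_sum"):
        raise ValueError(f"unknown SWE convention {swe_convention!r}")
    if len(per_epoch) != hyp.n_epochs:
        raise ValueError("per-epoch band powers not aligned with hypnogram")
    stages = hyp.stages
    nan = math.nan

    def usable(ep: EpochBandPower) -> bool:
        return not ep.artifact and not math.isnan(ep.values.get("swa", nan))

    nrem = [ep for ep in per_epoch if stages[ep.epoch_index] in ("N2", "N3") and usable(ep)]
    n3 = [ep for ep in per_epoch if stages[ep.epoch_index] == "N3" and usable(ep)]

    if not nrem:
        logger.warning("no usable NREM epochs; spectral summaries missing")
        return SpectralSummary(
            swa_mean_nrem=nan, swa_mean_n3=nan, swe=nan,
            band_means_nrem={b: nan for b in per_epoch[0].values} if per_epoch else {},
            swe_convention=swe_convention,
        )

    swa_vals = np.array([ep.values["swa"] for ep in nrem])
    swa_mean_nrem = float(swa_vals.mean())
    swa_mean_n3 = float(np.mean([ep.values["swa"] for ep in n3])) if n3 else nan
    if swe_convention == "linear_sum":
        swe = float(np.log(np.exp(swa_vals).sum()))
    else:
        swe = float(swa_vals.sum())

    band_names = nrem[0].values.keys()
    band_means = {}
    for b in band_names:
        vals = [ep.values[b] for ep in nrem if not math.isnan(ep.values[b])]
        band_means[b] = float(np.mean(vals)) if vals else nan

    return SpectralSummary(
        swa_mean_nrem=swa_mean_nrem,
        swa_mean_n3=swa_mean_n3,
        swe=swe,
        band_means_nrem=band_means,
        swe_convention=swe_convention,
        n_epochs_nrem=len(nrem),
        n_epochs_n3=len(n3),
    )
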