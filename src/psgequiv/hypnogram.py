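"""Staged hypnograms and the sleep variables derived from them.

A hypnogram is the technologist's scoring of one night: one stage label per
30-s epoch over the interval from lights-off to lights-on, plus the list of
scored arousal events.  All summary sleep variables (TST, SE, SL, WASO, stage
percentages, stage latencies, arousal index) are computed here from that
sequence alone; spectral quantities live in :mod:`psgequiv.spectral`.

Conventions
-----------
* Epoch ``i`` covers ``[lights_off + 30*i, lights_off + 30*(i+1))`` seconds.
* Sleep onset is the first epoch scored anything other than W.
* WASO counts every W epoch strictly after sleep onset, including terminal
  wake before lights-on, so ``SL + TST + WASO == TRT`` whenever onset exists.
* A latency is missing (NaN) iff the stage never occurs.
* Artifact flags are carried but ignored by these metrics; artifact exclusion
  applies to spectral analysis only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30.0
EPOCH_MINUTES = 0.5
STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = ("N1", "N2", "N3", "R")


@dataclass
class Hypnogram:
    """One night of 30-s stage epochs with arousal events.

    Parameters
    ----------
    stages
        Ordered stage labels, one per 30-s epoch, drawn from ``{W,N1,N2,N3,R}``.
    arousals
        Scored arousal events as ``(onset_seconds, duration_seconds)`` pairs,
        onsets measured from lights-off.
    artifact_flags
        Per-epoch artifact marks (used downstream by the spectral pipeline).
    lights_off, lights_on
        Optional clock anchors (timezone-naive); all computation uses offsets.
    """

    stages: Sequence[str]
    arousals: list[tuple[float, float]] = field(default_factory=list)
    artifact_flags: Sequence[bool] | None = None
    lights_off: object = None
    lights_on: object = None

    def __post_init__(self) -> None:
        stages = [str(s) for s in self.stages]
        bad = [(i, s) for i, s in enumerate(stages) if s not in STAGES]
        if bad:
            i, s = bad[0]
            raise ValidationError(f"unknown stage label {s!r} at epoch {i}")
        self.stages = np.asarray(stages, dtype="U2")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(stages), dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if len(self.artifact_flags) != len(stages):
                raise ValidationError(
                    "artifact_flags length does not match number of epochs"
                )
        trt_s = len(stages) * EPOCH_SECONDS
        for onset, dur in self.arousals:
            if not 0 <= onset <= trt_s:
                raise ValidationError(
                    f"arousal onset {onset} s outside recording [0, {trt_s}] s"
                )
            if dur < 0:
                raise ValidationError(f"negative arousal duration {dur}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def trt_minutes(self) -> float:
        """Total recording time, lights-off to lights-on, in minutes."""
        return self.n_epochs * EPOCH_MINUTES

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            np.array_equal(self.stages, other.stages)
            and np.array_equal(self.artifact_flags, other.artifact_flags)
            and self.arousals == other.arousals
        )


@dataclass
class SleepVariables:
    """Summary sleep variables for one night (minutes, percent, events/h).

    Missing values are NaN: latencies when the stage never occurs, and every
    onset-dependent quantity when the night contains no sleep.
    """

    tst_min: float
    se_pct: float
    sl_min: float
    waso_min: float
    pct_n1: float
    pct_n2: float
    pct_n3: float
    pct_r: float
    lat_n1_min: float
    lat_n2_min: float
    lat_n3_min: float
    lat_r_min: float
    ari_per_h: float
    trt_min: float = math.nan

    FIELDS = (
        "tst_min", "se_pct", "sl_min", "waso_min",
        "pct_n1", "pct_n2", "pct_n3", "pct_r",
        "lat_n1_min", "lat_n2_min", "lat_n3_min", "lat_r_min",
        "ari_per_h",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def sleep_onset_epoch(hyp: Hypnogram) -> int | None:
    """Index of the first non-W epoch, or None for a night without sleep."""
    idx = np.flatnonzero(hyp.stages != "W")
    return int(idx[0]) if idx.size else None


def _first_index(stages: np.ndarray, stage: str) -> int | None:
    idx = np.flatnonzero(stages == stage)
    return int(idx[0]) if idx.size else None


def compute_sleep_variables(hyp: Hypnogram) -> SleepVariables:
    """Compute the full set of summary sleep variables for one night.

    TST counts 0.5 min per epoch in any sleep stage; SE = TST/TRT x 100;
    SL runs from lights-off to sleep onset; WASO counts W epochs strictly
    after onset; stage percentages are relative to TST; NREM latencies are
    measured from lights-off and stage-R latency from sleep onset; the
    arousal index is arousals / TST x 60 (events per hour of sleep).
    """
    stages = hyp.stages
    trt = hyp.trt_minutes
    is_sleep = np.isin(stages, SLEEP_STAGES)
    tst = float(is_sleep.sum()) * EPOCH_MINUTES
    se = tst / trt * 100.0 if trt > 0 else math.nan

    onset = sleep_onset_epoch(hyp)
    if tst == 0 or onset is None:
        logger.warning("night contains no sleep epochs; onset-dependent "
                       "variables reported missing")
        nan = math.nan
        return SleepVariables(
            tst_min=0.0, se_pct=0.0, sl_min=nan, waso_min=nan,
            pct_n1=nan, pct_n2=nan, pct_n3=nan, pct_r=nan,
            lat_n1_min=nan, lat_n2_min=nan, lat_n3_min=nan, lat_r_min=nan,
            ari_per_h=nan, trt_min=trt,
        )

    sl = onset * EPOCH_MINUTES
    waso = float(np.sum(stages[onset:] == "W")) * EPOCH_MINUTES

    def pct(stage: str) -> float:
        return float(np.sum(stages == stage)) * EPOCH_MINUTES / tst * 100.0

    def lat_from_lights_off(stage: str) -> float:
        i = _first_index(stages, stage)
        return math.nan if i is None else i * EPOCH_MINUTES

    i_r = _first_index(stages, "R")
    lat_r = math.nan if i_r is None else (i_r - onset) * EPOCH_MINUTES

    ari = len(hyp.arousals) / tst * 60.0

    return SleepVariables(
        tst_min=tst, se_pct=se, sl_min=sl, waso_min=waso,
        pct_n1=pct("N1"), pct_n2=pct("N2"), pct_n3=pct("N3"), pct_r=pct("R"),
        lat_n1_min=lat_from_lights_off("N1"),
        lat_n2_min=lat_from_lights_off("N2"),
        lat_n3_min=lat_from_lights_off("N3"),
        lat_r_min=lat_r,
        ari_per_h=ari,
        trt_min=trt,
    )


def stage_percent_profile(
    hyp: Hypnogram, window: tuple[int, int]
) -> dict[str, float]:
    """Stage percentages over the sleep epochs in a half-open epoch window.

    Percentages are relative to the number of *sleep* epochs inside
    ``[window[0], window[1])``; every value is NaN when the window contains
    no sleep.  Raises for an empty or out-of-range window.
    """
    lo, hi = window
    if not (0 <= lo < hi <= hyp.n_epochs):
        raise ValueError(
            f"window [{lo}, {hi}) empty or outside recording of "
            f"{hyp.n_epochs} epochs"
        )
    seg = hyp.stages[lo:hi]
    n_sleep = int(np.isin(seg, SLEEP_STAGES).sum())
    if n_sleep == 0:
        return {f"pct_{s.lower()}": math.nan for s in SLEEP_STAGES}
    return {
        f"pct_{s.lower()}": float(np.sum(seg == s)) / n_sleep * 100.0
        for s in SLEEP_STAGES
    }


def hourly_n3_percent(hyp: Hypnogram) -> list[float]:
    """%N3 per clock hour of the recording (120 epochs per hour)."""
    out = []
    for h in range(int(np.ceil(hyp.n_epochs / 120))):
        lo, hi = h * 120, min((h + 1) * 120, hyp.n_epochs)
        out.append(stage_percent_profile(hyp, (lo, hi))["pct_n3"])
    return out
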