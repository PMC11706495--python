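"""Synthetic two-site crossover PSG studies with known statistical structure.

The generator emulates the layout of a 15-participant, four-night crossover
sleep-lab comparison: each subject sleeps two consecutive nights in each of
two laboratories (conventional "HSL" and mobile "MSL", order randomized in
near-equal arms), producing a staged hypnogram, arousal events, an
environmental log, optionally raw EEG, and per-night self-report factor
scores.

Stage dynamics are a first-order Markov chain over {W, N1, N2, N3, R} at the
30-s epoch scale — a deliberate simplification with no ultradian cycling —
whose transition probabilities were chosen to give realistic healthy-adult
architecture (sleep efficiency ≈ 90%, %N2 ≈ 50, %N3 ≈ 20, %R ≈ 20).  Deep
sleep propensity is modulated on the logit of the N2→N3 entry probability
by a per-subject random effect, a site effect (MSL minus HSL), and an
optional first-night effect, so the site contrast and the between-subject
reliability of %N3 are both known by construction.

Seeding uses a master seed with per-subject and per-night substreams, so
enlarging the study never perturbs the data of existing subjects.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hypnogram import STAGES, Hypnogram, compute_sleep_variables
from .io import EnvLog, PsgRecording, write_env, write_hypnogram

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

# Per-epoch transition probabilities, rows/cols ordered W, N1, N2, N3, R.
DEFAULT_TRANSITIONS = np.array([
    #  W     N1     N2     N3     R
    [0.800, 0.180, 0.020, 0.000, 0.000],  # W
    [0.090, 0.350, 0.530, 0.000, 0.030],  # N1
    [0.015, 0.020, 0.860, 0.065, 0.040],  # N2
    [0.005, 0.005, 0.130, 0.860, 0.000],  # N3
    [0.020, 0.040, 0.090, 0.000, 0.850],  # R
])

DEFAULT_AROUSAL_RATES = {"W": 0.0, "N1": 25.0, "N2": 10.0, "N3": 4.0, "R": 14.0}

# Stage-dependent EEG composition, µV RMS per band: N3 delta-dominant,
# N2 with sigma activity, R theta-mixed, W alpha/beta-dominant.
DEFAULT_EEG_BAND_WEIGHTS = {
    "W":  {"delta": 5.0, "theta": 4.0, "alpha": 15.0, "sigma": 2.0, "beta": 8.0},
    "N1": {"delta": 8.0, "theta": 10.0, "alpha": 6.0, "sigma": 2.0, "beta": 3.0},
    "N2": {"so": 8.0, "delta": 15.0, "theta": 8.0, "alpha": 4.0, "sigma": 8.0, "beta": 2.0},
    "N3": {"so": 25.0, "delta": 40.0, "theta": 8.0, "alpha": 3.0, "sigma": 4.0, "beta": 1.5},
    "R":  {"delta": 6.0, "theta": 10.0, "alpha": 5.0, "sigma": 2.0, "beta": 4.0},
}

EEG_BAND_EDGES = {
    "so": (0.5, 1.0), "delta": (1.0, 4.0), "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0), "sigma": (12.0, 16.0), "beta": (16.0, 30.0),
}


@dataclass
class EnvModel:
    """Parameters of the synthetic bedroom environment (per-minute sampling)."""

    temperature_mean_c: float = 24.0
    temperature_drift_c: float = 0.5      # slow overnight cooling amplitude
    temperature_noise_c: float = 0.15
    humidity_mean_pct: float = 52.0       # MSL baseline
    humidity_hsl_offset_pct: float = 10.0  # HSL runs more humid
    humidity_noise_pct: float = 1.5
    sound_mean_db: float = 28.0
    sound_noise_db: float = 1.5
    msl_first_hour_sound_bump_db: float = 3.0
    vibration_mean: float = 0.020
    vibration_noise: float = 0.004
    sample_interval_s: float = 60.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic crossover PSG generator.

    ``place_effect_n3`` and ``subject_sd_n3`` act on the logit of the N2→N3
    entry probability; the defaults were calibrated by forward simulation so
    that the mobile lab reduces mean %N3 by about 3 percentage points and
    the test-retest ICC of %N3 is about 0.7.
    """

    n_subjects: int = 15
    trt_minutes: float = 480.0
    transitions: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    subject_sd_n3: float = 0.44
    night_sd_n3: float = 0.0
    place_effect_n3: float = -0.19
    fne_effect: float = 0.0
    arousal_rate_per_h: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AROUSAL_RATES))
    eeg_band_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_EEG_BAND_WEIGHTS.items()})
    eeg_sample_rate: float = 500.0
    eeg_channels: tuple[str, ...] = ("F3", "M2")
    artifact_epoch_prob: float = 0.0
    artifact_amplitude_uv: float = 800.0
    env: EnvModel = field(default_factory=EnvModel)
    osa_ma_intercept: float = 50.0
    osa_ma_slope: float = 0.6          # factor-2 points per %N3 point
    osa_ma_noise_sd: float = 9.0
    lights_off_clock: dt.time = dt.time(23, 0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, float)
        if t.shape != (5, 5) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValidationError("transition matrix rows must be >= 0 and sum to 1")
        if any(r < 0 for r in self.arousal_rate_per_h.values()):
            raise ValidationError("arousal rates must be >= 0")

    @property
    def n_epochs(self) -> int:
        return int(round(self.trt_minutes * 2))


@dataclass
class NightRecord:
    subject: int
    night: int          # 1-4, study order
    place: str          # HSL / MSL
    timepoint: int      # 1 or 2 (first/second night at this place)
    order: str          # HSL_first / MSL_first
    hypnogram: Hypnogram
    env: EnvLog | None = None
    eeg: PsgRecording | None = None
    osa_ma: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    config: SimConfig
    nights: list[NightRecord]

    def night(self, subject: int, night: int) -> NightRecord:
        for rec in self.nights:
            if rec.subject == subject and rec.night == night:
                return rec
        raise KeyError((subject, night))


def _subject_streams(cfg: SimConfig, subject: int) -> list[np.random.SeedSequence]:
    root = np.random.SeedSequence(cfg.master_seed)
    subj_ss = root.spawn(subject + 1)[subject]
    # children: [0] subject effects, [1..12] nights x (hyp, eeg, env), [13] osa
    return subj_ss.spawn(14)


def night_layout(order: str, night: int) -> tuple[str, int]:
    """(place, timepoint) of a study night given the crossover arm."""
    first, second = ("HSL", "MSL") if order == "HSL_first" else ("MSL", "HSL")
    return (first, night) if night <= 2 else (second, night - 2)


def subject_order(cfg: SimConfig, subject: int) -> str:
    """Near-equal arms: even-indexed subjects start in the HSL."""
    return "HSL_first" if subject % 2 == 0 else "MSL_first"


def _adjusted_transitions(cfg: SimConfig, logit_shift: float) -> np.ndarray:
    """Shift the N2→N3 entry probability on the logit scale, renormalizing
    the remainder of the N2 row proportionally."""
    t = cfg.transitions.copy()
    i2, i3 = STAGE_INDEX["N2"], STAGE_INDEX["N3"]
    p = t[i2, i3]
    logit = math.log(p / (1 - p)) + logit_shift
    p_new = 1.0 / (1.0 + math.exp(-logit))
    rest = 1.0 - p
    t[i2] = t[i2] * ((1.0 - p_new) / rest)
    t[i2, i3] = p_new
    return t


def _simulate_stages(transitions: np.ndarray, n_epochs: int,
                     uniforms: np.ndarray) -> np.ndarray:
    """First-order Markov stage sequence starting in W, driven by uniforms."""
    cum = np.cumsum(transitions, axis=1)
    states = np.empty(n_epochs, dtype=int)
    state = STAGE_INDEX["W"]
    for t in range(n_epochs):
        state = int(np.searchsorted(cum[state], uniforms[t], side="right"))
        state = min(state, 4)
        states[t] = state
    return states


def simulate_hypnogram(cfg: SimConfig, subject: int, night: int) -> Hypnogram:
    """One night's staged hypnogram with arousal events.

    Deep-sleep propensity combines the subject random effect, the site
    effect when the night is in the MSL, the optional first-night effect on
    study night 1, and any night-level jitter.
    """
    streams = _subject_streams(cfg, subject)
    eff_rng = np.random.default_rng(streams[0])
    u_subject = eff_rng.normal(0.0, cfg.subject_sd_n3)
    order = subject_order(cfg, subject)
    place, timepoint = night_layout(order, night)

    night_rng = np.random.default_rng(streams[1 + (night - 1) * 3])
    shift = u_subject
    if place == "MSL":
        shift += cfg.place_effect_n3
    if night == 1:
        shift += cfg.fne_effect
    if cfg.night_sd_n3 > 0:
        shift += night_rng.normal(0.0, cfg.night_sd_n3)

    transitions = _adjusted_transitions(cfg, shift)
    n = cfg.n_epochs
    uniforms = night_rng.random(n)
    states = _simulate_stages(transitions, n, uniforms)
    stages = [STAGES[s] for s in states]

    rates = np.array([cfg.arousal_rate_per_h[s] for s in STAGES])
    per_epoch_rate = rates[states] / 120.0  # events per 30-s epoch
    counts = night_rng.poisson(per_epoch_rate)
    arousals = []
    for i in np.flatnonzero(counts):
        for off in np.sort(night_rng.random(counts[i])):
            arousals.append((float((i + off) * 30.0), 5.0))

    flags = night_rng.random(n) < cfg.artifact_epoch_prob

    lights_off = dt.datetime.combine(dt.date(2020, 6, 1) + dt.timedelta(days=night - 1),
                                     cfg.lights_off_clock)
    lights_on = lights_off + dt.timedelta(minutes=cfg.trt_minutes)
    return Hypnogram(stages=stages, arousals=arousals, artifact_flags=flags,
                     lights_off=lights_off, lights_on=lights_on)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float, hi: float, rms: float) -> np.ndarray:
    """Gaussian noise restricted to [lo, hi) Hz, scaled to a target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.irfft(spec, n)
    cur = float(np.sqrt(np.mean(x ** 2)))
    return x * (rms / cur) if cur > 0 else x


def simulate_eeg(cfg: SimConfig, hyp: Hypnogram, subject: int = 0,
                 night: int = 1) -> PsgRecording:
    """Synthetic EEG for one night: stage-dependent band-limited noise.

    Each 30-s epoch is a sum of band-limited Gaussian components with the
    stage's RMS weights; mastoid reference channels (M1/M2) are zero so a
    derivation equals the active channel.  Epochs flagged as artifact in the
    hypnogram receive a high-amplitude transient.
    """
    streams = _subject_streams(cfg, subject)
    rng = np.random.default_rng(streams[2 + (night - 1) * 3])
    fs = cfg.eeg_sample_rate
    n_per = int(round(30.0 * fs))
    n_total = hyp.n_epochs * n_per
    signals = []
    for ch in cfg.eeg_channels:
        if ch.upper() in ("M1", "M2"):
            signals.append(np.zeros(n_total))
            continue
        x = np.empty(n_total)
        for i, stage in enumerate(hyp.stages):
            seg = np.zeros(n_per)
            for band, rms in cfg.eeg_band_weights[str(stage)].items():
                if rms > 0:
                    lo, hi = EEG_BAND_EDGES[band]
                    seg += _band_limited_noise(rng, n_per, fs, lo, hi, rms)
            if hyp.artifact_flags[i]:
                burst = np.zeros(n_per)
                center = n_per // 2
                burst[center : center + int(fs)] = cfg.artifact_amplitude_uv
                seg = seg + burst
            x[i * n_per : (i + 1) * n_per] = seg
        signals.append(x)
    return PsgRecording(
        channel_labels=list(cfg.eeg_channels), sample_rate=fs,
        signals=np.vstack(signals), start_time=hyp.lights_off,
        lights_off=hyp.lights_off, lights_on=hyp.lights_on,
    )


def simulate_environment(cfg: SimConfig, subject: int, night: int) -> EnvLog:
    """Per-minute environment series with the configured site structure.

    The HSL runs more humid by ``humidity_hsl_offset_pct``; the MSL has a
    sound bump in the first hour after lights-off.
    """
    streams = _subject_streams(cfg, subject)
    rng = np.random.default_rng(streams[3 + (night - 1) * 3])
    order = subject_order(cfg, subject)
    place, timepoint = night_layout(order, night)
    em = cfg.env

    lights_off = dt.datetime.combine(dt.date(2020, 6, 1) + dt.timedelta(days=night - 1),
                                     cfg.lights_off_clock)
    n = int(round(cfg.trt_minutes * 60.0 / em.sample_interval_s)) + 1
    ts = pd.date_range(lights_off, periods=n,
                       freq=pd.Timedelta(seconds=em.sample_interval_s))
    hours = np.arange(n) * em.sample_interval_s / 3600.0

    temp = (em.temperature_mean_c
            - em.temperature_drift_c * hours / 8.0
            + rng.normal(0.0, em.temperature_noise_c, n))
    hum = em.humidity_mean_pct + rng.normal(0.0, em.humidity_noise_pct, n)
    if place == "HSL":
        hum = hum + em.humidity_hsl_offset_pct
    sound = em.sound_mean_db + rng.normal(0.0, em.sound_noise_db, n)
    if place == "MSL":
        sound = sound + em.msl_first_hour_sound_bump_db * (hours < 1.0)
    vib = em.vibration_mean + rng.normal(0.0, em.vibration_noise, n)

    frame = pd.DataFrame({
        "timestamp": ts, "temperature_c": temp, "humidity_pct": hum,
        "sound_db": sound, "vibration": vib,
    })
    return EnvLog(frame=frame, night_id=f"s{subject:02d}_n{night}",
                  place=place, timepoint=timepoint)


def simulate_osa_ma(cfg: SimConfig, pct_n3_by_night: dict[int, float],
                    subject: int) -> dict[int, dict[str, float]]:
    """Per-night OSA-MA factor scores (standardized-score scale).

    Factor 2 ("initiation and maintenance of sleep") tracks that night's
    %N3 with slope ``osa_ma_slope`` plus noise; the other four factors are
    noise around the intercept.
    """
    streams = _subject_streams(cfg, subject)
    rng = np.random.default_rng(streams[13])
    out = {}
    for night, pct_n3 in sorted(pct_n3_by_night.items()):
        scores = {}
        for k in range(1, 6):
            base = cfg.osa_ma_intercept
            if k == 2:
                base = base + cfg.osa_ma_slope * (pct_n3 - 20.0)
            scores[f"factor{k}"] = float(base + rng.normal(0.0, cfg.osa_ma_noise_sd))
        out[night] = scores
    return out


def simulate_study(cfg: SimConfig | None = None, include_env: bool = True,
                   include_eeg: bool = False) -> SyntheticStudy:
    """Generate the full crossover study bundle.

    EEG is opt-in (it dominates run time and most analyses need only the
    hypnograms); environment logs are generated by default.
    """
    cfg = cfg or SimConfig()
    nights: list[NightRecord] = []
    for subject in range(cfg.n_subjects):
        order = subject_order(cfg, subject)
        pct_n3 = {}
        recs = []
        for night in (1, 2, 3, 4):
            place, timepoint = night_layout(order, night)
            hyp = simulate_hypnogram(cfg, subject, night)
            sv = compute_sleep_variables(hyp)
            pct_n3[night] = sv.pct_n3
            env = simulate_environment(cfg, subject, night) if include_env else None
            eeg = simulate_eeg(cfg, hyp, subject, night) if include_eeg else None
            recs.append(NightRecord(
                subject=subject, night=night, place=place, timepoint=timepoint,
                order=order, hypnogram=hyp, env=env, eeg=eeg,
            ))
        osa = simulate_osa_ma(cfg, pct_n3, subject)
        for rec in recs:
            rec.osa_ma = osa[rec.night]
        nights.extend(recs)
    return SyntheticStudy(config=cfg, nights=nights)


def score_study(study: SyntheticStudy) -> pd.DataFrame:
    """Long table of sleep variables (one row per subject-night)."""
    rows = []
    for rec in study.nights:
        sv = compute_sleep_variables(rec.hypnogram)
        row = {"subject": rec.subject, "night": rec.night, "place": rec.place,
               "timepoint": rec.timepoint, "order": rec.order}
        row.update(sv.as_dict())
        for k, v in rec.osa_ma.items():
            row[f"osa_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write the study bundle to disk in the package's file formats."""
    from .io import write_edf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in study.nights:
        stem = f"s{rec.subject:02d}_n{rec.night}"
        write_hypnogram(rec.hypnogram, outdir / f"{stem}_hypnogram.csv",
                        outdir / f"{stem}_arousals.csv")
        if rec.env is not None:
            write_env(rec.env, outdir / f"{stem}_env.csv")
        if rec.eeg is not None:
            write_edf(rec.eeg, outdir / f"{stem}.edf")
        meta_rows.append({
            "subject": rec.subject, "night": rec.night, "place": rec.place,
            "timepoint": rec.timepoint, "order": rec.order,
            **{f"osa_{k}": v for k, v in rec.osa_ma.items()},
        })
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    return outdir


def read_study(indir: str | Path) -> SyntheticStudy:
    """Read back a study bundle written by :func:`write_study`."""
    from .io import read_env, read_hypnogram

    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    nights = []
    for row in meta.itertuples():
        stem = f"s{row.subject:02d}_n{row.night}"
        hyp = read_hypnogram(indir / f"{stem}_hypnogram.csv",
                             indir / f"{stem}_arousals.csv")
        env_path = indir / f"{stem}_env.csv"
        env = read_env(env_path, night_id=stem, place=row.place,
                       timepoint=int(row.timepoint)) if env_path.exists() else None
        osa = {c[len("osa_"):]: getattr(row, c)
               for c in meta.columns if c.startswith("osa_")}
        nights.append(NightRecord(
            subject=int(row.subject), night=int(row.night), place=row.place,
            timepoint=int(row.timepoint), order=row.order, hypnogram=hyp,
            env=env, osa_ma=osa,
        ))
    n_subjects = meta["subject"].nunique()
    cfg = SimConfig(n_subjects=n_subjects)
    return SyntheticStudy(config=cfg, nights=nights)
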