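"""Reproducible pipeline stages over a study directory.

Each stage reads its upstream artifacts, writes tidy CSV tables plus a JSON
run manifest (config hash, seed, package version, row counts), and never
mutates its inputs.  The stages mirror the analysis of a two-site crossover
PSG study: simulate, score (sleep variables + environment summaries),
spectral, reliability (ICC), equivalence, compare (mixed models and
nonparametric tests), report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equivalence import DEFAULT_CI_LEVEL, DEFAULT_MARGIN_PCT, run_equivalence
from .errors import PsgEquivError, ValidationError
from .mixedmodel import fit_place_time_model
from .reliability import COMPARISONS, run_reliability
from .simulate import (SimConfig, read_study, score_study, simulate_study,
                       write_study)
from .spectral import BandTable, score_derivation, summarize_spectra
from .stats import (bonferroni, box_cox, cohens_d_lsmeans, cohens_d_raw,
                    env_summarize, friedman, wilcoxon_signed_rank)

logger = logging.getLogger(__name__)

SLEEP_VARIABLES = [
    "tst_min", "se_pct", "sl_min", "waso_min", "ari_per_h",
    "pct_n1", "pct_n2", "pct_n3", "pct_r", "lat_r_min",
]
EQUIVALENCE_VARIABLES = SLEEP_VARIABLES + ["lat_n2_min", "lat_n3_min"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study's settings."""

    study_dir: str = "study"
    out_dir: str = "results"
    seed: int = 0
    margin_pct: float = DEFAULT_MARGIN_PCT
    ci_level: float = DEFAULT_CI_LEVEL
    comparisons: tuple[str, ...] = COMPARISONS
    variables: list[str] = field(default_factory=lambda: list(SLEEP_VARIABLES))
    band_overrides: dict = field(default_factory=dict)
    include_eeg: bool = False
    n_subjects: int = 15
    trt_minutes: float = 480.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, outdir: Path, stage: str,
                    row_counts: dict[str, int]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "row_counts": row_counts,
    }
    (outdir / f"{stage}_manifest.json").write_text(
        json.dumps(manifest, indent=1))


def _require(path: Path, producer: str) -> None:
    if not path.exists():
        raise PsgEquivError(
            f"missing upstream artifact {path}; run '{producer}' first"
        )


def cmd_simulate(cfg: RunConfig) -> Path:
    """Generate a synthetic study bundle into the study directory."""
    sim_cfg = SimConfig(n_subjects=cfg.n_subjects, master_seed=cfg.seed,
                        trt_minutes=cfg.trt_minutes)
    study = simulate_study(sim_cfg, include_eeg=cfg.include_eeg)
    out = write_study(study, cfg.study_dir)
    _write_manifest(cfg, out, "simulate", {"nights": len(study.nights)})
    return out


def cmd_score(cfg: RunConfig) -> Path:
    """Sleep variables and environment summaries for every night."""
    study_dir = Path(cfg.study_dir)
    _require(study_dir / "metadata.csv", "simulate")
    study = read_study(study_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = score_study(study)
    table.to_csv(outdir / "sleep_variables.csv", index=False)

    env_rows = []
    for rec in study.nights:
        if rec.env is None or rec.hypnogram.lights_off is None:
            continue
        summ = env_summarize(rec.env, rec.hypnogram.lights_off,
                             rec.hypnogram.lights_on)
        row = {"subject": rec.subject, "night": rec.night,
               "place": rec.place, "timepoint": rec.timepoint}
        for param in summ.night_means:
            row[f"{param}_mean"] = summ.night_means[param]
            row[f"{param}_cv_pct"] = summ.cv_pct[param]
            for h, v in enumerate(summ.hourly_means[param], start=1):
                row[f"{param}_h{h}"] = v
        env_rows.append(row)
    if env_rows:
        pd.DataFrame(env_rows).to_csv(outdir / "env_summary.csv", index=False)

    _write_manifest(cfg, outdir, "score",
                    {"sleep_variables": len(table), "env_summary": len(env_rows)})
    return outdir


def cmd_spectral(cfg: RunConfig) -> Path:
    """Per-epoch band powers and night summaries for nights with EEG."""
    from .io import derive, read_edf

    study_dir = Path(cfg.study_dir)
    _require(study_dir / "metadata.csv", "simulate")
    meta = pd.read_csv(study_dir / "metadata.csv")
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bands = BandTable({**BandTable().bands, **{
        k: tuple(v) for k, v in cfg.band_overrides.items()}})

    from .io import read_hypnogram

    epoch_rows, summary_rows = [], []
    for row in meta.itertuples():
        stem = f"s{row.subject:02d}_n{row.night}"
        edf_path = study_dir / f"{stem}.edf"
        if not edf_path.exists():
            continue
        rec = read_edf(edf_path)
        hyp = read_hypnogram(study_dir / f"{stem}_hypnogram.csv",
                             study_dir / f"{stem}_arousals.csv")
        labels = [l for l in rec.channel_labels if l.upper() not in ("M1", "M2")]
        ref = "M2" if any(l.upper() == "M2" for l in rec.channel_labels) else "M1"
        for active in labels:
            sig = derive(rec, active, ref)
            per_epoch = score_derivation(sig, hyp, bands)
            for ep in per_epoch:
                epoch_rows.append({
                    "night_id": stem, "derivation": sig.name,
                    "epoch_index": ep.epoch_index,
                    "stage": hyp.stages[ep.epoch_index],
                    "artifact": ep.artifact, "n_windows": ep.n_windows_used,
                    **ep.values,
                })
            summ = summarize_spectra(per_epoch, hyp)
            summary_rows.append({
                "night_id": stem, "derivation": sig.name,
                "subject": row.subject, "night": row.night,
                "place": row.place, "timepoint": row.timepoint,
                "swa_mean_nrem": summ.swa_mean_nrem,
                "swa_mean_n3": summ.swa_mean_n3, "swe": summ.swe,
                "swe_convention": summ.swe_convention,
                **{f"{b}_mean_nrem": v for b, v in summ.band_means_nrem.items()},
            })
    if not epoch_rows:
        logger.warning("no EDF files found in %s; spectral stage skipped",
                       study_dir)
    else:
        pd.DataFrame(epoch_rows).to_csv(outdir / "band_power_epochs.csv",
                                        index=False)
        pd.DataFrame(summary_rows).to_csv(outdir / "spectral_summary.csv",
                                          index=False)
    _write_manifest(cfg, outdir, "spectral",
                    {"epochs": len(epoch_rows), "summaries": len(summary_rows)})
    return outdir


def _load_scored(cfg: RunConfig) -> pd.DataFrame:
    path = Path(cfg.out_dir) / "sleep_variables.csv"
    _require(path, "score")
    return pd.read_csv(path)


def cmd_reliability(cfg: RunConfig) -> Path:
    """ICC(A,1) per variable and comparison."""
    table = _load_scored(cfg)
    out = run_reliability(table, cfg.variables, tuple(cfg.comparisons))
    outdir = Path(cfg.out_dir)
    out.to_csv(outdir / "reliability_icc.csv", index=False)
    _write_manifest(cfg, outdir, "reliability", {"icc_rows": len(out)})
    return outdir


def cmd_equivalence(cfg: RunConfig) -> Path:
    """±margin CI-inclusion equivalence per variable and comparison."""
    table = _load_scored(cfg)
    variables = [v for v in EQUIVALENCE_VARIABLES if v in table.columns]
    out = run_equivalence(table, variables, tuple(cfg.comparisons),
                          cfg.margin_pct, cfg.ci_level)
    outdir = Path(cfg.out_dir)
    out.to_csv(outdir / "equivalence.csv", index=False)
    _write_manifest(cfg, outdir, "equivalence", {"equivalence_rows": len(out)})
    return outdir


def _four_cell_matrix(table: pd.DataFrame, variable: str) -> np.ndarray:
    """n_subjects x 4 matrix of the place x timepoint cells."""
    wide = table.pivot_table(index="subject", columns=["place", "timepoint"],
                             values=variable, aggfunc="first")
    cols = [("HSL", 1), ("HSL", 2), ("MSL", 1), ("MSL", 2)]
    return np.column_stack([
        wide[c] if c in wide else np.full(len(wide), np.nan) for c in cols
    ])


def cmd_compare(cfg: RunConfig) -> Path:
    """Per-variable inference: mixed model when normal (after Box-Cox where
    applicable), otherwise Friedman with Wilcoxon/Bonferroni post-hocs."""
    from scipy import stats as sstats

    table = _load_scored(cfg)
    rows = []
    for var in cfg.variables:
        vals = table[var].dropna().to_numpy(float)
        if len(vals) < 3 or np.ptp(vals) == 0:
            rows.append({"variable": var, "method": "skipped",
                         "note": "insufficient or constant data"})
            continue
        normal = float(sstats.shapiro(vals).pvalue) >= 0.05
        used = table.copy()
        transform = "none"
        if not normal and np.all(vals > 0):
            bc = box_cox(vals)
            if bc.normality_ok_after:
                lam = bc.lam
                used[var] = (np.log(used[var]) if lam == 0
                             else (used[var] ** lam - 1.0) / lam)
                normal, transform = True, f"boxcox(lambda={lam:.2f})"
        if normal:
            res = fit_place_time_model(used, var)
            if res.converged:
                place = res.effect("place")
                d = cohens_d_lsmeans(place.estimate, 0.0, place.se,
                                     res.n_subjects)
                rows.append({
                    "variable": var, "method": "mixed_model",
                    "transform": transform,
                    "structure": res.selected.structure,
                    "df_method": res.df_method,
                    **{f"{e.effect}_F": e.f for e in res.effects},
                    **{f"{e.effect}_df2": e.df2 for e in res.effects},
                    **{f"{e.effect}_p": e.p for e in res.effects},
                    "place_d": d,
                })
                continue
            rows.append({"variable": var, "method": "mixed_model_failed",
                         "transform": transform})
            continue
        # nonparametric branch
        m = _four_cell_matrix(table, var)
        fr = friedman(m)
        hsl = table[table["place"] == "HSL"][var].to_numpy(float)
        msl = table[table["place"] == "MSL"][var].to_numpy(float)
        pairs = [("HSL1-MSL1", (0, 2)), ("HSL2-MSL2", (1, 3)),
                 ("HSL1-HSL2", (0, 1)), ("MSL1-MSL2", (2, 3))]
        posthoc_p = []
        for _, (i, j) in pairs:
            w = wilcoxon_signed_rank(m[:, i], m[:, j])
            posthoc_p.append(w.p)
        adj = bonferroni(posthoc_p, len(posthoc_p))
        row = {
            "variable": var, "method": "friedman", "transform": "none",
            "friedman_chi2": fr.statistic, "friedman_df": fr.df,
            "friedman_p": fr.p,
            "place_d": cohens_d_raw(hsl[~np.isnan(hsl)], msl[~np.isnan(msl)]),
        }
        for (label, _), p_raw, p_adj in zip(pairs, posthoc_p, adj):
            row[f"wilcoxon_{label}_p"] = p_raw
            row[f"wilcoxon_{label}_p_adj"] = p_adj
        rows.append(row)

    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "compare.csv", index=False)
    _write_manifest(cfg, outdir, "compare", {"compare_rows": len(out)})
    return outdir


def cmd_report(cfg: RunConfig) -> Path:
    """Assemble the stage outputs into one JSON summary."""
    outdir = Path(cfg.out_dir)
    summary = {"config_hash": cfg.hash(), "seed": cfg.seed,
               "version": __version__}
    for name in ("sleep_variables", "env_summary", "reliability_icc",
                 "equivalence", "compare", "spectral_summary"):
        p = outdir / f"{name}.csv"
        if p.exists():
            df = pd.read_csv(p)
            summary[name] = {"rows": len(df),
                             "columns": list(df.columns)}
            if name == "reliability_icc":
                summary["icc_by_variable"] = {
                    v: g.set_index("comparison")["icc"].round(3).to_dict()
                    for v, g in df.groupby("variable")
                }
            if name == "equivalence":
                eq = df.dropna(subset=["equivalent"]) if "equivalent" in df else df
                summary["equivalent_fraction"] = (
                    float(eq["equivalent"].mean()) if len(eq) else None
                )
    (outdir / "report.json").write_text(json.dumps(summary, indent=1))
    _write_manifest(cfg, outdir, "report", {})
    return outdir
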