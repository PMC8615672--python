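"""End-to-end orchestration: epochs -> scoring -> phase -> rhythm metrics
-> group statistics, with reproducible configuration and reporting.

``run_pipeline`` takes a :class:`RunConfig` pointing at epoch/diary CSVs
(or an in-memory cohort), applies inclusion QC, computes per-participant
sleep and circadian measures, assembles the cohort-by-measure summary
(mean and SD per diagnostic group x age band), runs the Shapiro-gated
permutation ANOVAs with per-factor Holm correction across measures, fits
the hierarchical cognitive models where cognitive columns are present, and
derives the DS-vs-TD group contrasts.  The whole run is a pure function of
(input files, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import DiaryRecord, EpochSeries, qc_inclusion, read_diary_csv, read_epoch_csv, trim_to_full_days
from .npcra import circadian_metrics
from .phase import circular_mean_hours, cosinor_fit, template_match_offsets, template_match_onsets
from .scoring import resolve_rest_intervals, score_epochs, summarize_sleep
from .spectral import fft_circadian_power, periodogram
from .stats import HierarchicalRhythmModel, anova_with_gate, holm_correct

__all__ = [
    "RunConfig",
    "RunResult",
    "participant_measures",
    "cohort_measures",
    "group_summary",
    "anova_table",
    "cognitive_models",
    "derive_group_contrasts",
    "run_pipeline",
]

#: Measures reported in the group-summary table, in presentation order.
SUMMARY_MEASURES = ["TST", "SE", "WASO", "onset", "offset", "acrophase",
                    "IS", "IV", "FFT", "L5", "M10"]

#: Outcome -> (transform, extra covariates) for the cognitive models.
COGNITIVE_MODEL_SPECS: dict[str, tuple[str, tuple[str, ...]]] = {
    "reaction_time": ("none", ("ef_accuracy",)),
    "brief_gec": ("none", ()),
    "verbal_recall": ("log", ()),
    "object_binding": ("log", ()),
    "visual_recall": ("sqrt", ()),
    "spatial_recall": ("none", ()),
    "scene_recall": ("none", ()),
    "kbit_verbal": ("none", ()),
}


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    input_dir: str | None = None
    diary_csv: str | None = None
    cohort_csv: str | None = None
    out_dir: str | None = None
    day_start_hour: float = 0.0
    template_bins_per_day: int = 96  # 15-min bins for template matching
    sleep_scoring: dict = field(default_factory=lambda: {
        "threshold": 40.0, "onset_rule_minutes": 10.0, "snap_window_minutes": 0.0})
    npcra: dict = field(default_factory=lambda: {"bin_hours": 1.0, "l5m10_mode": "profile"})
    spectral: dict = field(default_factory=lambda: {"window": "rect", "pad_factor": 1,
                                                   "band_mode": "peak"})
    stats: dict = field(default_factory=lambda: {"n_perm": 9999, "holm_family": "per_factor",
                                                 "interaction_alpha": 0.10})
    qc: dict = field(default_factory=lambda: {"min_consecutive_days": 5})
    seed: int = 0
    make_figures: bool = False

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def participant_measures(
    series: EpochSeries,
    diary: DiaryRecord | None = None,
    config: RunConfig | None = None,
) -> dict | None:
    """All per-participant measures, or None when inclusion QC fails."""
    cfg = config or RunConfig()
    verdict = qc_inclusion(series, diary, day_start_hour=cfg.day_start_hour, **cfg.qc)
    if not verdict.include:
        return {"participant_id": series.participant_id, "included": False,
                "qc_reasons": ",".join(verdict.reasons)}
    dm_fine = trim_to_full_days(series, cfg.day_start_hour)
    dm_tpl = dm_fine.rebin(cfg.template_bins_per_day)
    bins = int(round(24.0 / cfg.npcra["bin_hours"]))
    dm_hr = dm_fine.rebin(bins)

    labels = score_epochs(series, threshold=cfg.sleep_scoring["threshold"])
    onsets_tpl = template_match_onsets(dm_tpl)
    offsets_tpl = template_match_offsets(dm_tpl)
    intervals = resolve_rest_intervals(
        series, diary, snap_window_minutes=cfg.sleep_scoring["snap_window_minutes"],
        labels=labels, auto_markers=(offsets_tpl, onsets_tpl),
    )
    sleep = summarize_sleep(series, labels, intervals,
                            onset_rule_minutes=cfg.sleep_scoring["onset_rule_minutes"])
    cos = cosinor_fit(dm_hr)
    met = circadian_metrics(dm_fine, bin_hours=cfg.npcra["bin_hours"],
                            l5m10_mode=cfg.npcra["l5m10_mode"])
    pg = periodogram(dm_hr.flatten(), sample_hours=cfg.npcra["bin_hours"],
                     window=cfg.spectral["window"], pad_factor=cfg.spectral["pad_factor"])
    fft_rp = fft_circadian_power(pg, band_mode=cfg.spectral["band_mode"])
    dates = pd.date_range(dm_fine.first_day_date, periods=dm_fine.n_days)
    return {
        "participant_id": series.participant_id,
        "included": True,
        "qc_reasons": "",
        "n_days": dm_fine.n_days,
        "weekend_days": int((dates.dayofweek >= 5).sum()),
        "TST": sleep.tst,
        "SE": sleep.efficiency,
        "WASO": sleep.waso,
        "onset": circular_mean_hours(onsets_tpl),
        "offset": circular_mean_hours(offsets_tpl),
        "acrophase": cos.acrophase,
        "MESOR": cos.mesor,
        "amplitude": cos.amplitude,
        "IS": met.IS,
        "IV": met.IV,
        "L5": met.L5,
        "M10": met.M10,
        "RA": met.RA,
        "FFT": fft_rp,
    }


def cohort_measures(
    participants: list[tuple[EpochSeries, DiaryRecord | None]],
    cohort: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-participant measure table, joined with the cohort table if given."""
    rows = []
    for series, diary in participants:
        row = participant_measures(series, diary, config)
        if row is not None:
            rows.append(row)
    df = pd.DataFrame(rows)
    if cohort is not None:
        df = cohort.merge(df.drop(columns=["weekend_days"], errors="ignore"),
                          on="participant_id", how="inner")
    return df


def group_summary(measures: pd.DataFrame,
                  measure_cols: list[str] | None = None) -> pd.DataFrame:
    """Long-format mean/SD per measure per group x age cell."""
    cols = measure_cols or [c for c in SUMMARY_MEASURES if c in measures.columns]
    inc = measures[measures.get("included", True) == True]  # noqa: E712
    rows = []
    for (grp, ag), sub in inc.groupby(["group", "age_group"], observed=True):
        for m in cols:
            rows.append({"measure": m, "group": grp, "age_group": ag,
                         "n": sub[m].notna().sum(),
                         "mean": sub[m].mean(), "sd": sub[m].std(ddof=1)})
    return pd.DataFrame(rows)


def anova_table(
    measures: pd.DataFrame,
    measure_cols: list[str] | None = None,
    factors: tuple[str, str] = ("age_group", "group"),
    n_perm: int = 9999,
    seed: int = 0,
    holm_family: str = "per_factor",
) -> pd.DataFrame:
    """Shapiro-gated (permutation | Kruskal-Wallis) ANOVA for every measure.

    Holm correction is applied per factor across measures by default (all
    tests of the same factor form one family), or per model with
    ``holm_family="per_model"``.
    """
    cols = measure_cols or [c for c in SUMMARY_MEASURES if c in measures.columns]
    inc = measures[measures.get("included", True) == True]  # noqa: E712
    usable = [f for f in factors if inc[f].nunique() >= 2]
    if not usable:
        raise ValueError("no factor has two or more observed levels")
    results = []
    for k, m in enumerate(cols):
        res = anova_with_gate(inc, m, usable, n_perm=n_perm,
                              seed=None if seed is None else seed + k)
        results.append(res)
    table = pd.concat([r.summary() for r in results], ignore_index=True)
    table["p_holm"] = np.nan
    if holm_family == "per_factor":
        for term in table["term"].unique():
            mask = table["term"] == term
            table.loc[mask, "p_holm"] = holm_correct(table.loc[mask, "p"].to_numpy())
    else:
        for outc in table["outcome"].unique():
            mask = table["outcome"] == outc
            table.loc[mask, "p_holm"] = holm_correct(table.loc[mask, "p"].to_numpy())
    return table


def cognitive_models(
    measures: pd.DataFrame,
    outcomes: dict[str, tuple[str, tuple[str, ...]]] | None = None,
    group: str = "DS",
    interaction_alpha: float = 0.10,
) -> dict[str, object]:
    """Fit the hierarchical rhythm-cognition model for each present outcome."""
    specs = outcomes or COGNITIVE_MODEL_SPECS
    sub = measures[measures["group"] == group]
    fits = {}
    for outcome, (transform, extra) in specs.items():
        if outcome not in sub.columns or sub[outcome].notna().sum() < 10:
            continue
        extra = tuple(c for c in extra if c in sub.columns)
        model = HierarchicalRhythmModel(
            sub, outcome, transform=transform, extra_covariates=extra,
            interaction_alpha=interaction_alpha,
        )
        fits[outcome] = model.fit()
    return fits


def derive_group_contrasts(summary: pd.DataFrame,
                           hour_measures: tuple[str, ...] = ("onset", "offset", "acrophase"),
                           ) -> pd.DataFrame:
    """DS-vs-TD percent and absolute differences per measure per age band.

    Percent difference is 100 * (DS - TD) / TD rounded to integer percent;
    clock-hour measures additionally report the difference in minutes.
    Cells missing either group are omitted with a note row.
    """
    rows = []
    for (m, ag), sub in summary.groupby(["measure", "age_group"], observed=True):
        ds = sub[sub["group"] == "DS"]["mean"]
        td = sub[sub["group"] == "TD"]["mean"]
        if ds.empty or td.empty:
            rows.append({"measure": m, "age_group": ag, "note": "missing group cell"})
            continue
        d, t = float(ds.iloc[0]), float(td.iloc[0])
        row = {"measure": m, "age_group": ag, "DS_mean": d, "TD_mean": t,
               "abs_diff": d - t, "pct_diff": round(100.0 * (d - t) / t) if t else np.nan,
               "note": ""}
        if m in hour_measures:
            row["diff_minutes"] = round((d - t) * 60.0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    """Bundle of all tables a run produces, plus its manifest."""

    measures: pd.DataFrame
    summary: pd.DataFrame
    anovas: pd.DataFrame
    contrasts: pd.DataFrame
    models: dict
    manifest: dict

    def model_table(self) -> pd.DataFrame:
        rows = []
        for outcome, res in self.models.items():
            rows.append({
                "outcome": outcome, "transform": res.transform, "n": res.n,
                "F": res.fvalue, "rsquared": res.rsquared,
                "interaction_retained": res.interaction_retained,
                "p_IS": res.pvalues.get("IS", np.nan),
                "p_SE": res.pvalues.get("SE", np.nan),
                "p_age": res.pvalues.get("age", np.nan),
                "excluded": ";".join(map(str, res.excluded_ids)),
            })
        return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    participants: list[tuple[EpochSeries, DiaryRecord | None]] | None = None,
    cohort: pd.DataFrame | None = None,
) -> RunResult:
    """Execute the full analysis described by ``config``.

    Inputs come either from ``config.input_dir`` (epoch CSVs + diary.csv +
    cohort.csv) or in memory via ``participants``/``cohort``.

    Raises
    ------
    RuntimeError
        If every participant fails inclusion QC (reason codes listed).
    """
    if participants is None:
        if config.input_dir is None:
            raise ValueError("config.input_dir or in-memory participants required")
        root = Path(config.input_dir)
        diary_path = Path(config.diary_csv) if config.diary_csv else root / "diary.csv"
        diaries = read_diary_csv(diary_path) if diary_path.exists() else {}
        participants = []
        for f in sorted(root.glob("*.csv")):
            if f.name in {"diary.csv", "cohort.csv"}:
                continue
            series = read_epoch_csv(f, participant_id=f.stem)
            participants.append((series, diaries.get(f.stem)))
        if cohort is None:
            cohort_path = Path(config.cohort_csv) if config.cohort_csv else root / "cohort.csv"
            if cohort_path.exists():
                cohort = pd.read_csv(cohort_path, dtype={"participant_id": str})
    measures = cohort_measures(participants, cohort, config)
    included = measures[measures["included"]] if "included" in measures else measures
    if included.empty:
        reasons = sorted(set(",".join(measures.get("qc_reasons", pd.Series(dtype=str))).split(",")))
        raise RuntimeError(f"all participants failed QC; reasons: {reasons}")
    have_groups = {"group", "age_group"}.issubset(measures.columns)
    summary = group_summary(measures) if have_groups else pd.DataFrame()
    anovas = (
        anova_table(measures, n_perm=config.stats["n_perm"], seed=config.seed,
                    holm_family=config.stats["holm_family"])
        if have_groups else pd.DataFrame()
    )
    contrasts = derive_group_contrasts(summary) if not summary.empty else pd.DataFrame()
    models = (
        cognitive_models(measures, interaction_alpha=config.stats["interaction_alpha"])
        if have_groups else {}
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": len(participants),
        "n_included": int(included.shape[0]),
    }
    result = RunResult(measures, summary, anovas, contrasts, models, manifest)
    if config.out_dir:
        _write_report(result, config)
    return result


def _write_report(result: RunResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.measures.to_csv(out / "participant_measures.csv", index=False)
    result.summary.to_csv(out / "group_summary.csv", index=False)
    result.anovas.to_csv(out / "anova_results.csv", index=False)
    result.contrasts.to_csv(out / "group_contrasts.csv", index=False)
    result.model_table().to_csv(out / "model_results.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    config.to_yaml(out / "run_config.yaml")
    if config.make_figures:
        from .plotting import save_report_figures

        save_report_figures(result, out)
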