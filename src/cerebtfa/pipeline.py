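"""End-to-end study analysis: recordings in, cohort tables out.

``run_study`` drives the full procedure for a subjects x {baseline, LPS}
x {normoxia, hyperoxia, hypoxia} layout: each recording's trailing
steady-state window is resampled to 10 Hz and run through Welch
cross-spectral transfer function analysis; per-subject oxygen
vasoreactivity slopes are computed from last-4-minute channel means
against the same-condition normoxic reference; subjects whose
low-frequency coherence fails the 0.4 criterion are excluded from the
autoregulation summaries (but kept for vasoreactivity); and the cohort
is summarised as median/IQR with exact Wilcoxon signed-rank paired
comparisons, Holm-corrected within each family.

The analysis contains no randomness: identical inputs give
byte-identical rendered tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as _io
from .errors import InvalidConfigurationError, ValidationError
from .oxygen import BloodGasPanel, compute_covr, compute_covr_cao2
from .preprocess import (
    HemodynamicRecording,
    extract_analysis_window,
    resample_to_analysis_rate,
    segment_mean,
)
from .simulate import CONDITIONS, INTERVENTIONS, SyntheticCohort
from .spectral import (
    DEFAULT_BANDS,
    BandDefinition,
    BandSummary,
    WelchConfig,
    band_average,
    interpret_direction,
    transfer_function,
    welch_cross_spectra,
)
from .stats import PairedSample, holm_adjust, median_iqr, wilcoxon_signed_rank

#: Autoregulation metrics summarised and compared per band (the results-table columns).
AUTOREG_METRICS = ("map_sp", "mcav_sp", "gain", "normalised_gain", "phase", "coherence")


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis constants in one place, defaulting to the standard protocol."""

    welch: WelchConfig = field(default_factory=WelchConfig)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    coherence_threshold: float = 0.4
    analysis_window_s: float = 600.0  # trailing window fed to Welch
    mean_window_s: float = 240.0  # trailing window for reported channel means
    target_rate: float = 10.0  # Hz
    band_method: str = "binwise"
    #: Band whose coherence criterion drives subject exclusion.
    exclusion_band: str = "LF"


@dataclass(frozen=True)
class StudyCell:
    """One recording + blood-gas panel, by object or by file path."""

    recording: Union[HemodynamicRecording, str, Path]
    blood_gas: Optional[Union[BloodGasPanel, str, Path]] = None


@dataclass(frozen=True)
class StudyLayout:
    """The subjects x condition x intervention grid of inputs."""

    cells: Mapping[tuple[str, str, str], StudyCell]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("study layout is empty")

    @property
    def subject_ids(self) -> list[str]:
        return sorted({k[0] for k in self.cells})

    @classmethod
    def from_cohort(
        cls, cohort: SyntheticCohort, config: Optional[AnalysisConfig] = None
    ) -> "StudyLayout":
        cells = {
            key: StudyCell(recording=rec, blood_gas=cohort.panels.get(key))
            for key, rec in cohort.recordings.items()
        }
        return cls(cells=cells, config=config or AnalysisConfig())

    @classmethod
    def from_yaml(
        cls, path: Union[str, Path], config: Optional[AnalysisConfig] = None
    ) -> "StudyLayout":
        """Load a ``layout.yaml`` study description; paths resolve beside it."""
        import yaml

        path = Path(path)
        spec = yaml.safe_load(path.read_text())
        base = path.parent
        cells: dict = {}
        for sid, conds in spec["subjects"].items():
            for condition, interventions in conds.items():
                for intervention, entry in interventions.items():
                    cells[(sid, condition, intervention)] = StudyCell(
                        recording=base / entry["recording"],
                        blood_gas=base / entry["blood_gas"] if entry.get("blood_gas") else None,
                    )
        return cls(cells=cells, config=config or AnalysisConfig())


@dataclass
class CohortTable:
    """Everything the study analysis produced, ready for rendering.

    ``per_recording`` holds one row per recording x band with the raw
    band summaries; ``summaries`` the cohort median/IQR over included
    subjects; ``comparisons`` the Wilcoxon/Holm paired tests;
    ``covr``/``covr_summary``/``covr_comparisons`` the vasoreactivity
    results (all subjects); ``exclusions`` and ``withheld`` the audit
    log; ``verdicts`` the per-band qualitative reading of the
    baseline-vs-LPS normoxia contrast; ``params`` the analysis constants
    used.
    """

    per_recording: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    covr: pd.DataFrame
    covr_summary: pd.DataFrame
    covr_comparisons: pd.DataFrame
    exclusions: list[dict]
    withheld: list[dict]
    verdicts: dict
    params: dict
    excluded_subjects: list[str]


def _resolve_recording(cell: StudyCell, key: tuple[str, str, str]) -> HemodynamicRecording:
    rec = cell.recording
    if isinstance(rec, HemodynamicRecording):
        return rec
    sid, condition, intervention = key
    return _io.read_recording(rec, subject_id=sid, condition=condition, intervention=intervention)


def _resolve_panel(cell: StudyCell) -> Optional[BloodGasPanel]:
    if cell.blood_gas is None:
        return None
    if isinstance(cell.blood_gas, BloodGasPanel):
        return cell.blood_gas
    return _io.read_panel(cell.blood_gas)


def analyse_recording(
    rec: HemodynamicRecording, config: AnalysisConfig = AnalysisConfig()
) -> tuple[list[BandSummary], dict]:
    """Window, resample and transfer-function-analyse a single recording.

    Returns the per-band summaries plus the last-minutes channel means
    used downstream for vasoreactivity.
    """
    rec = extract_analysis_window(rec, config.analysis_window_s)
    rec = resample_to_analysis_rate(rec, config.target_rate)
    est = welch_cross_spectra(rec.map, rec.mcav, config.welch)
    tf = transfer_function(est)
    summaries = band_average(
        tf,
        est,
        bands=config.bands,
        coherence_threshold=config.coherence_threshold,
        method=config.band_method,
    )
    means = {
        "map_mean": segment_mean(rec.map, rec.sampling_rate, config.mean_window_s),
        "mcav_mean": segment_mean(rec.mcav, rec.sampling_rate, config.mean_window_s),
        "n_segments": est.n_segments,
    }
    return summaries, means


def _paired_from_pivot(
    piv: pd.DataFrame, cell_a: tuple[str, str], cell_b: tuple[str, str]
) -> Optional[PairedSample]:
    if cell_a not in piv.columns or cell_b not in piv.columns:
        return None
    sub = piv[[cell_a, cell_b]].dropna()
    if sub.empty:
        return None
    return PairedSample(
        labels=tuple(sub.index), a=sub[cell_a].to_numpy(), b=sub[cell_b].to_numpy()
    )


def run_study(layout: StudyLayout) -> CohortTable:
    """Run the complete cohort analysis for a study layout."""
    cfg = layout.config
    band_names = [b.name for b in cfg.bands]

    rec_rows: list[dict] = []
    means: dict[tuple[str, str, str], dict] = {}
    panels: dict[tuple[str, str, str], Optional[BloodGasPanel]] = {}
    for key in sorted(layout.cells):
        cell = layout.cells[key]
        rec = _resolve_recording(cell, key)
        summaries, cell_means = analyse_recording(rec, cfg)
        means[key] = cell_means
        panels[key] = _resolve_panel(cell)
        sid, condition, intervention = key
        for s in summaries:
            rec_rows.append(
                {
                    "subject": sid,
                    "condition": condition,
                    "intervention": intervention,
                    "band": s.band.name,
                    "map_sp": s.map_power,
                    "mcav_sp": s.mcav_power,
                    "gain": s.gain,
                    "normalised_gain": s.normalised_gain,
                    "phase": s.phase,
                    "coherence": s.coherence,
                    "valid": s.valid,
                    "map_mean": cell_means["map_mean"],
                    "mcav_mean": cell_means["mcav_mean"],
                }
            )
    per_recording = pd.DataFrame(rec_rows)

    # --- subject exclusion on the coherence criterion ------------------
    exclusions: list[dict] = []
    crit = per_recording[per_recording["band"] == cfg.exclusion_band]
    for _, row in crit[~crit["valid"]].iterrows():
        exclusions.append(
            {
                "subject": row["subject"],
                "condition": row["condition"],
                "intervention": row["intervention"],
                "band": cfg.exclusion_band,
                "coherence": float(row["coherence"]),
                "reason": (
                    f"{cfg.exclusion_band} coherence {row['coherence']:.2f} < "
                    f"{cfg.coherence_threshold}; subject excluded from "
                    "autoregulation summaries"
                ),
            }
        )
    excluded_subjects = sorted({e["subject"] for e in exclusions})
    included_subjects = [s for s in layout.subject_ids if s not in excluded_subjects]
    autoreg = per_recording[per_recording["subject"].isin(included_subjects)]

    # --- cohort median/IQR summaries -----------------------------------
    withheld: list[dict] = []
    sum_rows: list[dict] = []
    grid = sorted(
        {(r["condition"], r["intervention"]) for r in rec_rows},
        key=lambda ci: (CONDITIONS.index(ci[0]), INTERVENTIONS.index(ci[1])),
    )
    for band in band_names:
        for condition, intervention in grid:
            sel = autoreg[
                (autoreg["band"] == band)
                & (autoreg["condition"] == condition)
                & (autoreg["intervention"] == intervention)
            ]
            if sel.empty:
                withheld.append(
                    {
                        "band": band,
                        "condition": condition,
                        "intervention": intervention,
                        "reason": "all subjects excluded; summary withheld",
                    }
                )
                continue
            for metric in AUTOREG_METRICS:
                med, q1, q3 = median_iqr(sel[metric].values)
                sum_rows.append(
                    {
                        "band": band,
                        "condition": condition,
                        "intervention": intervention,
                        "metric": metric,
                        "n": int(len(sel)),
                        "median": med,
                        "q1": q1,
                        "q3": q3,
                    }
                )
    summary_cols = ["band", "condition", "intervention", "metric", "n", "median", "q1", "q3"]
    summaries = pd.DataFrame(sum_rows, columns=summary_cols)

    # --- paired comparisons with Holm correction per family ------------
    conditions = sorted({c for c, _ in grid}, key=CONDITIONS.index)
    interventions = sorted({i for _, i in grid}, key=INTERVENTIONS.index)
    comp_rows: list[dict] = []
    for band in band_names:
        bdf = autoreg[autoreg["band"] == band]
        for metric in AUTOREG_METRICS:
            piv = bdf.pivot_table(
                index="subject", columns=["condition", "intervention"], values=metric
            )
            families: dict[str, list[dict]] = {"within_condition": [], "across_condition": []}
            if "normoxia" in interventions:
                for condition in conditions:
                    for intervention in interventions:
                        if intervention == "normoxia":
                            continue
                        sample = _paired_from_pivot(
                            piv, (condition, intervention), (condition, "normoxia")
                        )
                        if sample is None:
                            continue
                        families["within_condition"].append(
                            {
                                "comparison": f"{condition}: {intervention} vs normoxia",
                                "sample": sample,
                            }
                        )
            if len(conditions) == 2:
                for intervention in interventions:
                    sample = _paired_from_pivot(
                        piv, (conditions[1], intervention), (conditions[0], intervention)
                    )
                    if sample is None:
                        continue
                    families["across_condition"].append(
                        {
                            "comparison": f"{intervention}: {conditions[1]} vs {conditions[0]}",
                            "sample": sample,
                        }
                    )
            for family, entries in families.items():
                if not entries:
                    continue
                results = [wilcoxon_signed_rank(e["sample"]) for e in entries]
                adjusted = holm_adjust([r.p_raw for r in results])
                for e, r, p_adj in zip(entries, results, adjusted):
                    comp_rows.append(
                        {
                            "band": band,
                            "metric": metric,
                            "family": family,
                            "comparison": e["comparison"],
                            "n": r.n_effective,
                            "statistic": r.statistic,
                            "p_raw": r.p_raw,
                            "p_holm": float(p_adj),
                            "method": r.method,
                        }
                    )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["band", "metric", "family", "comparison", "n", "statistic",
                 "p_raw", "p_holm", "method"],
    )

    # --- oxygen vasoreactivity (all subjects, excluded ones included) ---
    covr_rows: list[dict] = []
    for sid in layout.subject_ids:
        for condition in conditions:
            ref_key = (sid, condition, "normoxia")
            if ref_key not in means or panels.get(ref_key) is None:
                continue
            for direction in ("hyperoxia", "hypoxia"):
                key = (sid, condition, direction)
                if key not in means or panels.get(key) is None:
                    continue
                ref_panel, test_panel = panels[ref_key], panels[key]
                try:
                    r_pa = compute_covr(
                        means[ref_key]["mcav_mean"],
                        means[key]["mcav_mean"],
                        ref_panel.paO2,
                        test_panel.paO2,
                    )
                    r_ca = compute_covr_cao2(
                        means[ref_key]["mcav_mean"],
                        means[key]["mcav_mean"],
                        ref_panel.caO2,
                        test_panel.caO2,
                    )
                except ValidationError:
                    continue
                covr_rows.append(
                    {
                        "subject": sid,
                        "condition": condition,
                        "direction": direction,
                        "slope_paO2": r_pa.slope,
                        "slope_caO2": r_ca.slope,
                        "delta_mcav_pct": r_pa.delta_mcav_pct,
                        "delta_paO2_kPa": r_pa.delta_x,
                        "delta_caO2_mM": r_ca.delta_x,
                    }
                )
    covr = pd.DataFrame(covr_rows)

    covr_sum_rows: list[dict] = []
    covr_comp_rows: list[dict] = []
    if not covr.empty:
        for direction in ("hyperoxia", "hypoxia"):
            for variant in ("slope_paO2", "slope_caO2"):
                for condition in conditions:
                    sel = covr[
                        (covr["direction"] == direction) & (covr["condition"] == condition)
                    ]
                    if sel.empty:
                        continue
                    med, q1, q3 = median_iqr(sel[variant].values)
                    covr_sum_rows.append(
                        {
                            "direction": direction,
                            "variant": variant,
                            "condition": condition,
                            "n": int(len(sel)),
                            "median": med,
                            "q1": q1,
                            "q3": q3,
                        }
                    )
        if len(conditions) == 2:
            for variant in ("slope_paO2", "slope_caO2"):
                entries = []
                for direction in ("hyperoxia", "hypoxia"):
                    piv = covr[covr["direction"] == direction].pivot_table(
                        index="subject", columns="condition", values=variant
                    )
                    if not set(conditions).issubset(piv.columns):
                        continue
                    piv = piv.dropna()
                    if piv.empty:
                        continue
                    sample = PairedSample(
                        labels=tuple(piv.index),
                        a=piv[conditions[1]].values,
                        b=piv[conditions[0]].values,
                    )
                    entries.append((direction, sample))
                if entries:
                    results = [wilcoxon_signed_rank(s) for _, s in entries]
                    adjusted = holm_adjust([r.p_raw for r in results])
                    for (direction, sample), r, p_adj in zip(entries, results, adjusted):
                        covr_comp_rows.append(
                            {
                                "variant": variant,
                                "direction": direction,
                                "comparison": f"{conditions[1]} vs {conditions[0]}",
                                "n": r.n_effective,
                                "statistic": r.statistic,
                                "p_raw": r.p_raw,
                                "p_holm": float(p_adj),
                                "method": r.method,
                            }
                        )
    covr_summary = pd.DataFrame(covr_sum_rows)
    covr_comparisons = pd.DataFrame(covr_comp_rows)

    # --- qualitative verdict on the condition effect (normoxia) --------
    verdicts: dict = {}
    if len(conditions) == 2 and "normoxia" in interventions and not summaries.empty:
        for band_def in cfg.bands:
            med = {}
            for condition in conditions:
                sel = summaries[
                    (summaries["band"] == band_def.name)
                    & (summaries["condition"] == condition)
                    & (summaries["intervention"] == "normoxia")
                ].set_index("metric")
                if sel.empty:
                    med[condition] = None
                    continue
                coh = float(sel.loc["coherence", "median"])
                med[condition] = BandSummary(
                    band=band_def,
                    gain=float(sel.loc["gain", "median"]),
                    normalised_gain=float(sel.loc["normalised_gain", "median"]),
                    phase=float(sel.loc["phase", "median"]),
                    coherence=coh,
                    map_power=float(sel.loc["map_sp", "median"]),
                    mcav_power=float(sel.loc["mcav_sp", "median"]),
                    valid=coh >= cfg.coherence_threshold,
                )
            if med[conditions[0]] is not None and med[conditions[1]] is not None:
                verdicts[band_def.name] = interpret_direction(
                    med[conditions[0]], med[conditions[1]]
                )

    params = {
        "segment_length": cfg.welch.segment_length,
        "overlap_s": cfg.welch.overlap_s,
        "window": cfg.welch.window,
        "sampling_rate": cfg.welch.sampling_rate,
        "bands": [(b.name, b.f_lo, b.f_hi) for b in cfg.bands],
        "coherence_threshold": cfg.coherence_threshold,
        "analysis_window_s": cfg.analysis_window_s,
        "mean_window_s": cfg.mean_window_s,
        "target_rate": cfg.target_rate,
        "band_method": cfg.band_method,
        "exclusion_band": cfg.exclusion_band,
        "n_subjects": len(layout.subject_ids),
        "n_excluded": len(excluded_subjects),
    }
    return CohortTable(
        per_recording=per_recording,
        summaries=summaries,
        comparisons=comparisons,
        covr=covr,
        covr_summary=covr_summary,
        covr_comparisons=covr_comparisons,
        exclusions=exclusions,
        withheld=withheld,
        verdicts=verdicts,
        params=params,
        excluded_subjects=excluded_subjects,
    )


def _fmt_median(df: pd.DataFrame) -> pd.Series:
    return df.apply(
        lambda r: f"{r['median']:.3g} ({r['q1']:.3g}–{r['q3']:.3g})", axis=1
    )


def render_tables(
    table: CohortTable,
    outdir: Union[str, Path],
    format: str = "csv",
    bands: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Write the cohort tables as delimited files plus a structured log.

    Rows follow the canonical band order (VLF, LF, HF blocks); every
    number is copied from the already-computed table (the renderer never
    recomputes). ``bands`` optionally restricts output to a subset.
    """
    seps = {"csv": ",", "tsv": "\t"}
    if format not in seps:
        raise InvalidConfigurationError(
            f"unknown format {format!r}; expected one of {sorted(seps)}"
        )
    sep = seps[format]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    band_order = [b for b, _, _ in table.params["bands"]]
    if bands is not None:
        unknown = set(bands) - set(band_order)
        if unknown:
            raise InvalidConfigurationError(f"unknown bands requested: {sorted(unknown)}")
        band_order = [b for b in band_order if b in bands]

    def order_bands(df: pd.DataFrame) -> pd.DataFrame:
        df = df[df["band"].isin(band_order)].copy()
        df["band"] = pd.Categorical(df["band"], categories=band_order, ordered=True)
        return df.sort_values(df.columns.tolist(), kind="stable").reset_index(drop=True)

    summaries = order_bands(table.summaries)
    summaries["formatted"] = _fmt_median(summaries)
    paths = {
        "autoregulation_summary": summaries,
        "autoregulation_comparisons": order_bands(table.comparisons),
        "per_recording": order_bands(table.per_recording),
        "covr_subjects": table.covr,
        "covr_comparisons": table.covr_comparisons,
        "exclusions": pd.DataFrame(table.exclusions),
    }
    if not table.covr_summary.empty:
        cs = table.covr_summary.copy()
        cs["formatted"] = _fmt_median(cs)
        paths["covr_summary"] = cs
    for name, df in paths.items():
        p = outdir / f"{name}.{format}"
        df.to_csv(p, sep=sep, index=False, float_format="%.6g")
        written[name] = p

    import json

    results = {
        "params": table.params,
        "excluded_subjects": table.excluded_subjects,
        "withheld": table.withheld,
        "verdicts": {
            band: {
                "gain": v.gain,
                "normalised_gain": v.normalised_gain,
                "phase": v.phase,
                "withheld": v.withheld,
                "reason": v.reason,
            }
            for band, v in table.verdicts.items()
            if band in band_order
        },
    }
    p = outdir / "results.json"
    p.write_text(json.dumps(results, indent=1, sort_keys=True))
    written["results"] = p
    return written
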