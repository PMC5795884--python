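"""Pipeline orchestration and report rendering.

:func:`run_pipeline` executes the full desk-scale study on the synthetic
cohort — simulation, preprocessing, blink-EOG quantification, coherence
matchup, and leave-one-seizure-out detection — and writes figure/table-
ready CSVs plus a frozen copy of the configuration into a run directory.
Every number in a rendered table is recomputable from the per-patient CSVs
next to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmarks import (
    CohortScale,
    run_detection_benchmark,
    run_eog_benchmark,
    run_matchup_benchmark,
)
from .detection import PerformanceReport, SvmConfig
from .spectral import round_half_up

__all__ = ["RunConfig", "run_pipeline", "render_tables", "performance_frame"]

log = logging.getLogger("earseiz")


@dataclass
class RunConfig:
    """Everything that, together with the seed, determines a pipeline run."""

    seed: int = 0
    out_dir: str = "earseiz_run"
    scale: CohortScale = field(default_factory=CohortScale)
    svm: SvmConfig = field(default_factory=SvmConfig)
    run_eog: bool = True
    run_matchup: bool = True
    run_detection: bool = True
    include_channel_subset: bool = True
    eog_n_patients: int = 5
    eog_segment_s: float = 300.0
    matchup_n_patients: int = 4
    detection_n_patients: int | None = None  # None -> all 12
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def performance_frame(report: PerformanceReport) -> pd.DataFrame:
    """Per-patient detection results as a tidy frame."""
    return pd.DataFrame(
        {
            "pid": report.patient_ids(),
            "montage": report.montage_label,
            "n_seizures": [p.n_seizures for p in report.per_patient],
            "n_detected": [p.n_detected for p in report.per_patient],
            "n_false": [p.n_false for p in report.per_patient],
            "tested_hours": [p.tested_hours for p in report.per_patient],
            "sensitivity_pct": report.sensitivities(),
            "fdr_per_hour": report.fdrs(),
            "single_seizure_protocol": [
                p.single_seizure_protocol for p in report.per_patient
            ],
        }
    )


def _aggregate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Median (min max) and mean +/- SD rows per montage, 2-decimal half-up."""
    rows = []
    for montage, grp in df.groupby("montage", sort=False):
        for metric, col in (
            ("sensitivity_pct", "sensitivity_pct"),
            ("fdr_per_hour", "fdr_per_hour"),
        ):
            vals = grp[col].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "montage": montage,
                    "metric": metric,
                    "median": round_half_up(float(np.median(vals))),
                    "min": round_half_up(float(np.min(vals))),
                    "max": round_half_up(float(np.max(vals))),
                    "mean": round_half_up(float(np.mean(vals))),
                    "sd": round_half_up(sd),
                }
            )
    return pd.DataFrame(rows)


def render_tables(run_dir) -> dict[str, Path]:
    """Aggregate the per-patient detection CSV of a run directory.

    Writes ``detection_aggregate.csv`` and a Markdown twin with
    "Median (min max)" and "Mean ± SD" rows, mirroring the clinical
    reporting convention.
    """
    run_dir = Path(run_dir)
    src = run_dir / "detection_per_patient.csv"
    if not src.exists():
        raise FileNotFoundError(f"no detection_per_patient.csv under {run_dir}")
    df = pd.read_csv(src)
    if df.empty:
        raise ValueError("empty per-patient report")
    agg = _aggregate_frame(df)
    csv_path = run_dir / "detection_aggregate.csv"
    agg.to_csv(csv_path, index=False)

    md_lines = ["| montage | metric | Median (min max) | Mean ± SD |",
                "|---|---|---|---|"]
    for _, r in agg.iterrows():
        md_lines.append(
            f"| {r['montage']} | {r['metric']} | "
            f"{r['median']:.2f} ({r['min']:.2f} {r['max']:.2f}) | "
            f"{r['mean']:.2f} ± {r['sd']:.2f} |"
        )
    md_path = run_dir / "detection_aggregate.md"
    md_path.write_text("\n".join(md_lines) + "\n", encoding="utf-8")
    return {"csv": csv_path, "markdown": md_path}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        (out / "config.yaml").write_text(
            yaml.safe_dump(cfg.to_dict(), sort_keys=False), encoding="utf-8"
        )
        log.info("pipeline start, seed=%d", cfg.seed)

        if cfg.run_eog:
            log.info("blink-EOG quantification (%d patients)", cfg.eog_n_patients)
            eog = run_eog_benchmark(
                seed=cfg.seed, n_patients=cfg.eog_n_patients,
                segment_s=cfg.eog_segment_s,
            )
            amp = pd.DataFrame(eog["amplitudes"])
            amp.insert(0, "patient", np.arange(1, len(amp) + 1))
            amp.to_csv(out / "eog_amplitudes.csv", index=False)
            if eog["wilcoxon_vs_frontal"]:
                pd.DataFrame(
                    {
                        "channel": list(eog["wilcoxon_vs_frontal"]),
                        "p_value": [
                            t["p_value"] for t in eog["wilcoxon_vs_frontal"].values()
                        ],
                    }
                ).to_csv(out / "eog_wilcoxon.csv", index=False)

        if cfg.run_matchup:
            log.info("coherence matchup (%d patients)", cfg.matchup_n_patients)
            rows = run_matchup_benchmark(
                seed=cfg.seed, n_patients=cfg.matchup_n_patients, scale=cfg.scale
            )
            pd.DataFrame(rows).to_csv(out / "matchup_per_patient.csv", index=False)

        if cfg.run_detection:
            log.info("leave-one-seizure-out detection")
            det = run_detection_benchmark(
                seed=cfg.seed,
                scale=cfg.scale,
                svm_cfg=dataclasses.replace(cfg.svm, seed=cfg.seed),
                include_channel_subset=cfg.include_channel_subset,
                n_patients=cfg.detection_n_patients,
            )
            frames = [performance_frame(det["scalp"]), performance_frame(det["ear"])]
            events = {
                lab: [p.events_per_seizure for p in det[lab].per_patient]
                for lab in ("scalp", "ear")
            }
            if cfg.include_channel_subset:
                for role, rep in det["subset"]["reports"].items():
                    frames.append(performance_frame(rep))
            per_patient = pd.concat(frames, ignore_index=True)
            per_patient.to_csv(out / "detection_per_patient.csv", index=False)
            (out / "detection_events.json").write_text(
                json.dumps(events, indent=1), encoding="utf-8"
            )
            comparisons = {"scalp_vs_ear": det["scalp_vs_ear_p"]}
            if cfg.include_channel_subset:
                comparisons["ear_channel_pairs"] = {
                    f"{a}_vs_{b}": p for (a, b), p in det["subset"]["pairwise_p"].items()
                }
            (out / "detection_comparisons.json").write_text(
                json.dumps(comparisons, indent=1), encoding="utf-8"
            )
            render_tables(out)

        log.info("pipeline done: %s", out)
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
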