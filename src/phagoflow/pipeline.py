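"""End-to-end orchestration: read samples, gate, quantify, run cohort stats.

A run consumes a sample sheet plus FCS files and produces, under the output
directory:

* ``per_sample_metrics.csv``   one row per patient x day x incubation time
* ``subset_percentages.csv``   the three CD16/CD62L subset percentages
* ``cohort_stats.json``        GEE betas, per-day Mann-Whitney tests,
                               healthy reference bands and band comparisons
* ``run_log.json``             seed, config, thresholds and quarantined samples

Per-sample failures are quarantined and listed; the cohort stage runs on the
surviving samples with an explicit exclusion report.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .fcs_io import ChannelMap, read_fcs, read_sample_sheet, meta_from_row
from .function_metrics import compute_sample_metrics
from .gating import GateConfig, gate_sample

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")

#: Metrics carried into the cohort layer (at the 60-min readout).
COHORT_METRICS = (
    "phagocytosis_pct", "mean_acid_ratio", "mfi_pf520", "mfi_phrodo",
    "pct_CD16dim_CD62Lbright", "pct_CD16bright_CD62Lbright", "pct_CD16bright_CD62Ldim",
)


@dataclass
class RunConfig:
    sample_sheet: str | Path = "sample_sheet.csv"
    fcs_dir: str | Path = "."
    outdir: str | Path = "results"
    gate: GateConfig = field(default_factory=GateConfig)
    channel_map: ChannelMap = field(default_factory=ChannelMap.identity)
    mfi_statistic: str = "mean"  # or "median"
    readout_incubation_min: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.gate.seed = self.seed


def process_samples(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Gate and quantify every sample on the sheet.

    Returns the tidy per-sample metrics frame and the quarantine list (one
    dict per failed sample with the error message).
    """
    sheet = read_sample_sheet(config.sample_sheet)
    rows, quarantined = [], []
    for _, srow in sheet.iterrows():
        meta = meta_from_row(srow)
        try:
            table = read_fcs(Path(config.fcs_dir) / srow["fcs_path"],
                             config.channel_map, meta)
            gres = gate_sample(table, config.gate)
            m = compute_sample_metrics(table, gres, config.gate,
                                       statistic=config.mfi_statistic)
        except Exception as exc:
            quarantined.append({"fcs_path": str(srow["fcs_path"]),
                                "patient_id": meta.patient_id, "error": str(exc)})
            logger.warning("quarantined %s: %s", srow["fcs_path"], exc)
            continue
        row = {
            "patient_id": meta.patient_id, "group": meta.group, "day": meta.day,
            "incubation_min": meta.incubation_min, "temperature_c": meta.temperature_c,
            "n_neutrophils": m.n_neutrophils, "n_pf520_positive": m.n_pf520_positive,
            "phagocytosis_pct": m.phagocytosis_pct, "mean_acid_ratio": m.mean_acid_ratio,
            "mfi_pf520": m.mfi_pf520, "mfi_phrodo": m.mfi_phrodo,
            "pf520_cut": m.pf520_cut, "undefined": m.undefined,
        }
        for s, pct in (m.subset_percentages or {}).items():
            row[f"pct_{s}"] = pct
        rows.append(row)
    return pd.DataFrame(rows), quarantined


def metrics_to_cohort_table(metrics: pd.DataFrame, incubation_min: int) -> pd.DataFrame:
    """Reshape per-sample metrics (at the readout incubation time) into the
    tidy long cohort table the statistics layer consumes."""
    d = metrics[metrics["incubation_min"] == incubation_min]
    long = d.melt(
        id_vars=["patient_id", "group", "day"],
        value_vars=[m for m in COHORT_METRICS if m in d.columns],
        var_name="metric", value_name="value",
    ).dropna(subset=["value"])
    return long


def cohort_statistics(long: pd.DataFrame) -> dict:
    """GEE, per-day tests, reference bands and band comparisons per metric."""
    out: dict = {"metrics": {}}
    days = sorted(long["day"].unique())
    for metric in sorted(long["metric"].unique()):
        entry: dict = {}
        sub = long[long["metric"] == metric]
        try:
            gee = cs.fit_gee(long, metric)
            entry["gee"] = dataclasses.asdict(gee)
        except cs.CohortStatsError as exc:
            entry["gee"] = {"error": str(exc)}
        entry["per_day"] = [cs.per_timepoint_test(long, metric, d) for d in days]

        controls = sub.loc[sub["group"] == "healthy", "value"].to_numpy(float)
        if controls.size >= 2:
            band = cs.reference_band(controls, metric)
            entry["reference_band"] = dataclasses.asdict(band)
            comp = {}
            for g in ("infection", "no_infection"):
                comp[g] = {}
                for d in days:
                    vals = sub.loc[(sub["group"] == g) & (sub["day"] == d), "value"]
                    if len(vals):
                        gm = float(vals.mean())
                        comp[g][str(d)] = {
                            "mean": gm,
                            "vs_band": band.classify(gm),
                            "below_band_midpoint": bool(gm < band.midpoint),
                        }
            entry["band_comparison"] = comp
        else:
            entry["reference_band"] = {"unavailable": True, "n_controls": int(controls.size)}
        out["metrics"][metric] = entry
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a summary dict with paths, the stats report and the quarantine
    list.  Raises on configuration errors; per-sample errors are quarantined.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    metrics, quarantined = process_samples(config)
    if metrics.empty:
        raise RuntimeError("no sample survived processing")
    metrics = metrics.sort_values(
        ["group", "patient_id", "day", "incubation_min"]).reset_index(drop=True)
    metrics.to_csv(outdir / "per_sample_metrics.csv", index=False)

    subset_cols = ["patient_id", "group", "day", "incubation_min"] + [
        c for c in metrics.columns if c.startswith("pct_")]
    metrics[subset_cols].to_csv(outdir / "subset_percentages.csv", index=False)

    long = metrics_to_cohort_table(metrics, config.readout_incubation_min)
    stats_report = cohort_statistics(long)
    (outdir / "cohort_stats.json").write_text(
        json.dumps(stats_report, indent=1, default=_jsonable))

    log = {
        "seed": config.seed,
        "readout_incubation_min": config.readout_incubation_min,
        "mfi_statistic": config.mfi_statistic,
        "n_samples": int(len(metrics)),
        "quarantined": quarantined,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return {"outdir": str(outdir), "metrics": metrics, "stats": stats_report,
            "quarantined": quarantined}
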