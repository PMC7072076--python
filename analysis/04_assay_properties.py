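"""Assay-level properties: incubation kinetics, temperature, subsets.

Three stand-alone checks of the assay model, written to
results/assay_properties.json:

* phagocytosis kinetics over 10/20/40/60 min of incubation (should rise
  with time while the acidification ratio stabilizes);
* the temperature dependence from 0 to 37 degC (phagocytosis increases,
  acidification ratio stays within a few percent);
* a one-way ANOVA with Tukey follow-up of the per-patient mean
  acidification ratio across the three CD16/CD62L subsets at 60 min (the
  generator acidifies all subsets identically, so this is a null check).

Run from the repository root:  python analysis/04_assay_properties.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from phagoflow.cohort_stats import subset_anova
from phagoflow.fcs_io import SampleMeta
from phagoflow.function_metrics import (
    acidification_metrics,
    pf520_positive_threshold,
    subset_acid_ratios,
)
from phagoflow.gating import GateConfig, gate_sample
from phagoflow.synthetic_data import SynthConfig, simulate_sample

ROOT = Path(__file__).resolve().parents[1]


def kinetics(seed: int) -> dict:
    config = SynthConfig(seed=seed, events_per_sample=5000)
    out = {}
    for t in (10, 20, 40, 60):
        table, truth = simulate_sample(config, SampleMeta("p", "healthy", 0, t, 37.0))
        flags = truth["is_neutrophil"].to_numpy()
        cut = pf520_positive_threshold(table, flags, GateConfig())
        m = acidification_metrics(table, flags, cut, GateConfig())
        out[t] = {"phagocytosis_pct": round(m.phagocytosis_pct, 2),
                  "mean_acid_ratio": round(m.mean_acid_ratio, 4)}
    return out


def temperature(seed: int) -> dict:
    config = SynthConfig(seed=seed + 1, events_per_sample=10_000)
    out = {}
    for T in (0.0, 25.0, 37.0):
        table, truth = simulate_sample(config, SampleMeta("p", "healthy", 0, 60, T))
        flags = truth["is_neutrophil"].to_numpy()
        cut = pf520_positive_threshold(table, flags, GateConfig())
        m = acidification_metrics(table, flags, cut, GateConfig())
        out[T] = {"phagocytosis_pct": round(m.phagocytosis_pct, 2),
                  "mean_acid_ratio": round(m.mean_acid_ratio, 4)}
    return out


def subset_comparison(seed: int, n_patients: int = 10) -> dict:
    by_subset = {s: [] for s in ("CD16dim_CD62Lbright", "CD16bright_CD62Lbright",
                                 "CD16bright_CD62Ldim")}
    for i in range(n_patients):
        config = SynthConfig(seed=seed * 100 + i, events_per_sample=8000)
        table, _ = simulate_sample(config, SampleMeta(f"p{i}", "healthy", 0, 60, 37.0))
        gres = gate_sample(table, GateConfig(seed=seed))
        cut = pf520_positive_threshold(table, gres.neutrophil, GateConfig())
        ratios = subset_acid_ratios(table, gres, cut, GateConfig())
        for s, v in ratios.items():
            if v is not None:
                by_subset[s].append(v)
    res = subset_anova({k: np.array(v) for k, v in by_subset.items()})
    return {"per_subset_mean": {k: round(float(np.mean(v)), 4) for k, v in by_subset.items()},
            "anova_F": round(res["F"], 4), "anova_p": round(res["p"], 4),
            "tukey": {k: round(v, 4) for k, v in res["tukey"].items()}}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    doc = {"kinetics_by_incubation_min": kinetics(args.seed),
           "by_temperature_c": temperature(args.seed),
           "subset_acidification": subset_comparison(args.seed)}
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "assay_properties.json").write_text(json.dumps(doc, indent=1))
    print(json.dumps(doc, indent=1))


if __name__ == "__main__":
    main()
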