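"""Simulate the default longitudinal cohort.

Generates the full study design — 6 infection / 9 no-infection patients
sampled on days 0, 3, 6, 10 and 15 plus 10 healthy controls, one 60-min
incubation sample each at 37 degC — and writes the FCS files, sample sheet
and generative truth under scratch/cohort/.  The binary event files are
scratch output; every downstream table derives from them reproducibly.

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

from phagoflow.synthetic_data import SynthConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--events", type=int, default=2000)
    args = ap.parse_args()

    outdir = ROOT / "scratch" / "cohort"
    config = SynthConfig(seed=args.seed, events_per_sample=args.events)
    sheet = simulate_cohort(config, outdir, incubation_minutes=(60,))
    n_pat = sheet[sheet.group != "healthy"]["patient_id"].nunique()
    n_hc = sheet[sheet.group == "healthy"]["patient_id"].nunique()
    print(f"wrote {len(sheet)} samples ({n_pat} patients x 5 days + {n_hc} controls) "
          f"at {args.events} events each to {outdir}")


if __name__ == "__main__":
    main()
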