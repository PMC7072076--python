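# phagoflow

Automated analysis of a whole-blood flow-cytometry assay of neutrophil
function after severe trauma. The assay incubates whole blood with
*S. aureus* bioparticles double-labeled with a pH-sensitive dye (pHrodo
Green, brighter as the phagolysosome acidifies) and a pH-insensitive dye
(PF520, reporting particle load), then reads two things per neutrophil:

* **phagocytosis** — the percentage of neutrophils that are PF520-positive;
* **phagosomal acidification** — the per-cell ratio

  *R* = pHrodo / PF520,

  which corrects the acidification signal for the number of ingested
  particles; the sample readout is the mean of *R* over PF520-positive
  neutrophils.

The cohort layer follows trauma patients at days 0 (< 12 h), 3, 6, 10 and
15 and compares patients who later develop infectious complications with
those who do not, using generalized estimating equations (identity link,
exchangeable working correlation, robust SEs clustered on patient),
per-day Mann-Whitney U tests, and a healthy-control 95% reference band.
Because no event-level patient data are available, the package ships a
synthetic-cytometry generator that emulates scatter-defined leukocyte
populations, CD16/CD62L neutrophil subsets, Poisson bioparticle uptake and
the two groups' temporal acidification trajectories, providing ground
truth for every stage.

The package is organised as an analysis project: the library under
`src/phagoflow/` (FCS 3.0/3.1 I/O, gating, metrics, cohort statistics,
generator, pipeline), numbered drivers under `analysis/`, and a `phagoflow`
CLI (`simulate`, `gate`, `metrics`, `stats`, `run`, `report`).

## Worked example

```bash
python analysis/01_simulate_cohort.py     # default cohort -> scratch/cohort/
python analysis/02_gate_and_quantify.py   # gating + metrics -> results/
python analysis/03_cohort_statistics.py   # GEE, bands, exact tests
```

The third step prints (seed 1):

```
acidification (mean pHrodo/PF520 ratio, 60 min):
  GEE infection-vs-no-infection beta = -0.2146 (robust p = 4.57e-07)
  healthy band [1.692, 1.850] (n = 10)
  infection vs band by day: {'0': 'above', '3': 'above', '6': 'below', '10': 'below', '15': 'below'}
  no_infection vs band by day: {'0': 'within', '3': 'within', '6': 'above', '10': 'above', '15': 'above'}
baseline-table exact tests (published counts):
  sex by outcome 2x2:        p = 0.580
  mechanism of injury 2x4:   p = 0.275
```

Read: patients destined for infection show *elevated* phagosomal
acidification immediately after trauma and at day 3, then fall below the
healthy band from day 6 on, while patients without infections rise above
the band in the second week — so the longitudinal group contrast (the GEE
beta) is negative. The exact tests recompute the published baseline-table
p-values from the printed demographic counts. A fourth driver
(`analysis/04_assay_properties.py`) checks the assay model itself:
phagocytosis rises with incubation time and temperature while the
acidification ratio stays flat, and the three CD16/CD62L subsets acidify
identically under the generator's null.

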