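"""Synthetic whole-blood cytometry generator for the phagocytosis assay.

No event-level patient data are deposited for this assay, so every pipeline
stage is exercised against simulated samples whose generative structure
matches what the analysis assumes:

* scatter-defined leukocyte populations (debris, lymphocytes, monocytes,
  granulocytes) as well-separated Gaussian clusters in FSC/SSC;
* a small CD16-negative eosinophil mode inside the granulocyte gate, and
  the three CD16/CD62L neutrophil subsets as log-normal marker modes;
* bioparticle uptake as a per-cell Poisson count ``k`` with rate
  ``lambda(t, T)`` increasing in incubation time and temperature;
* particle-load fluorescence: PF520 is the summed brightness of the ``k``
  ingested particles, pHrodo is the same brightness sum scaled by a
  strictly decreasing pH response ``f(pH)``, both under multiplicative
  log-normal measurement noise plus a low autofluorescence background
  (cells with ``k = 0`` show background only);
* phagosomal pH falling with incubation time to a depth set by a
  per-(group, day) acidification scale: the infection group is elevated at
  days 0-3 and low-normal from day 6 on, the no-infection group is normal
  early and elevated during days 6-15, healthy controls sit at 1.

Every draw flows from a single integer seed; identical seeds give identical
cohorts.  Ground-truth labels (population, subset, particle count) are
returned with every sample so gating and metric recovery can be scored.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs_io import ROLES, EventTable, SampleMeta, write_fcs

DAYS = (0, 3, 6, 10, 15)
INCUBATION_MIN = (10, 20, 40, 60)

#: Acidification scale by (group, day): the temporal pattern the cohort
#: analysis is meant to detect.  Infection-group acidification is elevated
#: immediately after trauma and at day 3, then drops to low-normal; the
#: no-infection group starts normal and rises above the healthy band in the
#: second week.
DEFAULT_TRAJECTORY: dict[str, dict[int, float]] = {
    "healthy": {d: 1.00 for d in DAYS},
    "infection": {0: 1.35, 3: 1.25, 6: 0.85, 10: 0.85, 15: 0.85},
    "no_infection": {0: 1.00, 3: 1.05, 6: 1.25, 10: 1.30, 15: 1.30},
}


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic cohort.

    Scatter units are arbitrary linear channels (0-1000 scale); marker
    intensities are log-normal in raw units and analysed after an asinh
    transform (cofactor 150).  ``population_fractions`` must sum to 1.
    """

    seed: int = 0
    events_per_sample: int = 5000

    # scatter populations: (FSC mean, SSC mean, FSC sd, SSC sd)
    population_fractions: dict[str, float] = field(default_factory=lambda: {
        "debris": 0.03, "lymphocyte": 0.27, "monocyte": 0.10, "granulocyte": 0.60,
    })
    scatter_params: dict[str, tuple[float, float, float, float]] = field(default_factory=lambda: {
        "debris": (25.0, 12.0, 8.0, 6.0),
        "lymphocyte": (250.0, 120.0, 25.0, 20.0),
        "monocyte": (450.0, 280.0, 35.0, 30.0),
        "granulocyte": (520.0, 600.0, 40.0, 45.0),
    })

    # markers (log-scale mean, log-scale sd of raw intensity)
    eosinophil_fraction: float = 0.05  # of granulocytes; CD16-negative
    subset_proportions: dict[str, float] = field(default_factory=lambda: {
        "CD16dim_CD62Lbright": 0.05,
        "CD16bright_CD62Lbright": 0.85,
        "CD16bright_CD62Ldim": 0.10,
    })
    cd16_logmeans: dict[str, float] = field(default_factory=lambda: {
        "eosinophil": math.log(100.0), "dim": math.log(5000.0), "bright": math.log(50000.0),
        "lymphocyte": math.log(80.0), "monocyte": math.log(1500.0), "debris": math.log(40.0),
    })
    cd62l_logmeans: dict[str, float] = field(default_factory=lambda: {
        "dim": math.log(1500.0), "bright": math.log(20000.0),
        "lymphocyte": math.log(12000.0), "monocyte": math.log(8000.0),
        "debris": math.log(60.0), "eosinophil": math.log(15000.0),
    })
    marker_sdlog: float = 0.28

    # bioparticle uptake: lambda(t, T) = lambda_max * (1 - exp(-t/tau)) * g(T)
    lambda_max: float = 3.0
    tau_uptake_min: float = 25.0
    temp_floor: float = 0.12      # g(0 degC)
    temp_power: float = 1.5       # g(T) = floor + (1-floor) * (T/37)^power

    # fluorescence model
    particle_brightness_logmean: float = math.log(8000.0)
    particle_brightness_sdlog: float = 0.25
    autofluor_logmean: float = math.log(100.0)
    autofluor_sdlog: float = 0.5
    noise_sdlog: float = 0.08     # multiplicative measurement noise

    # phagosomal pH: pH(t) = ph_rest - depth * a(group, day) * (1 - exp(-t/tau_ph))
    ph_rest: float = 7.4
    ph_depth: float = 1.6
    tau_ph_min: float = 20.0
    # pHrodo response f(pH): logistic, strictly decreasing on [4.5, 7.4]
    f_max: float = 2.2
    f_min: float = 0.05
    f_midpoint_ph: float = 6.5
    f_width_ph: float = 0.45

    trajectory: dict[str, dict[int, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_TRAJECTORY.items()})
    patient_cv: float = 0.08      # log-normal patient-level acidification scatter

    # cohort design (mirrors the 6 infection / 9 no-infection study split)
    n_infection: int = 6
    n_no_infection: int = 9
    n_controls: int = 10
    temperature_c: float = 37.0

    def validate(self) -> None:
        if abs(sum(self.population_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if not (0 <= self.eosinophil_fraction < 1):
            raise ValueError("eosinophil fraction must be in [0, 1)")
        if abs(sum(self.subset_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subset proportions must sum to 1")
        if self.lambda_max < 0 or self.tau_uptake_min <= 0:
            raise ValueError("uptake parameters must be positive")
        if not (0 < self.temp_floor <= 1) or self.temp_power <= 0:
            raise ValueError("temperature response must be increasing on [0, 37]")
        if self.f_max <= self.f_min or self.f_width_ph <= 0:
            raise ValueError("f(pH) must be strictly decreasing")
        for g, tab in self.trajectory.items():
            if any(a <= 0 for a in tab.values()):
                raise ValueError(f"acidification scales must be > 0 ({g})")

    # -- model functions ----------------------------------------------------

    def uptake_rate(self, t_min: float, temp_c: float) -> float:
        """Expected bioparticle count per neutrophil; non-decreasing in both
        incubation time and temperature (0-37 degC)."""
        g = self.temp_floor + (1.0 - self.temp_floor) * (max(temp_c, 0.0) / 37.0) ** self.temp_power
        return self.lambda_max * (1.0 - math.exp(-t_min / self.tau_uptake_min)) * g

    def phagosomal_ph(self, t_min: float, group: str, day: int, scale: float = 1.0) -> float:
        a = self.trajectory[group][day] * scale
        ph = self.ph_rest - self.ph_depth * a * (1.0 - math.exp(-t_min / self.tau_ph_min))
        return max(ph, 4.0)

    def ph_response(self, ph) -> np.ndarray | float:
        """pHrodo brightness factor: bounded logistic, brighter at low pH."""
        ph = np.asarray(ph, float)
        out = self.f_min + (self.f_max - self.f_min) / (1.0 + np.exp((ph - self.f_midpoint_ph) / self.f_width_ph))
        return out if out.ndim else float(out)


def _lognormal(rng: np.random.Generator, logmean: float, sdlog: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(logmean, sdlog, n))


def simulate_sample(
    config: SynthConfig,
    meta: SampleMeta,
    rng: np.random.Generator | None = None,
    acid_scale: float = 1.0,
) -> tuple[EventTable, pd.DataFrame]:
    """Draw one sample's events plus per-event ground truth.

    ``acid_scale`` multiplies the (group, day) acidification scale — used by
    :func:`simulate_cohort` to carry a per-patient random level.  Returns the
    event table and a truth frame with columns population, subset, k.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.events_per_sample

    pops = list(config.population_fractions)
    fractions = np.array([config.population_fractions[p] for p in pops])
    counts = rng.multinomial(n, fractions)

    population = np.repeat(pops, counts).astype(object)
    fsc = np.empty(n)
    ssc = np.empty(n)
    start = 0
    for p, c in zip(pops, counts):
        mf, ms, sf, ss = config.scatter_params[p]
        fsc[start:start + c] = rng.normal(mf, sf, c)
        ssc[start:start + c] = rng.normal(ms, ss, c)
        start += c

    # marker identities
    subset = np.full(n, "", dtype=object)
    is_gran = population == "granulocyte"
    gran_idx = np.where(is_gran)[0]
    is_eos = np.zeros(n, bool)
    if gran_idx.size:
        eos_mask = rng.random(gran_idx.size) < config.eosinophil_fraction
        is_eos[gran_idx[eos_mask]] = True
    is_neut = is_gran & ~is_eos
    neut_idx = np.where(is_neut)[0]
    subset_names = list(config.subset_proportions)
    if neut_idx.size:
        probs = np.array([config.subset_proportions[s] for s in subset_names])
        draw = rng.choice(len(subset_names), size=neut_idx.size, p=probs)
        subset[neut_idx] = np.array(subset_names, dtype=object)[draw]

    cd16 = np.empty(n)
    cd62l = np.empty(n)
    for p in ("debris", "lymphocyte", "monocyte"):
        m = population == p
        cd16[m] = _lognormal(rng, config.cd16_logmeans[p], 0.5, int(m.sum()))
        cd62l[m] = _lognormal(rng, config.cd62l_logmeans[p], 0.5, int(m.sum()))
    m = is_eos
    cd16[m] = _lognormal(rng, config.cd16_logmeans["eosinophil"], 0.5, int(m.sum()))
    cd62l[m] = _lognormal(rng, config.cd62l_logmeans["eosinophil"], 0.5, int(m.sum()))
    for s in subset_names:
        m = subset == s
        lvl16 = "dim" if s.startswith("CD16dim") else "bright"
        lvlL = "bright" if s.endswith("CD62Lbright") else "dim"
        cd16[m] = _lognormal(rng, config.cd16_logmeans[lvl16], config.marker_sdlog, int(m.sum()))
        cd62l[m] = _lognormal(rng, config.cd62l_logmeans[lvlL], config.marker_sdlog, int(m.sum()))

    # bioparticle uptake and the two particle channels (neutrophils only)
    k = np.zeros(n, dtype=int)
    lam = config.uptake_rate(meta.incubation_min, meta.temperature_c)
    k[neut_idx] = rng.poisson(lam, neut_idx.size)

    base = np.zeros(n)
    total_particles = int(k.sum())
    if total_particles:
        brightness = _lognormal(rng, config.particle_brightness_logmean,
                                config.particle_brightness_sdlog, total_particles)
        bounds = np.concatenate([[0], np.cumsum(k[k > 0])])
        sums = np.add.reduceat(brightness, bounds[:-1])
        base[k > 0] = sums

    ph = config.phagosomal_ph(meta.incubation_min, meta.group or "healthy", meta.day, acid_scale)
    f = config.ph_response(ph)
    noise_pf = np.exp(rng.normal(0.0, config.noise_sdlog, n))
    noise_ph = np.exp(rng.normal(0.0, config.noise_sdlog, n))
    auto_pf = _lognormal(rng, config.autofluor_logmean, config.autofluor_sdlog, n)
    auto_ph = _lognormal(rng, config.autofluor_logmean, config.autofluor_sdlog, n)
    pf520 = base * noise_pf + auto_pf
    phrodo = base * f * noise_ph + auto_ph

    events = np.column_stack([fsc, ssc, cd16, cd62l, phrodo, pf520])
    events = np.clip(events, 0.0, None)
    table = EventTable(events, ROLES, meta)
    truth = pd.DataFrame({
        "population": np.where(is_eos, "eosinophil", population),
        "is_neutrophil": is_neut,
        "subset": subset,
        "k": k,
    })
    return table, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def simulate_cohort(
    config: SynthConfig,
    outdir: str | Path,
    days: tuple[int, ...] = DAYS,
    incubation_minutes: tuple[int, ...] = INCUBATION_MIN,
    write_files: bool = True,
) -> pd.DataFrame:
    """Simulate the full longitudinal design and (optionally) write it out.

    One sample per patient x day x incubation time; healthy controls are
    acquired once (coded day 0).  Writes FCS 3.1 files, ``sample_sheet.csv``
    and ``truth.json`` under ``outdir``; partial output is removed on error.
    Returns the sample sheet with an extra in-memory column ``_table``
    holding the event tables (and ``_truth`` the truth frames) when
    ``write_files`` is False.
    """
    config.validate()
    if min(config.n_infection, config.n_no_infection) < 1:
        raise ValueError("need at least one patient per outcome group")
    outdir = Path(outdir)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)

    patients = (
        [("inf%02d" % i, "infection") for i in range(config.n_infection)]
        + [("non%02d" % i, "no_infection") for i in range(config.n_no_infection)]
        + [("hc%02d" % i, "healthy") for i in range(config.n_controls)]
    )
    patient_scale = {
        pid: float(np.exp(_sample_rng(config.seed, 9000 + j).normal(0.0, config.patient_cv)))
        for j, (pid, _) in enumerate(patients)
    }

    rows = []
    try:
        for j, (pid, group) in enumerate(patients):
            pdays = (0,) if group == "healthy" else days
            for day in pdays:
                for t in incubation_minutes:
                    meta = SampleMeta(pid, group, day, t, config.temperature_c)
                    rng = _sample_rng(config.seed, j, day, t)
                    table, truth = simulate_sample(config, meta, rng,
                                                   acid_scale=patient_scale[pid])
                    row = {
                        "patient_id": pid, "group": group, "day": day,
                        "incubation_min": t, "temperature_c": config.temperature_c,
                    }
                    if write_files:
                        fname = f"{pid}_d{day:02d}_t{t:02d}.fcs"
                        write_fcs(table, outdir / fname)
                        row["fcs_path"] = fname
                    else:
                        row["fcs_path"] = ""
                        row["_table"] = table
                        row["_truth"] = truth
                    rows.append(row)
    except Exception:
        if write_files and outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        raise

    sheet = pd.DataFrame(rows)
    if write_files:
        sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        truth_doc = {
            "config": {k: v for k, v in asdict(config).items()},
            "patient_acid_scale": patient_scale,
        }
        (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1, default=str))
    return sheet


def simulate_longitudinal_metric(
    n_per_group: int,
    delta: float,
    rho: float = 0.3,
    sigma: float = 0.3,
    days: tuple[int, ...] = DAYS,
    mu: float = 1.0,
    seed: int = 0,
    metric: str = "metric",
) -> pd.DataFrame:
    """Light-weight longitudinal cohort for estimator calibration.

    Per-patient responses share an exchangeable correlation ``rho``:
    y_ij = mu + delta * 1[infection] + day effect + b_i + e_ij with
    b_i ~ N(0, rho * sigma^2) and e_ij ~ N(0, (1 - rho) * sigma^2), so the
    total residual SD is ``sigma``.  Returns a tidy cohort table.
    """
    rng = np.random.default_rng(seed)
    day_effect = {d: 0.02 * i for i, d in enumerate(days)}
    rows = []
    for g, gname in ((1, "infection"), (0, "no_infection")):
        for i in range(n_per_group):
            pid = f"{gname[:3]}{i:02d}"
            b = rng.normal(0.0, math.sqrt(rho) * sigma)
            for d in days:
                e = rng.normal(0.0, math.sqrt(1.0 - rho) * sigma)
                rows.append({
                    "patient_id": pid, "group": gname, "day": d, "metric": metric,
                    "value": mu + delta * g + day_effect[d] + b + e,
                })
    return pd.DataFrame(rows)
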