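"""Automated gating of whole-blood leukocyte events.

The hierarchy mirrors the assay's readout: leukocyte classes are separated on
forward/side scatter, neutrophils are the CD16-positive granulocytes
(excluding eosinophils), and neutrophils are subdivided into the three
CD16/CD62L maturity/activation subsets:

* CD16dim/CD62Lbright  — banded (immature) neutrophils
* CD16bright/CD62Lbright — mature neutrophils
* CD16bright/CD62Ldim  — activated / hypersegmented neutrophils

Marker channels are analysed after an inverse-hyperbolic-sine transform
(per-channel cofactor, default 150); scatter is used untransformed.  All cuts
are placed automatically (mixture fit on scatter, kernel-density valley on
markers) and every threshold is recorded so a run can be replayed exactly in
manual mode.  Events falling exactly on a cut are assigned to the
bright/positive side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import stats
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .fcs_io import EventTable

POPULATIONS = ("debris", "lymphocyte", "other", "granulocyte")
SUBSETS = ("CD16dim_CD62Lbright", "CD16bright_CD62Lbright", "CD16bright_CD62Ldim", "unclassified")


class GatingError(RuntimeError):
    pass


@dataclass
class GateConfig:
    """Configuration of the gating hierarchy.

    ``mode="auto"`` fits thresholds per sample; ``mode="manual"`` replays the
    supplied polygon and scalar cuts (all in transformed units for markers).
    """

    mode: str = "auto"
    cofactors: dict[str, float] = field(
        default_factory=lambda: {"CD16": 150.0, "CD62L": 150.0, "PHRODO": 150.0, "PF520": 150.0}
    )
    min_events: int = 200
    min_granulocytes: int = 200
    debris_quantile: float = 0.001
    fallback_quantile: float = 0.01
    seed: int = 0
    # manual-mode parameters
    manual_polygon: Sequence[tuple[float, float]] | None = None  # FSC/SSC granulocyte gate
    cd16_positive_cut: float | None = None
    cd16_dim_bright_cut: float | None = None
    cd62l_dim_bright_cut: float | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cofactors.values()):
            raise ValueError("asinh cofactors must be > 0")
        if self.mode not in ("auto", "manual"):
            raise ValueError(f"unknown gating mode {self.mode!r}")
        if self.mode == "manual":
            needed = (self.manual_polygon, self.cd16_positive_cut,
                      self.cd16_dim_bright_cut, self.cd62l_dim_bright_cut)
            if any(v is None for v in needed):
                raise ValueError("manual mode requires polygon and all scalar cuts")


@dataclass
class GatingResult:
    """Per-event labels plus the thresholds that produced them."""

    population: np.ndarray  # str per event
    neutrophil: np.ndarray  # bool per event
    subset: np.ndarray  # str per event ('' for non-neutrophils)
    thresholds: dict = field(default_factory=dict)
    subset_percentages: dict | None = None  # None when undefined (0 neutrophils)
    seed: int = 0

    @property
    def n_neutrophils(self) -> int:
        return int(self.neutrophil.sum())


def transform(table: EventTable, role: str, config: GateConfig) -> np.ndarray:
    """Channel intensities in gating units: asinh(x / cofactor) for marker
    channels, identity for scatter."""
    x = table.channel(role)
    cof = config.cofactors.get(role)
    return np.arcsinh(x / cof) if cof else x.copy()


# ---------------------------------------------------------------------------
# 1-D cut placement
# ---------------------------------------------------------------------------

def density_valley_cut(values: np.ndarray, fallback_quantile: float,
                       rel_peak_height: float = 0.02) -> tuple[float, str]:
    """Place a scalar cut at the deepest density valley between the two
    dominant modes of ``values``.

    A Gaussian KDE (Scott bandwidth) is evaluated on a 512-point grid; local
    maxima with height at least ``rel_peak_height`` of the global maximum
    count as modes.  The cut is the global density minimum between the
    leftmost and rightmost mode (the deepest inter-mode valley).  With fewer
    than two modes the cut falls back to the ``fallback_quantile`` empirical
    quantile.  Returns ``(cut, method)`` with method in {"valley", "quantile"}.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10 or np.ptp(values) == 0:
        return float(np.quantile(values, fallback_quantile)), "quantile"
    kde = stats.gaussian_kde(values)
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    peaks = peaks[dens[peaks] >= rel_peak_height * dens.max()]
    if len(peaks) < 2:
        return float(np.quantile(values, fallback_quantile)), "quantile"
    a, b = int(peaks[0]), int(peaks[-1])
    valley = a + int(np.argmin(dens[a : b + 1]))
    return float(grid[valley]), "valley"


# ---------------------------------------------------------------------------
# gating layers
# ---------------------------------------------------------------------------

def _empty_result(config: GateConfig) -> GatingResult:
    return GatingResult(
        population=np.array([], dtype=object),
        neutrophil=np.array([], dtype=bool),
        subset=np.array([], dtype=object),
        seed=config.seed,
    )

def _fit_scatter_mixture(xy: np.ndarray, seed: int) -> GaussianMixture:
    # k-means initialization, best of several restarts; deterministic in seed
    gmm = GaussianMixture(
        n_components=3, covariance_type="full", init_params="kmeans",
        n_init=4, random_state=seed, reg_covar=1e-3, max_iter=500,
    )
    gmm.fit(xy)
    return gmm


def _lymphocyte_component(gmm: GaussianMixture, min_weight: float = 0.05) -> int:
    # lowest-SSC component, ignoring trace components (e.g. a debris sliver)
    idx = np.where(gmm.weights_ >= min_weight)[0]
    if idx.size == 0:
        idx = np.arange(gmm.means_.shape[0])
    return int(idx[np.argmin(gmm.means_[idx, 1])])


def gate_granulocytes(table: EventTable, config: GateConfig) -> GatingResult:
    """Label every event as debris / lymphocyte / other / granulocyte.

    Auto mode fits a 3-component Gaussian mixture on (FSC, SSC) and assigns
    the components to lymphocyte, other (monocyte) and granulocyte by
    ascending SSC centre; events below a low FSC quantile of the fitted
    lymphocyte component are debris.  The mixture is first fitted on all
    events to locate the debris floor, then refitted on non-debris events so
    debris does not distort the lymphocyte component.  Manual mode labels
    events inside the supplied FSC/SSC polygon as granulocytes.
    """
    n = len(table)
    if n == 0:
        return _empty_result(config)
    if n < config.min_events:
        raise GatingError(f"{n} events < configured minimum {config.min_events}")

    xy = np.column_stack([table.channel("FSC"), table.channel("SSC")])
    population = np.full(n, "other", dtype=object)

    if config.mode == "manual":
        poly = MplPath(np.asarray(config.manual_polygon, dtype=float))
        inside = poly.contains_points(xy)
        population[inside] = "granulocyte"
        population[~inside] = "other"
        return GatingResult(population, np.zeros(n, bool), np.full(n, "", dtype=object),
                            thresholds={"scatter": "manual_polygon"}, seed=config.seed)

    gmm = _fit_scatter_mixture(xy, config.seed)
    if not gmm.converged_:
        if config.manual_polygon is not None:
            warnings.warn("scatter mixture did not converge; using manual polygon")
            poly = MplPath(np.asarray(config.manual_polygon, dtype=float))
            inside = poly.contains_points(xy)
            population[inside] = "granulocyte"
            return GatingResult(population, np.zeros(n, bool), np.full(n, "", dtype=object),
                                thresholds={"scatter": "manual_polygon_fallback"}, seed=config.seed)
        raise GatingError("scatter mixture did not converge and no manual polygon given")

    # debris floor: low-FSC quantile of the fitted lymphocyte component, using
    # robust location/scale of its assigned events so debris contamination of
    # the component does not inflate the scale
    lymph0 = _lymphocyte_component(gmm)
    assigned = gmm.predict(xy) == lymph0
    fsc_l = xy[assigned, 0]
    mu = float(np.median(fsc_l))
    sd = float(1.4826 * np.median(np.abs(fsc_l - mu))) or float(fsc_l.std() + 1e-9)
    floor = norm.ppf(config.debris_quantile, loc=mu, scale=sd)
    debris = xy[:, 0] < floor
    population[debris] = "debris"

    keep = ~debris
    if debris.any():
        gmm = _fit_scatter_mixture(xy[keep], config.seed)
    order = np.argsort(gmm.means_[:, 1])  # ascending SSC centre
    comp_label = np.empty(3, dtype=object)
    comp_label[order] = ["lymphocyte", "other", "granulocyte"]
    population[keep] = comp_label[gmm.predict(xy[keep])]

    thresholds = {
        "debris_fsc_floor": float(floor),
        "scatter_means": gmm.means_.tolist(),
        "scatter_order_by_ssc": order.tolist(),
    }
    return GatingResult(population, np.zeros(n, bool), np.full(n, "", dtype=object),
                        thresholds=thresholds, seed=config.seed)


def gate_neutrophils(table: EventTable, result: GatingResult, config: GateConfig) -> GatingResult:
    """Flag CD16-positive granulocytes as neutrophils (excludes eosinophils).

    The CD16-positive cut is placed at the deepest density valley of the
    transformed CD16 distribution among granulocytes; a unimodal distribution
    falls back to the configured quantile cut.  Updates ``result`` in place
    and returns it.
    """
    gran = result.population == "granulocyte"
    n_gran = int(gran.sum())
    if n_gran == 0:
        raise GatingError("no granulocytes to gate neutrophils from")

    cd16 = transform(table, "CD16", config)[gran]
    if config.mode == "manual":
        cut, method = float(config.cd16_positive_cut), "manual"
    elif n_gran < config.min_granulocytes:
        warnings.warn(f"only {n_gran} granulocytes; quantile fallback for CD16 cut")
        cut, method = float(np.quantile(cd16, config.fallback_quantile)), "quantile"
    else:
        cut, method = density_valley_cut(cd16, config.fallback_quantile)

    flags = np.zeros(len(table), dtype=bool)
    flags[gran] = cd16 >= cut  # ties go to the positive side
    result.neutrophil = flags
    result.thresholds["cd16_positive_cut"] = cut
    result.thresholds["cd16_positive_method"] = method
    return result


def classify_subsets(table: EventTable, result: GatingResult, config: GateConfig) -> GatingResult:
    """Assign each neutrophil a CD16/CD62L quadrant label and compute the
    three named subset percentages (of all neutrophils).

    CD16dim/CD62Ldim cells are reported as ``unclassified`` and excluded from
    the three named subsets.  With zero neutrophils the percentages are left
    undefined (``None``), not zero.
    """
    neut = result.neutrophil
    subset = np.full(len(table), "", dtype=object)
    if neut.sum() == 0:
        result.subset = subset
        result.subset_percentages = None
        return result

    cd16 = transform(table, "CD16", config)[neut]
    cd62l = transform(table, "CD62L", config)[neut]
    if config.mode == "manual":
        cut16 = float(config.cd16_dim_bright_cut)
        cutL = float(config.cd62l_dim_bright_cut)
        m16 = mL = "manual"
    else:
        cut16, m16 = density_valley_cut(cd16, config.fallback_quantile)
        cutL, mL = density_valley_cut(cd62l, config.fallback_quantile)

    bright16 = cd16 >= cut16
    brightL = cd62l >= cutL
    lab = np.where(
        bright16 & brightL, "CD16bright_CD62Lbright",
        np.where(bright16 & ~brightL, "CD16bright_CD62Ldim",
                 np.where(~bright16 & brightL, "CD16dim_CD62Lbright", "unclassified")),
    )
    subset[neut] = lab
    n = float(neut.sum())
    result.subset = subset
    result.subset_percentages = {
        s: 100.0 * float((lab == s).sum()) / n for s in SUBSETS[:3]
    }
    result.thresholds.update({
        "cd16_dim_bright_cut": cut16, "cd16_dim_bright_method": m16,
        "cd62l_dim_bright_cut": cutL, "cd62l_dim_bright_method": mL,
    })
    return result


def gate_sample(table: EventTable, config: GateConfig) -> GatingResult:
    """Run the full hierarchy: populations -> neutrophils -> subsets."""
    result = gate_granulocytes(table, config)
    if len(table) == 0:
        return result
    result = gate_neutrophils(table, result, config)
    return classify_subsets(table, result, config)


def manual_replay_config(config: GateConfig, result: GatingResult,
                         polygon: Sequence[tuple[float, float]] | None = None) -> GateConfig:
    """Build a manual-mode config replaying the scalar cuts an auto run emitted."""
    return GateConfig(
        mode="manual",
        cofactors=dict(config.cofactors),
        min_events=config.min_events,
        min_granulocytes=config.min_granulocytes,
        debris_quantile=config.debris_quantile,
        fallback_quantile=config.fallback_quantile,
        seed=config.seed,
        manual_polygon=polygon if polygon is not None else [(0, 0), (1, 0), (1, 1)],
        cd16_positive_cut=result.thresholds["cd16_positive_cut"],
        cd16_dim_bright_cut=result.thresholds["cd16_dim_bright_cut"],
        cd62l_dim_bright_cut=result.thresholds["cd62l_dim_bright_cut"],
    )
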