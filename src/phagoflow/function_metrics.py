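"""Per-sample functional readouts of the phagocytosis/acidification assay.

Each sample (one patient, day and incubation time) yields:

* **phagocytosis** — the percentage of neutrophils that are PF520-positive,
  i.e. carry at least the particle-bound fluorescence of the pH-insensitive
  label;
* **acidification** — the per-cell ratio of pHrodo Green over PF520
  intensity, which corrects the pH-sensitive signal for the number of
  ingested bioparticles; the sample-level readout is the mean ratio over
  PF520-positive neutrophils (the ratio is undefined for cells that have
  ingested nothing);
* **channel MFIs** — mean (optionally median) PF520 and pHrodo fluorescence
  over PF520-positive neutrophils.

PF520 positivity is decided on asinh-transformed intensity; the ratio and
the MFIs are computed on raw (linear) intensities, since the
particle-number correction presumes linear signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fcs_io import EventTable, SampleMeta
from .gating import GateConfig, GatingResult, density_valley_cut, transform

INCUBATION_DESIGN = (10, 20, 40, 60)


class MetricsError(RuntimeError):
    pass


@dataclass
class FunctionMetrics:
    """Functional readouts for one sample.

    ``mean_acid_ratio`` and the MFIs are ``None`` (undefined, flagged via
    :attr:`undefined`) when no neutrophil is PF520-positive; ``phagocytosis_pct``
    is ``None`` when there are no neutrophils at all.
    """

    meta: SampleMeta
    n_neutrophils: int
    n_pf520_positive: int
    phagocytosis_pct: float | None
    mean_acid_ratio: float | None
    mfi_pf520: float | None
    mfi_phrodo: float | None
    pf520_cut: float | None = None
    undefined: bool = False
    subset_percentages: dict | None = None

    @property
    def incubation_min(self) -> int:
        return self.meta.incubation_min


def pf520_positive_threshold(
    table: EventTable,
    neutrophil_flags: np.ndarray,
    config: GateConfig,
    negative_reference: EventTable | None = None,
    reference_flags: np.ndarray | None = None,
    reference_percentile: float = 99.5,
) -> float:
    """Scalar PF520-positivity cut, in transformed units.

    With a negative reference sample (e.g. an on-ice incubation) the cut is
    the reference's 99.5th percentile of transformed PF520 among neutrophils.
    Without one, the cut is placed at the density valley of the sample's own
    transformed PF520 distribution (quantile fallback when unimodal).
    """
    if negative_reference is not None:
        ref = transform(negative_reference, "PF520", config)
        if reference_flags is not None:
            ref = ref[np.asarray(reference_flags, bool)]
        if ref.size == 0:
            import warnings

            warnings.warn("empty negative reference; falling back to density valley")
        else:
            return float(np.percentile(ref, reference_percentile))
    vals = transform(table, "PF520", config)[np.asarray(neutrophil_flags, bool)]
    cut, _ = density_valley_cut(vals, config.fallback_quantile)
    return cut


def phagocytosis_fraction(table: EventTable, neutrophil_flags: np.ndarray, cut: float,
                          config: GateConfig | None = None) -> float | None:
    """Percentage of neutrophils with transformed PF520 strictly above ``cut``.

    Returns ``None`` (undefined) when there are no neutrophils.
    """
    flags = np.asarray(neutrophil_flags, bool)
    n = int(flags.sum())
    if n == 0:
        return None
    vals = transform(table, "PF520", config or GateConfig())[flags]
    return 100.0 * float((vals > cut).sum()) / n


def acidification_metrics(
    table: EventTable,
    neutrophil_flags: np.ndarray,
    cut: float,
    config: GateConfig | None = None,
    statistic: str = "mean",
    subset_percentages: dict | None = None,
) -> FunctionMetrics:
    """Full per-sample metrics: phagocytosis %, mean acidification ratio and
    channel MFIs over PF520-positive neutrophils.

    ``statistic`` selects mean (default) or median for the MFIs and the
    ratio summary.  Ratios use raw intensities; positivity guarantees
    PF520 > 0 so the ratio is always finite.
    """
    config = config or GateConfig()
    flags = np.asarray(neutrophil_flags, bool)
    n_neut = int(flags.sum())
    summarize = np.mean if statistic == "mean" else np.median

    if n_neut == 0:
        return FunctionMetrics(table.meta, 0, 0, None, None, None, None,
                               pf520_cut=cut, undefined=True,
                               subset_percentages=subset_percentages)

    pf_t = transform(table, "PF520", config)[flags]
    positive = pf_t > cut
    n_pos = int(positive.sum())
    pct = 100.0 * n_pos / n_neut
    if n_pos == 0:
        return FunctionMetrics(table.meta, n_neut, 0, pct, None, None, None,
                               pf520_cut=cut, undefined=True,
                               subset_percentages=subset_percentages)

    pf_raw = table.channel("PF520")[flags][positive]
    ph_raw = table.channel("PHRODO")[flags][positive]
    ratios = ph_raw / pf_raw
    return FunctionMetrics(
        meta=table.meta,
        n_neutrophils=n_neut,
        n_pf520_positive=n_pos,
        phagocytosis_pct=pct,
        mean_acid_ratio=float(summarize(ratios)),
        mfi_pf520=float(summarize(pf_raw)),
        mfi_phrodo=float(summarize(ph_raw)),
        pf520_cut=cut,
        subset_percentages=subset_percentages,
    )


def compute_sample_metrics(table: EventTable, gating: GatingResult,
                           config: GateConfig | None = None,
                           statistic: str = "mean") -> FunctionMetrics:
    """Convenience: PF520 cut + metrics from a gated sample."""
    config = config or GateConfig()
    if gating.n_neutrophils == 0:
        return FunctionMetrics(table.meta, 0, 0, None, None, None, None,
                               undefined=True, subset_percentages=gating.subset_percentages)
    cut = pf520_positive_threshold(table, gating.neutrophil, config)
    return acidification_metrics(table, gating.neutrophil, cut, config,
                                 statistic=statistic,
                                 subset_percentages=gating.subset_percentages)


def subset_acid_ratios(table: EventTable, gating: GatingResult, cut: float,
                       config: GateConfig | None = None,
                       statistic: str = "mean") -> dict[str, float | None]:
    """Acidification ratio summarized per CD16/CD62L subset.

    For each named subset, the mean (or median) pHrodo/PF520 ratio over that
    subset's PF520-positive neutrophils; ``None`` where a subset has no
    positive cells.  Input for the across-patient subset comparison.
    """
    config = config or GateConfig()
    summarize = np.mean if statistic == "mean" else np.median
    pf_t = transform(table, "PF520", config)
    pf_raw = table.channel("PF520")
    ph_raw = table.channel("PHRODO")
    out: dict[str, float | None] = {}
    for name in ("CD16dim_CD62Lbright", "CD16bright_CD62Lbright", "CD16bright_CD62Ldim"):
        sel = (gating.subset == name) & (pf_t > cut)
        out[name] = float(summarize(ph_raw[sel] / pf_raw[sel])) if sel.any() else None
    return out


@dataclass
class KineticsSeries:
    """Metrics for one patient-day ordered by incubation time."""

    points: list[FunctionMetrics]
    missing_timepoints: tuple[int, ...] = field(default_factory=tuple)


def kinetics_curve(samples: Sequence[FunctionMetrics],
                   design: Sequence[int] = INCUBATION_DESIGN) -> KineticsSeries:
    """Order one patient-day's metrics by incubation time.

    Missing design time points are flagged, never interpolated; a duplicated
    time point is an error.
    """
    if not samples:
        raise MetricsError("kinetics_curve requires at least one time point")
    times = [m.incubation_min for m in samples]
    if len(times) != len(set(times)):
        raise MetricsError(f"duplicate incubation time points: {sorted(times)}")
    ordered = sorted(samples, key=lambda m: m.incubation_min)
    missing = tuple(t for t in design if t not in times)
    return KineticsSeries(points=list(ordered), missing_timepoints=missing)
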