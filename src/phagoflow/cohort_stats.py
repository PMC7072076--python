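"""Cohort-level statistics for the longitudinal trauma study design.

The design follows patients from admission (< 12 h, coded day 0) through
days 3, 6, 10 and 15, split into those who later develop infectious
complications and those who do not, with a healthy-control reference group.
The statistical layer provides:

* marginal longitudinal group comparison by generalized estimating
  equations (identity link, exchangeable working correlation, robust
  sandwich errors clustered on patient) — reported as the group beta;
* per-time-point two-group Mann-Whitney U tests (exact enumeration for
  small untied samples, tie- and continuity-corrected normal approximation
  otherwise);
* a healthy-control reference band (t-based 95% CI of the control mean);
* one-way ANOVA with Tukey HSD follow-up across the three neutrophil
  subsets;
* baseline-table tests: two-sided Fisher exact for 2x2 counts and its
  Freeman-Halton extension (full enumeration) for 2xk counts;
* Spearman rank correlation, the Friedman test for repeated conditions,
  and a Shapiro-Wilk normality screen.

All exact tests sum the probabilities of tables/configurations no more
probable than the observed one (two-sided).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

GROUPS = ("infection", "no_infection", "healthy")
DAYS = (0, 3, 6, 10, 15)

COHORT_COLUMNS = ["patient_id", "group", "day", "metric", "value"]


class CohortStatsError(RuntimeError):
    pass


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the tidy long-format cohort table (one row per
    patient x day x metric)."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups: {sorted(bad_groups)}")
    bad_days = set(df["day"].astype(int)) - set(DAYS)
    if bad_days:
        raise ValueError(f"days outside design set {DAYS}: {sorted(bad_days)}")
    dup = df.duplicated(["patient_id", "day", "metric"])
    if dup.any():
        raise ValueError("duplicate patient x day x metric rows")
    return df


# ---------------------------------------------------------------------------
# GEE
# ---------------------------------------------------------------------------

@dataclass
class GeeResult:
    beta: float
    se: float
    p_value: float
    working_correlation: str = "exchangeable"
    n_patients: int = 0
    n_obs: int = 0
    degenerate: bool = False  # single-time-point mean-difference path


def fit_gee(data: pd.DataFrame, metric: str, interaction: bool = False) -> GeeResult:
    """Compare a metric over time between infection and no-infection patients.

    Fits value ~ C(day) + group with identity link, exchangeable working
    correlation and robust (sandwich) standard errors clustered on patient;
    the reported beta is the infection-vs-no-infection coefficient.  With
    ``interaction=True`` a group x day interaction is added and the reported
    beta remains the group main effect (at the reference day).

    With a single time point the model degenerates to the two-group mean
    difference (flagged in the result).
    """
    d = data[(data["metric"] == metric) & (data["group"].isin(["infection", "no_infection"]))].copy()
    if d.empty:
        raise CohortStatsError(f"no rows for metric {metric!r}")
    for g in ("infection", "no_infection"):
        if d.loc[d["group"] == g, "patient_id"].nunique() < 2:
            raise CohortStatsError(f"need >= 2 patients in group {g!r}")
    d["infected"] = (d["group"] == "infection").astype(float)
    d = d.dropna(subset=["value"])
    if d["value"].var(ddof=0) == 0:
        # a constant response carries no group effect; GEE scale is degenerate
        return GeeResult(0.0, 0.0, 1.0, "degenerate (constant response)",
                         d["patient_id"].nunique(), len(d), degenerate=True)

    days = sorted(d["day"].unique())
    if len(days) < 2:
        a = d.loc[d["infected"] == 1, "value"].to_numpy(float)
        b = d.loc[d["infected"] == 0, "value"].to_numpy(float)
        beta = float(a.mean() - b.mean())
        va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
        se = float(np.sqrt(va + vb))
        if se > 0:
            p = 2 * stats.norm.sf(abs(beta) / se)
        else:
            p = 0.0 if beta != 0 else 1.0
        return GeeResult(beta, se, float(p), "none (single time point)",
                         d["patient_id"].nunique(), len(d), degenerate=True)

    formula = "value ~ C(day) + infected"
    if interaction:
        formula = "value ~ C(day) * infected"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE.from_formula(
            formula, groups="patient_id", data=d,
            cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Gaussian(),
        )
        try:
            fit = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - surfaced, not silenced
            raise CohortStatsError(f"GEE did not converge: {exc}") from exc
    beta = float(fit.params["infected"])
    se = float(fit.bse["infected"])
    p = float(fit.pvalues["infected"])
    return GeeResult(beta, se, p, "exchangeable", d["patient_id"].nunique(), len(d))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is at most 12 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise CohortStatsError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def per_timepoint_test(data: pd.DataFrame, metric: str, day: int) -> dict:
    """Mann-Whitney U comparing infection vs no-infection at one day.

    Returns a dict with U, p and group sizes; if either group has no values
    at that day the test is flagged missing instead of computed.
    """
    d = data[(data["metric"] == metric) & (data["day"] == day)]
    x = d.loc[d["group"] == "infection", "value"].dropna().to_numpy(float)
    y = d.loc[d["group"] == "no_infection", "value"].dropna().to_numpy(float)
    if x.size == 0 or y.size == 0:
        return {"day": day, "missing": True, "n_infection": int(x.size),
                "n_no_infection": int(y.size)}
    u, p = mann_whitney_u(x, y)
    return {"day": day, "missing": False, "U": u, "p": p,
            "n_infection": int(x.size), "n_no_infection": int(y.size)}


# ---------------------------------------------------------------------------
# reference band
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBand:
    metric: str
    lower: float
    upper: float
    n_controls: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def classify(self, value: float) -> str:
        if value > self.upper:
            return "above"
        if value < self.lower:
            return "below"
        return "within"


def reference_band(control_values, metric: str = "") -> ReferenceBand:
    """95% confidence interval of the healthy-control mean:
    mean +/- t(0.975, n-1) * SD / sqrt(n)."""
    v = np.asarray(control_values, float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise CohortStatsError("reference band requires >= 2 controls")
    m = float(v.mean())
    half = float(stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / math.sqrt(n))
    return ReferenceBand(metric, m - half, m + half, n)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def subset_anova(groups: dict[str, np.ndarray] | list) -> dict:
    """One-way ANOVA across the three neutrophil subsets with Tukey HSD
    follow-up.

    ``groups`` maps subset name -> per-patient values (or is a list of three
    arrays).  Zero pooled within-group variance with distinct means is
    degenerate: F is unbounded and p is reported as 0.0 with a flag.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], float) for k in names]
    else:
        arrays = [np.asarray(a, float) for a in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) != 3:
        raise CohortStatsError("subset ANOVA expects exactly 3 groups")
    if any(a.size < 2 for a in arrays):
        raise CohortStatsError("each group needs n >= 2")

    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if within_ss == 0 and len(set(means)) > 1:
        return {"F": math.inf, "p": 0.0, "degenerate": True, "tukey": None}

    F, p = stats.f_oneway(*arrays)
    tuk = stats.tukey_hsd(*arrays)
    pairs = {}
    for i, j in itertools.combinations(range(3), 2):
        pairs[f"{names[i]} vs {names[j]}"] = float(tuk.pvalue[i, j])
    return {"F": float(F), "p": float(p), "degenerate": False, "tukey": pairs}


# ---------------------------------------------------------------------------
# exact contingency tests
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    # hypergeometric probability of a 2xk table conditional on both margins
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = log_fact[rows].sum() + log_fact[cols].sum() - log_fact[n]
    lp -= log_fact[table].sum()
    return float(lp)


def fisher_freeman_halton(table) -> float:
    """Two-sided exact test of independence for a 2xk count table.

    For 2x2 this is Fisher's exact test; for k > 2 the Freeman-Halton
    extension, computed by full enumeration of all tables with the observed
    margins, summing the probabilities of tables no more probable than the
    observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise CohortStatsError("expected a 2xk table, k >= 2")
    if (t < 0).any():
        raise CohortStatsError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise CohortStatsError("empty margin")

    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])

    cols = t.sum(axis=0)
    r1 = int(t.sum(axis=1)[0])
    n = int(t.sum())
    log_fact = np.array([math.lgamma(i + 1) for i in range(n + 1)])
    obs_lp = _table_log_prob(t, log_fact)

    total = 0.0
    k = t.shape[1]

    def _recurse(j: int, remaining: int, row1: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= cols[j]:
                cand = np.array([row1 + [remaining],
                                 (cols - np.array(row1 + [remaining])).tolist()])
                lp = _table_log_prob(cand, log_fact)
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        for a in range(min(int(cols[j]), remaining) + 1):
            _recurse(j + 1, remaining - a, row1 + [a])

    _recurse(0, r1, [])
    return min(1.0, total)


def baseline_tests(table=None, x=None, y=None) -> dict:
    """Baseline-characteristics comparison between outcome groups.

    Categorical variables come as a 2xk count table (Fisher exact /
    Freeman-Halton); continuous covariates come as two samples (Mann-Whitney
    U).  Exactly one input form must be given.
    """
    if table is not None:
        return {"test": "fisher_exact" if np.asarray(table).shape[1] == 2 else "freeman_halton",
                "p": fisher_freeman_halton(table)}
    if x is not None and y is not None:
        u, p = mann_whitney_u(x, y)
        return {"test": "mann_whitney", "U": u, "p": p}
    raise CohortStatsError("supply either a count table or two samples")


# ---------------------------------------------------------------------------
# correlations, paired tests, normality screen
# ---------------------------------------------------------------------------

def spearman(x, y) -> dict:
    """Spearman rank correlation with tie-corrected ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise CohortStatsError("paired samples must have equal length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return {"rho": None, "p": None, "undefined": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "undefined": False}


def friedman(*conditions) -> dict:
    """Friedman chi-square test on within-subject ranks across repeated
    conditions (e.g. incubation temperatures)."""
    if len(conditions) < 2:
        raise CohortStatsError("Friedman test needs >= 2 conditions")
    arrays = [np.asarray(c, float) for c in conditions]
    if len({a.size for a in arrays}) != 1 or arrays[0].size < 2:
        raise CohortStatsError("conditions must share >= 2 subjects")
    # scipy requires >= 3 conditions; the 2-condition case reduces to a sign test
    if len(arrays) == 2:
        diff = arrays[0] - arrays[1]
        n = arrays[0].size
        chi2 = float((np.sign(diff).sum()) ** 2 / n)
        return {"statistic": chi2, "p": float(stats.chi2.sf(chi2, 1))}
    mat = np.column_stack(arrays)
    if np.all(np.ptp(mat, axis=1) == 0):
        return {"statistic": 0.0, "p": 1.0}
    chi2, p = stats.friedmanchisquare(*arrays)
    return {"statistic": float(chi2), "p": float(p)}


def shapiro_wilk(sample) -> dict:
    """Normality screen: Shapiro-Wilk W and p (pass-through contract)."""
    w, p = stats.shapiro(np.asarray(sample, float))
    return {"W": float(w), "p": float(p)}
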