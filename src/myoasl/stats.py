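"""Group statistics for regional perfusion cohorts.

Replicates the study's analysis plan on a long-format per-segment table:
paired two-sided t-test for rest vs stress (with segments dropped when
excluded in either condition), myocardial perfusion reserve summaries,
ordinary one-way ANOVA across timepoints for the cross-sectional
post-infarct comparison, and Holm-Sidak step-down adjustment of the
pairwise baseline-vs-timepoint p-values.  The unit of analysis is the
segment (slice-nested); alpha = 0.05, two-sided throughout; summaries are
mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateTestError",
    "paired_ttest",
    "oneway_anova",
    "holm_sidak",
    "filter_paired",
    "PairedData",
    "mpr",
    "MPRSummary",
    "regional_summary",
    "cross_sectional_compare",
    "CrossSectionalResult",
]

TIMEPOINT_ORDER = ["baseline", "day1_2", "week1_2", "week4"]
ALPHA = 0.05


class DegenerateTestError(ValueError):
    """A test statistic is undefined (zero variance where variance is needed)."""


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired Student t-test on index-matched samples.

    Returns ``(t, p)`` computed on the differences x - y.  Identical
    samples give (0.0, 1.0); zero-variance differences with a nonzero mean
    leave t undefined and raise :class:`DegenerateTestError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == d[0]) and d[0] == 0:
            return 0.0, 1.0
        raise DegenerateTestError("differences have zero variance but nonzero mean")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def oneway_anova(groups) -> tuple[float, float]:
    """Ordinary one-way ANOVA: between/within mean-square ratio and F-test p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within_ss == 0:
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        raise DegenerateTestError("zero within-group variance with unequal means")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sort ascending; the i-th smallest raw p (0-based rank i of m) becomes
    ``1 - (1 - p)**(m - i)``, a running maximum enforces monotonicity, and
    values are clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(adj_sorted))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class PairedData:
    """Index-matched condition vectors after both-condition exclusion."""

    a: np.ndarray
    b: np.ndarray
    keys: pd.DataFrame  # (subject, slice, segment) of the kept pairs
    n_kept: int
    n_dropped: int


def filter_paired(table: pd.DataFrame, condition_a: str, condition_b: str) -> PairedData:
    """Matched per-segment vectors for two conditions.

    A (subject, slice, segment) unit is kept only when it is present and
    ``included`` in BOTH conditions — a segment excluded at either rest or
    stress drops the pair.
    """
    key = ["subject", "slice", "segment"]
    a = table[table["condition"] == condition_a].set_index(key)
    b = table[table["condition"] == condition_b].set_index(key)
    common = a.index.intersection(b.index)
    total = len(common)
    keep = common[(a.loc[common, "included"].values) & (b.loc[common, "included"].values)]
    return PairedData(
        a=a.loc[keep, "mbf"].to_numpy(dtype=float),
        b=b.loc[keep, "mbf"].to_numpy(dtype=float),
        keys=keep.to_frame(index=False),
        n_kept=len(keep),
        n_dropped=total - len(keep),
    )


@dataclass
class MPRSummary:
    mean: float
    sd: float
    n: int
    n_undefined: int
    ratios: np.ndarray = field(repr=False)


def mpr(rest_mbf, stress_mbf) -> MPRSummary:
    """Per-segment myocardial perfusion reserve (stress / rest), mean +/- SD.

    Units with nonpositive resting MBF have an undefined reserve; they are
    omitted from the summary and counted in ``n_undefined``.
    """
    rest = np.asarray(rest_mbf, dtype=float)
    stress = np.asarray(stress_mbf, dtype=float)
    if rest.shape != stress.shape:
        raise ValueError("rest and stress vectors must match")
    defined = rest > 0
    ratios = np.full(rest.shape, np.nan)
    ratios[defined] = stress[defined] / rest[defined]
    vals = ratios[defined]
    return MPRSummary(
        mean=float(vals.mean()) if vals.size else float("nan"),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n=int(vals.size),
        n_undefined=int((~defined).sum()),
        ratios=ratios,
    )


def regional_summary(table: pd.DataFrame, use_all_rows: bool = False) -> pd.DataFrame:
    """Mean +/- SD of MBF by (region, timepoint, condition).

    The remote region pools its three segments.  Rows flagged excluded are
    skipped unless ``use_all_rows`` (the post-infarct comparison policy).
    Groups of one report SD 0 with n = 1.
    """
    df = table if use_all_rows else table[table["included"]]
    rows = []
    for (region, timepoint, condition), grp in df.groupby(
        ["region", "timepoint", "condition"], sort=True
    ):
        vals = grp["mbf"].to_numpy(dtype=float)
        rows.append(
            {
                "region": region,
                "timepoint": timepoint,
                "condition": condition,
                "mbf_mean": vals.mean(),
                "mbf_sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CrossSectionalResult:
    region: str
    timepoints: list[str]
    group_means: dict[str, float]
    group_ns: dict[str, int]
    anova_f: float
    anova_p: float
    comparisons: pd.DataFrame  # timepoint vs baseline: raw & adjusted p, significance


def cross_sectional_compare(
    table: pd.DataFrame,
    region: str,
    baseline_timepoint: str = "baseline",
    alpha: float = ALPHA,
) -> CrossSectionalResult:
    """Cross-sectional comparison of resting regional MBF across timepoints.

    One-way ANOVA over all timepoints present, then pairwise two-sample
    t-tests of each post-infarct timepoint against baseline with Holm-Sidak
    correction for the serial sampling.  Applied to all rows of the region
    (no tSNR exclusion): the infarcted segment is known in advance and low
    tSNR is part of its phenotype.
    """
    df = table[(table["region"] == region) & (table["condition"] == "rest")]
    timepoints = [t for t in TIMEPOINT_ORDER if t in set(df["timepoint"])]
    if baseline_timepoint not in timepoints:
        raise ValueError(f"no {baseline_timepoint!r} rows for region {region!r}")
    groups = {t: df.loc[df["timepoint"] == t, "mbf"].to_numpy(dtype=float) for t in timepoints}
    f, p = oneway_anova(list(groups.values()))
    others = [t for t in timepoints if t != baseline_timepoint]
    raw = []
    tstats = []
    base_vals = groups[baseline_timepoint]
    for t in others:
        tt, pp = sps.ttest_ind(groups[t], base_vals)
        raw.append(float(pp))
        tstats.append(float(tt))
    adj = holm_sidak(raw) if raw else np.array([])
    comparisons = pd.DataFrame(
        {
            "timepoint": others,
            "mean_diff": [groups[t].mean() - base_vals.mean() for t in others],
            "t": tstats,
            "p_raw": raw,
            "p_adjusted": adj,
            "significant": adj < alpha,
        }
    )
    return CrossSectionalResult(
        region=region,
        timepoints=timepoints,
        group_means={t: float(groups[t].mean()) for t in timepoints},
        group_ns={t: int(groups[t].size) for t in timepoints},
        anova_f=f,
        anova_p=p,
        comparisons=comparisons,
    )
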