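"""Cohort-level aggregation and statistics.

The analysis mirrors a two-group (benign vs malignant) biopsy study:
parameters are first averaged over all microcalcifications per subject,
then compared between groups; objects are additionally pooled and split by
volume at the mammographic visibility threshold (0.0042 mm³, a
0.2 mm-diameter sphere).  Group comparisons gate on a Lilliefors-corrected
one-sample Kolmogorov–Smirnov normality test: pooled-variance t-test when
both groups pass, Mann–Whitney U (mid-ranks, tie-corrected asymptotic p)
otherwise.  Expert-vs-automated count agreement uses the asymptotic
Wilcoxon signed-rank test, Bland–Altman limits, and three candidate ratio
estimators (reported separately, never merged, since a single "count
ratio" is ambiguous).  No multiple-testing correction is applied: each
parameter is tested independently at α = 0.05, and reports say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .defaults import ALPHA, MIN_OBJECT_VOXELS, VISIBILITY_THRESHOLD_MM3
from .io import CountTable, READER_COLUMNS
from .morphometry import ObjectMorphometry

__all__ = [
    "SubjectSummary",
    "ComparisonResult",
    "mean_sd",
    "summarize_subject",
    "classify_by_size",
    "size_class_shares",
    "normality_test",
    "compare_groups",
    "paired_count_test",
    "bland_altman",
    "count_ratio",
    "aggregate_readers",
    "PARAMETER_COLUMNS",
]

PARAMETER_COLUMNS = ["obj_v_mm3", "obj_s_mm2", "sv_per_mm", "st_th_mm", "smi"]


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n − 1 denominator).

    With a single value the SD is undefined and returned as NaN.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sd needs at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


@dataclass
class SubjectSummary:
    """Per-subject averages over measurable (> 2 voxel) objects plus counts."""

    subject: str
    group: str
    obj_v_mm3: float
    obj_s_mm2: float
    sv_per_mm: float
    st_th_mm: float
    smi: float
    obj_n: int
    obj_n_measurable: int

    def __post_init__(self) -> None:
        if self.obj_n < self.obj_n_measurable:
            raise ValueError("Obj.N cannot be below the measurable count")


def summarize_subject(
    objects: list[ObjectMorphometry],
    total_count: int,
    subject: str = "",
    group: str = "",
) -> SubjectSummary:
    """Average each parameter over a subject's measurable objects.

    ``total_count`` is Obj.N including sub-resolution objects.  With zero
    measurable objects the means are undefined and reported as NaN, never 0.
    """
    if objects:
        means = {
            "obj_v_mm3": float(np.mean([o.volume_mm3 for o in objects])),
            "obj_s_mm2": float(np.mean([o.surface_mm2 for o in objects])),
            "sv_per_mm": float(np.mean([o.sv_ratio_per_mm for o in objects])),
            "st_th_mm": float(np.mean([o.thickness_mm for o in objects])),
            "smi": float(np.mean([o.smi for o in objects])),
        }
    else:
        means = {k: float("nan") for k in PARAMETER_COLUMNS}
    return SubjectSummary(
        subject=subject,
        group=group,
        obj_n=int(total_count),
        obj_n_measurable=len(objects),
        **means,
    )


def classify_by_size(
    objects: list[ObjectMorphometry] | pd.DataFrame,
    visibility_threshold_mm3: float = VISIBILITY_THRESHOLD_MM3,
    min_voxels: int = MIN_OBJECT_VOXELS,
) -> pd.DataFrame:
    """Partition objects into disjoint volume classes.

    ``sub-resolution``: <= ``min_voxels`` voxels; ``small``: measurable and
    volume <= threshold (boundary inclusive); ``large``: volume above the
    threshold.  Returns one row per object with a ``size_class`` column
    added.
    """
    if not (visibility_threshold_mm3 > 0):
        raise ValueError("threshold must be > 0")
    if isinstance(objects, pd.DataFrame):
        df = objects.copy()
    else:
        df = pd.DataFrame(
            {
                "object_id": [o.object_id for o in objects],
                "voxels": [o.voxel_count for o in objects],
                "obj_v_mm3": [o.volume_mm3 for o in objects],
                "obj_s_mm2": [o.surface_mm2 for o in objects],
                "sv_per_mm": [o.sv_ratio_per_mm for o in objects],
                "st_th_mm": [o.thickness_mm for o in objects],
                "smi": [o.smi for o in objects],
            }
        )
    cls = np.where(
        df["voxels"] <= min_voxels,
        "sub-resolution",
        np.where(df["obj_v_mm3"] <= visibility_threshold_mm3, "small", "large"),
    )
    df["size_class"] = cls
    return df


def size_class_shares(
    small: dict[str, int], large: dict[str, int], total: dict[str, int]
) -> pd.DataFrame:
    """Bookkeeping on per-group size-class counts.

    ``small``/``large`` are measurable-object counts per group;
    ``total`` is Obj.N including sub-resolution objects.  Derives, per
    group: the inferred sub-resolution count, the count of all small
    objects (small + sub-resolution), the percentage of a group's objects
    that are small, and each group's share of the pooled small and large
    classes (in %).
    """
    groups = list(total)
    rows = []
    pooled_small = sum(small.values())
    pooled_large = sum(large.values())
    for g in groups:
        sub = total[g] - small[g] - large[g]
        if sub < 0:
            raise ValueError(f"class counts exceed group total for {g!r}")
        small_all = small[g] + sub
        rows.append(
            {
                "group": g,
                "total": total[g],
                "small": small[g],
                "large": large[g],
                "sub_resolution": sub,
                "small_incl_subres": small_all,
                "pct_small_in_group": 100.0 * small_all / total[g],
                "pct_group_share_small_class": 100.0 * small[g] / pooled_small,
                "pct_group_share_large_class": 100.0 * large[g] / pooled_large,
            }
        )
    return pd.DataFrame(rows)


def normality_test(values) -> float:
    """Lilliefors-corrected one-sample KS test against a fitted normal.

    Returns the p-value.  Needs n >= 4; smaller samples raise, and callers
    gating on normality fall back to the non-parametric branch.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("normality test needs at least 4 values")
    if np.ptp(arr) == 0:
        return 0.0  # degenerate: a constant sample is maximally non-normal
    _, p = lilliefors(arr, dist="norm", pvalmethod="table")
    return float(p)


@dataclass
class ComparisonResult:
    """Outcome of one two-group or paired comparison."""

    parameter: str
    test: str  # "t-test" | "mann-whitney" | "wilcoxon-signed-rank"
    statistic: float
    p_value: float
    n: tuple[int, ...]
    significant: bool
    normality_p: tuple[float, ...] = field(default_factory=tuple)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p-value out of [0, 1]")


def compare_groups(
    values_a, values_b, parameter: str = "", alpha: float = ALPHA,
    force: str | None = None,
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Both groups pass the Lilliefors KS gate (p > α) → pooled-variance
    two-sided t-test; otherwise Mann–Whitney U with mid-ranks and the
    tie-corrected asymptotic two-sided p.  ``force`` overrides the gate
    ("t-test" or "mann-whitney").  Identical constant groups are degenerate
    and report p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult(parameter, "degenerate", 0.0, 1.0,
                                (a.size, b.size), False, degenerate=True)
    norm_p: tuple[float, ...] = ()
    if force is None:
        try:
            norm_p = (normality_test(a), normality_test(b))
            use_t = all(p > alpha for p in norm_p)
        except ValueError:
            warnings.warn("group too small for the normality gate; "
                          "falling back to Mann-Whitney", stacklevel=2)
            use_t = False
    else:
        use_t = force == "t-test"
    if use_t:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        stat, p = res.statistic, res.pvalue
        test = "mann-whitney"
    return ComparisonResult(parameter, test, float(stat), float(p),
                            (a.size, b.size), bool(p < alpha), norm_p)


def aggregate_readers(table: CountTable, how: str = "mean") -> pd.DataFrame:
    """Collapse the six expert readings per subject into one value.

    ``how`` = "mean" (default), a reader column name, or "session1"/"session2"
    (mean of the three first- or second-session readings).
    """
    df = table.frame
    if how == "mean":
        agg = df[READER_COLUMNS].mean(axis=1)
    elif how in READER_COLUMNS:
        agg = df[how].astype(float)
    elif how in ("session1", "session2"):
        sess = [c for c in READER_COLUMNS if c.endswith("r1" if how == "session1" else "r2")]
        agg = df[sess].mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation {how!r}")
    return pd.DataFrame(
        {"subject": df["subject"], "group": df["group"],
         "expert": agg, "microct": df["microct"].astype(float)}
    )


def paired_count_test(
    table: CountTable, group: str | None = None, aggregation: str = "mean",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Asymptotic Wilcoxon signed-rank test of expert vs micro-CT counts.

    Differences are aggregated expert − micro-CT per subject; zero
    differences are dropped (standard convention), the normal
    approximation is used without continuity correction.  All-zero
    differences are degenerate with p = 1.
    """
    pairs = aggregate_readers(table, aggregation)
    if group is not None:
        pairs = pairs[pairs["group"] == group]
    if len(pairs) < 5:
        raise ValueError("paired count test needs at least 5 pairs")
    d = (pairs["expert"] - pairs["microct"]).to_numpy()
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return ComparisonResult(f"count[{group or 'all'}]", "wilcoxon-signed-rank",
                                0.0, 1.0, (len(pairs),), False, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n approximation notice
        stat, p = sps.wilcoxon(nonzero, zero_method="wilcox",
                               correction=False, method="approx")
    return ComparisonResult(f"count[{group or 'all'}]", "wilcoxon-signed-rank",
                            float(stat), float(p), (len(pairs),), bool(p < alpha))


def bland_altman(table: CountTable, aggregation: str = "mean") -> dict:
    """Bland–Altman agreement of aggregated expert vs micro-CT counts.

    Differences are expert − micro-CT; limits of agreement are the mean
    difference ± 2 sample SD.  Returns the mean difference, the limits and
    the per-subject (mean of pair, difference) points for plotting.
    """
    pairs = aggregate_readers(table, aggregation)
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = (pairs["expert"] - pairs["microct"]).to_numpy()
    mean_pair = ((pairs["expert"] + pairs["microct"]) / 2).to_numpy()
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    points = pd.DataFrame(
        {"subject": pairs["subject"], "group": pairs["group"],
         "pair_mean": mean_pair, "difference": diff}
    )
    return {"mean_difference": md, "sd": sd,
            "limits": (md - 2 * sd, md + 2 * sd), "points": points}


def count_ratio(
    table: CountTable, estimator: str = "through-origin-slope",
    aggregation: str = "mean",
) -> tuple[float, tuple[float, float]]:
    """Expert/micro-CT count ratio with a normal-theory 95% CI.

    Three estimators of "the ratio" are available and deliberately kept
    separate: ``through-origin-slope`` (Σxy/Σx², regression of expert on
    micro-CT forced through zero), ``ols-slope`` (ordinary least squares
    with intercept), and ``ratio-of-totals`` (Σy/Σx, the classical ratio
    estimator).  They answer different questions and can differ widely on
    skewed counts.
    """
    pairs = aggregate_readers(table, aggregation)
    x = pairs["microct"].to_numpy(dtype=float)
    y = pairs["expert"].to_numpy(dtype=float)
    keep = x > 0
    if not keep.all():
        warnings.warn("dropping pairs with zero micro-CT counts", stacklevel=2)
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("count ratio needs at least 3 usable pairs")
    z = sps.norm.ppf(0.975)
    if estimator == "through-origin-slope":
        b = float(np.sum(x * y) / np.sum(x * x))
        resid = y - b * x
        se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(x * x)))
    elif estimator == "ols-slope":
        res = sps.linregress(x, y)
        b, se = float(res.slope), float(res.stderr)
    elif estimator == "ratio-of-totals":
        b = float(y.sum() / x.sum())
        resid = y - b * x
        se = float(np.sqrt(np.sum(resid**2) / (n - 1) / n) / x.mean())
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return b, (b - z * se, b + z * se)
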