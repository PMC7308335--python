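"""Per-sample repertoire metrics and between-group comparisons.

Metrics follow the repertoire-profiling conventions: richness is the
post-cutoff clonotype count; the functional and D1/D2 ratios are computed
over clonotypes (not reads); fold changes between groups use medians, and a
two-vs-one contrast uses the mean of the two group medians in the numerator.
Group differences are tested with two-tailed Mann-Whitney U tests (exact for
small tie-free samples, normal approximation with tie and continuity
correction otherwise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

logger = logging.getLogger("repscan")

__all__ = [
    "SampleMetrics",
    "summarize_sample",
    "mann_whitney_two_tailed",
    "fold_change",
    "compare_groups",
    "METRIC_FIELDS",
]

METRIC_FIELDS = (
    "richness",
    "functional_ratio",
    "d1_d2_ratio",
    "median_cdr3_len",
    "mean_v_trunc",
    "mean_j_trunc",
    "mean_d5_trunc",
    "mean_d3_trunc",
    "mean_n_len",
)


@dataclass(frozen=True)
class SampleMetrics:
    """Summary metrics of one sample's post-cutoff clonotype table.

    Ratio metrics with a zero denominator are NaN (flagged undefined), never
    an exception.
    """

    sample: str
    richness: int
    functional_ratio: float
    d1_d2_ratio: float
    median_cdr3_len: float
    mean_v_trunc: float
    mean_j_trunc: float
    mean_d5_trunc: float
    mean_d3_trunc: float
    mean_n_len: float

    def as_dict(self) -> dict:
        return {"sample": self.sample, **{f: getattr(self, f) for f in METRIC_FIELDS}}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def summarize_sample(table: pd.DataFrame, sample: str = "",
                     weight_by_reads: bool = False) -> SampleMetrics:
    """Summarize a clonotype table with architecture columns.

    By default every clonotype counts once; ``weight_by_reads=True`` weights
    each clonotype by its read count instead.
    """
    if len(table) == 0:
        nan = float("nan")
        return SampleMetrics(sample, 0, nan, nan, nan, nan, nan, nan, nan, nan)
    if weight_by_reads and "read_count" in table:
        w = table["read_count"].to_numpy(dtype=float)
    else:
        w = np.ones(len(table))

    def wmean(values: pd.Series) -> float:
        v = values.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        return float(np.average(v[ok], weights=w[ok])) if ok.any() else float("nan")

    def wmedian(values: pd.Series) -> float:
        v = values.to_numpy(dtype=float)
        if not weight_by_reads:
            return float(np.median(v))
        order = np.argsort(v)
        cum = np.cumsum(w[order])
        return float(v[order][np.searchsorted(cum, cum[-1] / 2.0)])

    functional = table["functional"].astype(bool)
    n_func = int(w[functional.to_numpy()].sum())
    n_nonf = int(w[(~functional).to_numpy()].sum())
    d1 = int(w[table["d_name"].str.contains("D1", na=False).to_numpy()].sum())
    d2 = int(w[table["d_name"].str.contains("D2", na=False).to_numpy()].sum())
    n_len = table["n1_len"].astype(float) + table["n2_len"].astype(float)
    return SampleMetrics(
        sample=sample or (table["sample"].iloc[0] if "sample" in table else ""),
        richness=len(table),
        functional_ratio=_ratio(n_func, n_nonf),
        d1_d2_ratio=_ratio(d1, d2),
        median_cdr3_len=wmedian(table["cdr3_len"]),
        mean_v_trunc=wmean(table["v_trunc"]),
        mean_j_trunc=wmean(table["j_trunc"]),
        mean_d5_trunc=wmean(table["d5_trunc"]),
        mean_d3_trunc=wmean(table["d3_trunc"]),
        mean_n_len=wmean(n_len),
    )


def mann_whitney_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U test; returns (U of group_a, p, mode).

    Exact enumeration of the U null distribution when the pooled size is at
    most 12 and there are no ties; otherwise the normal approximation with
    tie correction and a 0.5 continuity correction.  The mode actually used
    is reported as "exact" or "asymptotic".
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 12 and no_ties:
        res = _st.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue), "asymptotic"


def fold_change(medians_group1: Sequence[float] | float, median_group2: float) -> float:
    """Median-based fold change.

    Single-group case: median1 / median2.  Two-vs-one case (``medians_group1``
    holds two medians): their mean over ``median_group2``.
    """
    if median_group2 <= 0 or math.isnan(median_group2):
        raise ValueError(f"denominator median must be > 0, got {median_group2}")
    if np.isscalar(medians_group1):
        num = float(medians_group1)  # type: ignore[arg-type]
    else:
        num = float(np.mean(np.asarray(medians_group1, dtype=float)))
    return num / median_group2


def compare_groups(
    metrics: Sequence[SampleMetrics] | pd.DataFrame,
    design: dict[str, str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Pairwise group comparison of every sample metric.

    ``design`` maps sample name -> group label.  For every metric and every
    (lexicographically ordered) group pair the output holds both group
    medians, the median fold change, the Mann-Whitney U and two-tailed p, and
    (for convenience, the published analyses report raw p-values) a
    Benjamini-Hochberg adjusted column across the whole report.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.copy()
    else:
        df = pd.DataFrame([m.as_dict() for m in metrics])
    unknown = set(df["sample"]) - set(design)
    if unknown:
        raise ValueError(f"samples without a design group: {sorted(unknown)}")
    df["group"] = df["sample"].map(design)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = df.groupby("group").size()
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 samples, got {dict(sizes)}")
    rows = []
    for metric in METRIC_FIELDS:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                va = df.loc[df["group"] == ga, metric].dropna().to_numpy()
                vb = df.loc[df["group"] == gb, metric].dropna().to_numpy()
                if va.size < 2 or vb.size < 2:
                    continue
                med_a, med_b = float(np.median(va)), float(np.median(vb))
                u, p, mode = mann_whitney_two_tailed(va, vb)
                fold = med_a / med_b if med_b > 0 else float("nan")
                rows.append(dict(metric=metric, group_a=ga, group_b=gb,
                                 median_a=med_a, median_b=med_b, fold=fold,
                                 U=u, p=p, mode=mode))
    report = pd.DataFrame(rows)
    if adjust and len(report):
        report["p_bh"] = _benjamini_hochberg(report["p"].to_numpy())
    logger.info("compare_groups: %d contrasts over %d groups", len(report), len(groups))
    return report


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
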