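"""Group comparison and reporting conventions for the phantom studies.

Summaries are median (IQR, 25th-75th with linear-interpolation quantiles),
except exactly-five-replicate samples which are reported mean +/- sample SD.
Group comparison runs Shapiro-Wilk and Levene screens (reported, never
gating), a tie-corrected Kruskal-Wallis omnibus test, and Dunn's post-hoc
z-tests on pooled ranks with Bonferroni correction at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import MammoqError

__all__ = ["Summary", "StatsReport", "summarize", "dunn_test", "compare_groups"]


@dataclass(frozen=True)
class Summary:
    kind: str           # "median_iqr" | "mean_sd"
    center: float       # median or mean
    spread: tuple       # (q25, q75) or (sd,)
    n: int

    def __str__(self) -> str:
        if self.kind == "median_iqr":
            q25, q75 = self.spread
            return f"{self.center:.1f} (IQR {q25:.1f}-{q75:.1f})"
        return f"{self.center:.1f} +/- {self.spread[0]:.1f}"


@dataclass
class StatsReport:
    metric: str
    group_summaries: dict[str, Summary]
    shapiro_p: dict[str, float]
    levene_p: float
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame          # columns: group1, group2, z, p_raw, p_corrected, significant
    alpha: float = 0.05
    excluded_groups: list = field(default_factory=list)

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.dunn[self.dunn["significant"]]
        return list(zip(sig["group1"], sig["group2"]))

    def pair_p(self, a, b) -> float:
        d = self.dunn
        row = d[((d.group1 == a) & (d.group2 == b)) | ((d.group1 == b) & (d.group2 == a))]
        if row.empty:
            raise KeyError(f"no Dunn comparison for pair ({a}, {b})")
        return float(row["p_corrected"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": {str(g): {"kind": s.kind, "center": s.center,
                                "spread": list(s.spread), "n": s.n}
                       for g, s in self.group_summaries.items()},
            "shapiro_p": {str(g): p for g, p in self.shapiro_p.items()},
            "levene_p": self.levene_p,
            "kruskal_h": self.kruskal_h,
            "kruskal_p": self.kruskal_p,
            "alpha": self.alpha,
            "dunn": self.dunn.assign(
                group1=self.dunn.group1.astype(str),
                group2=self.dunn.group2.astype(str)).to_dict(orient="records"),
        }


def summarize(values: Sequence[float], n_rule: str = "auto") -> Summary:
    """Median (IQR) summary; mean +/- SD when there are exactly five values.

    ``n_rule`` may be "auto" (five -> mean_sd), "median_iqr" or "mean_sd".
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise MammoqError("cannot summarise an empty sample")
    if n_rule == "auto":
        n_rule = "mean_sd" if arr.size == 5 else "median_iqr"
    if n_rule == "mean_sd":
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return Summary("mean_sd", float(arr.mean()), (sd,), arr.size)
    if n_rule == "median_iqr":
        q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # linear (type-7) quantiles
        return Summary("median_iqr", float(q50), (float(q25), float(q75)), arr.size)
    raise MammoqError(f"unknown summary rule {n_rule!r}")


def _tie_correction(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    n = all_values.size
    return float(((counts ** 3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0


def dunn_test(groups: Mapping, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks, Bonferroni-corrected.

    ``groups`` maps label -> sample. The correction family is all C(k, 2)
    pairwise comparisons among the groups present.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=np.float64) for g in labels]
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, pos = {}, {}, 0
    for g, s in zip(labels, samples):
        mean_ranks[g] = float(ranks[pos:pos + s.size].mean())
        sizes[g] = s.size
        pos += s.size
    tie = _tie_correction(pooled)
    base_var = n * (n + 1) / 12.0 - tie
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_cor = min(1.0, p_raw * m)
        rows.append({"group1": a, "group2": b, "z": float(z),
                     "p_raw": p_raw, "p_corrected": p_cor,
                     "significant": p_cor < alpha})
    return pd.DataFrame(rows)


def compare_groups(
    samples: pd.DataFrame,
    metric: Optional[str] = None,
    alpha: float = 0.05,
    min_replicates: int = 3,
) -> StatsReport:
    """Full comparison pipeline on a tidy (metric, group, replicate, value) table.

    Groups with fewer than ``min_replicates`` values are excluded from the
    omnibus and post-hoc tests with a warning (they still get a summary).
    """
    df = samples
    if metric is not None:
        df = df[df["metric"] == metric]
    elif "metric" in df.columns:
        uniq = df["metric"].unique()
        if len(uniq) != 1:
            raise MammoqError("pass metric= when the table holds several metrics")
        metric = uniq[0]
    if df.empty:
        raise MammoqError(f"no samples for metric {metric!r}")

    by_group = {g: sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group")}
    summaries = {g: summarize(v) for g, v in by_group.items()}
    excluded = [g for g, v in by_group.items() if v.size < min_replicates]
    if excluded:
        warnings.warn(f"excluding groups with < {min_replicates} replicates: {excluded}")
    tested = {g: v for g, v in by_group.items() if g not in excluded}
    if len(tested) < 2:
        raise MammoqError("need at least two groups with enough replicates")

    shapiro_p = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for g, v in tested.items():
            if np.ptp(v) == 0:
                shapiro_p[g] = float("nan")  # Shapiro undefined on constant samples
            else:
                shapiro_p[g] = float(sps.shapiro(v).pvalue)
        try:
            levene_p = float(sps.levene(*tested.values()).pvalue)
        except Exception:
            levene_p = float("nan")
    try:
        kw = sps.kruskal(*tested.values())
        kw_h, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:
        # all values identical across groups: H = 0 by convention
        kw_h, kw_p = 0.0, 1.0
    dunn = dunn_test(tested, alpha=alpha)
    return StatsReport(metric=metric or "value", group_summaries=summaries,
                       shapiro_p=shapiro_p, levene_p=levene_p,
                       kruskal_h=kw_h, kruskal_p=kw_p, dunn=dunn, alpha=alpha,
                       excluded_groups=excluded)
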