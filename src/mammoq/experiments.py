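"""Experiment orchestration: the AEC-position scan and the manual-mAs study.

The AEC scan images the phantom at each of the seven sensor positions
(replicated), groups positions 1-3 as "misused" (sensor under the Cu
implant surrogate) and 4-7 as "reference" (sensor clear of it), and runs
the comparison pipeline per metric. The manual study compares the
manufacturer's recommended manual mAs, the first console reduction level,
and the automatic reference arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analyze import analyze_image
from .config import RunConfig
from .exceptions import MammoqError
from .simulate import build_mean_signal_map, emulate_aec, simulate_acquisition
from .specs import ExposureSettings
from .stats import StatsReport, compare_groups, summarize

__all__ = ["ExperimentReport", "derive_seed", "run_aec_experiment", "run_manual_experiment"]

MISUSED_POSITIONS = (1, 2, 3)
REFERENCE_POSITIONS = (4, 5, 6, 7)
METRICS = ("SDNR", "dprime_0.1mm", "dprime_0.25mm", "AGD_mGy", "mAs", "kVp", "SNR_bg")


def derive_seed(seed_base: int, *keys: int) -> int:
    """Deterministic per-acquisition seed below 2**31 from a base and keys."""
    ss = np.random.SeedSequence(entropy=int(seed_base), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


@dataclass
class ExperimentReport:
    """Tidy samples, per-metric statistics and the acquisition log."""

    samples: pd.DataFrame                 # metric, group, replicate, value
    stats: dict[str, StatsReport]         # per metric, across all groups
    group_comparison: pd.DataFrame        # Table-style arm summary
    log: pd.DataFrame                     # one row per acquisition
    pairwise: dict[str, StatsReport] = field(default_factory=dict)
    percent_changes: Optional[pd.DataFrame] = None

    def metric_values(self, metric: str, group) -> np.ndarray:
        df = self.samples
        sel = df[(df["metric"] == metric) & (df["group"] == group)]
        return sel["value"].to_numpy(dtype=float)

    def markdown_table(self) -> str:
        lines = ["| Arm | " + " | ".join(c for c in self.group_comparison.columns
                                         if c != "arm") + " |"]
        lines.append("|" + "---|" * (len(self.group_comparison.columns)) )
        for _, row in self.group_comparison.iterrows():
            cells = [str(row["arm"])] + [str(row[c]) for c in self.group_comparison.columns
                                         if c != "arm"]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def _acquire_and_measure(config: RunConfig, exposure: ExposureSettings,
                         seed: int, mean_map: np.ndarray) -> dict:
    image = simulate_acquisition(
        mean_map, config.detector, seed,
        meta={"kvp": exposure.kvp, "mas": exposure.mas, "mode": exposure.mode,
              "aec_position": exposure.aec_position,
              "pmma_thickness_mm": config.phantom.pmma_thickness_mm})
    return analyze_image(image, config).metrics


def _collect(config: RunConfig, arms: dict, replicates: int, seed_base: int,
             arm_keys: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, log = [], []
    for arm, exposure in arms.items():
        mean_map = build_mean_signal_map(config.phantom, config.beam, config.detector,
                                         exposure, supersample=config.supersample)
        for rep in range(replicates):
            seed = derive_seed(seed_base, arm_keys[arm], rep)
            metrics = _acquire_and_measure(config, exposure, seed, mean_map)
            log.append({"arm": arm, "replicate": rep, "seed": seed,
                        "kvp": exposure.kvp, "mas": exposure.mas,
                        "mode": exposure.mode, "aec_position": exposure.aec_position})
            for metric, value in metrics.items():
                rows.append({"metric": metric, "group": arm, "replicate": rep,
                             "value": value})
    return pd.DataFrame(rows), pd.DataFrame(log)


def _safe_stats(samples: pd.DataFrame, metrics: Sequence[str]) -> dict:
    """Per-metric comparisons; metrics with too few replicates are skipped."""
    out = {}
    for m in metrics:
        try:
            out[m] = compare_groups(samples, m)
        except MammoqError:
            continue
    return out


def _arm_table(samples: pd.DataFrame, grouping: dict, metrics: Sequence[str],
               p_values: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for arm, members in grouping.items():
        row = {"arm": arm}
        for metric in metrics:
            df = samples[(samples["metric"] == metric) & samples["group"].isin(members)]
            row[metric] = str(summarize(df["value"].to_numpy(float), "median_iqr"))
        rows.append(row)
    if p_values is not None:
        rows.append({"arm": "p", **{m: f"{p_values[m]:.3g}" for m in metrics}})
    return pd.DataFrame(rows)


def run_aec_experiment(
    config: RunConfig,
    seed_base: int = 1000,
    replicates: int = 10,
    positions: Sequence[int] = tuple(range(1, 8)),
) -> ExperimentReport:
    """Image the phantom at each AEC position and compare misused vs reference."""
    if replicates < 1:
        raise MammoqError("need at least one replicate")
    arms = {}
    for pos in positions:
        arms[pos] = emulate_aec(config.phantom, config.beam, config.detector,
                                pos, aec=config.aec)
    samples, log = _collect(config, arms, replicates, seed_base,
                            {pos: pos for pos in arms})
    present = [m for m in METRICS if m != "kVp" and m in set(samples["metric"])]
    stats = _safe_stats(samples, present)

    # pooled misused (1-3) vs reference (4-7) comparison per metric
    pooled = samples.copy()
    pooled["group"] = pooled["group"].map(
        lambda g: "misused" if g in MISUSED_POSITIONS else "reference")
    pairwise = _safe_stats(pooled, present)
    table_metrics = [m for m in ("SDNR", "dprime_0.1mm", "dprime_0.25mm", "AGD_mGy")
                     if m in pairwise]
    p_vals = {m: float(pairwise[m].dunn["p_corrected"].iloc[0]) for m in table_metrics}
    table = _arm_table(samples,
                       {"misused": list(MISUSED_POSITIONS),
                        "reference": list(REFERENCE_POSITIONS)},
                       table_metrics, p_vals or None)
    return ExperimentReport(samples=samples, stats=stats, group_comparison=table,
                            log=log, pairwise=pairwise)


def _quantize(mas: float, quantum: float) -> float:
    return round(mas / quantum) * quantum


def paired_percent_change(old: np.ndarray, new: np.ndarray) -> tuple[float, float]:
    """Replicate-paired percent changes: mean and sample SD."""
    old, new = np.asarray(old, float), np.asarray(new, float)
    if old.shape != new.shape:
        raise MammoqError("paired percent change needs equal replicate counts")
    pct = 100.0 * (new - old) / old
    return float(pct.mean()), float(pct.std(ddof=1)) if pct.size > 1 else 0.0


def run_manual_experiment(
    config: RunConfig,
    seed_base: int = 2000,
    replicates: int = 10,
    reference_position: Optional[int] = None,
) -> ExperimentReport:
    """Recommended vs reduced manual mAs vs the automatic reference arm."""
    pos = reference_position or config.reference_aec_position
    kvp = config.aec.kvp_for_thickness(config.phantom.pmma_thickness_mm)
    reduced_mas = _quantize(config.recommended_mas * (1.0 - config.mas_reduction_fraction),
                            config.aec.mas_quantum)
    arms = {
        "recommended": ExposureSettings(kvp=kvp, mas=config.recommended_mas, mode="manual"),
        "reduced": ExposureSettings(kvp=kvp, mas=reduced_mas, mode="manual",
                                    mas_reduction_level=1),
        "reference": emulate_aec(config.phantom, config.beam, config.detector,
                                 pos, aec=config.aec),
    }
    samples, log = _collect(config, arms, replicates, seed_base,
                            {"recommended": 101, "reduced": 102, "reference": 103})
    present = [m for m in METRICS if m != "kVp" and m in set(samples["metric"])]
    stats = _safe_stats(samples, present)

    rows = []
    for m in ("SDNR", "dprime_0.1mm", "dprime_0.25mm", "AGD_mGy", "mAs"):
        row = {"metric": m}
        vals = {arm: samples[(samples["metric"] == m) & (samples["group"] == arm)]
                .sort_values("replicate")["value"].to_numpy(float) for arm in arms}
        for old, new, label in (("recommended", "reduced", "reduced_vs_recommended"),
                                ("reduced", "reference", "reference_vs_reduced"),
                                ("recommended", "reference", "reference_vs_recommended")):
            mean, sd = paired_percent_change(vals[old], vals[new])
            row[label] = f"{mean:+.1f} +/- {sd:.1f} %"
            row[label + "_mean"] = mean
        rows.append(row)
    changes = pd.DataFrame(rows)

    table = _arm_table(samples, {arm: [arm] for arm in arms},
                       ["SDNR", "dprime_0.1mm", "dprime_0.25mm", "AGD_mGy"])
    return ExperimentReport(samples=samples, stats=stats, group_comparison=table,
                            log=log, pairwise=stats, percent_changes=changes)
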