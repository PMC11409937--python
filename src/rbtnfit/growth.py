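"""Titers, MOI, EOP, and group comparisons from dilution-plating counts.

A plate observation is a colony or plaque count at a known dilution and
plated volume; the titer is ``count / (dilution * volume)`` per ml.
Averaging is hierarchical: technical replicates are averaged within each
biological replicate first, and only biological-replicate means enter the
statistics (technical replicates are never treated as independent).

Group comparisons use Tukey's HSD on the studentized-range distribution;
QQ normality is reported as a numeric diagnostic (the correlation of the
ordered sample with normal quantiles at plotting positions (i - 0.5) / n),
mirroring graphical usage rather than a formal test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = [
    "label", "day", "unit", "bio_rep", "tech_rep", "dilution", "volume_ml", "count",
]

#: colony counts outside this range are flagged (QC only, never excluded)
COUNTABLE_RANGE = (30, 300)


def significance_stars(p: float) -> str:
    """Figure-caption convention: * P<.05, ** P<.01, *** P<.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def titer_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Titers per (label, day, unit, biological replicate).

    Each observation contributes ``count / (dilution * volume_ml)``;
    technical replicates are averaged into one value per biological
    replicate. ``countable`` flags whether all raw counts were within the
    conventional countable range; ``lower_bound`` flags bio-reps whose
    every plate had zero counts (titer 0 is then a detection bound).
    """
    obs = observations.copy()
    if (obs["count"] < 0).any():
        raise ValueError("negative plate counts")
    if ((obs["dilution"] <= 0) | (obs["dilution"] > 1)).any():
        raise ValueError("dilution must be in (0, 1]")
    if (obs["volume_ml"] <= 0).any():
        raise ValueError("plated volume must be positive")
    obs["titer"] = obs["count"] / (obs["dilution"] * obs["volume_ml"])
    obs["countable"] = obs["count"].between(*COUNTABLE_RANGE)
    g = obs.groupby(["label", "day", "unit", "bio_rep"])
    out = g.agg(
        titer=("titer", "mean"),
        n_tech=("titer", "size"),
        countable=("countable", "all"),
        max_count=("count", "max"),
    ).reset_index()
    out["lower_bound"] = out["max_count"] == 0
    return out.drop(columns="max_count")


def titer_summary(bio_titers: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of titers across biological replicates."""
    g = bio_titers.groupby(["label", "day", "unit"])
    return g.agg(
        mean_titer=("titer", "mean"), sd_titer=("titer", "std"), n_bio=("titer", "size")
    ).reset_index()


def moi(pfu_inoculum: float, cfu_inoculum: float) -> float:
    """Multiplicity of infection: phage particles per host cell."""
    if cfu_inoculum <= 0:
        raise ValueError("MOI undefined for non-positive cfu inoculum")
    return pfu_inoculum / cfu_inoculum


@dataclass(frozen=True)
class EOPRecord:
    """Efficiency of plaquing of a phage on a mutant vs. wild-type lawn."""

    mutant_label: str
    mutant_pfu: float
    wildtype_pfu: float

    @property
    def eop(self) -> float:
        return eop(self.mutant_pfu, self.wildtype_pfu)


def eop(mutant_pfu: float, wildtype_pfu: float) -> float:
    """pfu on the test lawn over pfu on the wild-type lawn (0 = resistant)."""
    if wildtype_pfu <= 0:
        raise ValueError("EOP assay invalid: wild-type lawn produced no plaques")
    if mutant_pfu < 0:
        raise ValueError("negative pfu count")
    return mutant_pfu / wildtype_pfu


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's multiple comparisons of means (studentized range).

    ``groups`` maps labels to per-biological-replicate values. Groups with
    fewer than 2 values are excluded with a warning. Returns one row per
    unordered pair with the mean difference, q statistic, adjusted p-value,
    significance stars, and a reject flag at ``alpha``.
    """
    usable = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 2:
            warnings.warn(f"group {label!r} has <2 values; excluded from Tukey HSD")
            continue
        usable[label] = arr
    k = len(usable)
    if k < 2:
        raise ValueError("Tukey HSD needs at least two groups with >=2 values")
    ns = {g: len(v) for g, v in usable.items()}
    means = {g: float(v.mean()) for g, v in usable.items()}
    n_total = sum(ns.values())
    dof = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in usable.values())
    mse = sse / dof

    rows = []
    for a, b in combinations(sorted(usable), 2):
        diff = means[b] - means[a]
        if mse > 0:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, dof))
        else:  # degenerate: no within-group variance at all
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        rows.append(
            {
                "group_a": a, "group_b": b, "mean_diff": diff, "q": q,
                "p_adj": p, "stars": significance_stars(p), "reject": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def compare_growth(
    bio_titers: pd.DataFrame,
    day: int,
    unit: str = "cfu",
    alpha: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Tukey HSD across condition labels at one day.

    Titers span decades, so comparisons default to log10(titer + 1)
    per biological replicate (the +1 keeps extinct samples finite).
    """
    sub = bio_titers[(bio_titers["day"] == day) & (bio_titers["unit"] == unit)]
    groups = {
        label: (np.log10(v["titer"] + 1.0) if log_scale else v["titer"])
        for label, v in sub.groupby("label")
    }
    return tukey_hsd(groups, alpha=alpha)


@dataclass
class QQResult:
    """Ordered quantile pairs and their correlation diagnostic."""

    theoretical: np.ndarray
    sample: np.ndarray
    correlation: float


def qq_normality(values: Sequence[float]) -> QQResult:
    """Normal QQ pairs at plotting positions (i - 0.5)/n, with correlation.

    A constant vector has no defined correlation; NaN is returned for it.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError("QQ diagnostic requires at least 3 values")
    positions = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(positions)
    if np.ptp(x) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(theo, x)[0, 1])
    return QQResult(theoretical=theo, sample=x, correlation=corr)
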