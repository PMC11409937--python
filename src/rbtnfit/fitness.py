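"""Strain and gene fitness with two-stage normalization and moderated t-scores.

For each barcode surviving the count filters, the raw strain fitness is the
log2 change in relative abundance between the T0 reference and a day-3
sample, with a pseudocount for finiteness:

    f_s = log2( ((n_3 + eps) / N_3) / ((n_0 + eps) / N_0) ),  eps = 0.5.

Gene fitness is the weighted mean of its strains' fitness, with
inverse-variance style weights w_s = 2 / (1/(1+n_0) + 1/(1+n_3)) — the
approximate precision of a count log-ratio.

Two normalizations follow, per replicate:

1. *position*: a circular running median of gene fitness along the
   chromosome (window 251 genes, truncated when fewer exist) is subtracted,
   removing the copy-number trend toward the replication origin;
2. *mode*: the mode of the fitness distribution (histogram with 0.05-wide
   bins over the central 95% of values, ties broken toward 0) is
   subtracted, anchoring the assumed-neutral majority at zero.

The moderated t-score divides final gene fitness by a standard deviation
whose variance is floored by a count-limited term, so genes with few reads
cannot reach large |t| by chance:

    t = f / sqrt(max(V_between / n_eff, V_floor)),
    V_floor = (1/ln 2)^2 * (1/(1+N_0,gene) + 1/(1+N_3,gene)),

with n_eff = (sum w)^2 / sum w^2 the effective strain number. Replicates
are averaged arithmetically (fitness and t alike); a gene has a strong
effect when |mean t| >= 3, with the sign taken from the mean fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

LOG2_SQ = (1.0 / np.log(2.0)) ** 2


@dataclass(frozen=True)
class FitnessParams:
    """Tunable constants of the fitness model."""

    pseudocount: float = 0.5
    window: int = 251
    bin_width: float = 0.05
    central_range: float = 0.95
    t_threshold: float = 3.0


def strain_fitness(n_day3, n_t0, total_day3, total_t0, pseudocount: float = 0.5):
    """Raw log2 change in within-sample relative abundance."""
    if total_day3 <= 0 or total_t0 <= 0:
        raise ValueError("sample totals must be positive")
    n3 = np.asarray(n_day3, dtype=float)
    n0 = np.asarray(n_t0, dtype=float)
    return np.log2(
        ((n3 + pseudocount) / total_day3) / ((n0 + pseudocount) / total_t0)
    )


def strain_weight(n_t0, n_day3):
    """Inverse approximate variance of a count log-ratio (harmonic form)."""
    n0 = np.asarray(n_t0, dtype=float)
    n3 = np.asarray(n_day3, dtype=float)
    return 2.0 / (1.0 / (1.0 + n0) + 1.0 / (1.0 + n3))


def gene_fitness(fitness, weights) -> float:
    """Weighted mean of strain fitness values."""
    return float(np.average(np.asarray(fitness, float), weights=np.asarray(weights, float)))


def _effective_window(window: int, n: int) -> int:
    """Largest odd window <= min(window, n)."""
    eff = min(window, n)
    if eff % 2 == 0:
        eff -= 1
    return max(eff, 1)


def smoothed_median(values, window: int = 251) -> np.ndarray:
    """Circular centered running median (window truncated to odd <= n)."""
    x = np.asarray(values, dtype=float)
    eff = _effective_window(window, len(x))
    return median_filter(x, size=eff, mode="wrap")


def normalize_position(values, window: int = 251) -> np.ndarray:
    """Subtract the circular running median (values ordered by gene midpoint)."""
    x = np.asarray(values, dtype=float)
    return x - smoothed_median(x, window)


def fitness_mode(values, bin_width: float = 0.05, central_range: float = 0.95) -> float:
    """Mode of a fitness distribution via a fixed-width histogram scan.

    Bins of ``bin_width`` cover the central ``central_range`` of the values;
    the center of the fullest bin is returned, ties broken toward 0.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("mode estimation requires at least 10 values")
    tail = (1.0 - central_range) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    if hi - lo < bin_width:
        return float((lo + hi) / 2.0)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best = np.flatnonzero(counts == counts.max())
    # tie-break toward 0 (then toward the lower center, deterministically)
    pick = min(best, key=lambda i: (abs(centers[i]), centers[i]))
    return float(centers[pick])


def normalize_mode(values, bin_width: float = 0.05, central_range: float = 0.95):
    """Subtract the distribution mode, anchoring neutral genes at zero."""
    x = np.asarray(values, dtype=float)
    return x - fitness_mode(x, bin_width, central_range)


def gene_variance(strain_fit, weights, gene_t0_reads, gene_day3_reads) -> float:
    """Moderated variance: between-strain variance floored by a count term."""
    f = np.asarray(strain_fit, dtype=float)
    w = np.asarray(weights, dtype=float)
    sw = w.sum()
    n_eff = sw**2 / np.sum(w**2)
    if len(f) > 1:
        mu = np.average(f, weights=w)
        between = np.average((f - mu) ** 2, weights=w)
        v_between = between / n_eff
    else:
        v_between = 0.0
    v_floor = LOG2_SQ * (1.0 / (1.0 + gene_t0_reads) + 1.0 / (1.0 + gene_day3_reads))
    return float(max(v_between, v_floor))


def t_score(final_fitness: float, variance: float) -> float:
    """Moderated t-statistic: final fitness over its standard deviation."""
    return float(final_fitness / np.sqrt(variance))


def fit_replicate(
    counts: pd.DataFrame,
    strains: pd.DataFrame,
    t0: str,
    sample: str,
    gene_order: pd.Index,
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """Per-gene fitness and t-score for one day-3 sample against T0.

    ``strains`` maps retained central barcodes to genes; ``gene_order``
    lists retained genes by chromosomal midpoint (the running-median axis).
    """
    n0_all = counts[t0]
    n3_all = counts[sample]
    total0 = float(n0_all.sum())
    total3 = float(n3_all.sum())

    n0 = n0_all.loc[strains["barcode"]].to_numpy(float)
    n3 = n3_all.loc[strains["barcode"]].to_numpy(float)
    f = strain_fitness(n3, n0, total3, total0, params.pseudocount)
    w = strain_weight(n0, n3)

    df = pd.DataFrame(
        {"locus_tag": strains["locus_tag"].to_numpy(), "f": f, "w": w,
         "wf": w * f, "n0": n0, "n3": n3}
    )
    g = df.groupby("locus_tag")
    agg = g.agg(
        sw=("w", "sum"), swf=("wf", "sum"), n_strains=("f", "size"),
        reads_t0=("n0", "sum"), reads_day3=("n3", "sum"),
    )
    agg["raw"] = agg["swf"] / agg["sw"]

    agg = agg.reindex(gene_order)
    pos_norm = normalize_position(agg["raw"].to_numpy(), params.window)
    final = normalize_mode(pos_norm, params.bin_width, params.central_range)
    agg["fitness_posnorm"] = pos_norm
    agg["fitness"] = final

    groups = dict(iter(g))
    variances = np.empty(len(agg))
    for i, locus in enumerate(agg.index):
        sub = groups[locus]
        variances[i] = gene_variance(
            sub["f"].to_numpy(), sub["w"].to_numpy(),
            agg["reads_t0"].iloc[i], agg["reads_day3"].iloc[i],
        )
    agg["variance"] = variances
    agg["t"] = agg["fitness"] / np.sqrt(agg["variance"])

    out = agg.reset_index().rename(columns={"raw": "fitness_raw", "index": "locus_tag"})
    return out[
        ["locus_tag", "fitness_raw", "fitness_posnorm", "fitness", "variance", "t",
         "n_strains", "reads_t0", "reads_day3"]
    ]


def compute_fitness(
    filtered,
    genes: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """Per-replicate gene fitness for every day-3 sample in the sheet.

    ``filtered`` is a :class:`rbtnfit.counting.FilteredCounts`. Returns one
    row per gene x condition x replicate.
    """
    sheet = filtered.sample_sheet
    t0 = filtered.t0
    retained = filtered.strains["locus_tag"].unique()
    mid = genes.set_index("locus_tag").loc[retained]
    gene_order = pd.Index(
        ((mid["start"] + mid["end"]) / 2.0).sort_values().index, name="locus_tag"
    )

    frames = []
    for row in sheet[sheet["timepoint"] != "T0"].itertuples(index=False):
        rep = fit_replicate(
            filtered.counts, filtered.strains, t0, row.sample, gene_order, params
        )
        rep.insert(0, "replicate", row.replicate)
        rep.insert(0, "condition", row.condition)
        rep.insert(0, "sample", row.sample)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def aggregate_replicates(
    per_replicate: pd.DataFrame,
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """Average fitness and t across replicates; flag strong effects.

    A gene may fail filters in some replicates; it is averaged over the
    replicates where it is defined and ``n_replicates`` records how many.
    Strong effect: |mean t| >= threshold, sign from the mean fitness.
    """
    g = per_replicate.groupby(["locus_tag", "condition"])
    table = g.agg(
        fitness=("fitness", "mean"),
        t=("t", "mean"),
        n_replicates=("t", "size"),
        n_strains=("n_strains", "mean"),
    ).reset_index()
    strong = np.abs(table["t"]) >= params.t_threshold
    sign = np.sign(table["fitness"]).astype(int)
    table["strong"] = strong & (sign != 0)
    table["sign"] = np.where(table["strong"], sign, 0)
    return table
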