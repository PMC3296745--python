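"""Dosage-expression trend statistics and contiguous-cluster analysis.

Two families of questions:

* does the deregulation rate rise with the number of altered SNPs per gene
  or per region?  Answered with the Mantel-Haenszel linear-by-linear
  association chi-square ``M^2 = (N-1) r^2`` over ordered bins, and with
  Spearman correlation for the specifically-downregulated trend;
* are deregulated genes arranged in runs of 2+ contiguous neighbours more
  than chance allows?  Answered with a Monte-Carlo permutation-calibrated
  goodness-of-fit on clustered vs unclustered deregulated counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendTable",
    "ClusterReport",
    "bin_trend_table",
    "linear_by_linear_test",
    "downregulation_trend",
    "find_gene_clusters",
    "cluster_randomness_test",
    "DEFAULT_REGION_BINS",
    "DEFAULT_GENE_BINS",
]

# region bins by SNP count: 1-100, 101-500, >500
DEFAULT_REGION_BINS = (0, 100, 500, np.inf)
# per-gene altered-SNP bins: 0, 1, 2-5, 6-20, >20
DEFAULT_GENE_BINS = (-1, 0, 1, 5, 20, np.inf)


@dataclass
class TrendTable:
    """Ordered bins of units with per-bin deregulation counts."""

    table: pd.DataFrame          # columns: bin, score, n, k, pct
    n_total: int

    def nonempty(self) -> pd.DataFrame:
        return self.table[self.table["n"] > 0]


@dataclass
class ClusterReport:
    statuses: list[str]
    runs: list[tuple[int, int]]          # inclusive index ranges, length >= 2
    n_deregulated: int
    clustered: int

    @property
    def clustered_fraction(self) -> float:
        if self.n_deregulated == 0:
            return float("nan")
        return self.clustered / self.n_deregulated


def bin_trend_table(
    snp_counts: pd.Series | np.ndarray,
    de_flags: pd.Series | np.ndarray,
    bin_edges=DEFAULT_REGION_BINS,
) -> TrendTable:
    """Bin units by their altered-SNP count and tabulate deregulation.

    ``bin_edges`` are strictly increasing; unit u falls in bin i when
    ``edges[i] < count_u <= edges[i+1]``.  Empty bins are retained with
    n = 0 so the bin scores stay anchored.
    """
    counts = np.asarray(snp_counts, float)
    flags = np.asarray(de_flags, bool)
    edges = np.asarray(bin_edges, float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    if (counts <= edges[0]).any() or (counts > edges[-1]).any():
        raise ValueError("unit with SNP count outside the bin range")
    which = np.digitize(counts, edges[1:-1], right=True)
    rows = []
    for i in range(len(edges) - 1):
        mask = which == i
        n = int(mask.sum())
        k = int(flags[mask].sum())
        lo, hi = edges[i], edges[i + 1]
        label = f"{int(lo) + 1}-{int(hi)}" if np.isfinite(hi) else f">{int(lo)}"
        rows.append({"bin": label, "score": i + 1, "n": n, "k": k,
                     "pct": 100.0 * k / n if n else np.nan})
    return TrendTable(table=pd.DataFrame(rows), n_total=int(len(counts)))


def linear_by_linear_test(t: TrendTable) -> tuple[float, float]:
    """Mantel-Haenszel linear-by-linear association chi-square.

    ``M^2 = (N-1) r^2`` with r the Pearson correlation between the integer
    bin score and the binary outcome over all N units, computed from the
    binned counts.  Returns (m2, p) with p from the df=1 chi-square upper
    tail; NA when scores or outcomes have zero variance.
    """
    tb = t.nonempty()
    if len(tb) < 2:
        return float("nan"), float("nan")
    s = tb["score"].to_numpy(float)
    n = tb["n"].to_numpy(float)
    k = tb["k"].to_numpy(float)
    N = n.sum()
    K = k.sum()
    sxy = (s * k).sum() - (s * n).sum() * K / N
    sxx = (s**2 * n).sum() - (s * n).sum() ** 2 / N
    syy = K - K**2 / N
    if sxx <= 0 or syy <= 0:
        return float("nan"), float("nan")
    r = sxy / np.sqrt(sxx * syy)
    m2 = (N - 1) * r**2
    return float(m2), float(stats.chi2.sf(m2, df=1))


def downregulation_trend(
    snp_counts: pd.Series | np.ndarray,
    down_flags: pd.Series | np.ndarray,
    bin_edges=DEFAULT_GENE_BINS,
) -> dict:
    """Spearman trend of downregulation with the altered-SNP count.

    Reports both the bin-level correlation (bin rank vs downregulated
    fraction over non-empty bins) and the unit-level correlation (raw SNP
    count vs the binary downregulation indicator), with two-sided p values.
    Ties-only input yields NaN.
    """
    t = bin_trend_table(snp_counts, down_flags, bin_edges)
    tb = t.nonempty()
    out = {"bins": t.table, "rho_bins": np.nan, "p_bins": np.nan,
           "rho_units": np.nan, "p_units": np.nan}
    if len(tb) >= 3:
        if tb["pct"].nunique() > 1:
            rho, p = stats.spearmanr(tb["score"], tb["pct"])
            out["rho_bins"], out["p_bins"] = float(rho), float(p)
        else:  # perfectly flat fractions: no trend by definition
            out["rho_bins"], out["p_bins"] = 0.0, 1.0
    counts = np.asarray(snp_counts, float)
    flags = np.asarray(down_flags, float)
    if len(np.unique(counts)) > 1 and len(np.unique(flags)) > 1:
        rho, p = stats.spearmanr(counts, flags)
        out["rho_units"], out["p_units"] = float(rho), float(p)
    return out


def find_gene_clusters(statuses) -> ClusterReport:
    """Maximal runs of >=2 contiguous deregulated genes.

    ``statuses`` is the genomically ordered sequence of ``up``/``down``/
    ``unchanged`` for one region; runs may mix up and down genes.  Returns
    the runs as inclusive index ranges plus the clustered fraction
    (deregulated genes inside runs over all deregulated genes).
    """
    statuses = list(statuses)
    dereg = [s in ("up", "down") for s in statuses]
    runs = []
    i = 0
    n = len(statuses)
    while i < n:
        if not dereg[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and dereg[j + 1]:
            j += 1
        if j > i:
            runs.append((i, j))
        i = j + 1
    clustered = sum(b - a + 1 for a, b in runs)
    return ClusterReport(
        statuses=statuses,
        runs=runs,
        n_deregulated=int(sum(dereg)),
        clustered=clustered,
    )


def _clustered_count(dereg: np.ndarray) -> int:
    """Deregulated genes that have a deregulated neighbour."""
    left = np.zeros_like(dereg)
    right = np.zeros_like(dereg)
    left[1:] = dereg[:-1]
    right[:-1] = dereg[1:]
    return int((dereg & (left | right)).sum())


def cluster_randomness_test(
    report: ClusterReport,
    n_monte_carlo: int = 5000,
    seed: int = 0,
) -> dict:
    """Is the observed clustering compatible with a random arrangement?

    The expected number of clustered deregulated genes is estimated by
    Monte-Carlo permutation of the status sequence over positions
    (preserving the status counts).  A df=1 chi-square goodness-of-fit
    compares observed vs expected clustered/unclustered deregulated
    counts; when an expected cell is below 1 the Monte-Carlo exceedance
    probability is reported instead.  Deterministic for a fixed seed.
    """
    dereg = np.array([s in ("up", "down") for s in report.statuses])
    D = int(dereg.sum())
    if D < 2 or len(dereg) < 2:
        return {"chi2": np.nan, "p": np.nan, "expected_clustered": np.nan,
                "p_mc": np.nan, "n_monte_carlo": n_monte_carlo, "seed": seed}
    rng = np.random.default_rng(seed)
    obs = report.clustered
    sims = np.empty(n_monte_carlo)
    work = dereg.copy()
    for b in range(n_monte_carlo):
        rng.shuffle(work)
        sims[b] = _clustered_count(work)
    expected = float(sims.mean())
    p_mc = float((1 + (sims >= obs).sum()) / (n_monte_carlo + 1))
    exp_cells = np.array([expected, D - expected])
    obs_cells = np.array([obs, D - obs], float)
    if (exp_cells < 1).any():
        chi2, p = np.nan, p_mc
    else:
        chi2 = float(((obs_cells - exp_cells) ** 2 / exp_cells).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    return {"chi2": chi2, "p": p, "expected_clustered": expected,
            "p_mc": p_mc, "n_monte_carlo": n_monte_carlo, "seed": seed}
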