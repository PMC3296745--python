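"""Regional enrichment statistics: continuity-corrected 2x2 chi-square
with Fisher fallback, arm/cytoband enrichment scans, the parametric
gene-set Z score (PAGE), and the per-MRR deregulation test.

The PAGE score for a gene set of size *m* with mean fold change ``Sm`` is
``Z = (Sm - mu) * sqrt(m) / delta`` where ``mu`` and ``delta`` are the mean
and standard deviation of the fold change over *all* deregulated genes;
sets with fewer than 10 deregulated genes are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "two_by_two_chisq",
    "regional_enrichment_scan",
    "page_scan",
    "mrr_deregulation_test",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a,b) in the region of interest, (c,d) in the background."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        n = self.n
        r1, r2 = self.a + self.b, self.c + self.d
        c1, c2 = self.a + self.c, self.b + self.d
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], float) / n


def two_by_two_chisq(t: TwoByTwo, correction: bool = True) -> tuple[float, float, str]:
    """Chi-square test of a 2x2 table, Yates-corrected by default.

    ``chi2 = N (|ad - bc| - correction*N/2)^2 / ((a+b)(c+d)(a+c)(b+d))``,
    p from the df=1 upper tail.  Falls back to Fisher's exact test when a
    margin is zero or any expected count is below 5; the third element of
    the result names the method used (``chi2``, ``chi2_uncorrected`` or
    ``fisher``).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or 0 in margins or (t.expected() < 5).any():
        _, p = stats.fisher_exact([[a, b], [c, d]])
        return float("nan"), float(p), "fisher"
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, "chi2" if correction else "chi2_uncorrected"


def regional_enrichment_scan(
    labels: pd.Series,
    hits: pd.Series,
    alpha: float = 0.05,
    correction: bool = True,
) -> pd.DataFrame:
    """Per-region hit enrichment versus the rest of the genome.

    ``labels`` assigns each unit (SNP or gene) its arm or cytoband;
    ``hits`` is the boolean altered/deregulated flag.  Each region is
    tested region-vs-rest with the corrected chi-square (Fisher fallback);
    ``enriched`` flags regions whose hit rate exceeds the background rate
    with p < alpha.  Regions with zero units cannot occur (they have no
    label); a single-region scan yields NA p-values.
    """
    labels = labels.astype(str)
    hits = hits.astype(bool)
    total_hits = int(hits.sum())
    total = len(hits)
    rows = []
    regions = labels.unique()
    for region in sorted(regions):
        mask = (labels == region).to_numpy()
        k = int(hits[mask].sum())
        m = int(mask.sum())
        row = {
            "region": region,
            "hits": k,
            "n": m,
            "pct": 100.0 * k / m if m else np.nan,
            "chi2": np.nan,
            "p": np.nan,
            "method": "na",
            "enriched": False,
        }
        if len(regions) > 1 and m > 0:
            t = TwoByTwo(k, m - k, total_hits - k, (total - m) - (total_hits - k))
            chi2, p, method = two_by_two_chisq(t, correction=correction)
            bg_rate = (total_hits - k) / (total - m) if total > m else np.nan
            row.update(
                chi2=chi2, p=p, method=method,
                enriched=bool(p < alpha and m and k / m > bg_rate),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def page_scan(
    fold_changes: pd.Series,
    labels: pd.Series,
    min_m: int = 10,
    log_scale: bool = True,
) -> pd.DataFrame:
    """PAGE Z score per gene set over the deregulated genes.

    ``fold_changes`` holds the fold change of every deregulated gene and
    ``labels`` its region.  With ``log_scale`` the ratios are moved to the
    signed log2 axis so up- and downregulation are symmetric (1.5 and its
    reciprocal map to +/-0.585); mu and delta always come from the full
    deregulated set.  Sets below ``min_m`` are reported with NaN Z and the
    reason ``too_few_genes``.
    """
    x = np.log2(fold_changes.to_numpy(float)) if log_scale else fold_changes.to_numpy(float)
    mu = float(x.mean())
    delta = float(x.std(ddof=0))
    if delta == 0:
        raise ValueError("degenerate global fold-change distribution (delta=0)")
    labels = labels.astype(str)
    rows = []
    for region in sorted(labels.unique()):
        mask = (labels == region).to_numpy()
        m = int(mask.sum())
        sm = float(x[mask].mean()) if m else np.nan
        if m < min_m:
            rows.append({"set_name": region, "m": m, "Sm": sm, "z": np.nan,
                         "p": np.nan, "note": "too_few_genes"})
            continue
        z = (sm - mu) * np.sqrt(m) / delta
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"set_name": region, "m": m, "Sm": sm, "z": float(z),
                     "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    out.attrs["mu"] = mu
    out.attrs["delta"] = delta
    return out


def mrr_deregulation_test(
    per_mrr: pd.DataFrame,
    include_self_in_background: bool = True,
    correction: bool = True,
) -> pd.DataFrame:
    """Compare each MRR's deregulated-gene rate with the whole MRR set.

    ``per_mrr`` needs columns ``mrr_id``, ``explored`` (genes with an
    expression call) and ``deregulated``.  Each region's (k, n-k) is tested
    against the totals of the whole set, which by default include the
    tested MRR itself.  Regions with zero explored genes get an NA row.
    """
    total_n = int(per_mrr["explored"].sum())
    total_k = int(per_mrr["deregulated"].sum())
    rows = []
    for row in per_mrr.itertuples(index=False):
        n, k = int(row.explored), int(row.deregulated)
        rec = {"mrr_id": row.mrr_id, "explored": n, "deregulated": k,
               "pct": 100.0 * k / n if n else np.nan,
               "chi2": np.nan, "p": np.nan, "method": "na"}
        if n > 0:
            if include_self_in_background:
                bk, bn = total_k, total_n
            else:
                bk, bn = total_k - k, total_n - n
            t = TwoByTwo(k, n - k, bk, bn - bk)
            chi2, p, method = two_by_two_chisq(t, correction=correction)
            rec.update(chi2=chi2, p=p, method=method)
        rows.append(rec)
    return pd.DataFrame(rows)
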