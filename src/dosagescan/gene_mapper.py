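"""Mapping genes onto CNAs/MRRs and dosage-vs-expression accounting.

A gene is assigned to a region whenever its span intersects the region
interval at all (partial overlap counts).  Per sample, the gene's copy
number class is gain/loss/normal according to the overlapping CNA; the
number of altered probes whose position falls inside the gene span is
counted separately — many genes sit between two altered probes inside a
CNA and have zero altered probes of their own.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cna_builder import Cna, classify_states
from .io_model import SnpDataset
from .mrr_finder import Mrr

__all__ = ["map_genes", "average_dosage_rows", "build_dosage_expression_table"]


def _trees(regions, key) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # closed interval [start, end] -> half-open [start, end+1)
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    return trees


def map_genes(
    genes: pd.DataFrame,
    cna_sets: dict[str, list[Cna]],
    mrrs: list[Mrr],
    ds: SnpDataset,
) -> pd.DataFrame:
    """Per-gene dosage calls against per-sample CNAs and the MRR set.

    Returns a frame indexed by gene_id with, per sample ``s``, columns
    ``cn_class_<s>`` (gain/loss/normal), ``altered_snps_<s>`` and
    ``cna_ids_<s>``; plus ``mrr_ids``, ``recurrent`` (CN-altered in every
    sample) and ``recurrent_snps`` (probes in the span altered in all
    samples).  Genes on chromosomes absent from the probe map are excluded
    with a warning.

    When a gene span intersects CNAs of both directions in one sample the
    class of the largest-overlap CNA is used (ties resolve to gain).
    """
    known = set(ds.probes["chrom"].unique()) | {
        c.chrom for cl in cna_sets.values() for c in cl
    }
    unknown = ~genes["chrom"].isin(known)
    if unknown.any():
        warnings.warn(
            f"excluding {int(unknown.sum())} genes on chromosomes without probes"
        )
        genes = genes.loc[~unknown]

    samples = list(cna_sets)
    sample_trees = {s: _trees(cl, "cna_id") for s, cl in cna_sets.items()}
    mrr_tree = _trees(mrrs, "mrr_id")

    signs = np.column_stack(
        [classify_states(ds.states[s].to_numpy()) for s in samples]
    )
    probe_pos = ds.probes["pos"].to_numpy()
    probe_chrom = ds.probes["chrom"].to_numpy()
    pos_by_chrom = {
        c: (np.flatnonzero(probe_chrom == c), probe_pos[probe_chrom == c])
        for c in np.unique(probe_chrom)
    }

    records = []
    for row in genes.itertuples(index=False):
        rec: dict = {"gene_id": row.gene_id, "chrom": row.chrom,
                     "start": int(row.start), "end": int(row.end)}
        gstart, gend = int(row.start), int(row.end)
        if row.chrom in pos_by_chrom:
            idx, cpos = pos_by_chrom[row.chrom]
            lo = int(np.searchsorted(cpos, gstart, side="left"))
            hi = int(np.searchsorted(cpos, gend, side="right"))
            span_idx = idx[lo:hi]
        else:
            span_idx = np.array([], dtype=int)
        n_altered_all = 0
        if len(span_idx):
            span_signs = signs[span_idx]
            n_altered_all = int((span_signs != 0).all(axis=1).sum())
        rec["recurrent_snps"] = n_altered_all

        n_cn_samples = 0
        for j, s in enumerate(samples):
            hits = sample_trees[s].get(row.chrom, IntervalTree()).overlap(
                gstart, gend + 1
            ) if row.chrom in sample_trees[s] else set()
            hits = sorted(hits, key=lambda iv: iv.begin)
            if hits:
                n_cn_samples += 1
                best = max(
                    hits,
                    key=lambda iv: (
                        min(iv.end - 1, gend) - max(iv.begin, gstart),
                        iv.data.direction == "gain",
                    ),
                )
                rec[f"cn_class_{s}"] = best.data.direction
            else:
                rec[f"cn_class_{s}"] = "normal"
            rec[f"cna_ids_{s}"] = ",".join(iv.data.cna_id for iv in hits)
            if len(span_idx):
                rec[f"altered_snps_{s}"] = int((signs[span_idx, j] != 0).sum())
            else:
                rec[f"altered_snps_{s}"] = 0
        rec["recurrent"] = n_cn_samples == len(samples)
        mhits = mrr_tree.get(row.chrom, IntervalTree()).overlap(
            gstart, gend + 1
        ) if row.chrom in mrr_tree else set()
        rec["mrr_ids"] = ",".join(
            sorted(iv.data.mrr_id for iv in mhits)
        )
        records.append(rec)
    out = pd.DataFrame(records).set_index("gene_id")
    return out


def _pct(k, n):
    return 100.0 * k / n if n else float("nan")


def average_dosage_rows(rows: list[dict], n_explored: float | None = None) -> dict:
    """Average row of the dosage-expression table.

    Counts are averaged as plain means of the per-sample counts;
    percentages are ratios of the *averaged* counts (not means of
    percentages), the convention of the printed accounting this table
    replicates.  Count keys: ``genes_cn, cn_n, cn_ex, nocn_n, nocn_ex,
    all_ex``.
    """
    df = pd.DataFrame(rows)
    avg = df.mean(axis=0)
    out = {k: float(avg[k]) for k in
           ("genes_cn", "cn_n", "cn_ex", "nocn_n", "nocn_ex", "all_ex")
           if k in avg}
    out["cn_pct"] = _pct(avg["cn_ex"], avg["cn_n"])
    out["nocn_pct"] = _pct(avg["nocn_ex"], avg["nocn_n"])
    if n_explored is None:
        n_explored = float(avg["cn_n"] + avg["nocn_n"])
    out["all_pct"] = _pct(avg["all_ex"], n_explored)
    return out


def build_dosage_expression_table(
    calls: pd.DataFrame,
    de_status: pd.Series | pd.DataFrame,
    pooled_status: pd.Series | None = None,
    samples: list[str] | None = None,
) -> dict:
    """Dosage-vs-deregulation accounting across samples.

    Parameters
    ----------
    calls
        Output of :func:`map_genes`.
    de_status
        Per-gene status (``up``/``down``/``unchanged``) for the genes that
        were explored for expression.  A Series applies the same calls to
        every sample; a DataFrame with one column per sample supplies
        per-line calls.  Genes absent from the index count as unexplored
        and are excluded from all denominators.
    pooled_status
        Status from the pooled all-lines-vs-controls comparison, used for
        the recurrent-genes row.  Defaults to ``de_status`` when that is a
        Series.
    samples
        Sample order; inferred from the call columns by default.

    Returns a dict with per-sample rows (CN-altered genes, explored n,
    deregulated EX+ and %, same for CN-normal genes, and the overall
    deregulation column), an ``average`` row computed with
    :func:`average_dosage_rows`, and a ``recurrent`` row comparing genes
    CN-altered in all samples with all remaining explored genes.
    """
    if samples is None:
        samples = [c[len("cn_class_"):] for c in calls.columns
                   if c.startswith("cn_class_")]
    per_sample_status = isinstance(de_status, pd.DataFrame)
    if pooled_status is None:
        if per_sample_status:
            raise ValueError("per-sample statuses need an explicit pooled_status")
        pooled_status = de_status
    explored = calls.index.intersection(de_status.index)

    rows = {}
    for s in samples:
        status_s = de_status[s] if per_sample_status else de_status
        dereg_s = status_s.loc[explored] != "unchanged"
        cn = calls[f"cn_class_{s}"] != "normal"
        cn_explored = calls.index[cn].intersection(explored)
        nocn_explored = calls.index[~cn].intersection(explored)
        k_cn = int(dereg_s.loc[cn_explored].sum())
        k_no = int(dereg_s.loc[nocn_explored].sum())
        rows[s] = {
            "genes_cn": int(cn.sum()),
            "cn_n": len(cn_explored),
            "cn_ex": k_cn,
            "cn_pct": _pct(k_cn, len(cn_explored)),
            "nocn_n": len(nocn_explored),
            "nocn_ex": k_no,
            "nocn_pct": _pct(k_no, len(nocn_explored)),
            "all_ex": k_cn + k_no,
            "all_pct": _pct(k_cn + k_no, len(explored)),
        }
    average = average_dosage_rows(list(rows.values()), n_explored=len(explored))

    dereg = pooled_status.loc[explored] != "unchanged"
    rec = calls["recurrent"]
    rec_explored = calls.index[rec].intersection(explored)
    rest_explored = calls.index[~rec].intersection(explored)
    k_rec = int(dereg.loc[rec_explored].sum())
    k_rest = int(dereg.loc[rest_explored].sum())
    recurrent = {
        "genes_cn": int(rec.sum()),
        "cn_n": len(rec_explored),
        "cn_ex": k_rec,
        "cn_pct": _pct(k_rec, len(rec_explored)),
        "nocn_n": len(rest_explored),
        "nocn_ex": k_rest,
        "nocn_pct": _pct(k_rest, len(rest_explored)),
        "all_ex": k_rec + k_rest,
        "all_pct": _pct(k_rec + k_rest, len(explored)),
    }
    return {
        "per_sample": rows,
        "average": average,
        "recurrent": recurrent,
        "n_explored": len(explored),
    }
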