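"""Minimal recurrent regions (MRRs): intervals altered in every sample.

An MRR is a maximal genomic interval where every sample of the cohort
carries an overlapping CNA — the n-way intersection of the per-sample CNA
interval sets.  A region is labelled ``gained`` or ``deleted`` when all
supporting CNAs agree in direction, and ``combined`` when some samples
carry a gain and others a loss over the same interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cna_builder import Cna, classify_states
from .io_model import SnpDataset

__all__ = ["Mrr", "recurrent_altered_snps", "find_mrrs", "summarize_mrr", "mrrs_to_frame"]


@dataclass(frozen=True)
class Mrr:
    """A minimal recurrent region with its per-sample support."""

    mrr_id: str                     # e.g. "5-1": chromosome body, dash, rank
    chrom: str
    start: int
    end: int
    direction: str                  # gained | deleted | combined
    support: dict = field(hash=False)  # sample_id -> tuple of supporting cna_ids
    n_snps: int = 0
    recurrent_snp_count: int = 0

    @property
    def size_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


def recurrent_altered_snps(ds: SnpDataset) -> pd.Series:
    """Label each probe by recurrence of alteration across all samples.

    Returns a Series aligned to the probe table with values ``none``,
    ``recurrent-gained``, ``recurrent-deleted`` or ``recurrent-mixed``
    (altered in every sample but with disagreeing direction).
    """
    if len(ds.samples) < 2:
        raise ValueError("recurrence needs at least 2 samples")
    signs = np.column_stack([classify_states(ds.states[s].to_numpy()) for s in ds.samples])
    altered_all = (signs != 0).all(axis=1)
    all_gain = (signs == 1).all(axis=1)
    all_loss = (signs == -1).all(axis=1)
    out = np.full(len(signs), "none", dtype=object)
    out[altered_all] = "recurrent-mixed"
    out[altered_all & all_gain] = "recurrent-gained"
    out[altered_all & all_loss] = "recurrent-deleted"
    return pd.Series(out, index=ds.probes.index, name="recurrence")


def _chrom_rank(mrrs_on_chrom: list) -> None:
    pass  # ids assigned inline in find_mrrs


def find_mrrs(
    cna_sets: dict[str, list[Cna]],
    ds: SnpDataset,
    min_samples: int | None = None,
    require_recurrent_snp: bool = True,
) -> list[Mrr]:
    """Intersect per-sample CNA interval sets into minimal recurrent regions.

    Parameters
    ----------
    cna_sets
        Per-sample CNA lists (sorted, disjoint within a sample).
    ds
        The SNP dataset the CNAs were built from; used to count member and
        recurrent probes.
    min_samples
        Number of samples that must carry an overlapping CNA for an
        interval to qualify.  Default: all samples.
    require_recurrent_snp
        Keep only regions containing >=1 probe altered in every sample.

    Intervals containing zero probes are discarded.  Ids are assigned
    ``<chrom body>-<k>`` in genomic order per chromosome.
    """
    samples = list(cna_sets)
    if len(samples) < 2:
        raise ValueError("MRR identification needs at least 2 samples")
    n_req = len(samples) if min_samples is None else min_samples

    recurrence = recurrent_altered_snps(ds) if len(samples) >= 2 else None
    probe_chrom = ds.probes["chrom"].to_numpy()
    probe_pos = ds.probes["pos"].to_numpy()

    chroms: list[str] = []
    for cl in cna_sets.values():
        for c in cl:
            if c.chrom not in chroms:
                chroms.append(c.chrom)
    chroms.sort(key=lambda c: (0, int(c[3:])) if c[3:].isdigit() else (1, c[3:]))

    out: list[Mrr] = []
    for chrom in chroms:
        # coverage sweep over closed intervals: event at start (+1), end+1 (-1)
        events: list[tuple[int, int]] = []
        per_sample = {
            s: [c for c in cl if c.chrom == chrom] for s, cl in cna_sets.items()
        }
        for cl in per_sample.values():
            for c in cl:
                events.append((c.start, 1))
                events.append((c.end + 1, -1))
        events.sort()
        cover = 0
        seg_start = None
        candidates: list[tuple[int, int]] = []
        i = 0
        while i < len(events):
            posn = events[i][0]
            delta = 0
            while i < len(events) and events[i][0] == posn:
                delta += events[i][1]
                i += 1
            new_cover = cover + delta
            if cover < n_req <= new_cover:
                seg_start = posn
            elif new_cover < n_req <= cover and seg_start is not None:
                candidates.append((seg_start, posn - 1))
                seg_start = None
            cover = new_cover

        k = 0
        on_chrom = probe_chrom == chrom
        chrom_pos = probe_pos[on_chrom]
        chrom_rec = recurrence.to_numpy()[on_chrom]
        for start, end in candidates:
            inside = (chrom_pos >= start) & (chrom_pos <= end)
            n_snps = int(inside.sum())
            if n_snps == 0:
                continue
            rec_count = int((chrom_rec[inside] != "none").sum())
            if require_recurrent_snp and rec_count == 0:
                continue
            support = {}
            directions = set()
            n_support = 0
            for s, cl in per_sample.items():
                ids = tuple(
                    c.cna_id for c in cl if c.start <= end and c.end >= start
                )
                if ids:
                    n_support += 1
                support[s] = ids
                directions.update(
                    c.direction for c in cl if c.start <= end and c.end >= start
                )
            if n_support < n_req:
                continue
            if directions == {"gain"}:
                direction = "gained"
            elif directions == {"loss"}:
                direction = "deleted"
            else:
                direction = "combined"
            k += 1
            out.append(
                Mrr(
                    mrr_id=f"{chrom[3:]}-{k}",
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    direction=direction,
                    support=support,
                    n_snps=n_snps,
                    recurrent_snp_count=rec_count,
                )
            )
    return out


def summarize_mrr(mrrs: list[Mrr], ds: SnpDataset) -> pd.DataFrame:
    """Per-MRR summary: size, SNP count, mean log2 ratio and a t-test.

    The mean log2 ratio is taken over member probes x all samples; the
    one-sample t-test of those values against 0 is reported as -log10 p
    (values > 1.3 correspond to p < 0.05).  When log2 ratios are absent the
    ratio columns are NaN rather than an error.
    """
    rows = []
    pos = ds.probes["pos"].to_numpy()
    chrom = ds.probes["chrom"].to_numpy()
    for m in mrrs:
        inside = (chrom == m.chrom) & (pos >= m.start) & (pos <= m.end)
        row = {
            "mrr_id": m.mrr_id,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "direction": m.direction,
            "size_kb": m.size_kb,
            "n_snps": m.n_snps,
            "recurrent_snps": m.recurrent_snp_count,
            "mean_log2": np.nan,
            "neg_log10_p": np.nan,
        }
        if ds.log2 is not None and inside.any():
            vals = ds.log2.loc[inside].to_numpy(float).ravel()
            vals = vals[~np.isnan(vals)]
            if len(vals):
                row["mean_log2"] = float(vals.mean())
                if len(vals) > 1 and vals.std(ddof=1) > 0:
                    t, p = stats.ttest_1samp(vals, 0.0)
                    row["neg_log10_p"] = float(-np.log10(max(p, 1e-300)))
                else:
                    row["neg_log10_p"] = 0.0  # degenerate: all values equal
        rows.append(row)
    return pd.DataFrame(rows)


def mrrs_to_frame(mrrs: list[Mrr]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mrr_id": [m.mrr_id for m in mrrs],
            "chrom": [m.chrom for m in mrrs],
            "start": [m.start for m in mrrs],
            "end": [m.end for m in mrrs],
            "direction": [m.direction for m in mrrs],
            "size_kb": [m.size_kb for m in mrrs],
            "n_snps": [m.n_snps for m in mrrs],
            "recurrent_snps": [m.recurrent_snp_count for m in mrrs],
        }
    )
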