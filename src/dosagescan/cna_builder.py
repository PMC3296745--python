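"""Construction of per-sample copy-number-altered regions (CNAs).

A CNA is a maximal run of consecutive altered SNP probes sharing one
direction (gain for states 3-4, loss for states 0-1) within a chromosome.
An isolated altered probe flanked by diploid probes forms a single-SNP CNA.
The CNA interval spans the positions of its first and last member probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import SnpDataset, SnpTrack, VALID_STATES

__all__ = [
    "Cna",
    "classify_snp_state",
    "classify_states",
    "build_cnas",
    "build_all_cnas",
    "cnas_to_frame",
    "genome_altered_fraction",
    "state_composition_summary",
]

_GAIN_STATES = (3, 4)
_LOSS_STATES = (0, 1)


@dataclass(frozen=True)
class Cna:
    """One maximal same-direction run of altered SNPs in one sample."""

    cna_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    direction: str              # "gain" | "loss"
    snp_ids: tuple[str, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def classify_snp_state(state: int) -> str:
    """Map a 0-4 copy-number state to gain / loss / normal."""
    if state in _GAIN_STATES:
        return "gain"
    if state in _LOSS_STATES:
        return "loss"
    if state == 2:
        return "normal"
    raise ValueError(f"invalid copy-number state {state!r}")


def classify_states(states: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_snp_state`; returns +1 gain, -1 loss, 0 normal."""
    states = np.asarray(states)
    if not np.isin(states, list(VALID_STATES)).all():
        bad = states[~np.isin(states, list(VALID_STATES))][0]
        raise ValueError(f"invalid copy-number state {bad!r}")
    out = np.zeros(states.shape, dtype=np.int8)
    out[np.isin(states, _GAIN_STATES)] = 1
    out[np.isin(states, _LOSS_STATES)] = -1
    return out


def build_cnas(track: SnpTrack, probes: pd.DataFrame) -> list[Cna]:
    """Build the CNA list of one sample from its aligned state vector.

    Runs never cross chromosome boundaries and break whenever direction
    changes; output is in genomic order (the probe order).
    """
    if len(track.states) != len(probes):
        raise ValueError("state vector not aligned to probe list")
    sign = classify_states(track.states)
    chroms = probes["chrom"].to_numpy()
    pos = probes["pos"].to_numpy()
    snp_ids = probes["snp_id"].to_numpy()

    out: list[Cna] = []
    n = len(sign)
    i = 0
    k = 0
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i + 1
        while j < n and sign[j] == sign[i] and chroms[j] == chroms[i]:
            j += 1
        k += 1
        direction = "gain" if sign[i] > 0 else "loss"
        out.append(
            Cna(
                cna_id=f"{track.sample_id}.{k}",
                sample_id=track.sample_id,
                chrom=str(chroms[i]),
                start=int(pos[i]),
                end=int(pos[j - 1]),
                direction=direction,
                snp_ids=tuple(snp_ids[i:j]),
            )
        )
        i = j
    return out


def build_all_cnas(ds: SnpDataset) -> dict[str, list[Cna]]:
    """CNA lists per sample for every track of a dataset."""
    return {s: build_cnas(ds.track(s), ds.probes) for s in ds.samples}


def cnas_to_frame(cnas: list[Cna]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cna_id": [c.cna_id for c in cnas],
            "sample_id": [c.sample_id for c in cnas],
            "chrom": [c.chrom for c in cnas],
            "start": [c.start for c in cnas],
            "end": [c.end for c in cnas],
            "direction": [c.direction for c in cnas],
            "n_snps": [c.n_snps for c in cnas],
            "span_bp": [c.span_bp for c in cnas],
        }
    )


def genome_altered_fraction(cnas: list[Cna], chrom_lengths: dict[str, int]) -> float:
    """Percent of the genome covered by a sample's CNAs.

    Single-SNP CNAs contribute 1 bp.  CNAs of one sample are disjoint by
    construction, so spans are simply summed.
    """
    total = 0
    for c in cnas:
        if c.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {c.chrom}")
        total += c.span_bp
    genome = sum(chrom_lengths.values())
    return 100.0 * total / genome


def state_composition_summary(ds: SnpDataset) -> pd.DataFrame:
    """Per-sample composition of altered SNPs by state class.

    Returns one row per sample plus an ``average`` row, with the percentage
    of altered SNPs falling in each class (gain=3, single deletion=1,
    amplification=4, double deletion=0) and the percent of all evaluated
    SNPs that are altered.
    """
    rows = []
    classes = {"gain": 3, "single_deletion": 1, "amplification": 4, "double_deletion": 0}
    for s in ds.samples:
        st = ds.states[s].to_numpy()
        altered = st != 2
        n_alt = int(altered.sum())
        row = {"sample_id": s, "n_snps": len(st), "n_altered": n_alt,
               "pct_altered": 100.0 * n_alt / len(st) if len(st) else 0.0}
        for name, code in classes.items():
            count = int((st == code).sum())
            row[f"n_{name}"] = count
            row[f"pct_{name}"] = 100.0 * count / n_alt if n_alt else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    avg = df.drop(columns="sample_id").mean(numeric_only=True)
    avg["sample_id"] = "average"
    return pd.concat([df, avg.to_frame().T], ignore_index=True)
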