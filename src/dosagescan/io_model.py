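"""Domain types and readers/writers for the package's external formats.

Coordinate conventions
----------------------
All coordinates inside the package are **1-based, closed** intervals, the
convention of genome-browser position displays.  The only place a different
convention appears is BED import/export, where the standard 0-based
half-open encoding is converted at the boundary.  Chromosome names are
normalized to ``chr``-prefixed strings on input.

The central in-memory containers are plain :class:`pandas.DataFrame` objects
with documented column schemas, wrapped in light dataclasses where grouped
state is needed (a SNP dataset, a cytoband map, an expression matrix).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpDataset",
    "SnpTrack",
    "CytobandMap",
    "ExpressionMatrix",
    "ParseError",
    "normalize_chrom",
    "read_snp_states",
    "write_snp_states",
    "read_cytobands",
    "write_cytobands",
    "read_gene_annotation",
    "write_gene_annotation",
    "annotate_genes_with_bands",
    "read_expression",
    "write_expression",
    "export_bed",
    "read_bed",
]

VALID_STATES = frozenset({0, 1, 2, 3, 4})


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to a ``chr``-prefixed string."""
    name = str(name).strip()
    if not name:
        raise ParseError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def sort_genomic(df: pd.DataFrame, start_col: str = "pos") -> pd.DataFrame:
    """Sort a frame by (chrom, position) using natural chromosome order."""
    key = df["chrom"].map(_chrom_sort_key)
    out = df.assign(_key=key).sort_values(["_key", start_col], kind="mergesort")
    return out.drop(columns="_key").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP probes and per-sample copy-number state tracks
# ---------------------------------------------------------------------------

@dataclass
class SnpTrack:
    """Per-sample view of the aligned SNP state vector.

    States follow the 5-level coding of SNP-array copy-number segmentation:
    0 homozygous deletion, 1 heterozygous deletion, 2 diploid,
    3 single-copy gain, 4 amplification.
    """

    sample_id: str
    states: np.ndarray
    log2_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        bad = ~np.isin(self.states, list(VALID_STATES))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"sample {self.sample_id!r}: state {self.states[i]} at probe "
                f"index {i} outside {{0..4}}"
            )


@dataclass
class SnpDataset:
    """Ordered SNP probes plus aligned per-sample state (and log2) tracks.

    ``probes`` columns: ``snp_id, chrom, pos`` and, once a cytoband map has
    been applied with :meth:`annotate_bands`, ``arm`` and ``cytoband``.
    ``states`` shares the probe row order; one integer column per sample.
    """

    probes: pd.DataFrame
    states: pd.DataFrame
    log2: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def track(self, sample_id: str) -> SnpTrack:
        lr = None if self.log2 is None else self.log2[sample_id].to_numpy(float)
        return SnpTrack(sample_id, self.states[sample_id].to_numpy(), lr)

    def tracks(self) -> list[SnpTrack]:
        return [self.track(s) for s in self.samples]

    def annotate_bands(self, bands: "CytobandMap") -> None:
        """Attach arm/cytoband columns to the probe table."""
        arms, cbs = [], []
        for chrom, pos in zip(self.probes["chrom"], self.probes["pos"]):
            arm, cb = bands.locate(chrom, int(pos))
            arms.append(arm)
            cbs.append(cb)
        self.probes = self.probes.assign(arm=arms, cytoband=cbs)

    def validate(self) -> None:
        p = self.probes
        if (p["pos"] < 1).any():
            raise ParseError("probe positions must be >= 1")
        dup = p.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = p.loc[dup].iloc[0]
            raise ParseError(
                f"duplicate probe position {row['chrom']}:{row['pos']}"
            )
        if len(self.states) != len(p):
            raise ParseError("state table not aligned to probe list")
        for s in self.samples:
            SnpTrack(s, self.states[s].to_numpy())
        if self.log2 is not None and list(self.log2.columns) != self.samples:
            raise ParseError("log2 table samples differ from state table")


def read_snp_states(path, log2_path=None) -> SnpDataset:
    """Read a SNP-state TSV (``snp_id  chrom  pos  <sample>...``).

    States must be integers in {0..4}; probes are sorted by (chrom, pos)
    and all sample tracks are aligned to the sorted probe list.  An optional
    parallel log2-ratio TSV with the same layout may be supplied.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = ["snp_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing} in {path}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ParseError(f"no sample state columns in {path}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | ~vals.isin(list(VALID_STATES))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: row {i + 2} sample {col!r}: state "
                f"{df[col].iloc[i]!r} is not an integer in 0..4"
            )
        df[col] = vals.astype(np.int64)
    df = sort_genomic(df)
    probes = df[required].copy()
    states = df[sample_cols].copy()
    ds = SnpDataset(probes=probes, states=states)
    if log2_path is not None:
        lr = pd.read_csv(log2_path, sep="\t", dtype={"snp_id": str, "chrom": str})
        lr["chrom"] = lr["chrom"].map(normalize_chrom)
        lr = sort_genomic(lr)
        if list(lr["snp_id"]) != list(probes["snp_id"]):
            raise ParseError("log2 file probes do not match state file")
        ds.log2 = lr[sample_cols].astype(float)
    ds.validate()
    return ds


def write_snp_states(ds: SnpDataset, path, log2_path=None) -> None:
    out = pd.concat([ds.probes[["snp_id", "chrom", "pos"]], ds.states], axis=1)
    out.to_csv(path, sep="\t", index=False)
    if log2_path is not None and ds.log2 is not None:
        lr = pd.concat([ds.probes[["snp_id", "chrom", "pos"]], ds.log2], axis=1)
        lr.to_csv(log2_path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Cytoband map
# ---------------------------------------------------------------------------

@dataclass
class CytobandMap:
    """Giemsa cytoband map with derived chromosome-arm boundaries.

    ``bands`` columns: ``chrom, start, end, band, stain, arm, name``
    (1-based closed coordinates; ``name`` is e.g. ``5p15.2``,
    ``arm`` is e.g. ``5p``).  Bands of one chromosome are contiguous and
    non-overlapping.
    """

    bands: pd.DataFrame
    _starts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        b = self.bands
        for chrom, grp in b.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if starts[0] != 1:
                raise ParseError(f"{chrom}: first band does not start at 1")
            gaps = starts[1:] != ends[:-1] + 1
            if gaps.any():
                i = int(np.flatnonzero(gaps)[0])
                raise ParseError(
                    f"{chrom}: gap/overlap between bands "
                    f"{g['band'].iloc[i]!r} and {g['band'].iloc[i + 1]!r}"
                )
            bad = ~g["band"].str.match(r"[pq]")
            if bad.any():
                raise ParseError(f"{chrom}: band name must begin with p or q")
            self._starts[chrom] = (starts, ends, g)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(v[1][-1]) for c, v in self._starts.items()}

    def arm_bounds(self, chrom: str) -> dict[str, tuple[int, int]]:
        """Arm intervals; the p arm ends at the end of its last band."""
        _, _, g = self._starts[chrom]
        out = {}
        for arm_letter in ("p", "q"):
            sub = g[g["band"].str.startswith(arm_letter)]
            if len(sub):
                out[f"{chrom[3:]}{arm_letter}"] = (
                    int(sub["start"].min()),
                    int(sub["end"].max()),
                )
        return out

    def locate(self, chrom: str, pos: int) -> tuple[str, str]:
        """Containing (arm, cytoband) of a position.

        A position on the shared boundary of two closed intervals (possible
        only for externally built maps) is assigned to the lower-coordinate
        band.
        """
        chrom = normalize_chrom(chrom)
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom} not in cytoband map")
        starts, ends, g = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos > ends[i]:
            raise ValueError(f"position {chrom}:{pos} outside all bands")
        row = g.iloc[i]
        return str(row["arm"]), str(row["name"])


def read_cytobands(path) -> CytobandMap:
    """Read a UCSC ``cytoBand.txt`` file (5 columns, 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str, "stain": str},
        comment="#",
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    # UCSC 0-based half-open -> 1-based closed
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    body = df["chrom"].str.replace("chr", "", regex=False)
    df["arm"] = body + df["band"].str[0]
    df["name"] = body + df["band"]
    df = sort_genomic(df, start_col="start")
    return CytobandMap(bands=df)


def write_cytobands(bands: CytobandMap, path) -> None:
    out = bands.bands[["chrom", "start", "end", "band", "stain"]].copy()
    out["start"] = out["start"] - 1  # back to UCSC convention
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (1-based closed coordinates).

    Columns: ``gene_id symbol chrom start end strand`` plus optional extras
    (an ``explored`` 0/1 flag marks genes probed by the expression array).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"gene annotation missing columns {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] > df["end"]).any():
        raise ParseError("gene with start > end")
    if df["gene_id"].duplicated().any():
        raise ParseError("duplicate gene_id in annotation")
    if "explored" in df.columns:
        df["explored"] = df["explored"].astype(bool)
    return sort_genomic(df, start_col="start")


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def annotate_genes_with_bands(genes: pd.DataFrame, bands: CytobandMap) -> pd.DataFrame:
    """Assign each gene the arm/cytoband containing its start position."""
    arms, cbs = [], []
    for chrom, start in zip(genes["chrom"], genes["start"]):
        arm, cb = bands.locate(chrom, int(start))
        arms.append(arm)
        cbs.append(cb)
    return genes.assign(arm=arms, cytoband=cbs)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized intensities with sample roles.

    Intensities are positive reals in arbitrary ("relative") units; each
    sample carries a role, ``tumor`` or ``control``.
    """

    values: pd.DataFrame            # index gene_id, columns sample ids
    roles: pd.Series                # index sample ids, values tumor|control

    def __post_init__(self) -> None:
        bad_roles = set(self.roles.unique()) - {"tumor", "control"}
        if bad_roles:
            raise ParseError(f"unknown sample roles {sorted(bad_roles)}")
        if list(self.roles.index) != list(self.values.columns):
            raise ParseError("role line does not match sample columns")
        if (self.values.to_numpy() <= 0).any():
            raise ParseError("expression intensities must be positive")

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "tumor"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "control"])

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(tumor, control) intensity arrays, genes x samples."""
        return (
            self.values[self.tumor_samples].to_numpy(float),
            self.values[self.control_samples].to_numpy(float),
        )


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV.

    Line 1: ``gene_id <sample>...`` header; line 2: ``#role`` followed by
    one role per sample; remaining lines: positive intensities.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        role_line = fh.readline().rstrip("\n").split("\t")
        body = fh.read()
    if header[0] != "gene_id":
        raise ParseError("expression header must start with gene_id")
    if role_line[0] != "#role":
        raise ParseError("second line must be the #role line")
    samples = header[1:]
    if len(role_line) - 1 != len(samples):
        raise ParseError("role line length does not match sample columns")
    values = pd.read_csv(
        io.StringIO(body), sep="\t", names=header, index_col="gene_id"
    ).astype(float)
    roles = pd.Series(role_line[1:], index=samples)
    return ExpressionMatrix(values=values, roles=roles)


def write_expression(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.values.columns) + "\n")
        fh.write("#role\t" + "\t".join(expr.roles) + "\n")
        expr.values.to_csv(fh, sep="\t", header=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# BED export / import for region collections (CNAs, MRRs)
# ---------------------------------------------------------------------------

def export_bed(regions: Iterable, path) -> None:
    """Write regions with chrom/start/end/direction attributes as BED.

    Internal 1-based closed intervals become 0-based half-open BED lines
    ``chrom  start-1  end  name  0  .  direction``.  Regions are sorted
    before writing; a header comment is always present.
    """
    rows = []
    for r in regions:
        name = getattr(r, "cna_id", None) or getattr(r, "mrr_id", None) or "region"
        if r.start < 1:
            raise ValueError(f"negative/zero coordinate in region {name}")
        rows.append((r.chrom, int(r.start) - 1, int(r.end), name, 0, ".", r.direction))
    rows.sort(key=lambda t: (_chrom_sort_key(t[0]), t[1]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tdirection\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED written by :func:`export_bed` back to 1-based closed."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand", "direction"],
        dtype={"chrom": str, "name": str, "direction": str},
    )
    if df.empty:
        return df
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df
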