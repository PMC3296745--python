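"""Coupled synthetic datasets with planted truth.

The generator emulates the structure the analysis assumes: a SNP map with
~23.6 kb mean inter-probe spacing (a Poisson process along each
chromosome), per-sample 5-state copy-number tracks with planted gain/loss
regions of controllable recurrence and continuity, a cytoband map, a gene
annotation, and an expression matrix in which amplification drives
upregulation with a configurable repressed fraction, partial (SNP-sparse)
alteration raises the downregulation probability, and deregulation can be
spatially autocorrelated along the gene order.  Every planted fact is
recorded in a truth object so each pipeline stage can be checked against
known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from . import io_model
from .io_model import CytobandMap, ExpressionMatrix, SnpDataset

__all__ = ["SimConfig", "SimTruth", "generate_genome", "plant_cnas",
           "simulate_expression", "generate_dataset"]

_LOG2_MEANS = {0: -1.2, 1: -0.45, 2: 0.0, 3: 0.32, 4: 0.8}
_LOG2_SDS = {0: 0.15, 1: 0.10, 2: 0.08, 3: 0.08, 4: 0.10}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults follow the assayed design: 4 tumor cell lines, triplicate
    expression experiments per line, 10 controls, 23.6 kb mean SNP
    spacing, gains slightly outnumbering losses, amplification (state 4)
    and homozygous deletion (state 0) rare relative to single-copy events.
    The genome itself is scaled to a few tens of megabases per chromosome,
    which preserves every statistical structure the pipeline measures.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    snp_spacing_mean: float = 23_600.0
    n_samples: int = 4
    n_genes: int = 600
    gene_length_median: float = 30_000.0
    gene_length_log_sd: float = 0.8
    genes_non_overlapping: bool = False
    n_cna_regions: int = 40
    region_chrom: str | None = None      # pin all planted regions to one chromosome
    cna_length_mean: float = 1_500_000.0
    cna_length_min: float = 200_000.0
    cna_length_max: float = 8_000_000.0
    recurrence_prob: float = 0.25
    continuity: float = 1.0
    gain_fraction: float = 0.55
    amplification_prob: float = 0.12    # state 4 given gain
    double_deletion_prob: float = 0.01  # state 0 given loss
    dosage_up_prob: float = 0.4
    repression_prob: float = 0.1
    partial_silencing_slope: float = 0.0
    cluster_rho: float = 0.0
    background_de_prob: float = 0.08
    fc_log2_low: float = 0.7            # planted effects, log2 scale
    fc_log2_high: float = 1.8
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.15
    n_tumor_replicates: int = 3
    n_controls: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recurrence_prob", "gain_fraction", "amplification_prob",
                     "double_deletion_prob", "dosage_up_prob",
                     "repression_prob", "background_de_prob", "cluster_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.continuity <= 1.0:
            raise ValueError("continuity must be in (0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"line{i + 1}" for i in range(self.n_samples)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted files."""

    regions: list = field(default_factory=list)   # dicts per planted region
    mrr_intervals: list = field(default_factory=list)  # expected recurrent SNP spans
    gene_truth: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "regions": self.regions,
            "mrr_intervals": self.mrr_intervals,
            "gene_truth": (
                self.gene_truth.reset_index().to_dict(orient="list")
                if self.gene_truth is not None else None
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gt = payload.get("gene_truth")
        return cls(
            regions=payload["regions"],
            mrr_intervals=payload["mrr_intervals"],
            gene_truth=(
                pd.DataFrame(gt).set_index("gene_id") if gt is not None else None
            ),
        )


def _make_cytobands(config: SimConfig) -> CytobandMap:
    """Synthetic banding: p arm = first 40%, 3 sub-bands per arm."""
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        L = config.chrom_length_bp
        centromere = int(L * 0.4)
        p_edges = np.linspace(0, centromere, 4).astype(int)
        q_edges = np.linspace(centromere, L, 4).astype(int)
        # p bands named outward-in (p13..p11), q bands inward-out (q11..q13)
        p_names = ["p13", "p12", "p11"]
        q_names = ["q11", "q12", "q13"]
        for i, band in enumerate(p_names):
            rows.append((chrom, int(p_edges[i]) + 1, int(p_edges[i + 1]),
                         band, "gneg"))
        for i, band in enumerate(q_names):
            rows.append((chrom, int(q_edges[i]) + 1, int(q_edges[i + 1]),
                         band, "gpos50"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])
    body = df["chrom"].str.replace("chr", "", regex=False)
    df["arm"] = body + df["band"].str[0]
    df["name"] = body + df["band"]
    return CytobandMap(bands=df)


def generate_genome(config: SimConfig):
    """SNP map, cytoband map and gene annotation for one synthetic genome.

    SNP positions follow a Poisson process (exponential spacings with the
    configured mean); gene spans are lognormal around the configured
    median length and placed uniformly, optionally without overlap.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    probe_rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 0.0
        while True:
            pos += rng.exponential(config.snp_spacing_mean)
            if pos > config.chrom_length_bp:
                break
            probe_rows.append((chrom, int(pos)))
    probes = pd.DataFrame(probe_rows, columns=["chrom", "pos"])
    probes = probes.drop_duplicates(subset=["chrom", "pos"])
    probes.insert(0, "snp_id", [f"snp{i + 1}" for i in range(len(probes))])
    probes = io_model.sort_genomic(probes)

    bands = _make_cytobands(config)

    lengths = np.exp(
        rng.normal(np.log(config.gene_length_median), config.gene_length_log_sd,
                   config.n_genes)
    ).astype(int)
    lengths = np.clip(lengths, 1_000, config.chrom_length_bp // 10)
    chroms = rng.integers(1, config.n_chromosomes + 1, config.n_genes)
    gene_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in range(config.n_genes):
        chrom = f"chr{chroms[g]}"
        for _ in range(50):
            start = int(rng.integers(1, config.chrom_length_bp - lengths[g]))
            end = start + int(lengths[g]) - 1
            if config.genes_non_overlapping:
                clash = any(s <= end and e >= start
                            for s, e in occupied.get(chrom, []))
                if clash:
                    continue
                occupied.setdefault(chrom, []).append((start, end))
            break
        else:
            raise RuntimeError("could not place gene without overlap")
        gene_rows.append((chrom, start, end,
                          "+" if rng.random() < 0.5 else "-"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])
    genes = io_model.sort_genomic(genes, start_col="start")
    genes.insert(0, "gene_id", [f"g{i + 1:04d}" for i in range(len(genes))])
    genes.insert(1, "symbol", ["G" + str(i + 1) for i in range(len(genes))])
    # ~85% of genes are on the expression array ("explored"), as a flag
    genes["explored"] = rng.random(len(genes)) < 0.85
    return probes, bands, genes


def plant_cnas(config: SimConfig, probes: pd.DataFrame):
    """Plant copy-number regions and emit per-sample state tracks.

    Planted regions are mutually non-overlapping genome-wide (rejected and
    re-drawn otherwise).  Each region is recurrent (planted congruently in
    every sample) with probability ``recurrence_prob``, else private to one
    sample.  Within a region each member SNP is set altered independently
    with probability ``continuity``; gains use state 3 (4 with the
    configured probability), losses state 1 (0 rarely).
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = config.sample_ids
    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()

    # placed regions are tracked as probe-index ranges; a new region must
    # leave >=1 diploid probe between itself and every neighbour so that
    # planted regions can never fuse into a single CNA run
    placed: list[tuple[str, int, int]] = []
    regions = []
    attempts = 0
    while len(regions) < config.n_cna_regions and attempts < config.n_cna_regions * 60:
        attempts += 1
        chrom = config.region_chrom or f"chr{rng.integers(1, config.n_chromosomes + 1)}"
        length = float(np.clip(rng.exponential(config.cna_length_mean),
                               config.cna_length_min, config.cna_length_max))
        start = int(rng.integers(1, max(2, config.chrom_length_bp - int(length))))
        end = start + int(length) - 1
        member = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start)
                                & (pos_arr <= end))
        if len(member) < 2:
            continue
        m0, m1 = int(member[0]), int(member[-1])
        if any(c == chrom and m0 <= p1 + 1 and m1 >= p0 - 1
               for c, p0, p1 in placed):
            continue
        placed.append((chrom, m0, m1))
        direction = "gain" if rng.random() < config.gain_fraction else "loss"
        recurrent = bool(rng.random() < config.recurrence_prob)
        carriers = samples if recurrent else [samples[rng.integers(len(samples))]]
        regions.append({
            "chrom": chrom, "start": start, "end": end,
            "direction": direction, "recurrent": recurrent,
            "samples": list(carriers),
            "snp_indices": member.tolist(),
        })

    states = pd.DataFrame(
        np.full((len(probes), len(samples)), 2, dtype=np.int64),
        columns=samples,
    )
    for region in regions:
        member = np.asarray(region["snp_indices"])
        for s in region["samples"]:
            altered = member[rng.random(len(member)) < config.continuity]
            if len(altered) == 0:  # guarantee the region leaves a footprint
                altered = member[[rng.integers(len(member))]]
            if region["direction"] == "gain":
                vals = np.where(rng.random(len(altered)) < config.amplification_prob,
                                4, 3)
            else:
                vals = np.where(rng.random(len(altered)) < config.double_deletion_prob,
                                0, 1)
            col = states.columns.get_loc(s)
            states.iloc[altered, col] = vals

    # log2 ratios mirroring the states
    log2 = pd.DataFrame(index=states.index, columns=samples, dtype=float)
    for s in samples:
        st = states[s].to_numpy()
        mu = np.vectorize(_LOG2_MEANS.get)(st)
        sd = np.vectorize(_LOG2_SDS.get)(st)
        log2[s] = rng.normal(mu, sd)

    ds = SnpDataset(probes=probes.copy(), states=states, log2=log2)

    truth = SimTruth(regions=[
        {k: v for k, v in r.items() if k != "snp_indices"} | {
            "n_member_snps": len(r["snp_indices"]),
            "first_snp_pos": int(pos_arr[r["snp_indices"][0]]),
            "last_snp_pos": int(pos_arr[r["snp_indices"][-1]]),
        }
        for r in regions
    ])
    truth.mrr_intervals = [
        {"chrom": r["chrom"],
         "start": int(pos_arr[r["snp_indices"][0]]),
         "end": int(pos_arr[r["snp_indices"][-1]]),
         "direction": "gained" if r["direction"] == "gain" else "deleted"}
        for r in regions if r["recurrent"]
    ]
    return ds, truth


def simulate_expression(config: SimConfig, genes: pd.DataFrame,
                        ds: SnpDataset, truth: SimTruth) -> ExpressionMatrix:
    """Expression matrix with dosage-driven deregulation.

    Genes overlapping a planted recurrent gain are upregulated with
    probability ``dosage_up_prob`` and downregulated with
    ``repression_prob`` (+ ``partial_silencing_slope`` per altered SNP in
    the gene span when the region is discontinuous); recurrent losses are
    symmetric.  A latent AR(1) field along the gene order (parameter
    ``cluster_rho``) makes deregulation spatially autocorrelated.  Tumor
    lines share each gene's effect (deregulation is uniform across lines);
    intensities are lognormal with replicate noise ``noise_sd`` on the
    log2 scale.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(genes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    # latent AR(1) -> uniform via the normal CDF: spatially correlated coin
    z = np.empty(n)
    z[0] = rng.normal()
    rho = config.cluster_rho
    innov = rng.normal(size=n)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + np.sqrt(1 - rho**2) * innov[i]
    u = _stats.norm.cdf(z)

    chrom_arr = ds.probes["chrom"].to_numpy()
    pos_arr = ds.probes["pos"].to_numpy()
    signs_nonzero = (ds.states.to_numpy() != 2)

    status = np.full(n, "unchanged", dtype=object)
    region_of_gene = np.full(n, "", dtype=object)
    # dosage covariate: mean over samples of altered probes in the span
    altered_snps_in_span = np.zeros(n, dtype=float)
    recurrent_regions = [r for r in truth.regions if r["recurrent"]]
    cn_truth = {s: np.full(n, "normal", dtype=object) for s in config.sample_ids}
    for i, g in enumerate(genes.itertuples(index=False)):
        inside = None
        for r in truth.regions:
            if (r["chrom"] == g.chrom and r["first_snp_pos"] <= g.end
                    and r["last_snp_pos"] >= g.start):
                for s in r["samples"]:
                    cn_truth[s][i] = r["direction"]
                if r["recurrent"] and inside is None:
                    inside = r
        mask = (chrom_arr == g.chrom) & (pos_arr >= g.start) & (pos_arr <= g.end)
        if mask.any():
            altered_snps_in_span[i] = float(
                signs_nonzero[mask].sum(axis=0).mean())
        if inside is None:
            p_up = p_down = config.background_de_prob / 2.0
        else:
            region_of_gene[i] = f"{inside['chrom']}:{inside['start']}"
            continuous = config.continuity >= 1.0
            p_dosage = config.dosage_up_prob
            p_rep = config.repression_prob
            if not continuous:
                p_rep = min(1.0, p_rep + config.partial_silencing_slope
                            * altered_snps_in_span[i])
            if inside["direction"] == "gain":
                p_up, p_down = p_dosage, p_rep
            else:
                p_up, p_down = p_rep, p_dosage
        if u[i] < p_up:
            status[i] = "up"
        elif u[i] > 1.0 - p_down:
            status[i] = "down"

    effect = np.zeros(n)
    mag = rng.uniform(config.fc_log2_low, config.fc_log2_high, n)
    effect[status == "up"] = mag[status == "up"]
    effect[status == "down"] = -mag[status == "down"]

    cols, data, roles = [], [], []
    for s in config.sample_ids:
        for r in range(config.n_tumor_replicates):
            cols.append(f"{s}_rep{r + 1}")
            roles.append("tumor")
            data.append(baseline + effect + rng.normal(0, config.noise_sd, n))
    for c in range(config.n_controls):
        cols.append(f"ctrl{c + 1}")
        roles.append("control")
        data.append(baseline + rng.normal(0, config.noise_sd, n))
    values = pd.DataFrame(
        np.power(2.0, np.column_stack(data)),
        index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=cols,
    )
    expr = ExpressionMatrix(values=values, roles=pd.Series(roles, index=cols))

    truth.gene_truth = pd.DataFrame(
        {
            "status": status,
            "planted_region": region_of_gene,
            "altered_snps_mean": altered_snps_in_span,
            "explored": genes["explored"].to_numpy()
            if "explored" in genes else np.ones(n, bool),
            **{f"cn_class_{s}": cn_truth[s] for s in config.sample_ids},
        },
        index=pd.Index(genes["gene_id"], name="gene_id"),
    )
    return expr


def _qpcr_fixture(config: SimConfig, rng) -> pd.DataFrame:
    """Triplicate target/reference quantities: lines at CN 4, controls CN 2."""
    rows = []
    for s in config.sample_ids:
        for _ in range(3):
            ref = rng.lognormal(np.log(10.0), 0.05)
            rows.append((s, ref * 2.0 * rng.lognormal(0, 0.05), ref, False))
    for c in range(config.n_controls):
        for _ in range(3):
            ref = rng.lognormal(np.log(10.0), 0.05)
            rows.append((f"ctrl{c + 1}", ref * rng.lognormal(0, 0.05), ref, True))
    return pd.DataFrame(rows, columns=["sample_id", "target", "reference",
                                       "is_control"])


def _fish_fixture(config: SimConfig, rng, true_ratio: float = 2.3,
                  n_nuclei: int = 25) -> pd.DataFrame:
    control = rng.poisson(2.0, n_nuclei) + 1
    target = rng.poisson(true_ratio * control.mean(), n_nuclei)
    return pd.DataFrame({
        "nucleus_id": [f"nuc{i + 1}" for i in range(n_nuclei)],
        "target_signals": target,
        "control_signals": control,
    })


def generate_dataset(config: SimConfig, outdir) -> dict:
    """Emit the full coupled dataset to disk and return the paths + truth.

    Writes: SNP state and log2 TSVs, cytoband map, gene annotation,
    expression TSV, qPCR and FISH fixture tables, the truth JSON and the
    config YAML.  Byte-identical across runs with the same config/seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probes, bands, genes = generate_genome(config)
    ds, truth = plant_cnas(config, probes)
    ds.annotate_bands(bands)
    genes = io_model.annotate_genes_with_bands(genes, bands)
    expr = simulate_expression(config, genes, ds, truth)
    rng = np.random.default_rng(config.seed + 3)

    paths = {
        "snp_states": outdir / "snp_states.tsv",
        "snp_log2": outdir / "snp_log2.tsv",
        "cytobands": outdir / "cytobands.txt",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "fish": outdir / "fish.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.yaml",
    }
    io_model.write_snp_states(ds, paths["snp_states"], paths["snp_log2"])
    io_model.write_cytobands(bands, paths["cytobands"])
    io_model.write_gene_annotation(genes, paths["genes"])
    io_model.write_expression(expr, paths["expression"])
    _qpcr_fixture(config, rng).to_csv(paths["qpcr"], sep="\t", index=False,
                                      float_format="%.6g")
    _fish_fixture(config, rng).to_csv(paths["fish"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    config.to_yaml(paths["config"])
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "dataset": ds, "genes": genes, "expression": expr, "bands": bands}
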