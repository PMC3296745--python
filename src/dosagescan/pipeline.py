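"""End-to-end orchestration: states -> CNAs -> MRRs -> gene mapping ->
DE calls -> enrichment -> trends/clusters, with a provenance-stamped
report bundle on disk."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cna_builder, de_caller, enrichment, gene_mapper, io_model, \
    mrr_finder, trend_cluster

log = logging.getLogger("dosagescan")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and knobs of a full pipeline run; YAML round-trippable."""

    snp_states: str
    cytobands: str
    genes: str
    expression: str
    snp_log2: str | None = None
    out_dir: str = "dosagescan_run"
    seed: int = 0
    de: dict = field(default_factory=dict)          # DeConfig overrides
    yates_correction: bool = True
    mrr_background_includes_self: bool = True
    region_bin_edges: list = field(
        default_factory=lambda: list(trend_cluster.DEFAULT_REGION_BINS))
    gene_bin_edges: list = field(
        default_factory=lambda: list(trend_cluster.DEFAULT_GENE_BINS))
    cluster_monte_carlo: int = 5000

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(dataclasses.asdict(self)), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _stage(name):
    log.info("stage %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns the JSON summary (also written to ``summary.json``).  A stage
    failure aborts with an error naming the stage; partial outputs remain
    on disk next to a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(dataclasses.asdict(config)),
        }
    }
    stage = "load"
    try:
        t0 = _stage(stage)
        bands = io_model.read_cytobands(config.cytobands)
        ds = io_model.read_snp_states(config.snp_states, config.snp_log2)
        ds.annotate_bands(bands)
        genes = io_model.read_gene_annotation(config.genes)
        genes = io_model.annotate_genes_with_bands(genes, bands)
        expr = io_model.read_expression(config.expression)

        stage = "cna"
        t0 = _stage(stage)
        cna_sets = cna_builder.build_all_cnas(ds)
        all_cnas = [c for cl in cna_sets.values() for c in cl]
        io_model.export_bed(all_cnas, out / "cnas.bed")
        cna_builder.cnas_to_frame(all_cnas).to_csv(out / "cnas.tsv", sep="\t",
                                                   index=False)
        comp = cna_builder.state_composition_summary(ds)
        comp.to_csv(out / "state_composition.tsv", sep="\t", index=False)
        lengths = bands.chrom_lengths()
        summary["cna"] = {
            "n_cnas": len(all_cnas),
            "n_gains": sum(c.direction == "gain" for c in all_cnas),
            "n_losses": sum(c.direction == "loss" for c in all_cnas),
            "altered_genome_pct_per_sample": {
                s: cna_builder.genome_altered_fraction(cl, lengths)
                for s, cl in cna_sets.items()
            },
        }

        stage = "mrr"
        t0 = _stage(stage)
        mrrs = mrr_finder.find_mrrs(cna_sets, ds)
        io_model.export_bed(mrrs, out / "mrrs.bed")
        mrr_table = mrr_finder.summarize_mrr(mrrs, ds)
        mrr_table.to_csv(out / "mrrs.tsv", sep="\t", index=False)
        rec = mrr_finder.recurrent_altered_snps(ds)
        summary["mrr"] = {
            "n_mrrs": len(mrrs),
            "pct_recurrent_snps": float(100.0 * (rec != "none").mean()),
            "mrr_genome_pct": float(
                100.0 * sum(m.end - m.start + 1 for m in mrrs)
                / sum(lengths.values())
            ),
        }

        stage = "genemap"
        t0 = _stage(stage)
        calls = gene_mapper.map_genes(genes, cna_sets, mrrs, ds)
        calls.to_csv(out / "gene_calls.tsv", sep="\t")

        stage = "de"
        t0 = _stage(stage)
        de_cfg = de_caller.DeConfig(**{"seed": config.seed, **config.de})
        de_calls = de_caller.run_de(expr, de_cfg)
        de_calls.to_csv(out / "de_calls.tsv", sep="\t")
        explored = genes.set_index("gene_id")["explored"] \
            if "explored" in genes else pd.Series(True, index=genes["gene_id"])
        status = de_calls.loc[de_calls.index.intersection(
            explored.index[explored])]["status"]
        summary["de"] = {
            "n_explored": int(len(status)),
            "n_up": int((status == "up").sum()),
            "n_down": int((status == "down").sum()),
        }

        stage = "table1"
        t0 = _stage(stage)
        table1 = gene_mapper.build_dosage_expression_table(calls, status)
        with open(out / "dosage_expression_table.json", "w") as fh:
            json.dump(_jsonable(table1), fh, indent=1)
        summary["dosage_expression"] = _jsonable({
            "average": table1["average"], "recurrent": table1["recurrent"]})

        stage = "enrichment"
        t0 = _stage(stage)
        gene_view = calls.join(genes.set_index("gene_id")[["arm", "cytoband"]])
        gene_view = gene_view.join(status.rename("status"), how="inner")
        dereg = gene_view["status"] != "unchanged"
        arm_genes = enrichment.regional_enrichment_scan(
            gene_view["arm"], dereg, correction=config.yates_correction)
        arm_genes.to_csv(out / "arm_gene_enrichment.tsv", sep="\t", index=False)
        snp_rec = (rec != "none")
        arm_snps = enrichment.regional_enrichment_scan(
            ds.probes["arm"], snp_rec, correction=config.yates_correction)
        arm_snps.to_csv(out / "arm_snp_enrichment.tsv", sep="\t", index=False)
        cb_genes = enrichment.regional_enrichment_scan(
            gene_view["cytoband"], dereg, correction=config.yates_correction)
        cb_genes.to_csv(out / "cytoband_gene_enrichment.tsv", sep="\t",
                        index=False)
        dg = gene_view[dereg]
        page = enrichment.page_scan(
            de_calls.loc[dg.index, "fc"], dg["arm"]) if dereg.sum() else None
        if page is not None:
            page.to_csv(out / "page_arms.tsv", sep="\t", index=False)
        per_mrr_rows = []
        for m in mrrs:
            in_m = gene_view["mrr_ids"].str.contains(
                rf"(?:^|,){m.mrr_id}(?:,|$)", regex=True)
            per_mrr_rows.append({
                "mrr_id": m.mrr_id,
                "explored": int(in_m.sum()),
                "deregulated": int((in_m & dereg).sum()),
            })
        per_mrr = pd.DataFrame(per_mrr_rows)
        mrr_test = enrichment.mrr_deregulation_test(
            per_mrr,
            include_self_in_background=config.mrr_background_includes_self,
            correction=config.yates_correction,
        ) if len(per_mrr) else pd.DataFrame()
        mrr_test.to_csv(out / "mrr_deregulation.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "arms_enriched_genes": arm_genes.loc[arm_genes["enriched"],
                                                 "region"].tolist(),
            "arms_enriched_snps": arm_snps.loc[arm_snps["enriched"],
                                               "region"].tolist(),
            "arms_page_significant": (
                page.loc[page["p"] < 0.05, "set_name"].tolist()
                if page is not None else []
            ),
        }

        stage = "trend_cluster"
        t0 = _stage(stage)
        in_any_mrr = gene_view["mrr_ids"] != ""
        trend_summary = {}
        if in_any_mrr.sum() >= 10:
            mrr_snps = {m.mrr_id: m.n_snps for m in mrrs}
            first_mrr = gene_view.loc[in_any_mrr, "mrr_ids"].str.split(",").str[0]
            region_counts = first_mrr.map(mrr_snps)
            tt = trend_cluster.bin_trend_table(
                region_counts, dereg[in_any_mrr],
                bin_edges=tuple(config.region_bin_edges))
            tt.table.to_csv(out / "trend_by_region_snps.tsv", sep="\t",
                            index=False)
            m2, p = trend_cluster.linear_by_linear_test(tt)
            trend_summary["region_m2"] = m2
            trend_summary["region_p"] = p
            gt = trend_cluster.bin_trend_table(
                gene_view.loc[in_any_mrr, "recurrent_snps"], dereg[in_any_mrr],
                bin_edges=tuple(config.gene_bin_edges))
            gt.table.to_csv(out / "trend_by_gene_snps.tsv", sep="\t",
                            index=False)
            m2g, pg = trend_cluster.linear_by_linear_test(gt)
            trend_summary["gene_m2"] = m2g
            trend_summary["gene_p"] = pg
            down = gene_view["status"] == "down"
            dtr = trend_cluster.downregulation_trend(
                gene_view.loc[in_any_mrr, "recurrent_snps"], down[in_any_mrr],
                bin_edges=tuple(config.gene_bin_edges))
            trend_summary["down_rho_units"] = dtr["rho_units"]
            trend_summary["down_p_units"] = dtr["p_units"]
        summary["trend"] = _jsonable(trend_summary)

        cluster_out = {}
        ordered = gene_view.sort_values(["chrom", "start"])
        for arm, grp in ordered.groupby("arm", sort=True):
            rep = trend_cluster.find_gene_clusters(grp["status"].tolist())
            if rep.n_deregulated >= 10:
                test = trend_cluster.cluster_randomness_test(
                    rep, n_monte_carlo=config.cluster_monte_carlo,
                    seed=config.seed)
                cluster_out[arm] = {
                    "n_deregulated": rep.n_deregulated,
                    "clustered": rep.clustered,
                    "clustered_fraction": rep.clustered_fraction,
                    **test,
                }
        with open(out / "cluster_reports.json", "w") as fh:
            json.dump(_jsonable(cluster_out), fh, indent=1)
        summary["clusters"] = _jsonable(cluster_out)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    manifest = sorted(p.name for p in out.iterdir() if p.name != "MANIFEST")
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return summary
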