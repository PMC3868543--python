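"""End-to-end orchestration: simulate -> filter -> concordance ->
recurrence -> normalize -> co-expression/enrichment -> fusions -> splice
scan, with a JSON run manifest.

A single run seed fans out to per-stage child seeds by stable hashing, so
any stage can be rerun in isolation and reproduce its output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .coexpr import gsea_enrichment, ptm_neighbors, rank_by_group_lfc
from .concordance import allelic_imbalance_breakdown, compare_callsets
from .errors import ConfigurationError
from .fusions import calls_to_frame, triage_fusions
from .normalize import cluster_subtypes, mds_embedding, normalize_pipeline
from .recurrence import compare_mutation_burden, median_burden, select_recurrent_genes
from .simulate import SimulationConfig, simulate_cohort, stage_seed
from .splicing import scan_events
from .variants import FilterConfig, run_filter_cascade


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add(self, name: str, outputs: dict[str, str], rows: dict[str, int]) -> None:
        self.stages.append({"stage": name, "outputs": outputs, "rows": rows,
                            "timestamp": time.time()})

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "stages": self.stages,
                "started": self.started, "finished": self.finished}

    def write(self, path) -> None:
        io.write_json(self.to_dict(), path)


def load_config(config_path) -> SimulationConfig:
    text = Path(config_path).read_text()
    if str(config_path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    if "skipping_events" in data:
        data["skipping_events"] = [tuple(e) for e in data["skipping_events"]]
    return SimulationConfig.from_dict(data)


def run_pipeline(config_path, outdir, seed: int | None = None) -> RunManifest:
    config = load_config(config_path)
    if seed is None:
        seed = config.seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = Path(config_path).read_text()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        seed=seed, version=__version__, started=time.time())

    # --- simulate
    bundle = simulate_cohort(config, seed=seed)
    paths = {
        "genes": out / "genes.gtf", "samples": out / "samples.tsv",
        "exome": out / "exome.vcf", "rna": out / "rna.vcf",
        "counts": out / "counts.tsv", "fusions": out / "fusion_candidates.tsv",
        "junctions": out / "junctions.tsv",
    }
    io.write_gtf(bundle.gene_models, paths["genes"])
    bundle.sample_meta.to_csv(paths["samples"], sep="\t", index=False)
    io.write_vcf(bundle.exome_variants, paths["exome"], bundle.gene_models)
    io.write_vcf(bundle.rna_variants, paths["rna"], bundle.gene_models)
    io.write_counts(bundle.counts, paths["counts"])
    io.write_tsv(bundle.fusions, paths["fusions"])
    io.write_tsv(bundle.junctions, paths["junctions"])
    manifest.add("simulate", {k: str(v) for k, v in paths.items()},
                 {"exome_variants": len(bundle.exome_variants),
                  "rna_variants": len(bundle.rna_variants),
                  "genes": len(bundle.gene_models),
                  "fusion_candidates": len(bundle.fusions)})

    # --- variant triage
    fcfg = FilterConfig()
    retained, traces = run_filter_cascade(bundle.rna_variants, fcfg)
    io.write_tsv(retained, out / "retained_variants.tsv")
    io.write_json({k: t.to_dict() for k, t in traces.items()},
                  out / "filter_trace.json")
    io.write_tsv(pd.concat([t.to_frame().assign(variant_class=k)
                            for k, t in traces.items()]),
                 out / "filter_trace.tsv")
    manifest.add("filter_variants",
                 {"retained": str(out / "retained_variants.tsv"),
                  "trace": str(out / "filter_trace.json")},
                 {"retained": len(retained)})

    # --- concordance
    het_mask = (bundle.exome_variants["vaf"].between(0.2, 0.8, inclusive="left")
                & (bundle.exome_variants["depth"] > 20))
    report = compare_callsets(bundle.exome_variants, bundle.rna_variants)
    report.het_breakdown = allelic_imbalance_breakdown(
        bundle.exome_variants[het_mask], bundle.rna_variants)
    io.write_json(report.to_dict(), out / "concordance.json")
    io.write_tsv(report.vaf_pairs, out / "vaf_scatter.tsv")
    manifest.add("concordance", {"report": str(out / "concordance.json"),
                                 "scatter": str(out / "vaf_scatter.tsv")},
                 {"shared_sites": report.n_both})

    # --- recurrence
    rec = select_recurrent_genes(retained, bundle.sample_meta)
    io.write_tsv(rec.to_frame(), out / "recurrence.tsv")
    burden = rec.per_sample_counts
    stat, pval = compare_mutation_burden(burden, bundle.sample_meta)
    io.write_json({"selected_genes": rec.selected,
                   "mann_whitney_u": stat, "p_value": pval,
                   "median_patient_burden": median_burden(
                       burden, bundle.sample_meta, "patient")},
                  out / "burden.json")
    manifest.add("recurrence", {"table": str(out / "recurrence.tsv"),
                                "burden": str(out / "burden.json")},
                 {"selected_genes": len(rec.selected)})

    # --- normalization and clustering
    nm = normalize_pipeline(bundle.counts)
    nm.values.to_csv(out / "normalized.tsv", sep="\t", index_label="gene_id")
    io.write_json(nm.provenance, out / "normalization_provenance.json")
    mds = mds_embedding(nm)
    mds.to_csv(out / "mds.tsv", sep="\t", index_label="sample_id")
    tf_list = [tf for tf in config.subtype_programs if tf in nm.values.index]
    clusters = cluster_subtypes(nm, tf_list=tf_list,
                                k=min(len(tf_list), nm.shape[1]) or 1)
    clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                               index_label="sample_id")
    manifest.add("normalize", {"matrix": str(out / "normalized.tsv"),
                               "mds": str(out / "mds.tsv"),
                               "clusters": str(out / "clusters.tsv")},
                 {"genes": nm.shape[0], "samples": nm.shape[1]})

    # --- co-expression and enrichment on the planted subtype programs
    coexpr_out = {}
    for tf in tf_list:
        neighbors = ptm_neighbors(nm, tf)
        entry = {"n_neighbors": len(neighbors),
                 "top": neighbors.head(10).to_dict(orient="records")}
        signature = bundle.truth.counts.signature_genes.get(tf, [])
        if len(signature) >= 5:
            ranking = rank_by_group_lfc(nm, marker_gene=tf)
            enr = gsea_enrichment(ranking, signature, n_perm=200,
                                  seed=stage_seed(seed, f"gsea:{tf}"),
                                  gene_set_id=f"{tf}_signature")
            entry["enrichment"] = enr.to_dict()
        coexpr_out[tf] = entry
    io.write_json(coexpr_out, out / "coexpression.json")
    manifest.add("coexpr", {"report": str(out / "coexpression.json")},
                 {"templates": len(coexpr_out)})

    # --- fusion triage
    control = "THYMUS" if "THYMUS" in nm.values.columns else nm.values.columns[-1]
    calls = triage_fusions(bundle.fusions, bundle.gene_models, nm, control)
    io.write_tsv(calls_to_frame(calls), out / "fusion_calls.tsv")
    manifest.add("fusions", {"calls": str(out / "fusion_calls.tsv")},
                 {"retained": sum(c.retained for c in calls)})

    # --- splice scan
    events = scan_events(bundle.junctions, control_sample=control, alpha=0.05)
    io.write_tsv(events, out / "splice_events.tsv")
    manifest.add("splice", {"events": str(out / "splice_events.tsv")},
                 {"significant": len(events)})

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
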