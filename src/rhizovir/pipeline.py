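"""Pipeline orchestration: runs the stages in fixed order over validated
inputs and writes all outputs plus a machine-readable manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .activity import (
    call_active_votus,
    compute_gene_tpm,
    filter_gene_counts,
    summarize_activity,
)
from .classify import (
    assess_ssrna_completeness,
    call_lifestyle,
    filter_hosts,
)
from .config import PipelineConfig, config_to_dict
from .detection import (
    accumulation_curve,
    aggregate_dna_libraries,
    call_presence,
    compute_cpm,
)
from .differential import enrichment_summary, nb_wald_test, size_factors
from .ecostats import bray_curtis, mantel, nmds, permanova, shannon_diversity
from .priming import (
    count_active_votus,
    identify_priming_votus,
    priming_activity_trajectory,
    proportion_summaries,
    summaries_to_frame,
)
from .simulate import (
    SimulationConfig,
    simulate_bundle,
    simulate_host_predictions,
    simulate_host_table,
    write_bundle,
)
from .types import Compartment, NucleicType, SourceLibrary

logger = logging.getLogger("rhizovir")

STAGES = [
    "detect",
    "quantify",
    "activity",
    "ecology",
    "differential",
    "classify",
    "priming",
    "report",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_simulation(config: PipelineConfig, outdir: str | Path) -> dict[str, str]:
    """Generate the synthetic input bundle under outdir."""
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    design, catalog, annotations, bundle, truth = simulate_bundle(sim)
    host_table = simulate_host_table(truth, design, sim)
    host_preds = simulate_host_predictions(truth, sim)
    return write_bundle(
        outdir, design, catalog, annotations, bundle, truth,
        host_table=host_table, host_predictions=host_preds,
    )


def _load_inputs(config: PipelineConfig) -> dict:
    indir = Path(config.input_dir)
    design = rio.read_sample_design(indir / "design.tsv")
    catalog = rio.read_votu_catalog(indir / "catalog.tsv")
    annotations = rio.read_gene_annotations(
        indir / "genes.gff3", indir / "gene_functions.tsv", catalog=catalog
    )
    library_sizes = rio.read_library_sizes(indir / "library_sizes.tsv")
    dna_counts, breadth = {}, {}
    for lib in (SourceLibrary.DNA_VIROME, SourceLibrary.TOTAL_METAGENOME):
        cpath = indir / f"counts_{lib.value}.tsv"
        if cpath.exists():
            dna_counts[lib] = rio.read_matrix(cpath, dtype=np.int64)
            breadth[lib] = rio.read_matrix(indir / f"breadth_{lib.value}.tsv")
    rna = rio.read_matrix(indir / "rna_gene_counts.tsv", dtype=np.int64)
    ctx = {
        "design": design,
        "catalog": catalog,
        "annotations": annotations,
        "library_sizes": library_sizes,
        "dna_counts": dna_counts,
        "breadth": breadth,
        "rna_counts": rna,
    }
    host_pred_path = indir / "host_predictions.tsv"
    if host_pred_path.exists():
        ctx["host_predictions"] = rio.read_host_predictions(host_pred_path)
    host_table_path = indir / "host_otu_table.tsv"
    if host_table_path.exists():
        ctx["host_table"] = rio.read_matrix(host_table_path)
    return ctx


def _stage_detect(ctx, config, outdir):
    presence = call_presence(ctx["breadth"], threshold=config.thresholds.breadth)
    ctx["presence"] = presence
    rio.write_matrix(presence.merged.astype(int), outdir / "presence.tsv")
    return {
        "n_votus_detected": int(presence.merged.any(axis=1).sum()),
        "n_votus": int(presence.merged.shape[0]),
    }


def _stage_quantify(ctx, config, outdir):
    lengths = ctx["catalog"].lengths()
    cpms = {}
    for lib, counts in ctx["dna_counts"].items():
        cpms[lib] = compute_cpm(counts, lengths, ctx["library_sizes"][lib])
    abundance = aggregate_dna_libraries(
        cpms.get(SourceLibrary.DNA_VIROME),
        cpms.get(SourceLibrary.TOTAL_METAGENOME),
        presence=ctx["presence"],
    )
    ctx["abundance"] = abundance
    rio.write_matrix(abundance, outdir / "abundance_cpm.tsv")
    curve = accumulation_curve(
        ctx["presence"].merged, n_permutations=100, seed=config.seed
    )
    curve.to_csv(outdir / "accumulation.tsv", sep="\t", index=False,
                 float_format=rio.REAL_FORMAT)
    return {"n_cells_nonzero": int((abundance.to_numpy() > 0).sum())}


def _stage_activity(ctx, config, outdir):
    filtered = filter_gene_counts(
        ctx["rna_counts"],
        ctx["design"],
        min_group_reads=config.thresholds.min_group_reads,
        per_replicate=config.per_replicate_filter,
    )
    tpm = compute_gene_tpm(
        filtered,
        ctx["annotations"].gene_lengths(),
        ctx["library_sizes"][SourceLibrary.METATRANSCRIPTOME],
    )
    result = call_active_votus(
        filtered,
        ctx["catalog"],
        ctx["annotations"],
        activity_window_bp=config.thresholds.activity_window_bp,
    )
    ctx["filtered_rna"] = filtered
    ctx["gene_tpm"] = tpm
    ctx["active"] = result
    rio.write_matrix(filtered, outdir / "filtered_gene_counts.tsv")
    rio.write_matrix(tpm, outdir / "gene_tpm.tsv")
    long = (
        result.active_votu.stack()
        .rename("active")
        .to_frame()
        .join(result.active_gene_count.stack().rename("k"))
        .reset_index()
    )
    long.columns = ["votu_id", "sample_id", "active", "k"]
    long.to_csv(outdir / "active_votus.tsv", sep="\t", index=False)
    metabolic = [
        g.gene_id
        for g in ctx["annotations"]
        if g.cog_letter in set("CEFGHIPQ")
    ]
    summary = summarize_activity(tpm, {"metabolic": metabolic}, ctx["design"])
    summary.to_csv(outdir / "activity_summary.tsv", sep="\t", index=False,
                   float_format=rio.REAL_FORMAT)
    return {
        "n_active_votus": int(result.active_votu.any(axis=1).sum()),
        "n_genes_passing_filter": int((filtered.sum(axis=1) > 0).sum()),
        "n_genes": int(filtered.shape[0]),
    }


def _stage_ecology(ctx, config, outdir):
    abundance = ctx["abundance"]
    design = ctx["design"]
    shannon = pd.Series(
        {s: shannon_diversity(abundance[s]) for s in abundance.columns},
        name="shannon_h",
    )
    shannon.to_csv(outdir / "ecology.tsv", sep="\t", index_label="sample_id",
                   float_format=rio.REAL_FORMAT)
    dist = bray_curtis(abundance.T, transform="sqrt")
    rio.write_matrix(dist.values, outdir / "distances.tsv")
    ord_result = nmds(
        dist, k=2, n_starts=config.nmds_starts, seed=config.seed
    )
    rio.write_matrix(ord_result.coordinates, outdir / "nmds_coords.tsv")
    factors = {
        "compartment": design.factor("compartment", dist.sample_ids),
        "rotation": design.factor("rotation", dist.sample_ids),
    }
    perm = permanova(
        dist, factors, n_permutations=config.n_permutations, seed=config.seed
    )
    pd.DataFrame(
        [
            {
                "term": r.term, "pseudo_f": r.statistic, "r2": r.effect_size,
                "p": r.p_value, "df": r.df,
            }
            for r in perm
        ]
    ).to_csv(outdir / "permanova.tsv", sep="\t", index=False,
             float_format=rio.REAL_FORMAT)

    mantel_rows = []
    if "host_table" in ctx:
        host = ctx["host_table"][dist.sample_ids]
        host_dist = bray_curtis(
            (host - host.min().min()).T, transform=None
        )
        m = mantel(
            dist, host_dist, n_permutations=config.n_permutations,
            seed=config.seed,
        )
        mantel_rows.append(
            {"comparison": "dna_vs_host", "r": m.statistic, "p": m.p_value}
        )
    pd.DataFrame(mantel_rows, columns=["comparison", "r", "p"]).to_csv(
        outdir / "mantel.tsv", sep="\t", index=False,
        float_format=rio.REAL_FORMAT,
    )
    return {
        "nmds_stress": ord_result.stress,
        "permanova_terms": {r.term: r.p_value for r in perm},
    }


def _stage_differential(ctx, config, outdir):
    design = ctx["design"]
    soil = [
        s.sample_id
        for s in design
        if s.compartment in (Compartment.BULK, Compartment.RHIZOSPHERE)
    ]
    counts = ctx["rna_counts"][soil]
    counts = counts.loc[counts.sum(axis=1) > 0]
    sf = size_factors(counts)
    labels = pd.Series(
        {s: design[s].compartment.value for s in soil}
    )
    diff = nb_wald_test(
        counts, sf, labels, alpha=config.thresholds.differential_alpha
    )
    ctx["differential"] = diff
    diff.to_csv(outdir / "differential.tsv", sep="\t",
                float_format=rio.REAL_FORMAT)
    frac = enrichment_summary(ctx["gene_tpm"], diff["enriched_label"], design)
    ctx["enrichment_fractions"] = frac
    frac.to_csv(outdir / "enrichment_fractions.tsv", sep="\t",
                float_format=rio.REAL_FORMAT)
    n_bulk = int((diff["enriched_label"] == Compartment.BULK.value).sum())
    n_rhizo = int((diff["enriched_label"] == Compartment.RHIZOSPHERE.value).sum())
    return {"n_bulk_enriched": n_bulk, "n_rhizosphere_enriched": n_rhizo,
            "gradient_root_to_bulk": frac.attrs.get("gradient_root_to_bulk")}


def _stage_classify(ctx, config, outdir):
    catalog = ctx["catalog"]
    lifestyle = call_lifestyle(catalog, ctx["annotations"])
    ctx["lifestyle"] = lifestyle
    pd.DataFrame(
        {
            "votu_id": [c.votu_id for c in lifestyle],
            "lifestyle": [c.lifestyle for c in lifestyle],
            "evidence": [";".join(sorted(c.evidence)) for c in lifestyle],
        }
    ).to_csv(outdir / "lifestyle.tsv", sep="\t", index=False)

    info = {"n_temperate": sum(c.lifestyle == "temperate" for c in lifestyle)}
    if "host_predictions" in ctx:
        detected = (
            set(ctx["host_table"].index) if "host_table" in ctx else set()
        )
        hosts = filter_hosts(
            ctx["host_predictions"], detected_genera=detected,
            p_threshold=config.thresholds.host_p,
        )
        ctx["hosts"] = hosts
        hosts.filtered.to_csv(outdir / "hosts_filtered.tsv", sep="\t",
                              float_format=rio.REAL_FORMAT)
        info["n_host_assigned"] = int(len(hosts.filtered))

    ssrna = [v for v in catalog if v.nucleic_type is NucleicType.SSRNA]
    if ssrna:
        from .types import VOTUCatalog

        completeness = assess_ssrna_completeness(
            VOTUCatalog(ssrna, validate_lengths=False), ctx["annotations"]
        )
        ctx["ssrna_completeness"] = completeness
        pd.DataFrame(
            {
                "votu_id": [c.votu_id for c in completeness],
                "has_cores": [c.has_cores for c in completeness],
                "near_complete": [c.near_complete for c in completeness],
            }
        ).to_csv(outdir / "ssrna_taxonomy.tsv", sep="\t", index=False)
        info["n_ssrna_near_complete"] = sum(
            c.near_complete for c in completeness
        )
    return info


def _stage_priming(ctx, config, outdir):
    matrix = (
        ctx["presence"].merged
        if config.priming_use_presence
        else ctx["active"].active_votu
    )
    pset = identify_priming_votus(
        matrix, ctx["design"],
        min_active_replicates=config.priming_min_active_replicates,
    )
    ctx["priming"] = pset
    pd.DataFrame(
        {
            "votu_id": sorted(pset.votu_ids),
            "first_active_stage": [
                pset.first_active_stage.get(v, "") for v in sorted(pset.votu_ids)
            ],
        }
    ).to_csv(outdir / "priming_set.tsv", sep="\t", index=False)
    traj = priming_activity_trajectory(
        pset, ctx["gene_tpm"], ctx["annotations"], ctx["design"]
    )
    traj.to_csv(outdir / "priming_trajectory.tsv", sep="\t",
                float_format=rio.REAL_FORMAT)
    counts = count_active_votus(ctx["active"].active_votu, ctx["design"])
    counts.to_csv(outdir / "active_counts.tsv", sep="\t")
    return {"priming_set_size": len(pset)}


def _stage_report(ctx, config, outdir):
    kwargs = {
        "lifestyle_calls": ctx.get("lifestyle"),
        "catalog": ctx["catalog"],
        "presence_merged": ctx["presence"].merged,
        "active_votu": ctx["active"].active_votu,
    }
    if "hosts" in ctx:
        dsdna_ids = {
            v.votu_id
            for v in ctx["catalog"]
            if v.nucleic_type is NucleicType.DSDNA
        }
        assigned = set(ctx["hosts"].filtered.index)
        kwargs["host_results"] = {
            "dsdna": (len(assigned & dsdna_ids), len(dsdna_ids)),
        }
        kwargs["detected_host_counts"] = (
            ctx["hosts"].n_detected_genera,
            ctx["hosts"].n_predicted_genera,
        )
    if "differential" in ctx:
        kwargs["differential_labels"] = ctx["differential"]["enriched_label"]
    summaries = proportion_summaries(**kwargs)
    frame = summaries_to_frame(summaries)
    frame.to_csv(outdir / "summaries.tsv", sep="\t",
                 float_format=rio.REAL_FORMAT)
    return {"n_summaries": len(frame)}


_STAGE_FUNCS = {
    "detect": _stage_detect,
    "quantify": _stage_quantify,
    "activity": _stage_activity,
    "ecology": _stage_ecology,
    "differential": _stage_differential,
    "classify": _stage_classify,
    "priming": _stage_priming,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order; returns the manifest dict.

    Any stage failure aborts with the stage name and cause; the manifest
    written so far flags partial completion.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": config_to_dict(config),
        "stages": [],
        "complete": False,
    }
    ctx = _load_inputs(config)
    for stage in STAGES:
        try:
            info = _STAGE_FUNCS[stage](ctx, config, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest["stages"].append({"stage": stage, "status": "failed",
                                       "error": str(exc)})
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        manifest["stages"].append({"stage": stage, "status": "completed",
                                   "info": info})
    manifest["complete"] = True
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
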