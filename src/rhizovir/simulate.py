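"""Synthetic input-bundle generator with planted ground truth.

Generates the complete set of inputs the pipeline consumes — catalog, gene
annotations, sample design, DNA/RNA count matrices, coverage breadth,
library sizes, host tables — around a planted active-vOTU matrix, priming
set, compartment/rotation compositional effects, enriched gene labels, and
a negative active-vOTU/host-abundance coupling, so every stage has a
recoverable answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .types import (
    Compartment,
    CoreGeneRole,
    Gene,
    GeneAnnotations,
    GrowthStage,
    HostPrediction,
    NucleicType,
    Rotation,
    Sample,
    SampleDesign,
    SourceLibrary,
    VOTU,
    VOTUCatalog,
    CountBundle,
)

logger = logging.getLogger("rhizovir")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic bundle; all randomness flows from seed."""

    n_votus: int = 120
    n_ssrna_votus: int = 30
    genome_length_log_mean: float = np.log(25_000.0)
    genome_length_log_sd: float = 0.4
    genes_per_kb: float = 1.0
    provirus_fraction: float = 0.1
    temperate_vc_fraction: float = 0.05
    metabolic_cog_fraction: float = 0.2
    ssrna_full_length_fraction: float = 0.7

    compartments: tuple[str, ...] = ("bulk", "rhizosphere", "root")
    rotations: tuple[str, ...] = ("continuous", "virgin")
    growth_stages: tuple[str, ...] = ("seedling", "stem_extension", "pre_harvest")
    n_replicates: int = 2

    library_size_log_mean: float = np.log(2e6)
    library_size_log_sd: float = 0.2
    unmapped_fraction: float = 0.5
    read_length_bp: int = 150

    compartment_effect: float = 0.5
    rotation_effect: float = 0.5
    dirichlet_concentration: float = 500.0
    nb_dispersion: float = 0.1
    breadth_delta: float = 1.0

    active_fraction: float = 0.5
    priming_set_size: int = 15
    rna_activity_mean: float = 25.0
    leak_rate: float = 0.0
    leak_mean: float = 0.5
    priming_stage_ramp: float = 1.0  # per-stage multiplicative activity increase

    enriched_gene_fraction: float = 0.2
    enrichment_fold: float = 8.0
    #: extra multiplier on rhizosphere-enriched genes in root samples, so the
    #: planted spatial gradient (root >= rhizosphere >= bulk) is recoverable
    root_gradient_boost: float = 2.0

    n_host_genera: int = 20
    ktw_slope: float = -0.039
    host_noise_sd: float = 0.1

    seed: int = 0

    def validate(self) -> None:
        if self.n_votus <= 0:
            raise ValueError("n_votus must be positive")
        n_active = int(round(self.active_fraction * self.n_votus))
        if self.priming_set_size > n_active:
            raise ValueError(
                "priming_set_size must not exceed n_votus * active_fraction"
            )
        for name in (
            "active_fraction",
            "leak_rate",
            "provirus_fraction",
            "unmapped_fraction",
            "enriched_gene_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.unmapped_fraction >= 1.0:
            raise ValueError("unmapped_fraction must be < 1")
        if self.nb_dispersion < 0 or self.breadth_delta < 0:
            raise ValueError("dispersion and breadth delta must be nonnegative")


@dataclass
class GroundTruth:
    active_matrix: pd.DataFrame  # boolean vOTU x sample
    priming_set: set[str]
    enriched_gene_labels: pd.Series  # gene_id -> bulk/rhizosphere/none
    planted_ktw_slope: float
    group_composition_centers: pd.DataFrame  # group key x vOTU
    host_assignment: pd.Series  # active vOTU -> host genus


def _substream(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG sub-stream derived from the run seed."""
    ss = np.random.SeedSequence(
        [config.seed, int.from_bytes(stage.encode(), "big") % (2**32)]
    )
    return np.random.default_rng(ss)


def simulate_design(config: SimulationConfig) -> SampleDesign:
    samples = []
    for comp in config.compartments:
        for rot in config.rotations:
            for stage in config.growth_stages:
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{comp[:4]}_{rot[:4]}_{stage[:4]}_r{rep}"
                    samples.append(
                        Sample(
                            sample_id=sid,
                            compartment=Compartment(comp),
                            rotation=Rotation(rot),
                            growth_stage=GrowthStage(stage),
                            replicate=rep,
                        )
                    )
    return SampleDesign(samples)


def simulate_catalog(
    config: SimulationConfig,
) -> tuple[VOTUCatalog, GeneAnnotations]:
    """Catalog of dsDNA + ssRNA vOTUs and tiling gene annotations."""
    config.validate()
    rng = _substream(config, "catalog")
    votus, genes = [], []

    sources = list(SourceLibrary)
    for i in range(config.n_votus):
        votu_id = f"votu{i:04d}"
        is_provirus = rng.random() < config.provirus_fraction
        floor = (
            VOTUCatalog.MIN_PROVIRUS_LENGTH
            if is_provirus
            else VOTUCatalog.MIN_DSDNA_LENGTH
        )
        length = int(
            round(
                max(
                    floor,
                    rng.lognormal(
                        config.genome_length_log_mean, config.genome_length_log_sd
                    ),
                )
            )
        )
        votus.append(
            VOTU(
                votu_id=votu_id,
                genome_length_bp=length,
                nucleic_type=NucleicType.DSDNA,
                source_library=sources[int(rng.integers(0, 3))],
                is_provirus=is_provirus,
                vc_with_known_temperate=rng.random() < config.temperate_vc_fraction,
            )
        )
        n_genes = int(round(length / 1000.0 * config.genes_per_kb))
        if n_genes < 1:
            logger.info("%s: gene density gave 0 genes; forcing 1", votu_id)
            n_genes = 1
        width = length // n_genes
        for j in range(n_genes):
            start = j * width
            end = (j + 1) * width if j < n_genes - 1 else length
            cog = None
            if rng.random() < config.metabolic_cog_fraction:
                cog = str(rng.choice(list("CEFGHIPQ")))
            genes.append(
                Gene(
                    gene_id=f"{votu_id}_g{j:03d}",
                    votu_id=votu_id,
                    start_bp=start,
                    end_bp=end,
                    cog_letter=cog,
                )
            )

    roles = [CoreGeneRole.MP, CoreGeneRole.CP, CoreGeneRole.RDRP]
    for i in range(config.n_ssrna_votus):
        votu_id = f"rvotu{i:04d}"
        length = int(rng.normal(3500, 200))
        votus.append(
            VOTU(
                votu_id=votu_id,
                genome_length_bp=max(2500, length),
                nucleic_type=NucleicType.SSRNA,
                source_library=SourceLibrary.METATRANSCRIPTOME,
            )
        )
        width = max(2500, length) // 3
        for j, role in enumerate(roles):
            genes.append(
                Gene(
                    gene_id=f"{votu_id}_g{j}",
                    votu_id=votu_id,
                    start_bp=j * width,
                    end_bp=(j + 1) * width,
                    core_gene_role=role,
                    full_length=bool(
                        rng.random() < config.ssrna_full_length_fraction
                    ),
                )
            )
    return VOTUCatalog(votus), GeneAnnotations(genes)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with var = m + dispersion*m^2; dispersion 0 is the
    deterministic noiseless limit (rounded means)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return np.rint(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_counts(
    catalog: VOTUCatalog,
    annotations: GeneAnnotations,
    design: SampleDesign,
    config: SimulationConfig,
) -> tuple[CountBundle, GroundTruth]:
    """Generate count matrices, breadth, and library sizes with planted truth."""
    config.validate()
    rng = _substream(config, "counts")
    dsdna = [v for v in catalog if v.nucleic_type is NucleicType.DSDNA]
    votu_ids = [v.votu_id for v in dsdna]
    lengths = np.array([v.genome_length_bp for v in dsdna], dtype=float)
    n_votu = len(dsdna)
    samples = design.sample_ids
    n_samp = len(samples)

    # --- group composition centers (compartment/rotation displacement) ---
    base = rng.dirichlet(np.full(n_votu, 5.0))
    z_comp = {c: rng.standard_normal(n_votu) for c in config.compartments}
    z_rot = {r: rng.standard_normal(n_votu) for r in config.rotations}
    centers = {}
    for comp in config.compartments:
        for rot in config.rotations:
            shift = np.exp(
                config.compartment_effect * z_comp[comp]
                + config.rotation_effect * z_rot[rot]
            )
            center = base * shift
            centers[(comp, rot)] = center / center.sum()
    center_frame = pd.DataFrame(
        {f"{c}|{r}": v for (c, r), v in centers.items()}, index=votu_ids
    ).T
    center_frame.index.name = "group"

    # --- planted activity structure ---
    order = rng.permutation(n_votu)
    n_active = int(round(config.active_fraction * n_votu))
    active_ids = [votu_ids[i] for i in order[:n_active]]
    priming_ids = set(active_ids[: config.priming_set_size])
    always_active = set(active_ids[config.priming_set_size :])

    active = pd.DataFrame(False, index=votu_ids, columns=samples)
    for s in design:
        for votu in always_active:
            active.loc[votu, s.sample_id] = True
        if s.rotation is Rotation.CONTINUOUS and (
            s.compartment is Compartment.RHIZOSPHERE
        ):
            for votu in priming_ids:
                active.loc[votu, s.sample_id] = True

    # --- enriched gene labels (planted compartment-specific boosts) ---
    gene_ids = [g.gene_id for g in annotations if g.votu_id in set(votu_ids)]
    labels = pd.Series("none", index=gene_ids, dtype=object)
    votu_of = {g.gene_id: g.votu_id for g in annotations}
    active_set = set(active_ids)
    candidates = [g for g in gene_ids if votu_of[g] in active_set]
    n_enriched = int(round(config.enriched_gene_fraction * len(candidates)))
    if n_enriched:
        chosen = rng.choice(len(candidates), size=n_enriched, replace=False)
        half = n_enriched // 2
        for k, idx in enumerate(chosen):
            labels[candidates[idx]] = "bulk" if k < half else "rhizosphere"

    # --- DNA library counts and breadth ---
    stage_index = {s: i for i, s in enumerate(config.growth_stages)}
    nominal = {}
    dna_counts: dict[SourceLibrary, pd.DataFrame] = {}
    breadth: dict[SourceLibrary, pd.DataFrame] = {}
    library_sizes: dict[SourceLibrary, pd.Series] = {}
    for lib in (SourceLibrary.DNA_VIROME, SourceLibrary.TOTAL_METAGENOME):
        nominal[lib] = rng.lognormal(
            config.library_size_log_mean, config.library_size_log_sd, size=n_samp
        )
        counts = np.zeros((n_votu, n_samp), dtype=np.int64)
        for j, s in enumerate(design):
            center = centers[(s.compartment.value, s.rotation.value)]
            comp = rng.dirichlet(center * config.dirichlet_concentration)
            mapped = nominal[lib][j] * (1.0 - config.unmapped_fraction)
            counts[:, j] = _nb_draw(rng, comp * mapped, config.nb_dispersion)
        counts_df = pd.DataFrame(counts, index=votu_ids, columns=samples)
        dna_counts[lib] = counts_df
        depth = counts * config.read_length_bp / lengths[:, None]
        if config.breadth_delta == 0.0:
            b = (depth > 0).astype(float)
        else:
            b = 1.0 - np.exp(-depth / config.breadth_delta)
        breadth[lib] = pd.DataFrame(b, index=votu_ids, columns=samples)
        library_sizes[lib] = pd.Series(
            counts_df.sum(axis=0).to_numpy() / (1.0 - config.unmapped_fraction),
            index=samples,
            name="total_reads",
        )

    # --- RNA gene counts ---
    all_gene_ids = annotations.gene_ids
    rna = np.zeros((len(all_gene_ids), n_samp), dtype=np.int64)
    gene_index = {g: i for i, g in enumerate(all_gene_ids)}
    for j, s in enumerate(design):
        comp_name = s.compartment.value
        ramp = 1.0 + config.priming_stage_ramp * stage_index[
            s.growth_stage.value
        ]
        for g in annotations:
            if g.votu_id not in active_set:
                continue
            if not active.loc[g.votu_id, s.sample_id]:
                continue
            mean = config.rna_activity_mean
            if g.votu_id in priming_ids:
                mean *= ramp
            label = labels.get(g.gene_id, "none")
            if label != "none" and comp_name == label:
                mean *= config.enrichment_fold
            elif label == "rhizosphere" and comp_name == "root":
                mean *= config.enrichment_fold * config.root_gradient_boost
            rna[gene_index[g.gene_id], j] = _nb_draw(
                rng, np.array([mean]), config.nb_dispersion
            )[0]
        if config.leak_rate > 0:
            leak_mask = rng.random(len(all_gene_ids)) < config.leak_rate
            inactive_gene = np.array(
                [
                    not (
                        annotations[g].votu_id in active_set
                        and active.loc[annotations[g].votu_id, s.sample_id]
                    )
                    for g in all_gene_ids
                ]
            )
            leak_mask &= inactive_gene
            rna[leak_mask, j] += rng.poisson(
                config.leak_mean, size=int(leak_mask.sum())
            )
    rna_df = pd.DataFrame(rna, index=all_gene_ids, columns=samples)
    library_sizes[SourceLibrary.METATRANSCRIPTOME] = pd.Series(
        rna_df.sum(axis=0).to_numpy() / (1.0 - config.unmapped_fraction),
        index=samples,
        name="total_reads",
    )

    # --- host coupling (Kill-the-Winner style depression) ---
    host_rng = _substream(config, "hosts")
    genera = [f"genus{h:02d}" for h in range(config.n_host_genera)]
    host_assignment = pd.Series(
        {
            votu: genera[int(host_rng.integers(0, config.n_host_genera))]
            for votu in active_ids
        },
        name="host_genus",
    )

    bundle = CountBundle(
        dna_counts=dna_counts,
        rna_gene_counts=rna_df,
        library_sizes=library_sizes,
        coverage_breadth=breadth,
    )
    bundle.validate()
    truth = GroundTruth(
        active_matrix=active,
        priming_set=priming_ids,
        enriched_gene_labels=labels,
        planted_ktw_slope=config.ktw_slope,
        group_composition_centers=center_frame,
        host_assignment=host_assignment,
    )
    return bundle, truth


def simulate_host_table(
    truth: GroundTruth,
    design: SampleDesign,
    config: SimulationConfig,
) -> pd.DataFrame:
    """16S-style host genus log-abundance table with the planted KtW slope.

    log abundance of genus h in sample s = base_h + ktw_slope * (number of
    planted-active vOTUs assigned to h and active in s) + noise.
    """
    rng = _substream(config, "host_table")
    genera = sorted(set(truth.host_assignment))
    base = {h: rng.normal(5.0, 0.5) for h in genera}
    rows = np.zeros((len(genera), len(design)))
    active = truth.active_matrix
    for j, s in enumerate(design):
        for i, h in enumerate(genera):
            members = truth.host_assignment.index[truth.host_assignment == h]
            n_active = int(active.loc[members, s.sample_id].sum())
            rows[i, j] = (
                base[h]
                + config.ktw_slope * n_active
                + rng.normal(0.0, config.host_noise_sd)
            )
    return pd.DataFrame(rows, index=genera, columns=design.sample_ids)


def simulate_host_predictions(
    truth: GroundTruth, config: SimulationConfig
) -> list[HostPrediction]:
    """Host-prediction table: assigned vOTUs get confident p-values."""
    rng = _substream(config, "host_preds")
    preds = []
    for votu, genus in truth.host_assignment.items():
        preds.append(
            HostPrediction(
                votu_id=votu, host_genus=genus, p_value=float(rng.uniform(0, 0.04))
            )
        )
    return preds


def write_bundle(
    outdir: str | Path,
    design: SampleDesign,
    catalog: VOTUCatalog,
    annotations: GeneAnnotations,
    bundle: CountBundle,
    truth: GroundTruth,
    host_table: pd.DataFrame | None = None,
    host_predictions: list[HostPrediction] | None = None,
) -> dict[str, str]:
    """Write the exact input formats the readers consume, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rio.write_sample_design(design, outdir / "design.tsv")
    paths["design"] = "design.tsv"
    rio.write_votu_catalog(catalog, outdir / "catalog.tsv")
    paths["catalog"] = "catalog.tsv"
    rio.write_gene_annotations(
        annotations, outdir / "genes.gff3", outdir / "gene_functions.tsv"
    )
    paths["genes_gff3"] = "genes.gff3"
    paths["gene_functions"] = "gene_functions.tsv"
    for lib, m in bundle.dna_counts.items():
        name = f"counts_{lib.value}.tsv"
        rio.write_matrix(m, outdir / name)
        paths[f"counts_{lib.value}"] = name
    for lib, m in bundle.coverage_breadth.items():
        name = f"breadth_{lib.value}.tsv"
        rio.write_matrix(m, outdir / name)
        paths[f"breadth_{lib.value}"] = name
    rio.write_matrix(bundle.rna_gene_counts, outdir / "rna_gene_counts.tsv")
    paths["rna_gene_counts"] = "rna_gene_counts.tsv"
    rio.write_library_sizes(bundle.library_sizes, outdir / "library_sizes.tsv")
    paths["library_sizes"] = "library_sizes.tsv"
    if host_table is not None:
        rio.write_matrix(host_table, outdir / "host_otu_table.tsv")
        paths["host_otu_table"] = "host_otu_table.tsv"
    if host_predictions is not None:
        rio.write_host_predictions(host_predictions, outdir / "host_predictions.tsv")
        paths["host_predictions"] = "host_predictions.tsv"

    truth.active_matrix.to_csv(outdir / "ground_truth_active.tsv", sep="\t")
    pd.Series(sorted(truth.priming_set), name="votu_id").to_csv(
        outdir / "ground_truth_priming.tsv", sep="\t", index=False
    )
    truth.enriched_gene_labels.rename("enriched_label").to_csv(
        outdir / "ground_truth_enriched_genes.tsv", sep="\t",
        index_label="gene_id",
    )
    paths["ground_truth_active"] = "ground_truth_active.tsv"
    paths["ground_truth_priming"] = "ground_truth_priming.tsv"
    paths["ground_truth_enriched_genes"] = "ground_truth_enriched_genes.tsv"
    return paths


def simulate_bundle(
    config: SimulationConfig,
) -> tuple[SampleDesign, VOTUCatalog, GeneAnnotations, CountBundle, GroundTruth]:
    """One-call convenience wrapper chaining all generators."""
    design = simulate_design(config)
    catalog, annotations = simulate_catalog(config)
    bundle, truth = simulate_counts(catalog, annotations, design, config)
    return design, catalog, annotations, bundle, truth
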