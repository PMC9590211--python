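"""Metatranscriptome gene-count filtering, relative activity, and
active-vOTU classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GeneAnnotations, SampleDesign, VOTUCatalog

logger = logging.getLogger("rhizovir")

#: minimum summed reads per gene across a treatment group's replicates
MIN_GROUP_READS = 4
#: one transcribed gene is required per this many bp of genome for activity
ACTIVITY_WINDOW_BP = 10_000


def filter_gene_counts(
    rna_gene_counts: pd.DataFrame,
    design: SampleDesign,
    min_group_reads: int = MIN_GROUP_READS,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Zero out genes with < min_group_reads summed across a group's replicates.

    The decision is taken per gene per (compartment, rotation, growth stage)
    group on the sum over that group's replicates; failing genes are zeroed
    in every replicate of that group only. With per_replicate=True the
    threshold instead applies to each sample column independently.
    """
    missing = [c for c in rna_gene_counts.columns if c not in design]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    out = rna_gene_counts.copy()
    if per_replicate:
        out[out < min_group_reads] = 0
        return out
    for _key, sample_ids in design.groups().items():
        cols = [c for c in sample_ids if c in out.columns]
        if not cols:
            continue
        group_sum = out[cols].sum(axis=1)
        failing = group_sum < min_group_reads
        out.loc[failing, cols] = 0
    return out


def compute_gene_tpm(
    filtered_counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_size: pd.Series,
) -> pd.DataFrame:
    """Per-gene relative activity: count / (length/1e3) / (depth/1e6).

    Note this is the length-and-depth normalization as used throughout the
    pipeline (RPKM-form); columns are deliberately NOT rescaled to sum to
    1e6.
    """
    from .detection import compute_cpm

    return compute_cpm(filtered_counts, gene_lengths, library_size)


@dataclass
class ActivityResult:
    """Active-vOTU calls with the supporting transcribed-gene counts."""

    active_votu: pd.DataFrame  # boolean vOTU x sample
    active_gene_count: pd.DataFrame  # integer vOTU x sample


def call_active_votus(
    filtered_counts: pd.DataFrame,
    catalog: VOTUCatalog,
    annotations: GeneAnnotations,
    activity_window_bp: int = ACTIVITY_WINDOW_BP,
) -> ActivityResult:
    """A vOTU is active in a sample when its transcribed-gene density reaches
    one gene per activity_window_bp of genome.

    With k(i, s) = number of genes of vOTU i with filtered count > 0 in
    sample s, vOTU i is active iff k(i, s) * activity_window_bp >=
    genome_length_bp(i).
    """
    votu_of = annotations.votu_of()
    unknown = sorted(set(votu_of.unique()) - set(catalog.votu_ids))
    if unknown:
        raise ValueError(f"genes reference uncataloged vOTU(s): {unknown}")
    expressed = (filtered_counts > 0).astype(int)
    gene_votu = votu_of.reindex(filtered_counts.index)
    if gene_votu.isna().any():
        missing = list(filtered_counts.index[gene_votu.isna()])
        raise ValueError(f"counts for unannotated gene(s): {missing}")

    k = expressed.groupby(gene_votu).sum()
    k = k.reindex(catalog.votu_ids, fill_value=0)
    no_genes = [v.votu_id for v in catalog if not annotations.for_votu(v.votu_id)]
    if no_genes:
        logger.warning(
            "%d vOTU(s) with zero annotated genes can never be active", len(no_genes)
        )
    lengths = catalog.lengths().reindex(k.index).to_numpy()[:, None]
    active = pd.DataFrame(
        k.to_numpy() * activity_window_bp >= lengths,
        index=k.index,
        columns=k.columns,
    )
    return ActivityResult(active_votu=active, active_gene_count=k)


def summarize_activity(
    gene_tpm: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    design: SampleDesign | None = None,
) -> pd.DataFrame:
    """Summed relative activity per gene set per sample, with total fractions.

    Returns a long frame (set_label, sample_id, summed_tpm, fraction). When a
    design is supplied, per-group means and 95% CI half-widths are appended
    as separate rows keyed by the group tuple.
    """
    total = gene_tpm.sum(axis=0)
    rows = []
    for label, genes in gene_sets.items():
        if not genes:
            logger.warning("gene set %r is empty", label)
        subset = gene_tpm.reindex(index=genes).fillna(0.0)
        summed = subset.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, summed / total, np.nan)
        for sample, s_val, f_val in zip(gene_tpm.columns, summed, frac):
            rows.append(
                {
                    "set_label": label,
                    "sample_id": sample,
                    "summed_tpm": s_val,
                    "fraction": f_val,
                }
            )
    out = pd.DataFrame(rows)
    if design is not None and not out.empty:
        meta = design.to_frame()
        out = out.join(meta, on="sample_id")
    return out


def group_mean_ci(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Group means with 95% t-interval half-widths over replicates."""
    from scipy import stats

    rows = []
    for key, sub in values.groupby(groups):
        n = len(sub)
        mean = float(sub.mean())
        if n > 1 and float(sub.std(ddof=1)) > 0:
            half = float(
                stats.t.ppf(0.975, n - 1) * sub.std(ddof=1) / np.sqrt(n)
            )
        else:
            half = 0.0
        rows.append({"group": key, "n": n, "mean": mean, "ci95_half_width": half})
    return pd.DataFrame(rows)
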