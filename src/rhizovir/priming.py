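"""Rhizosphere priming-set identification, activity trajectories, active
vOTU counts, and the headline proportion summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .types import (
    Compartment,
    GeneAnnotations,
    GrowthStage,
    Rotation,
    SampleDesign,
)

logger = logging.getLogger("rhizovir")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (reporting convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionSummary:
    label: str
    numerator: int
    denominator: int

    def __post_init__(self):
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(
                f"{self.label}: numerator {self.numerator} outside "
                f"[0, {self.denominator}]"
            )

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.numerator / self.denominator, 1)


@dataclass
class PrimingSet:
    votu_ids: set[str]
    min_active_replicates: int
    first_active_stage: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.votu_ids)


_STAGE_ORDER = [
    GrowthStage.SEEDLING.value,
    GrowthStage.STEM_EXTENSION.value,
    GrowthStage.PRE_HARVEST.value,
]


def identify_priming_votus(
    active_votu: pd.DataFrame,
    design: SampleDesign,
    min_active_replicates: int = 1,
) -> PrimingSet:
    """vOTUs active in the seedling rhizosphere under continuous cropping
    but in no virgin-rotation seedling rhizosphere replicate.

    Membership requires activity in >= min_active_replicates continuous
    replicates and zero active virgin replicates. Also records each
    member's first active growth stage (any sample).
    """

    def _samples(rotation: Rotation) -> list[str]:
        return [
            s.sample_id
            for s in design
            if s.compartment is Compartment.RHIZOSPHERE
            and s.rotation is rotation
            and s.growth_stage is GrowthStage.SEEDLING
            and s.sample_id in active_votu.columns
        ]

    cont = _samples(Rotation.CONTINUOUS)
    virg = _samples(Rotation.VIRGIN)
    if not cont or not virg:
        raise ValueError(
            "active matrix must cover seedling rhizosphere samples of both "
            "rotations"
        )
    n_active_cont = active_votu[cont].sum(axis=1)
    n_active_virg = active_votu[virg].sum(axis=1)
    members = set(
        active_votu.index[
            (n_active_cont >= min_active_replicates) & (n_active_virg == 0)
        ]
    )

    first_stage: dict[str, str] = {}
    stage_of = {s.sample_id: s.growth_stage.value for s in design}
    for votu in members:
        row = active_votu.loc[votu]
        stages = {
            stage_of[c] for c in active_votu.columns if c in stage_of and row[c]
        }
        for stage in _STAGE_ORDER:
            if stage in stages:
                first_stage[votu] = stage
                break
    return PrimingSet(
        votu_ids=members,
        min_active_replicates=min_active_replicates,
        first_active_stage=first_stage,
    )


def priming_activity_trajectory(
    priming_set: PrimingSet,
    gene_tpm: pd.DataFrame,
    annotations: GeneAnnotations,
    design: SampleDesign,
) -> pd.DataFrame:
    """Summed relative activity of the priming set's genes per sample, with
    (growth_stage, rotation, compartment) group means and 95% CIs."""
    from .activity import group_mean_ci

    if not priming_set.votu_ids:
        logger.warning("empty priming set: trajectory is all zeros")
    member_genes = [
        g.gene_id
        for votu in sorted(priming_set.votu_ids)
        for g in annotations.for_votu(votu)
    ]
    summed = (
        gene_tpm.reindex(index=member_genes).fillna(0.0).sum(axis=0)
        if member_genes
        else pd.Series(0.0, index=gene_tpm.columns)
    )
    meta = design.to_frame().reindex(summed.index)
    per_sample = pd.DataFrame({"summed_tpm": summed}).join(meta)
    keys = meta[["growth_stage", "rotation", "compartment"]].apply(tuple, axis=1)
    means = group_mean_ci(summed, keys)
    means[["growth_stage", "rotation", "compartment"]] = pd.DataFrame(
        means["group"].tolist(), index=means.index
    )
    means = means.drop(columns="group")
    per_sample.attrs["group_means"] = means
    return per_sample


def count_active_votus(
    active_votu: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Active vOTUs per sample (boolean column sums) with group mean/CI."""
    from .activity import group_mean_ci

    counts = active_votu.sum(axis=0).astype(int)
    counts.name = "n_active"
    meta = design.to_frame().reindex(counts.index)
    out = pd.DataFrame({"n_active": counts}).join(meta)
    keys = meta[["compartment", "rotation", "growth_stage"]].apply(tuple, axis=1)
    out.attrs["group_means"] = group_mean_ci(counts.astype(float), keys)
    return out


def proportion_summaries(
    *,
    lifestyle_calls=None,
    catalog=None,
    presence_merged: pd.DataFrame | None = None,
    active_votu: pd.DataFrame | None = None,
    ssrna_detected: pd.Series | None = None,
    ssrna_taxonomy: pd.DataFrame | None = None,
    host_results: dict[str, tuple[int, int]] | None = None,
    detected_host_counts: tuple[int, int] | None = None,
    differential_labels: pd.Series | None = None,
    enriched_label_names: tuple[str, str] = ("bulk", "rhizosphere"),
) -> dict[str, ProportionSummary | float]:
    """Compute the headline proportion summaries from upstream stage outputs.

    Every summary is pure arithmetic on counts derived from the provided
    inputs; inputs left as None simply omit their summaries. ssrna_taxonomy
    needs columns cluster_level ('genus'/'species') and is_new;
    host_results maps a label to (n_assigned, n_total); detected_host_counts
    is (n_detected_genera, n_predicted_genera). The differential ratio
    (bulk:rhizosphere enriched gene counts) is returned as a plain float
    under 'bulk_to_rhizosphere_gene_ratio'.
    """
    out: dict[str, ProportionSummary | float] = {}

    if lifestyle_calls is not None and catalog is not None:
        from .types import NucleicType

        dsdna_ids = {
            v.votu_id for v in catalog if v.nucleic_type is NucleicType.DSDNA
        }
        n_temperate = sum(
            1
            for c in lifestyle_calls
            if c.votu_id in dsdna_ids and c.lifestyle == "temperate"
        )
        _add(out, "temperate_dsdna", n_temperate, len(dsdna_ids))

    if presence_merged is not None:
        detected = presence_merged.any(axis=1)
        _add(out, "detected_overall", int(detected.sum()), len(detected))
        if catalog is not None:
            by_source = {}
            for v in catalog:
                if v.votu_id in detected.index:
                    by_source.setdefault(v.source_library.value, []).append(
                        bool(detected[v.votu_id])
                    )
            for source, flags in sorted(by_source.items()):
                _add(out, f"detected_{source}", sum(flags), len(flags))

    if active_votu is not None:
        active_any = active_votu.any(axis=1)
        _add(out, "active_overall", int(active_any.sum()), len(active_any))
        if catalog is not None:
            by_source = {}
            for v in catalog:
                if v.votu_id in active_any.index:
                    by_source.setdefault(v.source_library.value, []).append(
                        bool(active_any[v.votu_id])
                    )
            for source, flags in sorted(by_source.items()):
                _add(out, f"active_{source}", sum(flags), len(flags))

    if ssrna_detected is not None:
        _add(out, "detected_ssrna", int(ssrna_detected.sum()), len(ssrna_detected))

    if ssrna_taxonomy is not None:
        for level in ("genus", "species"):
            sub = ssrna_taxonomy[ssrna_taxonomy["cluster_level"] == level]
            if len(sub):
                _add(out, f"new_{level}", int(sub["is_new"].sum()), len(sub))

    if host_results:
        for label, (n_assigned, n_total) in host_results.items():
            _add(out, f"host_assigned_{label}", n_assigned, n_total)

    if detected_host_counts is not None:
        _add(out, "host_genera_detected", *detected_host_counts)

    if differential_labels is not None:
        ref_name, trt_name = enriched_label_names
        n_ref = int((differential_labels == ref_name).sum())
        n_trt = int((differential_labels == trt_name).sum())
        if n_trt > 0:
            out["bulk_to_rhizosphere_gene_ratio"] = n_ref / n_trt
        else:
            logger.warning("no %s-enriched genes: ratio omitted", trt_name)
    return out


def _add(out: dict, label: str, num: int, den: int) -> None:
    if den == 0:
        logger.warning("summary %s: zero denominator, omitted", label)
        return
    out[label] = ProportionSummary(label=label, numerator=num, denominator=den)


def summaries_to_frame(
    summaries: dict[str, ProportionSummary | float]
) -> pd.DataFrame:
    rows = []
    for label, s in summaries.items():
        if isinstance(s, ProportionSummary):
            rows.append(
                {
                    "label": label,
                    "numerator": s.numerator,
                    "denominator": s.denominator,
                    "percent": s.percent,
                }
            )
        else:
            rows.append(
                {"label": label, "numerator": None, "denominator": None, "percent": s}
            )
    return pd.DataFrame(rows).set_index("label")
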