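"""Rule-based vOTU characterization: lifestyle calls, host-prediction
filtering, ssRNA phage completeness, and RdRp identity clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .detection import greedy_dedup
from .types import (
    CoreGeneRole,
    GeneAnnotations,
    HostPrediction,
    VOTUCatalog,
)

logger = logging.getLogger("rhizovir")

HOST_P_THRESHOLD = 0.05
KNOWN_SPECIES_ANI = 0.95


def load_lysogeny_pfam_list() -> frozenset[str]:
    """Packaged list of lysogeny-associated Pfam accessions."""
    text = (
        resources.files("rhizovir.data")
        .joinpath("lysogeny_pfam_list.txt")
        .read_text()
    )
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class LifestyleCall:
    votu_id: str
    lifestyle: str  # 'temperate' or 'lytic'
    evidence: frozenset[str]  # subset of {lysogeny_domain, temperate_vc, provirus}


def call_lifestyle(
    catalog: VOTUCatalog,
    annotations: GeneAnnotations,
    lysogeny_domains: frozenset[str] | None = None,
) -> list[LifestyleCall]:
    """Temperate iff any lysogeny Pfam domain, temperate-VC membership, or
    proviral origin; otherwise lytic. Exhaustive and exclusive."""
    if lysogeny_domains is None:
        lysogeny_domains = load_lysogeny_pfam_list()
    calls = []
    for votu in catalog:
        evidence = set()
        for gene in annotations.for_votu(votu.votu_id):
            if gene.pfam_domains & lysogeny_domains:
                evidence.add("lysogeny_domain")
                break
        if votu.vc_with_known_temperate:
            evidence.add("temperate_vc")
        if votu.is_provirus:
            evidence.add("provirus")
        calls.append(
            LifestyleCall(
                votu_id=votu.votu_id,
                lifestyle="temperate" if evidence else "lytic",
                evidence=frozenset(evidence),
            )
        )
    return calls


@dataclass
class HostFilterResult:
    filtered: pd.DataFrame  # votu_id-indexed: host_genus, p_value, host_detected
    n_predicted_genera: int
    n_detected_genera: int

    @property
    def detected_fraction(self) -> float:
        if self.n_predicted_genera == 0:
            return float("nan")
        return self.n_detected_genera / self.n_predicted_genera


def filter_hosts(
    predictions: list[HostPrediction],
    detected_genera: set[str] | None = None,
    p_threshold: float = HOST_P_THRESHOLD,
) -> HostFilterResult:
    """Keep predictions with strictly p < threshold, one best per vOTU.

    Duplicate (votu, genus) rows keep the minimum p (logged); when several
    genera survive for one vOTU the lowest-p one wins. Each surviving genus
    is cross-referenced against detected_genera (e.g. from a 16S table).
    """
    best: dict[tuple[str, str], float] = {}
    n_dup = 0
    for pred in predictions:
        key = (pred.votu_id, pred.host_genus)
        if key in best:
            n_dup += 1
            best[key] = min(best[key], pred.p_value)
        else:
            best[key] = pred.p_value
    if n_dup:
        logger.info("host predictions: %d duplicate (votu, genus) row(s)", n_dup)

    per_votu: dict[str, tuple[str, float]] = {}
    for (votu_id, genus), p in best.items():
        if p >= p_threshold:
            continue
        prev = per_votu.get(votu_id)
        if prev is None or p < prev[1] or (p == prev[1] and genus < prev[0]):
            per_votu[votu_id] = (genus, p)

    detected_genera = detected_genera or set()
    rows = [
        {
            "votu_id": votu_id,
            "host_genus": genus,
            "p_value": p,
            "host_detected": genus in detected_genera,
        }
        for votu_id, (genus, p) in sorted(per_votu.items())
    ]
    filtered = pd.DataFrame(
        rows, columns=["votu_id", "host_genus", "p_value", "host_detected"]
    ).set_index("votu_id")
    predicted_genera = set(filtered["host_genus"])
    return HostFilterResult(
        filtered=filtered,
        n_predicted_genera=len(predicted_genera),
        n_detected_genera=len(predicted_genera & detected_genera),
    )


@dataclass(frozen=True)
class SsrnaCompleteness:
    votu_id: str
    has_cores: bool
    near_complete: bool
    genus_id: str | None = None
    species_id: str | None = None


_CORE_ROLES = {CoreGeneRole.MP, CoreGeneRole.CP, CoreGeneRole.RDRP}


def assess_ssrna_completeness(
    catalog: VOTUCatalog, annotations: GeneAnnotations
) -> list[SsrnaCompleteness]:
    """ssRNA vOTU completeness: has_cores iff MP, CP, and RdRp are all
    present (any order); near_complete additionally requires a full-length
    copy of each. Duplicate roles use any full-length copy if present."""
    out = []
    for votu in catalog:
        roles_present: set[CoreGeneRole] = set()
        roles_full: set[CoreGeneRole] = set()
        for gene in annotations.for_votu(votu.votu_id):
            if gene.core_gene_role is None:
                continue
            roles_present.add(gene.core_gene_role)
            if gene.full_length:
                roles_full.add(gene.core_gene_role)
        has_cores = _CORE_ROLES <= roles_present
        out.append(
            SsrnaCompleteness(
                votu_id=votu.votu_id,
                has_cores=has_cores,
                near_complete=has_cores and _CORE_ROLES <= roles_full,
            )
        )
    return out


def cluster_rdrp(
    pairwise_aa_identity: pd.DataFrame,
    lengths: pd.Series,
    genus_threshold: float,
    species_threshold: float,
) -> pd.DataFrame:
    """Two-level greedy clustering of RdRp sequences.

    Members cluster at genus_threshold, then again within each genus at
    species_threshold, so species clusters nest within genus clusters by
    construction. Thresholds are mandatory (no defaults). Returns a frame
    indexed by member id with genus_id and species_id columns (labels are
    the representative ids).
    """
    if not (0.0 < genus_threshold < 1.0 and 0.0 < species_threshold < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    if species_threshold <= genus_threshold:
        raise ValueError("species threshold must exceed genus threshold")
    genus = greedy_dedup(pairwise_aa_identity, lengths, id_threshold=genus_threshold,
                         cov_threshold=0.0)
    species = pd.Series(index=lengths.index, dtype=object, name="species_id")
    for rep in genus.unique():
        members = genus.index[genus == rep]
        sub_lengths = lengths.loc[members]
        mask = pairwise_aa_identity["a"].isin(members) & pairwise_aa_identity[
            "b"
        ].isin(members)
        sub = greedy_dedup(
            pairwise_aa_identity[mask], sub_lengths,
            id_threshold=species_threshold, cov_threshold=0.0,
        )
        species.loc[sub.index] = sub
    out = pd.DataFrame({"genus_id": genus, "species_id": species})
    out.index.name = "member_id"
    return out


def match_known_species(
    ani_table: pd.DataFrame,
    votu_ids: list[str],
    ani_threshold: float = KNOWN_SPECIES_ANI,
) -> pd.Series:
    """known_species_match iff max ANI to any reference genome >= threshold.

    ani_table has columns votu_id, reference_id, ani; vOTUs without rows do
    not match. An empty table flags everything False with a warning.
    """
    if ani_table.empty:
        logger.warning("empty reference ANI table: no known-species matches")
        return pd.Series(False, index=votu_ids, name="known_species_match")
    best = ani_table.groupby("votu_id")["ani"].max()
    out = best.reindex(votu_ids).fillna(0.0) >= ani_threshold
    out.name = "known_species_match"
    return out
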