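"""Core domain types shared across all pipeline stages.

Tabular data (counts, breadth, abundances) is carried as pandas DataFrames
with vOTU/gene ids on the index and sample ids on the columns; the
dataclasses below wrap these with validated metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Compartment(str, enum.Enum):
    BULK = "bulk"
    RHIZOSPHERE = "rhizosphere"
    ROOT = "root"


class Rotation(str, enum.Enum):
    CONTINUOUS = "continuous"
    VIRGIN = "virgin"


class GrowthStage(str, enum.Enum):
    SEEDLING = "seedling"
    STEM_EXTENSION = "stem_extension"
    PRE_HARVEST = "pre_harvest"


class NucleicType(str, enum.Enum):
    DSDNA = "dsDNA"
    SSRNA = "ssRNA"


class SourceLibrary(str, enum.Enum):
    DNA_VIROME = "dna_virome"
    TOTAL_METAGENOME = "total_metagenome"
    METATRANSCRIPTOME = "metatranscriptome"


#: DNA library types used for vOTU read mapping.
DNA_LIBRARIES = (SourceLibrary.DNA_VIROME, SourceLibrary.TOTAL_METAGENOME)


@dataclass(frozen=True)
class Sample:
    """One sequenced sample in the factorial field design."""

    sample_id: str
    compartment: Compartment
    rotation: Rotation
    growth_stage: GrowthStage
    replicate: int

    @property
    def group_key(self) -> tuple[str, str, str]:
        """Deterministic treatment-group key (compartment, rotation, stage)."""
        return (
            self.compartment.value,
            self.rotation.value,
            self.growth_stage.value,
        )


class SampleDesign:
    """Validated collection of samples keyed by sample_id."""

    def __init__(self, samples: list[Sample]):
        ids = [s.sample_id for s in samples]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate sample_id values: {sorted(dup)}")
        self.samples = list(samples)
        self._by_id = {s.sample_id: s for s in samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def groups(self) -> dict[tuple[str, str, str], list[str]]:
        """Map each (compartment, rotation, stage) key to its sample ids."""
        out: dict[tuple[str, str, str], list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group_key, []).append(s.sample_id)
        return out

    def subset(self, sample_ids: list[str]) -> "SampleDesign":
        return SampleDesign([self._by_id[i] for i in sample_ids])

    def factor(self, name: str, sample_ids: list[str] | None = None) -> list[str]:
        """Factor level per sample, in sample order."""
        ids = sample_ids if sample_ids is not None else self.sample_ids
        return [getattr(self._by_id[i], name).value for i in ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "compartment": [s.compartment.value for s in self.samples],
                "rotation": [s.rotation.value for s in self.samples],
                "growth_stage": [s.growth_stage.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id")


@dataclass(frozen=True)
class VOTU:
    """Catalog entry for one viral population (dereplicated contig)."""

    votu_id: str
    genome_length_bp: int
    nucleic_type: NucleicType
    source_library: SourceLibrary
    is_provirus: bool = False
    vc_with_known_temperate: bool = False
    known_species_match: bool = False


class VOTUCatalog:
    """Validated collection of vOTUs keyed by votu_id."""

    #: minimum contig length for non-proviral dsDNA entries
    MIN_DSDNA_LENGTH = 10_000
    #: minimum retained length for proviral sequences
    MIN_PROVIRUS_LENGTH = 5_000

    def __init__(self, votus: list[VOTU], validate_lengths: bool = True):
        ids = [v.votu_id for v in votus]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate votu_id values: {sorted(dup)}")
        if validate_lengths:
            for v in votus:
                if v.genome_length_bp <= 0:
                    raise ValueError(f"{v.votu_id}: non-positive genome length")
                if v.nucleic_type is NucleicType.DSDNA:
                    floor = (
                        self.MIN_PROVIRUS_LENGTH
                        if v.is_provirus
                        else self.MIN_DSDNA_LENGTH
                    )
                    if v.genome_length_bp < floor:
                        raise ValueError(
                            f"{v.votu_id}: length {v.genome_length_bp} below "
                            f"{floor} bp floor"
                        )
        self.votus = list(votus)
        self._by_id = {v.votu_id: v for v in votus}

    def __len__(self) -> int:
        return len(self.votus)

    def __iter__(self):
        return iter(self.votus)

    def __getitem__(self, votu_id: str) -> VOTU:
        return self._by_id[votu_id]

    def __contains__(self, votu_id: str) -> bool:
        return votu_id in self._by_id

    @property
    def votu_ids(self) -> list[str]:
        return [v.votu_id for v in self.votus]

    def lengths(self) -> pd.Series:
        return pd.Series(
            {v.votu_id: v.genome_length_bp for v in self.votus}, name="genome_length_bp"
        )

    def select(self, **criteria) -> list[VOTU]:
        """Filter vOTUs by attribute equality, e.g. nucleic_type=NucleicType.DSDNA."""
        out = self.votus
        for k, want in criteria.items():
            out = [v for v in out if getattr(v, k) == want]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "votu_id": [v.votu_id for v in self.votus],
                "genome_length_bp": [v.genome_length_bp for v in self.votus],
                "nucleic_type": [v.nucleic_type.value for v in self.votus],
                "source_library": [v.source_library.value for v in self.votus],
                "is_provirus": [v.is_provirus for v in self.votus],
                "vc_with_known_temperate": [
                    v.vc_with_known_temperate for v in self.votus
                ],
                "known_species_match": [v.known_species_match for v in self.votus],
            }
        ).set_index("votu_id")


class CoreGeneRole(str, enum.Enum):
    MP = "MP"
    CP = "CP"
    RDRP = "RdRp"


@dataclass(frozen=True)
class Gene:
    """One annotated gene; coordinates are 0-based half-open."""

    gene_id: str
    votu_id: str
    start_bp: int
    end_bp: int
    cog_letter: str | None = None
    pfam_domains: frozenset[str] = field(default_factory=frozenset)
    core_gene_role: CoreGeneRole | None = None
    full_length: bool = True

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"{self.gene_id}: end ({self.end_bp}) must exceed start "
                f"({self.start_bp}) in half-open coordinates"
            )

    @property
    def gene_length_bp(self) -> int:
        return self.end_bp - self.start_bp


class GeneAnnotations:
    """Collection of genes, indexed by gene and grouped by vOTU."""

    def __init__(self, genes: list[Gene]):
        ids = [g.gene_id for g in genes]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate gene_id values: {sorted(dup)}")
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in genes}
        self._by_votu: dict[str, list[Gene]] = {}
        for g in genes:
            self._by_votu.setdefault(g.votu_id, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def for_votu(self, votu_id: str) -> list[Gene]:
        return self._by_votu.get(votu_id, [])

    def votu_of(self) -> pd.Series:
        return pd.Series({g.gene_id: g.votu_id for g in self.genes}, name="votu_id")

    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.gene_length_bp for g in self.genes}, name="gene_length_bp"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "votu_id": [g.votu_id for g in self.genes],
                "start_bp": [g.start_bp for g in self.genes],
                "end_bp": [g.end_bp for g in self.genes],
                "gene_length_bp": [g.gene_length_bp for g in self.genes],
                "cog_letter": [g.cog_letter or "" for g in self.genes],
                "pfam_domains": [
                    ";".join(sorted(g.pfam_domains)) for g in self.genes
                ],
                "core_gene_role": [
                    g.core_gene_role.value if g.core_gene_role else ""
                    for g in self.genes
                ],
                "full_length": [g.full_length for g in self.genes],
            }
        ).set_index("gene_id")


@dataclass
class CountBundle:
    """Raw read counts and coverage breadth from upstream read mapping.

    dna_counts maps each DNA library type to a vOTU x sample integer matrix;
    rna_gene_counts is gene x sample; library_sizes maps library type to a
    per-sample total-read Series; coverage_breadth maps DNA library type to a
    vOTU x sample breadth matrix with entries in [0, 1].
    """

    dna_counts: dict[SourceLibrary, pd.DataFrame]
    rna_gene_counts: pd.DataFrame
    library_sizes: dict[SourceLibrary, pd.Series]
    coverage_breadth: dict[SourceLibrary, pd.DataFrame]

    def validate(self) -> None:
        for lib, m in self.dna_counts.items():
            if (m.to_numpy() < 0).any():
                raise ValueError(f"negative counts in {lib.value}")
        if (self.rna_gene_counts.to_numpy() < 0).any():
            raise ValueError("negative counts in rna_gene_counts")
        for lib, b in self.coverage_breadth.items():
            arr = b.to_numpy(dtype=float)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"breadth outside [0,1] in {lib.value}")
        for lib, m in self.dna_counts.items():
            sizes = self.library_sizes[lib]
            nonzero = m.sum(axis=0) > 0
            bad = nonzero & (sizes.reindex(m.columns).fillna(0) <= 0)
            if bad.any():
                raise ValueError(
                    f"{lib.value}: zero library size for samples with counts: "
                    f"{list(m.columns[bad])}"
                )


@dataclass(frozen=True)
class HostPrediction:
    votu_id: str
    host_genus: str
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.votu_id}: p_value outside [0,1]")
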