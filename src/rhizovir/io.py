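"""Readers and writers for the pipeline's tab-separated interchange formats.

All stages consume the validated domain types produced here; no stage
re-reads raw files. Real-valued matrices are written with 12 significant
digits so that a write/read round trip is exact at that precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

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
)

logger = logging.getLogger("rhizovir")

REAL_FORMAT = "%.12g"

_DESIGN_COLUMNS = ["sample_id", "compartment", "rotation", "growth_stage", "replicate"]


def _canon(value: str) -> str:
    return str(value).strip().lower()


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s): {', '.join(missing)}")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read the sample design TSV; enum values are trimmed and lowercased."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _DESIGN_COLUMNS, "sample design")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]).strip(),
                compartment=Compartment(_canon(row["compartment"])),
                rotation=Rotation(_canon(row["rotation"])),
                growth_stage=GrowthStage(_canon(row["growth_stage"])),
                replicate=int(row["replicate"]),
            )
        )
    return SampleDesign(samples)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t")


def read_votu_catalog(path: str | Path) -> VOTUCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        df,
        ["votu_id", "genome_length_bp", "nucleic_type", "source_library"],
        "vOTU catalog",
    )

    def _bool(row, col):
        return str(row.get(col, "False")).strip().lower() in ("true", "1")

    votus = [
        VOTU(
            votu_id=str(row["votu_id"]).strip(),
            genome_length_bp=int(row["genome_length_bp"]),
            nucleic_type=NucleicType(str(row["nucleic_type"]).strip()),
            source_library=SourceLibrary(_canon(row["source_library"])),
            is_provirus=_bool(row, "is_provirus"),
            vc_with_known_temperate=_bool(row, "vc_with_known_temperate"),
            known_species_match=_bool(row, "known_species_match"),
        )
        for _, row in df.iterrows()
    ]
    return VOTUCatalog(votus)


def write_votu_catalog(catalog: VOTUCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t")


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            key, _, value = part.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_gene_annotations(
    gff3_path: str | Path,
    function_table_path: str | Path,
    catalog: VOTUCatalog | None = None,
) -> GeneAnnotations:
    """Read gene models (GFF3, 1-based inclusive) and a functional side table.

    Internal coordinates are 0-based half-open: a GFF3 feature with
    start=1, end=300 becomes (0, 300) with length 300. The side table is
    keyed by gene_id with columns cog_letter, pfam_domains
    (semicolon-separated accessions), and optional core_gene_role /
    full_length flags; rows for absent gene ids are skipped with a logged
    count.
    """
    records = []
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 fields): {line!r}")
            seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype.lower() not in ("gene", "cds"):
                continue
            attributes = _parse_gff_attributes(attrs)
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID attribute: {line!r}")
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(
                    f"gene {gene_id}: end ({end_i}) < start ({start_i})"
                )
            records.append((gene_id, seqid, start_i - 1, end_i))

    func = pd.read_csv(function_table_path, sep="\t", dtype=str)
    _require_columns(func, ["gene_id"], "gene function table")
    func = func.set_index("gene_id")
    known_ids = {r[0] for r in records}
    orphans = [g for g in func.index if g not in known_ids]
    if orphans:
        logger.warning(
            "gene function table: skipped %d row(s) for absent gene ids", len(orphans)
        )
        func = func.drop(index=orphans)

    genes = []
    for gene_id, votu_id, start0, end0 in records:
        cog, pfams, role, full = None, frozenset(), None, True
        if gene_id in func.index:
            row = func.loc[gene_id]
            cog_raw = row.get("cog_letter")
            if isinstance(cog_raw, str) and cog_raw.strip():
                cog = cog_raw.strip()
            pfam_raw = row.get("pfam_domains")
            if isinstance(pfam_raw, str) and pfam_raw.strip():
                pfams = frozenset(
                    p.strip() for p in pfam_raw.split(";") if p.strip()
                )
            role_raw = row.get("core_gene_role")
            if isinstance(role_raw, str) and role_raw.strip():
                role = CoreGeneRole(role_raw.strip())
            full_raw = row.get("full_length")
            if isinstance(full_raw, str) and full_raw.strip():
                full = full_raw.strip().lower() in ("true", "1")
        genes.append(
            Gene(
                gene_id=gene_id,
                votu_id=votu_id,
                start_bp=start0,
                end_bp=end0,
                cog_letter=cog,
                pfam_domains=pfams,
                core_gene_role=role,
                full_length=full,
            )
        )

    if catalog is not None:
        unknown = sorted({g.votu_id for g in genes if g.votu_id not in catalog})
        if unknown:
            raise ValueError(
                f"genes reference unknown vOTU id(s): {', '.join(unknown)}"
            )
    return GeneAnnotations(genes)


def write_gene_annotations(
    annotations: GeneAnnotations, gff3_path: str | Path, function_table_path: str | Path
) -> None:
    """Write gene models as GFF3 (back in 1-based inclusive) plus side table."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotations:
            fh.write(
                f"{g.votu_id}\trhizovir\tgene\t{g.start_bp + 1}\t{g.end_bp}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
    side = annotations.to_frame()[
        ["cog_letter", "pfam_domains", "core_gene_role", "full_length"]
    ]
    side.to_csv(function_table_path, sep="\t")


def read_matrix(path: str | Path, dtype=float) -> pd.DataFrame:
    """Read a row-label x sample TSV matrix (first column = index)."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(dtype)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    if matrix.dtypes.map(pd.api.types.is_integer_dtype).all():
        matrix.to_csv(path, sep="\t")
    else:
        matrix.to_csv(path, sep="\t", float_format=REAL_FORMAT)


def read_library_sizes(path: str | Path) -> dict[SourceLibrary, pd.Series]:
    df = pd.read_csv(path, sep="\t", dtype={"library": str, "sample_id": str})
    _require_columns(df, ["library", "sample_id", "total_reads"], "library sizes")
    out: dict[SourceLibrary, pd.Series] = {}
    for lib, sub in df.groupby("library"):
        out[SourceLibrary(lib)] = pd.Series(
            sub["total_reads"].astype(float).to_numpy(),
            index=sub["sample_id"].to_numpy(),
            name="total_reads",
        )
    return out


def write_library_sizes(
    sizes: dict[SourceLibrary, pd.Series], path: str | Path
) -> None:
    rows = []
    for lib, s in sizes.items():
        for sample_id, n in s.items():
            rows.append({"library": lib.value, "sample_id": sample_id, "total_reads": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=REAL_FORMAT)


def read_host_predictions(path: str | Path) -> list[HostPrediction]:
    df = pd.read_csv(path, sep="\t", dtype={"votu_id": str, "host_genus": str})
    _require_columns(df, ["votu_id", "host_genus", "p_value"], "host predictions")
    return [
        HostPrediction(
            votu_id=row["votu_id"],
            host_genus=row["host_genus"],
            p_value=float(row["p_value"]),
        )
        for _, row in df.iterrows()
    ]


def write_host_predictions(preds: list[HostPrediction], path: str | Path) -> None:
    pd.DataFrame(
        {
            "votu_id": [p.votu_id for p in preds],
            "host_genus": [p.host_genus for p in preds],
            "p_value": [p.p_value for p in preds],
        }
    ).to_csv(path, sep="\t", index=False, float_format=REAL_FORMAT)


def read_pairwise_table(path: str | Path) -> pd.DataFrame:
    """Read a pairwise identity table (a, b, identity, aligned_fraction)."""
    df = pd.read_csv(path, sep="\t", dtype={"a": str, "b": str})
    _require_columns(df, ["a", "b", "identity"], "pairwise table")
    if "aligned_fraction" not in df.columns:
        df["aligned_fraction"] = 1.0
    df["identity"] = df["identity"].astype(float)
    df["aligned_fraction"] = df["aligned_fraction"].astype(float)
    return df
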