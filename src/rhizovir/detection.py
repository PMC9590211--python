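"""vOTU presence calling, CPM normalization, library aggregation,
accumulation curves, and greedy identity-based clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import DNA_LIBRARIES, SourceLibrary

logger = logging.getLogger("rhizovir")

#: presence requires this fraction of genome positions covered >= 1x
BREADTH_THRESHOLD = 0.75


@dataclass
class PresenceMatrix:
    """Boolean vOTU x sample presence, per DNA library and merged (OR)."""

    per_library: dict[SourceLibrary, pd.DataFrame]
    merged: pd.DataFrame


def call_presence(
    coverage_breadth: dict[SourceLibrary, pd.DataFrame] | pd.DataFrame,
    threshold: float = BREADTH_THRESHOLD,
) -> PresenceMatrix:
    """Call a vOTU present where breadth of coverage >= threshold (inclusive).

    Accepts either one breadth matrix or a per-library dict; the merged
    matrix is the elementwise OR across libraries (missing entries absent).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"breadth threshold must be in [0,1], got {threshold}")
    if isinstance(coverage_breadth, pd.DataFrame):
        coverage_breadth = {SourceLibrary.DNA_VIROME: coverage_breadth}

    per_library = {}
    for lib, breadth in coverage_breadth.items():
        arr = breadth.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError(f"{lib.value}: breadth values outside [0,1]")
        present = breadth >= threshold
        empty = ~present.any(axis=0)
        if empty.any():
            logger.warning(
                "%s: %d sample(s) with no vOTU present", lib.value, int(empty.sum())
            )
        per_library[lib] = present

    votus = sorted(set().union(*(m.index for m in per_library.values())))
    samples = sorted(set().union(*(m.columns for m in per_library.values())))
    merged = pd.DataFrame(False, index=votus, columns=samples)
    for m in per_library.values():
        merged |= m.reindex(index=votus, columns=samples, fill_value=False)
    return PresenceMatrix(per_library=per_library, merged=merged)


def compute_cpm(
    counts: pd.DataFrame, genome_lengths: pd.Series, library_size: pd.Series
) -> pd.DataFrame:
    """Counts per kilobase per million reads.

    CPM(i, s) = count(i, s) / (L_i / 1e3) / (N_s / 1e6). Library size N_s is
    the total QC-passed reads in the library, not mapped reads.
    """
    lengths = genome_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise ValueError(f"missing genome length for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be positive")
    sizes = library_size.reindex(counts.columns)
    nonzero_cols = counts.sum(axis=0) > 0
    bad = nonzero_cols & (sizes.isna() | (sizes <= 0))
    if bad.any():
        raise ValueError(
            f"zero/missing library size for samples with counts: "
            f"{list(counts.columns[bad])}"
        )
    sizes = sizes.fillna(1.0)  # all-zero columns: divisor irrelevant
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = sizes.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / kb / millions,
        index=counts.index,
        columns=counts.columns,
    )


def aggregate_dna_libraries(
    cpm_virome: pd.DataFrame | None,
    cpm_metagenome: pd.DataFrame | None,
    presence: PresenceMatrix | None = None,
) -> pd.DataFrame:
    """One abundance value per vOTU per sample: median of available library CPMs.

    With both libraries present the median of two values is their mean; where
    a sample was sequenced in one library only, that library's value is used
    as-is. If a presence matrix is given, cells not present in the merged
    matrix are masked to zero after aggregation.
    """
    frames = [m for m in (cpm_virome, cpm_metagenome) if m is not None]
    if not frames:
        raise ValueError("at least one CPM matrix required")
    votus = sorted(set().union(*(m.index for m in frames)))
    samples = sorted(set().union(*(m.columns for m in frames)))
    stack = np.stack(
        [
            m.reindex(index=votus, columns=samples).to_numpy(dtype=float)
            for m in frames
        ]
    )
    with np.errstate(invalid="ignore"):
        agg = np.nanmedian(stack, axis=0)
    n_all_missing = int(np.isnan(agg).sum())
    if n_all_missing:
        logger.info("aggregation: %d cell(s) missing in all libraries -> 0", n_all_missing)
    agg = np.nan_to_num(agg, nan=0.0)
    out = pd.DataFrame(agg, index=votus, columns=samples)
    if presence is not None:
        mask = presence.merged.reindex(index=votus, columns=samples, fill_value=False)
        out = out.where(mask, 0.0)
    return out


def accumulation_curve(
    presence: pd.DataFrame, n_permutations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean cumulative detected richness over random sample orderings.

    Returns a frame with columns n_samples (1..S) and mean_richness, the
    average over permutations of the union size of the first k samples'
    detected vOTU sets.
    """
    if presence.shape[1] < 1:
        raise ValueError("at least one sample required")
    rng = np.random.default_rng(seed)
    arr = presence.to_numpy(dtype=bool)
    n_samples = arr.shape[1]
    totals = np.zeros(n_samples)
    for _ in range(n_permutations):
        order = rng.permutation(n_samples)
        seen = np.zeros(arr.shape[0], dtype=bool)
        for k, j in enumerate(order):
            seen |= arr[:, j]
            totals[k] += seen.sum()
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n_samples + 1),
            "mean_richness": totals / n_permutations,
        }
    )


def greedy_dedup(
    pairwise: pd.DataFrame,
    lengths: pd.Series,
    id_threshold: float = 0.95,
    cov_threshold: float = 0.95,
) -> pd.Series:
    """Greedy length-sorted clustering (CD-HIT-like semantics).

    Members are visited by descending length (ties broken lexicographically
    by id) and join the first existing cluster whose representative they
    match at identity >= id_threshold and aligned fraction >= cov_threshold;
    otherwise they found a new cluster. Missing pairs count as below
    threshold; self-pairs are ignored. Returns member id -> representative id.
    """
    pair_lookup: dict[tuple[str, str], tuple[float, float]] = {}
    for row in pairwise.itertuples(index=False):
        a, b = str(row.a), str(row.b)
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        ident = float(row.identity)
        cov = float(getattr(row, "aligned_fraction", 1.0))
        prev = pair_lookup.get(key)
        # keep the best-scoring record for duplicated pairs
        if prev is None or (ident, cov) > prev:
            pair_lookup[key] = (ident, cov)

    order = sorted(lengths.index, key=lambda i: (-lengths[i], i))
    representatives: list[str] = []
    assignment: dict[str, str] = {}
    for member in order:
        joined = None
        for rep in representatives:
            key = (member, rep) if member <= rep else (rep, member)
            hit = pair_lookup.get(key)
            if hit is not None and hit[0] >= id_threshold and hit[1] >= cov_threshold:
                joined = rep
                break
        if joined is None:
            representatives.append(member)
            assignment[member] = member
        else:
            assignment[member] = joined
    return pd.Series(assignment, name="representative")
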