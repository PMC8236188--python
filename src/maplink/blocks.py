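"""Graphical genotyping: genotype blocks and O/R marker allocation.

Along an ordered linkage group, consecutive solid (S) markers with an
identical genotype pattern across the F2 lines delimit a *genotype block* —
a chromosome segment inside which no line recombined.  The remaining one-site
(O) and representative (R) markers, whose vectors are noisier, are placed by
matching each against every block pattern and allocating to the block with
the fewest discordant lines, provided that minimum is unique and does not
exceed a cap (10 lines by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import Call, MaplinkError, genotypes_to_chars
from .linkage import GeneticMap
from .markers import MarkerClass, UnigeneMarker

#: a marker with more missing lines than this is never allocated
MAX_MISSING_FRACTION = 0.2


@dataclass
class GenotypeBlock:
    block_id: str
    group_index: int                  # 0-based linkage-group index
    span_cM: tuple                    # (first, last) map position of core members
    pattern: np.ndarray               # int8 per-line vector shared by the core
    core_members: list[str]           # S markers, in map order
    allocated_members: list = field(default_factory=list)  # (marker_id, class, mismatches)


@dataclass(frozen=True)
class Allocation:
    marker_id: str
    block_id: str | None
    mismatches: int | None
    reason: str | None                # None if allocated; 'tie' | 'over_cap' | 'too_missing'


def build_blocks(gmap: GeneticMap, vectors: dict[str, np.ndarray]) -> list[GenotypeBlock]:
    """Maximal runs of map-adjacent markers sharing one genotype vector.

    ``vectors`` maps every mapped (S) marker to its per-line genotype vector;
    adjacent blocks within a group necessarily have different patterns.
    """
    blocks: list[GenotypeBlock] = []
    for gi, group in enumerate(gmap.groups):
        for m in group.markers:
            if m not in vectors:
                raise MaplinkError(f"marker {m} is on the map but has no genotype vector")
        start = 0
        markers = group.markers
        n = len(markers)
        for i in range(1, n + 1):
            if i == n or not np.array_equal(vectors[markers[i]], vectors[markers[start]]):
                blocks.append(GenotypeBlock(
                    block_id=f"LG{gi + 1}_B{len([b for b in blocks if b.group_index == gi]) + 1:03d}",
                    group_index=gi,
                    span_cM=(group.positions_cM[start], group.positions_cM[i - 1]),
                    pattern=np.asarray(vectors[markers[start]], dtype=np.int8),
                    core_members=markers[start:i],
                ))
                start = i
    return blocks


def mismatch_count(vector: np.ndarray, pattern: np.ndarray) -> int:
    """Lines where both calls are non-missing and differ (missing is neutral)."""
    v = np.asarray(vector, dtype=np.int8)
    p = np.asarray(pattern, dtype=np.int8)
    if v.shape != p.shape:
        raise MaplinkError("marker vector and block pattern lengths differ")
    both = (v != Call.MISSING) & (p != Call.MISSING)
    return int(np.count_nonzero(both & (v != p)))


def allocate_marker(
    marker: UnigeneMarker,
    blocks: list[GenotypeBlock],
    max_block_mismatch: int = 10,
) -> Allocation:
    """Place one O/R marker on the block with the fewest discordant lines.

    The search is genome-wide over all blocks.  Allocation requires the
    minimum mismatch count to be unique and <= the cap; a tie or an
    over-cap minimum leaves the marker unallocated with the reason recorded.
    Markers with > 20% missing lines are never allocated (a mostly-missing
    vector would match vacuously).
    """
    v = marker.genotype_vector
    if np.count_nonzero(v == Call.MISSING) > MAX_MISSING_FRACTION * len(v):
        return Allocation(marker.unigene_id, None, None, "too_missing")
    mism = np.array([mismatch_count(v, b.pattern) for b in blocks])
    best = int(mism.min())
    if best > max_block_mismatch:
        return Allocation(marker.unigene_id, None, None, "over_cap")
    winners = np.flatnonzero(mism == best)
    if len(winners) > 1:
        return Allocation(marker.unigene_id, None, None, "tie")
    return Allocation(marker.unigene_id, blocks[int(winners[0])].block_id, best, None)


def allocate_all(
    markers: list[UnigeneMarker],
    blocks: list[GenotypeBlock],
    max_block_mismatch: int = 10,
) -> list[Allocation]:
    """Allocate every O/R marker; successful allocations are attached to
    their block's ``allocated_members``."""
    by_id = {b.block_id: b for b in blocks}
    out = []
    for m in markers:
        if m.marker_class is MarkerClass.S:
            continue
        alloc = allocate_marker(m, blocks, max_block_mismatch)
        out.append(alloc)
        if alloc.block_id is not None:
            by_id[alloc.block_id].allocated_members.append(
                (m.unigene_id, m.marker_class.value, alloc.mismatches))
    return out


def graphical_genotype_table(
    gmap: GeneticMap,
    blocks: list[GenotypeBlock],
    marker_vectors: dict[str, np.ndarray],
    line_names: list[str],
) -> pd.DataFrame:
    """Export table: one row per placed marker, in map order.

    Within each block the S core members come first (map order), then
    allocated O/R members sorted by mismatch count and id.  Cells hold the
    A/H/B encoding of each line's call; block, class and chromosome columns
    are included.
    """
    rows = []
    for b in blocks:
        chrom = gmap.groups[b.group_index].chromosome or 0
        members = [(m, "S", 0) for m in b.core_members]
        members += sorted(b.allocated_members, key=lambda t: (t[2], t[0]))
        for marker_id, klass, mm in members:
            vec = marker_vectors[marker_id]
            row = {"marker": marker_id, "block_id": b.block_id, "class": klass,
                   "chromosome": chrom, "linkage_group": b.group_index + 1,
                   "mismatches": mm}
            row.update(dict(zip(line_names, genotypes_to_chars(vec))))
            rows.append(row)
    return pd.DataFrame(rows)


def render_block_heatmap(table: pd.DataFrame, line_names: list[str], path: str) -> None:
    """Optional PNG rendering of the graphical genotypes (lines x markers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code = {"A": 0, "H": 1, "B": 2, "-": np.nan}
    mat = table[line_names].map(code.get).to_numpy(dtype=float).T
    fig, ax = plt.subplots(figsize=(max(6, mat.shape[1] / 25), max(4, mat.shape[0] / 12)))
    cmap = ListedColormap(["#3b6fb6", "#8fce8f", "#c94f4f"])
    ax.imshow(mat, aspect="auto", interpolation="nearest", cmap=cmap, vmin=0, vmax=2)
    ax.set_xlabel("markers (map order)")
    ax.set_ylabel("F2 lines")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
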