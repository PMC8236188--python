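"""Text-table input/output: marker, anchor, map, block and JoinMap exports.

Every artifact is TSV with a header row and stable column order, so reruns
with the same seed are byte-identical.  Genotype vectors are encoded one
column per line with the single characters A (reference homozygote), H
(heterozygote), B (alternative homozygote) and ``-`` (missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anchoring import AnchorResult, AnchorStatus
from .calls import MaplinkError, chars_to_genotypes, genotypes_to_chars
from .linkage import GeneticMap, LinkageGroup, MappingFunction
from .markers import MarkerClass, UnigeneMarker

_MARKER_FIXED_COLS = ["unigene_id", "marker_class", "n_sites", "support"]
_ANCHOR_COLS = ["unigene_id", "chromosome", "status", "representative_site", "n_sites_used"]


def write_marker_table(markers, path: str, line_names: list[str] | None = None) -> None:
    """Write UnigeneMarkers or AnchorResults as a TSV (dispatch on type)."""
    markers = list(markers)
    if not markers:
        raise MaplinkError("refusing to write an empty marker table")
    if isinstance(markers[0], AnchorResult):
        _write_anchor_table(markers, path)
    else:
        _write_unigene_markers(markers, path, line_names)


def _write_unigene_markers(markers: list[UnigeneMarker], path: str,
                           line_names: list[str] | None) -> None:
    n_lines = len(markers[0].genotype_vector)
    line_names = line_names or [f"F2_{i + 1:03d}" for i in range(n_lines)]
    if len(line_names) != n_lines:
        raise MaplinkError("line_names length must match genotype vectors")
    rows = []
    for m in markers:
        row = {"unigene_id": m.unigene_id, "marker_class": m.marker_class.value,
               "n_sites": m.n_sites, "support": m.support}
        row.update(dict(zip(line_names, genotypes_to_chars(m.genotype_vector))))
        rows.append(row)
    pd.DataFrame(rows, columns=_MARKER_FIXED_COLS + line_names).to_csv(
        path, sep="\t", index=False)


def read_marker_table(path: str) -> tuple[list[UnigeneMarker], list[str]]:
    """Inverse of :func:`write_marker_table` for UnigeneMarker tables."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    line_names = [c for c in df.columns if c not in _MARKER_FIXED_COLS]
    markers = []
    for _, row in df.iterrows():
        vec = chars_to_genotypes([row[c] for c in line_names])
        markers.append(UnigeneMarker(
            unigene_id=row["unigene_id"],
            marker_class=MarkerClass(row["marker_class"]),
            genotype_vector=vec,
            n_sites=int(row["n_sites"]),
            support=int(row["support"]),
        ))
    return markers, line_names


def _write_anchor_table(anchors: list[AnchorResult], path: str) -> None:
    rows = [{"unigene_id": a.unigene_id,
             "chromosome": a.chromosome if a.chromosome is not None else 0,
             "status": a.status.value,
             "representative_site": a.representative_site if a.representative_site else 0,
             "n_sites_used": a.n_sites_used} for a in anchors]
    pd.DataFrame(rows, columns=_ANCHOR_COLS).to_csv(path, sep="\t", index=False)


def read_anchor_table(path: str) -> list[AnchorResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        chrom = int(row["chromosome"]) or None
        rep = int(row["representative_site"]) or None
        out.append(AnchorResult(str(row["unigene_id"]), chrom,
                                AnchorStatus(row["status"]), rep, int(row["n_sites_used"])))
    return out


# ---------------------------------------------------------------------------
# map exports


def write_map_tsv(gmap: GeneticMap, path: str) -> None:
    gmap.marker_positions().to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str) -> GeneticMap:
    """Rebuild a GeneticMap from its TSV export (adjacent r not recoverable
    from positions alone; adjacent_r is left empty)."""
    df = pd.read_csv(path, sep="\t")
    groups = []
    for _, sub in df.groupby("linkage_group", sort=True):
        sub = sub.sort_values("position_cM", kind="mergesort")
        chrom = int(sub["chromosome"].iloc[0]) or None
        groups.append(LinkageGroup(markers=[str(m) for m in sub["marker"]],
                                   adjacent_r=[],
                                   positions_cM=[float(p) for p in sub["position_cM"]],
                                   chromosome=chrom))
    return GeneticMap(groups, MappingFunction.KOSAMBI)


_JOINMAP_CODE = {0: "a", 1: "h", 2: "b", -1: "-"}


def write_joinmap(gmap: GeneticMap, vectors: dict[str, np.ndarray],
                  prefix: str, population_name: str = "maplink_pop") -> None:
    """JoinMap-style text export: ``<prefix>.loc`` (F2 locus file, codes
    a/h/b) and ``<prefix>.map`` (group/position list) for interoperability."""
    mapped = [m for g in gmap.groups for m in g.markers]
    missing = [m for m in mapped if m not in vectors]
    if missing:
        raise MaplinkError(f"no genotype vector for mapped marker(s) {missing[:3]}")
    n_ind = len(vectors[mapped[0]]) if mapped else 0
    with open(f"{prefix}.loc", "w") as fh:
        fh.write(f"name = {population_name}\npopt = F2\n"
                 f"nloc = {len(mapped)}\nnind = {n_ind}\n\n")
        for m in mapped:
            codes = " ".join(_JOINMAP_CODE[int(v)] for v in vectors[m])
            fh.write(f"{m}\n {codes}\n")
    with open(f"{prefix}.map", "w") as fh:
        for gi, g in enumerate(gmap.groups):
            fh.write(f"group {gi + 1}\n")
            for m, p in zip(g.markers, g.positions_cM):
                fh.write(f"{m} {p:.3f}\n")


def write_block_table(blocks, path: str) -> None:
    rows = [{"block_id": b.block_id, "linkage_group": b.group_index + 1,
             "span_start_cM": round(b.span_cM[0], 4), "span_end_cM": round(b.span_cM[1], 4),
             "n_core": len(b.core_members), "n_allocated": len(b.allocated_members),
             "core_members": ",".join(b.core_members)} for b in blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
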