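"""End-to-end pipeline: panels in, anchor/marker/map/block artifacts out.

The configuration (a plain dict, loadable from YAML) either names the two
input VCFs with their sample roles or carries a ``simulate`` block; the
stages then run in order — anchor the MAL panel, build F2 markers, map the
solid markers, cut genotype blocks and allocate the O/R markers — writing
every intermediate artifact plus a summary whose count matrices have the
same shape as the study's printed tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .anchoring import anchor_all
from .blocks import allocate_all, build_blocks, graphical_genotype_table
from .calls import CallMatrix, Call, ConfigError, MaplinkError, PanelKind, Thresholds
from .linkage import (
    GeneticMap,
    MappingFunction,
    assign_chromosomes,
    build_map,
    group_markers,
    order_markers,
    pairwise_estimates,
)
from .markers import MarkerClass, build_markers
from .tables import (
    write_block_table,
    write_joinmap,
    write_map_tsv,
    write_marker_table,
)
from .vcfio import read_genotype_vcf, write_genotype_vcf


class PipelineStageError(MaplinkError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    out_dir: Path
    anchors_path: Path
    markers_path: Path
    map_path: Path
    blocks_path: Path
    graphical_path: Path
    summary: dict
    genetic_map: GeneticMap


def _thresholds_from(config: dict) -> Thresholds:
    return Thresholds(**config.get("thresholds", {}))


def _load_panels(config: dict, seed: int):
    """Return (mal_panel, f2_panel, truth) from VCF inputs or simulation."""
    if "simulate" in config:
        s = dict(config["simulate"])
        em_f2 = sim.ErrorModel(**s.get("error_model", {}))
        mal_em_args = {"mean_depth": 30.0, **s.get("mal_error_model", {})}
        em_mal = sim.ErrorModel(**mal_em_args)
        true_map = sim.simulate_true_map(
            n_unigenes=s.get("n_unigenes", 800),
            total_cM=s.get("total_cM", sim.DEFAULT_TOTAL_CM),
            seed=seed,
        )
        geno = sim.simulate_f2_genotypes(true_map, s.get("n_lines", sim.DEFAULT_N_LINES),
                                         seed=seed + 1)
        f2_panel = sim.simulate_read_calls(geno, true_map, em_f2, seed=seed + 2)
        mal_panel = sim.simulate_mal_panel(true_map, em_mal, seed=seed + 3)
        return mal_panel, f2_panel, (true_map, geno)
    inputs = config.get("inputs")
    if not inputs or "mal_vcf" not in inputs or "f2_vcf" not in inputs:
        raise ConfigError("config needs either a 'simulate' block or "
                          "'inputs' with mal_vcf and f2_vcf")
    mal_panel = read_genotype_vcf(inputs["mal_vcf"], inputs["mal_roles"], PanelKind.MAL)
    f2_panel = read_genotype_vcf(inputs["f2_vcf"], inputs["f2_roles"], PanelKind.F2)
    return mal_panel, f2_panel, None


def map_from_markers(
    solid_markers,
    anchors: dict[str, int],
    thresholds: Thresholds,
    mapping_function: MappingFunction = MappingFunction.KOSAMBI,
):
    """Group, order and measure the solid markers; label groups from anchors.

    Returns (GeneticMap, chromosome report, singleton marker ids).
    """
    ids = [m.unigene_id for m in solid_markers]
    geno = np.vstack([m.genotype_vector for m in solid_markers])
    r, lod = pairwise_estimates(geno)
    groups, singleton_idx = group_markers(lod, ids, thresholds.lod_threshold)
    ordered = [order_markers(g, r, ids) for g in groups]
    gmap = build_map(ordered, r, ids, mapping_function)
    chrom_report = assign_chromosomes(gmap, anchors)
    return gmap, chrom_report, [ids[i] for i in singleton_idx]


def run_pipeline(config: dict, out_dir: str, seed: int = 0) -> PipelineResult:
    """Execute every stage, writing artifacts under ``out_dir``.

    Deterministic: the same config and seed produce byte-identical tables.
    Any stage error aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = _thresholds_from(config)
    mapping_function = MappingFunction(config.get("mapping_function", "kosambi"))

    stage = "load"
    try:
        mal_panel, f2_panel, truth = _load_panels(config, seed)
        if truth is not None and config.get("write_vcfs", False):
            write_genotype_vcf(mal_panel, str(out / "mal_panel.vcf"))
            write_genotype_vcf(f2_panel, str(out / "f2_panel.vcf"))
            sim.write_truth_table(truth[0], truth[1], str(out / "truth.tsv"))

        stage = "anchor"
        anchor_results, anchor_summary, anchor_drops = anchor_all(mal_panel, thresholds)
        anchors_path = out / "anchors.tsv"
        write_marker_table(anchor_results, str(anchors_path))
        anchor_summary.to_csv(out / "anchor_summary.tsv", sep="\t")

        stage = "build-markers"
        markers, marker_summary, marker_drops = build_markers(f2_panel, thresholds)
        line_names = [f2_panel.samples[i] for i in f2_panel.f2_indices]
        markers_path = out / "markers.tsv"
        write_marker_table(markers, str(markers_path), line_names)

        stage = "map"
        anchors = {a.unigene_id: a.chromosome for a in anchor_results
                   if a.chromosome is not None}
        solid = [m for m in markers if m.marker_class is MarkerClass.S]
        if len(solid) < 2:
            raise MaplinkError("fewer than two solid markers; cannot map")
        gmap, chrom_report, singletons = map_from_markers(
            solid, anchors, thresholds, mapping_function)
        map_path = out / "map.tsv"
        write_map_tsv(gmap, str(map_path))
        vectors = {m.unigene_id: m.genotype_vector for m in markers}
        write_joinmap(gmap, vectors, str(out / "map_joinmap"))
        chrom_report.to_csv(out / "chromosome_report.tsv", sep="\t", index=False)

        stage = "blocks"
        blocks = build_blocks(gmap, vectors)
        allocations = allocate_all(markers, blocks, thresholds.max_block_mismatch)
        blocks_path = out / "blocks.tsv"
        write_block_table(blocks, str(blocks_path))
        gg = graphical_genotype_table(gmap, blocks, vectors, line_names)
        graphical_path = out / "graphical_genotypes.tsv"
        gg.to_csv(graphical_path, sep="\t", index=False)

        stage = "summary"
        class_by_chrom = _class_by_chromosome(markers, blocks, gmap, allocations)
        n_allocated = sum(1 for a in allocations if a.block_id is not None)
        summary = {
            "seed": seed,
            "anchor": {
                "drop_reasons": dict(anchor_drops),
                "status_by_chromosome": {r: anchor_summary.loc[r].to_dict()
                                         for r in anchor_summary.index},
            },
            "markers": {**marker_summary, "drop_reasons": dict(marker_drops)},
            "map": {
                "n_groups": len(gmap.groups),
                "n_mapped_markers": gmap.n_markers,
                "n_singletons": len(singletons),
                "total_cM": round(gmap.total_cM, 2),
                "mean_interval_cM": round(gmap.mean_interval_cM, 4),
            },
            "blocks": {
                "n_blocks": len(blocks),
                "n_allocated": n_allocated,
                "n_unallocated": len(allocations) - n_allocated,
                "graphical_rows": int(len(gg)),
            },
            "class_by_chromosome": class_by_chrom,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception as exc:
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    return PipelineResult(out, anchors_path, markers_path, map_path, blocks_path,
                          graphical_path, summary, gmap)


def _class_by_chromosome(markers, blocks, gmap, allocations) -> dict:
    """S/R/O x chromosome count matrix (shape of the study's marker table):
    S markers count on their linkage group's chromosome; O/R markers on the
    chromosome of the block they were allocated to."""
    chrom_of_block = {b.block_id: (gmap.groups[b.group_index].chromosome or 0)
                      for b in blocks}
    chrom_of_marker = {}
    for g in gmap.groups:
        for m in g.markers:
            chrom_of_marker[m] = g.chromosome or 0
    for a in allocations:
        if a.block_id is not None:
            chrom_of_marker[a.marker_id] = chrom_of_block[a.block_id]
    table: dict[str, dict[str, int]] = {k: {f"chr{c}": 0 for c in range(1, 9)}
                                        for k in ("S", "R", "O")}
    for m in markers:
        chrom = chrom_of_marker.get(m.unigene_id, 0)
        if chrom:
            table[m.marker_class.value][f"chr{chrom}"] += 1
    for k in table:
        table[k]["Total"] = sum(table[k].values())
    return table
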