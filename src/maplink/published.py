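"""Published per-chromosome marker counts from the onion transcriptome
mapping study, used as reference inputs for summary arithmetic.

Two count matrices are transcribed from the study's printed tables: the
MAL-anchoring accounting (unigenes with SNPs detected on the eight monosomic
addition lines, split by how they were assigned) and the per-chromosome F2
marker-class accounting (S/R/O).  Only the per-chromosome body entries are
stored; totals are recomputed, never transcribed, so the arithmetic checks
actually check something.
"""

from __future__ import annotations

import pandas as pd

_CHR_COLS = [f"chr{c}" for c in range(1, 9)]

#: unigenes anchored via the MAL panel, by assignment route and chromosome
MAL_ANCHOR_COUNTS = pd.DataFrame(
    {
        "multi_single_chromosome": [3404, 3900, 3148, 2538, 2588, 2546, 2032, 1840],
        "representative_snp":      [30,   35,   33,   21,   16,   16,   18,   19],
        "one_snp":                 [486,  578,  455,  397,  357,  376,  319,  310],
    },
    index=_CHR_COLS,
).T

#: F2 markers by consolidation class and chromosome
F2_MARKER_COUNTS = pd.DataFrame(
    {
        "S": [270, 126, 200, 170, 199, 198, 170, 102],
        "R": [175, 416, 195, 163, 148, 123, 110, 96],
        "O": [239, 278, 229, 192, 135, 186, 148, 130],
    },
    index=_CHR_COLS,
).T

#: headline map figures printed by the study
PUBLISHED_MAP_TOTAL_CM = 936.6
PUBLISHED_N_SNP_MARKERS = 1435     # solid unigene markers on the map
PUBLISHED_N_PCR_MARKERS = 14       # SSR/InDel markers integrated on the map
PUBLISHED_N_LINKAGE_GROUPS = 8
PUBLISHED_N_BLOCKS = 610


def anchor_row_totals() -> pd.Series:
    """Per-route totals of the anchoring table (sum over chromosomes)."""
    return MAL_ANCHOR_COUNTS.sum(axis=1)


def anchor_grand_total() -> int:
    """Total anchored unigenes, from the 24 per-chromosome entries."""
    return int(MAL_ANCHOR_COUNTS.to_numpy().sum())


def anchor_column_totals() -> pd.Series:
    """Per-chromosome totals of the anchoring table."""
    return MAL_ANCHOR_COUNTS.sum(axis=0)


def marker_class_totals() -> pd.Series:
    """Per-class totals (S, R, O) of the marker table."""
    return F2_MARKER_COUNTS.sum(axis=1)


def marker_grand_total() -> int:
    return int(F2_MARKER_COUNTS.to_numpy().sum())


def mean_marker_interval_cM() -> float:
    """Mean interval of the published map: total length over the number of
    adjacent intervals (markers minus one per linkage group)."""
    n_markers = PUBLISHED_N_SNP_MARKERS + PUBLISHED_N_PCR_MARKERS
    n_intervals = n_markers - PUBLISHED_N_LINKAGE_GROUPS
    return PUBLISHED_MAP_TOTAL_CM / n_intervals
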