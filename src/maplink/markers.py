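"""F2 marker construction: site filtering and per-unigene S/O/R consolidation.

RNA-seq genotype calls give several SNP sites per unigene, but sites on the
same unigene are perfectly linked and should segregate identically; observed
disagreement is genotyping error (dominantly a homozygous call at a truly
heterozygous site, from low depth or allele-biased expression).  Sites are
therefore consolidated into a single marker per unigene:

S (solid)
    at least two sites share one identical genotype pattern across the lines;
    that shared pattern is taken as the unigene genotype.
O (one)
    the unigene has a single usable site.
R (representative)
    multiple sites, all pairwise distinct; the per-line modal call across
    sites is taken, so majority voting suppresses independent site errors.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .calls import (
    Call,
    CallMatrix,
    ConfigError,
    MaplinkError,
    PanelKind,
    ROLE_PARENT_ALT,
    ROLE_PARENT_REF,
    Thresholds,
)


class MarkerClass(str, enum.Enum):
    S = "S"
    O = "O"
    R = "R"


@dataclass(frozen=True)
class UnigeneMarker:
    """Consolidated co-dominant genotype of one unigene across the F2 lines."""

    unigene_id: str
    marker_class: MarkerClass
    genotype_vector: np.ndarray   # int8 over F2 lines, A/H/B (MISSING only from A-vs-B modal ties)
    n_sites: int
    support: int                  # for S: number of sites sharing the solid pattern, else n_sites
    flagged_lines: tuple = ()     # line indices where an R modal vote tied A vs B

    def __post_init__(self) -> None:
        if (self.marker_class is MarkerClass.O) != (self.n_sites == 1):
            raise MaplinkError("class O iff exactly one site")
        if self.marker_class is MarkerClass.S and self.support < 2:
            raise MaplinkError("class S requires support >= 2")


@dataclass(frozen=True)
class RetainedSite:
    unigene_id: str
    position: int
    f2_calls: np.ndarray   # int8 over F2 lines, no MISSING (depth filter guarantees calls)


def filter_f2_sites(
    panel: CallMatrix, thresholds: Thresholds | None = None
) -> tuple[list[RetainedSite], Counter]:
    """Select co-dominant, well-covered F2 sites; count drops by reason.

    Retention requires, in order: (a) the parental pattern DHA REF_HOM and
    DHC ALT_HOM (the site is a true interparental SNP), (b) read depth >=
    ``f2_min_depth`` in every F2 line, and (c) co-dominance — at least one
    heterozygous call among the F2 lines.
    """
    thresholds = thresholds or Thresholds()
    if panel.panel_kind is not PanelKind.F2:
        raise ConfigError("filter_f2_sites requires an F2 panel")
    i_ref = panel.sample_index(ROLE_PARENT_REF)
    i_alt = panel.sample_index(ROLE_PARENT_ALT)
    f2 = panel.f2_indices

    retained: list[RetainedSite] = []
    dropped: Counter = Counter()
    parental_ok = (panel.calls[:, i_ref] == Call.REF_HOM) & (panel.calls[:, i_alt] == Call.ALT_HOM)
    depth_ok = (panel.depths[:, f2] >= thresholds.f2_min_depth).all(axis=1)
    has_het = (panel.calls[:, f2] == Call.HET).any(axis=1)
    for i in range(panel.n_sites):
        if not parental_ok[i]:
            dropped["parental_pattern"] += 1
        elif not depth_ok[i]:
            dropped["depth"] += 1
        elif not has_het[i]:
            dropped["co_dominance"] += 1
        else:
            calls = panel.calls[i, f2].copy()
            if (calls == Call.MISSING).any():
                # cannot happen with a caller that reports a GT wherever DP>0
                dropped["missing_call"] += 1
                continue
            retained.append(RetainedSite(str(panel.sites.at[i, "unigene"]),
                                         int(panel.sites.at[i, "position"]), calls))
    return retained, dropped


def _pick_solid_pattern(keys: list[bytes], counts: Counter, positions: dict[bytes, int]):
    """Tie-breaking for the solid pattern: multiplicity, then heterozygote
    count, then smallest first-supporting-site position."""
    best = max(
        counts,
        key=lambda k: (
            counts[k],
            np.count_nonzero(np.frombuffer(k, dtype=np.int8) == Call.HET),
            -positions[k],
        ),
    )
    return best


def consolidate_unigene(
    unigene_id: str,
    sites: list[RetainedSite],
    strict_solid: bool = False,
) -> UnigeneMarker:
    """Collapse the retained sites of one unigene into a single marker.

    ``strict_solid=False`` (default) classifies a unigene as S whenever some
    pattern is shared by >= 2 sites, even if other sites disagree; with
    ``strict_solid=True`` S additionally requires *all* sites identical, and
    mixed cases fall through to R.

    R vectors take the per-line modal call; a tie involving HET resolves to
    HET (the dominant error is a heterozygote collapsing to a homozygote, so
    an observed H outvotes equal homozygote evidence), while an A-vs-B tie
    with no H carries no usable information and is emitted as MISSING with
    the line flagged.
    """
    if not sites:
        raise MaplinkError(f"no retained sites for unigene {unigene_id}")
    vectors = np.vstack([s.f2_calls for s in sites]).astype(np.int8)
    if len(sites) == 1:
        return UnigeneMarker(unigene_id, MarkerClass.O, vectors[0], 1, 1)

    keys = [v.tobytes() for v in vectors]
    counts = Counter(keys)
    first_pos: dict[bytes, int] = {}
    for s, k in zip(sites, keys):
        first_pos.setdefault(k, s.position)
    max_mult = max(counts.values())
    solid_ok = max_mult >= 2 and (not strict_solid or max_mult == len(sites))
    if solid_ok:
        best = _pick_solid_pattern(keys, counts, first_pos)
        return UnigeneMarker(unigene_id, MarkerClass.S,
                             np.frombuffer(best, dtype=np.int8).copy(),
                             len(sites), counts[best])

    # representative: per-line majority vote across sites
    n_lines = vectors.shape[1]
    votes = np.zeros((3, n_lines), dtype=np.int64)
    for g in (Call.REF_HOM, Call.HET, Call.ALT_HOM):
        votes[int(g)] = (vectors == g).sum(axis=0)
    out = np.empty(n_lines, dtype=np.int8)
    flagged = []
    for j in range(n_lines):
        top = votes[:, j].max()
        winners = set(np.flatnonzero(votes[:, j] == top).tolist())
        if len(winners) == 1:
            out[j] = winners.pop()
        elif int(Call.HET) in winners:
            out[j] = Call.HET
        else:  # A vs B tie, no heterozygote evidence
            out[j] = Call.MISSING
            flagged.append(j)
    return UnigeneMarker(unigene_id, MarkerClass.R, out, len(sites), len(sites),
                         tuple(flagged))


def build_markers(
    panel: CallMatrix,
    thresholds: Thresholds | None = None,
    strict_solid: bool = False,
) -> tuple[list[UnigeneMarker], dict, Counter]:
    """Filter an F2 panel and consolidate one marker per retained unigene.

    The summary dict reports retained sites/unigenes, the one-SNP vs
    multi-SNP split and per-class counts; #S + #R = #multi-SNP unigenes and
    #S + #O + #R = #markers by construction.
    """
    retained, dropped = filter_f2_sites(panel, thresholds)
    by_unigene: dict[str, list[RetainedSite]] = {}
    for s in retained:
        by_unigene.setdefault(s.unigene_id, []).append(s)
    markers = [consolidate_unigene(u, sites, strict_solid=strict_solid)
               for u, sites in by_unigene.items()]
    class_counts = Counter(m.marker_class for m in markers)
    summary = {
        "retained_sites": len(retained),
        "retained_unigenes": len(markers),
        "one_snp_unigenes": class_counts[MarkerClass.O],
        "multi_snp_unigenes": len(markers) - class_counts[MarkerClass.O],
        "S": class_counts[MarkerClass.S],
        "O": class_counts[MarkerClass.O],
        "R": class_counts[MarkerClass.R],
    }
    return markers, summary, dropped
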