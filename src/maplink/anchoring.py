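"""Chromosome anchoring of unigenes from a monosomic-addition-line (MAL) panel.

Each of the eight MALs carries the full bunching-onion chromosome set plus a
single extra shallot chromosome.  A unigene residing on shallot chromosome *c*
is therefore heterozygous in MAL *c* and homozygous for the bunching-onion
allele in the other seven.  Anchoring reads that signature off the MAL panel:
sites are first filtered (all eight MAL depths at or above a cutoff, and the
expected parental pattern — bunching onion ALT_HOM, DHA REF_HOM), each
retained site is classified *clean(c)* (exactly one heterozygous MAL) or
*ambiguous*, and the unigene's sites are then combined into one assignment
with a status recording how direct the evidence was.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import (
    Call,
    CallMatrix,
    ConfigError,
    MaplinkError,
    N_CHROMOSOMES,
    PanelKind,
    ROLE_PARENT_ALT,
    ROLE_PARENT_REF,
    Thresholds,
)


class AnchorStatus(str, enum.Enum):
    ONE_SNP = "ONE_SNP"                    # single usable site, clean
    MULTI_CONSISTENT = "MULTI_CONSISTENT"  # several sites, all clean, same chromosome
    REPRESENTATIVE = "REPRESENTATIVE"      # ambiguity present, resolved by a clean site
    UNASSIGNED = "UNASSIGNED"              # no clean evidence, or conflicting clean sites


@dataclass(frozen=True)
class SitePattern:
    """Per-site MAL signature after filtering."""

    unigene_id: str
    position: int
    het_mals: frozenset       # chromosomes (1..8) whose MAL is heterozygous
    parental_ok: bool
    depth_ok: bool
    has_missing: bool         # a MAL call MISSING despite passing the depth filter
    min_mal_depth: int


@dataclass(frozen=True)
class AnchorResult:
    unigene_id: str
    chromosome: int | None
    status: AnchorStatus
    representative_site: int | None   # position of the site that resolved ambiguity
    n_sites_used: int
    n_ambiguous_sites: int = 0        # debug: ambiguous sites seen in the unigene

    def __post_init__(self) -> None:
        if (self.chromosome is None) != (self.status is AnchorStatus.UNASSIGNED):
            raise MaplinkError("chromosome must be unset iff status is UNASSIGNED")


def filter_mal_sites(
    panel: CallMatrix, thresholds: Thresholds | None = None
) -> tuple[list[SitePattern], Counter]:
    """Retain sites usable for anchoring; count dropped sites by reason.

    A site is kept iff every MAL depth is >= ``mal_min_depth`` *and* the
    parental calls show the interspecific SNP (bunching onion ALT_HOM, DHA
    REF_HOM).  Each dropped site is counted under exactly one reason, depth
    being checked first.
    """
    thresholds = thresholds or Thresholds()
    if panel.panel_kind is not PanelKind.MAL:
        raise ConfigError("filter_mal_sites requires a MAL panel")
    i_ref = panel.sample_index(ROLE_PARENT_REF)
    i_alt = panel.sample_index(ROLE_PARENT_ALT)
    mal_idx = panel.mal_indices

    retained: list[SitePattern] = []
    dropped: Counter = Counter()
    mal_depths = panel.depths[:, mal_idx]
    mal_calls = panel.calls[:, mal_idx]
    depth_ok = (mal_depths >= thresholds.mal_min_depth).all(axis=1)
    parental_ok = (panel.calls[:, i_alt] == Call.ALT_HOM) & (panel.calls[:, i_ref] == Call.REF_HOM)
    for i in range(panel.n_sites):
        if not depth_ok[i]:
            dropped["depth"] += 1
            continue
        if not parental_ok[i]:
            dropped["parental_pattern"] += 1
            continue
        calls = mal_calls[i]
        retained.append(
            SitePattern(
                unigene_id=str(panel.sites.at[i, "unigene"]),
                position=int(panel.sites.at[i, "position"]),
                het_mals=frozenset(int(c + 1) for c in np.flatnonzero(calls == Call.HET)),
                parental_ok=True,
                depth_ok=True,
                has_missing=bool((calls == Call.MISSING).any()),
                min_mal_depth=int(mal_depths[i].min()),
            )
        )
    return retained, dropped


def classify_site(pattern: SitePattern) -> int | None:
    """Chromosome 1..8 if the site is clean, else None (ambiguous).

    Clean means exactly one MAL is heterozygous and no MAL call is missing;
    zero or multiple heterozygous MALs (downregulation, partial homology of
    the shallot gene) give no usable evidence.
    """
    if pattern.has_missing or len(pattern.het_mals) != 1:
        return None
    return next(iter(pattern.het_mals))


def anchor_unigene(unigene_id: str, patterns: list[SitePattern]) -> AnchorResult:
    """Combine the retained sites of one unigene into a chromosome assignment.

    Rules: a single clean site anchors directly (ONE_SNP); multiple sites all
    clean and agreeing anchor with corroboration (MULTI_CONSISTENT); a mixture
    of ambiguous and clean sites anchors through a representative clean site
    (REPRESENTATIVE) — chosen as the clean site with the highest minimum MAL
    depth, ties broken by smallest position; no clean site, or clean sites
    pointing at different chromosomes, leaves the unigene UNASSIGNED.
    """
    if not patterns:
        raise MaplinkError(f"no retained sites for unigene {unigene_id}")
    clean = [(p, classify_site(p)) for p in patterns]
    clean_sites = [(p, c) for p, c in clean if c is not None]
    n_ambiguous = len(patterns) - len(clean_sites)
    chroms = {c for _, c in clean_sites}

    if not clean_sites or len(chroms) > 1:
        return AnchorResult(unigene_id, None, AnchorStatus.UNASSIGNED, None,
                            len(patterns), n_ambiguous)
    chrom = chroms.pop()
    if len(patterns) == 1:
        return AnchorResult(unigene_id, chrom, AnchorStatus.ONE_SNP, None, 1, 0)
    if n_ambiguous == 0:
        return AnchorResult(unigene_id, chrom, AnchorStatus.MULTI_CONSISTENT, None,
                            len(patterns), 0)
    rep = min(clean_sites, key=lambda pc: (-pc[0].min_mal_depth, pc[0].position))[0]
    return AnchorResult(unigene_id, chrom, AnchorStatus.REPRESENTATIVE, rep.position,
                        len(patterns), n_ambiguous)


#: summary row order mirrors the published anchoring table
_SUMMARY_ROWS = [AnchorStatus.MULTI_CONSISTENT, AnchorStatus.REPRESENTATIVE,
                 AnchorStatus.ONE_SNP]


def summarize_anchors(results: list[AnchorResult]) -> pd.DataFrame:
    """Status x chromosome count matrix with Total row/column.

    Assigned statuses are cross-tabulated against chromosomes 1..8; the
    UNASSIGNED row carries only a total (those unigenes have no chromosome).
    """
    cols = [f"chr{c}" for c in range(1, N_CHROMOSOMES + 1)]
    table = pd.DataFrame(0, index=[s.value for s in _SUMMARY_ROWS], columns=cols, dtype=int)
    unassigned = 0
    for r in results:
        if r.status is AnchorStatus.UNASSIGNED:
            unassigned += 1
        else:
            table.loc[r.status.value, f"chr{r.chromosome}"] += 1
    table["Total"] = table.sum(axis=1)
    total = table.sum(axis=0).to_frame().T
    total.index = ["Total_assigned"]
    table = pd.concat([table, total])
    table.loc["UNASSIGNED"] = 0
    table.loc["UNASSIGNED", "Total"] = unassigned
    return table


def anchor_all(
    panel: CallMatrix, thresholds: Thresholds | None = None
) -> tuple[list[AnchorResult], pd.DataFrame, Counter]:
    """Anchor every unigene with at least one retained site.

    Returns the per-unigene results, the status x chromosome summary matrix,
    and the site drop-reason counts from filtering.
    """
    retained, dropped = filter_mal_sites(panel, thresholds)
    by_unigene: dict[str, list[SitePattern]] = {}
    for p in retained:
        by_unigene.setdefault(p.unigene_id, []).append(p)
    results = [anchor_unigene(u, pats) for u, pats in by_unigene.items()]
    return results, summarize_anchors(results), dropped
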