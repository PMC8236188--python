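"""De-novo F2 linkage mapping from co-dominant marker genotypes.

Both parents are doubled haploids, so every marker pair is in coupling phase
and the two-locus genotype distribution of an F2 line is the convolution of
two independent gametes with recombination fraction r.  The recombination
fraction of each pair is estimated by maximum likelihood (an EM iteration on
the expected number of recombinant gametes; the only latent class is the
double heterozygote, which mixes parental/parental with recombinant/
recombinant gametes).  Markers are grouped by transitive closure over pairs
whose linkage LOD — log10 L(r_hat)/L(0.5) — reaches a cutoff, ordered within
each group by minimizing the sum of adjacent recombination fractions (greedy
chain extension refined by 2-opt), and adjacent fractions are converted to
additive centimorgan distances with the Kosambi (default) or Haldane mapping
function.  Linkage groups inherit physical chromosome labels from member
markers anchored via the MAL panel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .calls import Call, MaplinkError

# ---------------------------------------------------------------------------
# mapping functions


class MappingFunction(str, enum.Enum):
    KOSAMBI = "kosambi"
    HALDANE = "haldane"


def kosambi_cM(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM, for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise MaplinkError("Kosambi distance requires 0 <= r < 0.5")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def inverse_kosambi(d):
    """Recombination fraction r = tanh(2d/100)/2 for a Kosambi distance d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise MaplinkError("map distance must be non-negative")
    out = 0.5 * np.tanh(2 * d / 100.0)
    return float(out) if out.ndim == 0 else out


def haldane_cM(r):
    """Haldane map distance d = -50 ln(1-2r) in cM, for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise MaplinkError("Haldane distance requires 0 <= r < 0.5")
    out = -50.0 * np.log(1 - 2 * r)
    return float(out) if out.ndim == 0 else out


def inverse_haldane(d):
    """Recombination fraction r = (1 - exp(-2d/100))/2 for a Haldane distance d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise MaplinkError("map distance must be non-negative")
    out = 0.5 * (1.0 - np.exp(-2 * d / 100.0))
    return float(out) if out.ndim == 0 else out


MAP_FUNCS = {MappingFunction.KOSAMBI: (kosambi_cM, inverse_kosambi),
             MappingFunction.HALDANE: (haldane_cM, inverse_haldane)}


# ---------------------------------------------------------------------------
# two-locus F2 likelihood (coupling phase)


def f2_joint_class_probs(r: float) -> np.ndarray:
    """3x3 joint probability table over (A,H,B) x (A,H,B) for two linked loci.

    Built from the gamete distribution: parental haplotypes each (1-r)/2,
    recombinant haplotypes each r/2; an F2 line is the union of two
    independent gametes.  Index 0=A (REF_HOM), 1=H, 2=B (ALT_HOM).
    """
    if not 0 <= r <= 0.5:
        raise MaplinkError("recombination fraction must lie in [0, 0.5]")
    # gamete haplotype probabilities over (allele at locus 1, allele at locus 2),
    # alleles coded 0 (DHA) / 1 (DHC)
    hap = np.array([[(1 - r) / 2, r / 2], [r / 2, (1 - r) / 2]])
    table = np.zeros((3, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            for b1 in (0, 1):
                for b2 in (0, 1):
                    table[a1 + b1, a2 + b2] += hap[a1, a2] * hap[b1, b2]
    return table


# expected recombinant gametes contributed by each observed two-locus class;
# the double heterozygote (None) is latent: 0 or 2 with posterior weight
_FIXED_REC = np.array([[0, 1, 2],
                       [1, 0, 1],   # [1,1] entry handled separately
                       [2, 1, 0]], dtype=float)
_HH = (1, 1)


@dataclass(frozen=True)
class PairEstimate:
    r_hat: float
    lod: float
    n_informative: int
    low_confidence: bool = False


def pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 two-locus class counts over lines where both calls are non-missing."""
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape:
        raise MaplinkError("genotype vectors must have equal length")
    ok = (g1 != Call.MISSING) & (g2 != Call.MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1[ok], g2[ok]), 1)
    return counts


def em_recombination(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 2000) -> np.ndarray:
    """ML recombination fraction(s) by EM from 3x3 class counts.

    ``counts`` may be one 3x3 table or a stack (..., 3, 3); returns a scalar
    or an array of the leading shape.  Each line contributes two gametes whose
    recombinant status is determined by its class except for the double
    heterozygote; EM imputes that class with posterior r^2/(r^2+(1-r)^2) of
    being doubly recombinant.  The update is clipped to [0, 0.5] (repulsion-
    leaning data have their ML at the 0.5 boundary).
    """
    counts = np.asarray(counts, dtype=float)
    flat = counts.reshape(-1, 3, 3)
    n_gametes = 2.0 * flat.sum(axis=(1, 2))
    fixed = (flat * _FIXED_REC).sum(axis=(1, 2))
    n_hh = flat[:, _HH[0], _HH[1]]
    r = np.full(flat.shape[0], 0.25)
    empty = n_gametes == 0
    for _ in range(max_iter):
        denom = r**2 + (1 - r) ** 2
        post2 = np.divide(2.0 * r**2, denom, out=np.zeros_like(r), where=denom > 0)
        r_new = np.divide(fixed + n_hh * post2, n_gametes,
                          out=np.full_like(r, 0.5), where=~empty)
        r_new = np.clip(r_new, 0.0, 0.5)
        if np.max(np.abs(r_new - r), initial=0.0) < tol:
            r = r_new
            break
        r = r_new
    return r.reshape(counts.shape[:-2]) if counts.ndim > 2 else float(r[0])


def _log10_lik(counts: np.ndarray, r: float) -> float:
    table = f2_joint_class_probs(r)
    with np.errstate(divide="ignore"):
        lt = np.log10(table)
    mask = counts > 0
    return float((counts[mask] * lt[mask]).sum())


def linkage_lod(counts: np.ndarray, r_hat: float) -> float:
    """LOD of linkage: log10 L(r_hat) - log10 L(0.5)."""
    return _log10_lik(counts, r_hat) - _log10_lik(counts, 0.5)


def estimate_r(g1: np.ndarray, g2: np.ndarray) -> PairEstimate:
    """ML recombination fraction and linkage LOD for one marker pair.

    Lines with a missing call in either marker are skipped; pairs with fewer
    than 10 informative lines are flagged low-confidence but still returned.
    """
    counts = pair_counts(g1, g2)
    n = int(counts.sum())
    r_hat = float(em_recombination(counts))
    lod = max(0.0, linkage_lod(counts, r_hat))
    return PairEstimate(r_hat, lod, n, low_confidence=n < 10)


def _class_prob_stack(r: np.ndarray) -> np.ndarray:
    """Closed-form joint class probabilities for an array of r values.

    Returns shape r.shape + (3, 3); agrees with the gamete-convolution table
    of :func:`f2_joint_class_probs` entry for entry.
    """
    r = np.asarray(r, dtype=float)
    aa = (1 - r) ** 2 / 4
    ab = r**2 / 4
    ah = r * (1 - r) / 2
    hh = ((1 - r) ** 2 + r**2) / 2
    out = np.empty(r.shape + (3, 3))
    out[..., 0, 0] = out[..., 2, 2] = aa
    out[..., 0, 2] = out[..., 2, 0] = ab
    out[..., 0, 1] = out[..., 1, 0] = out[..., 1, 2] = out[..., 2, 1] = ah
    out[..., 1, 1] = hh
    return out


def pairwise_estimates(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r_hat and LOD for a marker x line genotype matrix.

    Vectorized: two-locus class counts for every pair come from nine
    indicator-matrix products, and the EM update and LOD evaluation run on
    all pairs at once.  Returns symmetric (m, m) arrays (diagonal: r=0 and
    the LOD of a marker against itself).
    """
    g = np.asarray(genotypes, dtype=np.int8)
    ind = np.stack([(g == c).astype(np.float64) for c in (0, 1, 2)])  # (3, m, n)
    counts = np.einsum("aik,bjk->ijab", ind, ind)                     # (m, m, 3, 3)
    r = em_recombination(counts)
    with np.errstate(divide="ignore"):
        lt = np.log10(_class_prob_stack(r))
        lh = np.log10(_class_prob_stack(np.array(0.5)))
    diff = np.where(counts > 0, counts * (lt - lh), 0.0)
    lod = np.maximum(diff.sum(axis=(2, 3)), 0.0)
    return r, lod


# ---------------------------------------------------------------------------
# grouping and ordering


def group_markers(lod: np.ndarray, ids: list[str], lod_threshold: float = 5.0):
    """Partition markers into linkage groups: connected components of the
    graph with an edge wherever LOD >= threshold.  Returns (groups, singletons)
    as lists of index lists / indices; groups have size >= 2 and are sorted by
    size (desc) then smallest member id for determinism."""
    m = len(ids)
    graph = nx.Graph()
    graph.add_nodes_from(range(m))
    ii, jj = np.where(np.triu(lod, k=1) >= lod_threshold)
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(graph)]
    groups = [c for c in comps if len(c) >= 2]
    singletons = [c[0] for c in comps if len(c) == 1]
    groups.sort(key=lambda c: (-len(c), min(ids[i] for i in c)))
    return groups, sorted(singletons)


def _sarf(order: list[int], r: np.ndarray) -> float:
    return float(sum(r[order[k], order[k + 1]] for k in range(len(order) - 1)))


def order_markers(group: list[int], r: np.ndarray, ids: list[str]) -> list[int]:
    """Order one linkage group by minimizing the sum of adjacent recombination
    fractions: greedy chain extension from the tightest pair, then repeated
    2-opt segment reversals until no reversal improves.  The orientation is
    canonicalized so the terminal marker with the smaller id comes first."""
    if len(group) < 2:
        return list(group)
    sub = r[np.ix_(group, group)]
    m = len(group)

    # greedy seed: closest pair, then extend whichever end has the nearest marker
    iu = np.triu_indices(m, k=1)
    k = int(np.argmin(sub[iu]))
    chain = [int(iu[0][k]), int(iu[1][k])]
    remaining = set(range(m)) - set(chain)
    while remaining:
        rem = list(remaining)
        d_head = [sub[chain[0], x] for x in rem]
        d_tail = [sub[chain[-1], x] for x in rem]
        if min(d_head) < min(d_tail):
            x = rem[int(np.argmin(d_head))]
            chain.insert(0, x)
        else:
            x = rem[int(np.argmin(d_tail))]
            chain.append(x)
        remaining.discard(x)

    # 2-opt: reversing chain[i..j] only changes the two boundary adjacencies
    improved = True
    passes = 0
    while improved and passes < 200:
        improved = False
        passes += 1
        for i in range(m - 1):
            for j in range(i + 1, m):
                before = 0.0
                after = 0.0
                if i > 0:
                    before += sub[chain[i - 1], chain[i]]
                    after += sub[chain[i - 1], chain[j]]
                if j < m - 1:
                    before += sub[chain[j], chain[j + 1]]
                    after += sub[chain[i], chain[j + 1]]
                if after < before - 1e-12:
                    chain[i:j + 1] = chain[i:j + 1][::-1]
                    improved = True
    ordered = [group[i] for i in chain]
    if ids[ordered[-1]] < ids[ordered[0]]:
        ordered.reverse()
    return ordered


# ---------------------------------------------------------------------------
# map assembly


_R_CAP = 0.49
_R_NEAR_HALF = 0.5 - 1e-6


@dataclass
class LinkageGroup:
    markers: list[str]
    adjacent_r: list[float]
    positions_cM: list[float]
    chromosome: int | None = None
    conflicts: int = 0
    capped_intervals: list[int] = field(default_factory=list)

    @property
    def length_cM(self) -> float:
        return self.positions_cM[-1] if self.positions_cM else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    mapping_function: MappingFunction

    @property
    def total_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def mean_interval_cM(self) -> float:
        n_intervals = sum(len(g.markers) - 1 for g in self.groups)
        return self.total_cM / n_intervals if n_intervals else 0.0

    def marker_positions(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.groups):
            for marker, pos in zip(g.markers, g.positions_cM):
                rows.append({"marker": marker, "linkage_group": gi + 1,
                             "position_cM": round(pos, 4),
                             "chromosome": g.chromosome if g.chromosome else 0})
        return pd.DataFrame(rows, columns=["marker", "linkage_group", "position_cM", "chromosome"])


def build_map(
    ordered_groups: list[list[int]],
    r: np.ndarray,
    ids: list[str],
    mapping_function: MappingFunction = MappingFunction.KOSAMBI,
) -> GeneticMap:
    """Turn ordered groups and the pairwise r matrix into a genetic map.

    Positions are cumulative mapping-function distances from the first marker
    of each group.  An adjacent r_hat within optimizer tolerance of 0.5 (only
    possible after ordering noise) would map to an infinite distance; it is
    capped at the function value of r=0.49 and the interval recorded."""
    to_cM = MAP_FUNCS[MappingFunction(mapping_function)][0]
    groups = []
    for order in ordered_groups:
        names = [ids[i] for i in order]
        adj, pos, capped = [], [0.0], []
        for k in range(len(order) - 1):
            rk = float(r[order[k], order[k + 1]])
            adj.append(rk)
            if rk >= _R_NEAR_HALF:
                capped.append(k)
                rk = _R_CAP
            pos.append(pos[-1] + float(to_cM(min(rk, _R_CAP))))
        groups.append(LinkageGroup(names, adj, pos, capped_intervals=capped))
    return GeneticMap(groups, MappingFunction(mapping_function))


def assign_chromosomes(gmap: GeneticMap, anchors: dict[str, int]) -> pd.DataFrame:
    """Label each linkage group with the majority chromosome among its
    anchored members (mutating the map); returns a per-group conflict report.

    Members whose anchor disagrees with the label are counted (not dropped);
    a majority tie or a group with no anchored member leaves the label unset.
    """
    rows = []
    for gi, g in enumerate(gmap.groups):
        votes = [anchors[m] for m in g.markers if m in anchors]
        if not votes:
            g.chromosome, g.conflicts = None, 0
            rows.append({"linkage_group": gi + 1, "chromosome": 0, "n_anchored": 0,
                         "conflicts": 0, "note": "no anchored member"})
            continue
        counts = pd.Series(votes).value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            g.chromosome, g.conflicts = None, 0
            rows.append({"linkage_group": gi + 1, "chromosome": 0,
                         "n_anchored": len(votes), "conflicts": 0, "note": "majority tie"})
            continue
        label = int(top.index[0])
        g.chromosome = label
        g.conflicts = int(sum(v != label for v in votes))
        rows.append({"linkage_group": gi + 1, "chromosome": label,
                     "n_anchored": len(votes), "conflicts": g.conflicts, "note": ""})
    return pd.DataFrame(rows)


def compare_maps(
    map_a: GeneticMap,
    map_b: GeneticMap,
    shared_marker_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Concordance of two maps on shared markers, per group of ``map_a``.

    For each group: whether its shared markers all fall in a single group of
    ``map_b``, and the Spearman rank correlation of their positions with the
    orientation (sign) chosen to maximize |rho| — map orientation is
    arbitrary, so only the magnitude is meaningful and the sign is reported.
    """
    pos_b: dict[str, tuple[int, float]] = {}
    for gi, g in enumerate(map_b.groups):
        for marker, p in zip(g.markers, g.positions_cM):
            pos_b[marker] = (gi, p)
    rows = []
    for gi, g in enumerate(map_a.groups):
        shared = [m for m in g.markers
                  if m in pos_b and (shared_marker_ids is None or m in shared_marker_ids)]
        if not shared:
            rows.append({"linkage_group_a": gi + 1, "chromosome": g.chromosome or 0,
                         "n_shared": 0, "co_grouped": False, "rho_abs": np.nan,
                         "orientation": 0, "note": "no shared markers"})
            continue
        b_groups = {pos_b[m][0] for m in shared}
        co_grouped = len(b_groups) == 1
        if len(shared) < 2 or not co_grouped:
            rows.append({"linkage_group_a": gi + 1, "chromosome": g.chromosome or 0,
                         "n_shared": len(shared), "co_grouped": co_grouped,
                         "rho_abs": np.nan, "orientation": 0,
                         "note": "correlation undefined" if len(shared) < 2 else "split"})
            continue
        pa = [g.positions_cM[g.markers.index(m)] for m in shared]
        pb = [pos_b[m][1] for m in shared]
        rho = stats.spearmanr(pa, pb).statistic
        if np.isnan(rho):  # ties everywhere (e.g. two markers at one position)
            rho, sign = 1.0, 1
        else:
            sign = 1 if rho >= 0 else -1
        rows.append({"linkage_group_a": gi + 1, "chromosome": g.chromosome or 0,
                     "n_shared": len(shared), "co_grouped": True,
                     "rho_abs": abs(float(rho)), "orientation": sign, "note": ""})
    return pd.DataFrame(rows)
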