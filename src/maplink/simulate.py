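"""Synthetic MAL and F2 panels with the statistical structure the pipeline assumes.

The generator stands in for the study's RNA-seq genotype calls.  It draws a
ground-truth genome (8 chromosomes, unigene loci with true centimorgan
positions and 1..k SNP sites each), meioses for an F2 population (Markov
crossover process along each chromosome, no interference, interval
recombination fractions obtained by inverting the selected mapping function
so that estimation with the same function is self-consistent), and read-depth
dependent genotype calls.  The dominant error it reproduces is heterozygote
dropout: at a truly heterozygous site the reference-allele read count is
binomial(depth, 1/2), and a heterozygote is only called when both alleles are
seen, so low depth collapses H to a homozygous call.  SNP sites within a
unigene get independent depth draws, which is what creates the downstream
S/O/R distinction.

Defaults mirror the study conditions: 96 F2 lines, 8 chromosomes totalling
936.6 cM, a 0.395 fraction of one-SNP unigenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import (
    Call,
    CallMatrix,
    MAL_ROLES,
    MaplinkError,
    N_CHROMOSOMES,
    PanelKind,
    ROLE_F2,
    ROLE_PARENT_ALT,
    ROLE_PARENT_REF,
)
from .linkage import MAP_FUNCS, MappingFunction

#: fraction of unigenes carrying a single SNP site (F2-panel accounting of the study)
ONE_SNP_FRACTION = 0.395
#: mean extra sites (beyond 2) for multi-SNP unigenes; gives ~4.5 sites/multi-SNP
#: unigene, matching the study's ~4.6 ((16,872-2,109)/3,230)
_MULTI_EXTRA_MEAN = 2.5

DEFAULT_TOTAL_CM = 936.6
DEFAULT_N_LINES = 96


@dataclass(frozen=True)
class ErrorModel:
    """Read-depth and genotyping-noise parameters.

    mean_depth / depth_dispersion
        read depth is hierarchical: each SNP site draws an expression level
        lambda ~ Gamma(shape=dispersion, mean=mean_depth) shared by all
        samples (expression varies between genes much more than between
        individuals of one cross), and each sample's depth at the site is
        Poisson(lambda).  Marginally depth is negative-binomial with this
        mean and size=dispersion; smaller dispersion = stronger
        between-site spread.
    min_alt_reads
        reads of each allele required to call a heterozygote; with the
        default 1, a true heterozygote at depth d is mis-called homozygous
        with probability 2 * 0.5^d.
    het_dropout_floor
        extra depth-independent probability that a true heterozygote is
        emitted as a homozygote (models allele-biased expression; default 0).
    mal_spurious_het_rate
        per-site probability that one random non-carrier MAL is called
        heterozygous (partial homology of the shallot gene).
    mal_dropout_rate
        per-site probability that the carrier MAL is called homozygous
        (downregulation of the corresponding gene).
    """

    mean_depth: float = 10.0
    depth_dispersion: float = 2.0
    min_alt_reads: int = 1
    het_dropout_floor: float = 0.0
    mal_spurious_het_rate: float = 0.02
    mal_dropout_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise MaplinkError("mean_depth and depth_dispersion must be positive")
        for p in (self.het_dropout_floor, self.mal_spurious_het_rate, self.mal_dropout_rate):
            if not 0 <= p <= 1:
                raise MaplinkError("error probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TrueMap:
    """Ground-truth genome: unigene loci with true cM positions on 8 chromosomes."""

    chromosome_lengths: tuple      # cM per chromosome
    unigenes: pd.DataFrame         # columns: unigene, chromosome (1..8), position_cM
    snp_counts: dict               # unigene -> number of SNP sites (>= 1)
    mapping_function: MappingFunction = MappingFunction.KOSAMBI

    def __post_init__(self) -> None:
        for _, sub in self.unigenes.groupby("chromosome"):
            pos = sub["position_cM"].to_numpy()
            if (pos < 0).any() or (np.diff(pos) <= 0).any():
                raise MaplinkError("positions must be non-negative and strictly increasing")

    @property
    def n_unigenes(self) -> int:
        return len(self.unigenes)

    def loci_on(self, chromosome: int) -> pd.DataFrame:
        return self.unigenes[self.unigenes["chromosome"] == chromosome]

    def chromosome_of(self) -> dict[str, int]:
        return dict(zip(self.unigenes["unigene"], self.unigenes["chromosome"].astype(int)))


def _sample_snp_counts(rng: np.random.Generator, n: int, dist: dict[int, float] | None) -> np.ndarray:
    if dist is not None:
        ks = np.array(sorted(dist), dtype=int)
        ps = np.array([dist[int(k)] for k in ks], dtype=float)
        if (ks < 0).any() or ps.sum() <= 0 or (ps < 0).any():
            raise MaplinkError("invalid snp count distribution")
        ps = ps / ps.sum()
        if not (ks * ps).sum() > 0 or ks.max() == 0:
            raise MaplinkError("snp count distribution puts all mass at 0 sites")
        counts = rng.choice(ks, size=n, p=ps)
        if (counts == 0).any():
            counts = np.maximum(counts, 1)  # a unigene without sites is unobservable
        return counts
    one = rng.random(n) < ONE_SNP_FRACTION
    counts = np.where(one, 1, 2 + rng.poisson(_MULTI_EXTRA_MEAN, size=n))
    return counts


def simulate_true_map(
    n_unigenes: int = 800,
    total_cM: float = DEFAULT_TOTAL_CM,
    snp_count_distribution: dict[int, float] | None = None,
    chromosome_weights: np.ndarray | None = None,
    mapping_function: MappingFunction = MappingFunction.KOSAMBI,
    seed: int = 0,
) -> TrueMap:
    """Draw a ground-truth genome.

    Chromosome lengths split ``total_cM`` proportionally to
    ``chromosome_weights`` (equal by default); unigene counts per chromosome
    follow the same proportions (largest-remainder rounding so every
    chromosome is populated); loci are placed uniformly then sorted.
    """
    if n_unigenes < 16:
        raise MaplinkError("need at least 16 unigenes (2 per chromosome)")
    if total_cM <= 0:
        raise MaplinkError("total_cM must be positive")
    rng = np.random.default_rng(seed)
    w = np.full(N_CHROMOSOMES, 1.0) if chromosome_weights is None else np.asarray(
        chromosome_weights, dtype=float)
    if len(w) != N_CHROMOSOMES or (w <= 0).any():
        raise MaplinkError("chromosome_weights must be 8 positive values")
    w = w / w.sum()
    lengths = total_cM * w

    # largest-remainder allocation of unigene counts
    raw = n_unigenes * w
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_unigenes - counts.sum()]:
        counts[i] += 1

    rows = []
    k = 0
    for c in range(N_CHROMOSOMES):
        pos = np.sort(rng.uniform(0, lengths[c], size=counts[c]))
        # perturb exact ties (zero-probability event, but positions must strictly increase)
        while (np.diff(pos) <= 0).any():
            pos = np.sort(pos + rng.uniform(0, 1e-9, size=len(pos)))
        for p in pos:
            rows.append({"unigene": f"UG{k:05d}", "chromosome": c + 1, "position_cM": float(p)})
            k += 1
    unigenes = pd.DataFrame(rows)
    snp_counts = dict(zip(unigenes["unigene"],
                          (int(x) for x in _sample_snp_counts(rng, n_unigenes,
                                                              snp_count_distribution))))
    return TrueMap(tuple(float(x) for x in lengths), unigenes, snp_counts,
                   MappingFunction(mapping_function))


def simulate_f2_genotypes(true_map: TrueMap, n_lines: int = DEFAULT_N_LINES,
                          seed: int = 0) -> np.ndarray:
    """True F2 genotypes (n_lines x n_unigenes, codes 0=A, 1=H, 2=B).

    Each line is the union of two independent gametes; each gamete is a
    Markov chain along the ordered loci of each chromosome whose interval
    crossover probability is the inverse mapping function of the cM gap
    (no interference across intervals).  Selfing of a single F1 means both
    gametes follow the same meiosis distribution.
    """
    if n_lines < 1:
        raise MaplinkError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    inv = MAP_FUNCS[true_map.mapping_function][1]
    geno = np.empty((n_lines, true_map.n_unigenes), dtype=np.int8)
    col = 0
    for c in range(1, N_CHROMOSOMES + 1):
        loci = true_map.loci_on(c)
        m = len(loci)
        gaps = np.diff(loci["position_cM"].to_numpy())
        rs = inv(gaps) if m > 1 else np.empty(0)
        # 2 gametes per line; allele 0 = DHA, 1 = DHC
        first = rng.integers(0, 2, size=(2 * n_lines, 1))
        if m > 1:
            switches = rng.random((2 * n_lines, m - 1)) < rs
            path = np.concatenate([first, switches], axis=1)
            alleles = np.cumsum(path, axis=1) % 2
        else:
            alleles = first
        geno[:, col:col + m] = (alleles[:n_lines] + alleles[n_lines:]).astype(np.int8)
        col += m
    return geno


def _site_positions(rng: np.random.Generator, k: int) -> np.ndarray:
    """1-based transcript coordinates for k SNP sites on one unigene."""
    return np.sort(rng.choice(np.arange(1, 2001), size=k, replace=False))


def _nb_depths(rng: np.random.Generator, error_model: ErrorModel, shape) -> np.ndarray:
    """Depths for (n_sites, n_samples): per-site Gamma expression level,
    Poisson sampling per sample (marginally negative-binomial)."""
    n_sites, n_samples = shape
    k = error_model.depth_dispersion
    lam = rng.gamma(k, error_model.mean_depth / k, size=(n_sites, 1))
    return rng.poisson(np.broadcast_to(lam, shape)).astype(np.int32)


def _emit_het_calls(rng: np.random.Generator, depths: np.ndarray,
                    error_model: ErrorModel) -> np.ndarray:
    """Observed calls at truly heterozygous sites, given read depths."""
    ref = rng.binomial(depths, 0.5)
    alt = depths - ref
    m = error_model.min_alt_reads
    calls = np.where(
        (ref >= m) & (alt >= m), np.int8(Call.HET),
        np.where(ref > alt, np.int8(Call.REF_HOM),
                 np.where(alt > ref, np.int8(Call.ALT_HOM), np.int8(Call.HET))),
    ).astype(np.int8)
    if error_model.het_dropout_floor > 0:
        drop = rng.random(depths.shape) < error_model.het_dropout_floor
        rand_hom = np.where(rng.random(depths.shape) < 0.5,
                            np.int8(Call.REF_HOM), np.int8(Call.ALT_HOM))
        calls = np.where(drop, rand_hom, calls)
    calls[depths == 0] = Call.MISSING
    return calls


def simulate_read_calls(
    true_genotypes: np.ndarray,
    true_map: TrueMap,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> CallMatrix:
    """Emit an F2 CallMatrix from true genotypes through the depth/error model.

    Every SNP site of a unigene shares the unigene's true genotype column but
    receives an independent depth draw and, when heterozygous, an independent
    allele-sampling draw.  Parental columns (DHA REF_HOM, DHC ALT_HOM) are
    error-free at high depth.
    """
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    n_lines = true_genotypes.shape[0]
    unigene_order = true_map.unigenes["unigene"].tolist()

    site_unigene, site_pos, truth_cols = [], [], []
    for j, u in enumerate(unigene_order):
        k = true_map.snp_counts[u]
        for p in _site_positions(rng, k):
            site_unigene.append(u)
            site_pos.append(int(p))
            truth_cols.append(j)
    n_sites = len(site_unigene)
    truth = true_genotypes[:, truth_cols].T.astype(np.int8)      # (n_sites, n_lines)

    depths = _nb_depths(rng, error_model, (n_sites, n_lines))
    calls = truth.copy()
    het = truth == Call.HET
    calls[het] = _emit_het_calls(rng, depths[het], error_model)
    calls[depths == 0] = Call.MISSING

    samples = ["DHA", "DHC"] + [f"F2_{i + 1:03d}" for i in range(n_lines)]
    roles = {"DHA": ROLE_PARENT_REF, "DHC": ROLE_PARENT_ALT}
    roles.update({s: ROLE_F2 for s in samples[2:]})
    parent_depth = np.full((n_sites, 1), 100, dtype=np.int32)
    all_calls = np.hstack([
        np.full((n_sites, 1), np.int8(Call.REF_HOM)),
        np.full((n_sites, 1), np.int8(Call.ALT_HOM)),
        calls,
    ])
    all_depths = np.hstack([parent_depth, parent_depth, depths])
    sites = pd.DataFrame({"unigene": site_unigene, "position": site_pos})
    return CallMatrix(samples, roles, sites, all_calls, all_depths, PanelKind.F2)


def simulate_mal_panel(
    true_map: TrueMap,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> CallMatrix:
    """Emit a MAL CallMatrix: for a unigene on chromosome c, MAL c is
    heterozygous and the other seven are homozygous for the bunching-onion
    allele; the parental columns show the interspecific SNP (bunching onion
    ALT_HOM, DHA REF_HOM).

    Noise: with probability ``mal_dropout_rate`` (per site) the carrier call
    collapses to ALT_HOM; with probability ``mal_spurious_het_rate`` one
    random non-carrier MAL is called heterozygous.  Depths follow the same
    negative-binomial model as the F2 panel (use a higher ``mean_depth`` —
    the anchoring filter demands depth >= 4 in all eight MALs).
    """
    error_model = error_model or ErrorModel(mean_depth=30.0)
    rng = np.random.default_rng(seed)
    chrom_of = true_map.chromosome_of()

    site_unigene, site_pos, carrier = [], [], []
    for u in true_map.unigenes["unigene"]:
        for p in _site_positions(rng, true_map.snp_counts[u]):
            site_unigene.append(u)
            site_pos.append(int(p))
            carrier.append(chrom_of[u] - 1)
    n_sites = len(site_unigene)
    carrier = np.asarray(carrier)

    mal_calls = np.full((n_sites, N_CHROMOSOMES), np.int8(Call.ALT_HOM))
    mal_calls[np.arange(n_sites), carrier] = Call.HET
    dropout = rng.random(n_sites) < error_model.mal_dropout_rate
    mal_calls[dropout, carrier[dropout]] = Call.ALT_HOM
    spurious = rng.random(n_sites) < error_model.mal_spurious_het_rate
    for i in np.flatnonzero(spurious):
        others = [m for m in range(N_CHROMOSOMES) if m != carrier[i]]
        mal_calls[i, rng.choice(others)] = Call.HET

    depths = _nb_depths(rng, error_model, (n_sites, N_CHROMOSOMES))
    mal_calls = np.where(depths == 0, np.int8(Call.MISSING), mal_calls)

    samples = ["Fistulosum", "DHA"] + [f"MAL{c}" for c in range(1, N_CHROMOSOMES + 1)]
    roles = {"Fistulosum": ROLE_PARENT_ALT, "DHA": ROLE_PARENT_REF}
    roles.update({f"MAL{c}": MAL_ROLES[c - 1] for c in range(1, N_CHROMOSOMES + 1)})
    parent_depth = np.full((n_sites, 1), 100, dtype=np.int32)
    all_calls = np.hstack([
        np.full((n_sites, 1), np.int8(Call.ALT_HOM)),   # bunching onion
        np.full((n_sites, 1), np.int8(Call.REF_HOM)),   # DHA
        mal_calls,
    ])
    all_depths = np.hstack([parent_depth, parent_depth, depths])
    sites = pd.DataFrame({"unigene": site_unigene, "position": site_pos})
    return CallMatrix(samples, roles, sites, all_calls, all_depths, PanelKind.MAL)


def write_truth_table(true_map: TrueMap, genotypes: np.ndarray, path: str) -> None:
    """Ground-truth TSV (unigene, chromosome, true cM, n_sites, per-line genotypes)."""
    from .calls import genotypes_to_chars

    cols = {"unigene": true_map.unigenes["unigene"],
            "chromosome": true_map.unigenes["chromosome"],
            "position_cM": true_map.unigenes["position_cM"].round(4),
            "n_snp_sites": [true_map.snp_counts[u] for u in true_map.unigenes["unigene"]]}
    df = pd.DataFrame(cols)
    geno_chars = np.array(genotypes_to_chars(genotypes)).reshape(genotypes.shape)
    for i in range(genotypes.shape[0]):
        df[f"F2_{i + 1:03d}"] = geno_chars[i]
    df.to_csv(path, sep="\t", index=False)
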