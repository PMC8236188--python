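"""Core genotype-call containers shared by every pipeline stage.

Genotypes are the three co-dominant F2 classes expected from a cross of two
fully homozygous doubled-haploid parents — reference homozygote (the shallot
DHA allele, written ``A``), heterozygote (``H``) and alternative homozygote
(``B``) — plus ``MISSING`` for uncallable sites.  A :class:`CallMatrix` holds
the calls and per-sample read depths for one panel (either the eight
monosomic-addition-line samples plus their two parents, or an F2 mapping
population plus its two parents), with sites grouped by the unigene they were
called on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MaplinkError(Exception):
    """Base class for errors raised by this package."""


class FormatError(MaplinkError):
    """Malformed input file (missing fields, bad encodings, ...)."""


class ConfigError(MaplinkError):
    """Inconsistent configuration (roles, thresholds, missing inputs)."""


class Call(enum.IntEnum):
    """One genotype call; integer codes are used in the call matrices."""

    MISSING = -1
    REF_HOM = 0   # two DHA alleles ("A")
    HET = 1       # one allele from each parent ("H")
    ALT_HOM = 2   # two alternative-parent alleles ("B")


#: integer code -> single-character encoding used in all text tables
CALL_TO_CHAR = {Call.REF_HOM: "A", Call.HET: "H", Call.ALT_HOM: "B", Call.MISSING: "-"}
CHAR_TO_CALL = {v: k for k, v in CALL_TO_CHAR.items()}

N_CHROMOSOMES = 8

# sample roles
ROLE_PARENT_REF = "parent_ref"   # DHA: the reference parent (shallot DH)
ROLE_PARENT_ALT = "parent_alt"   # bunching onion (MAL panel) or DHC (F2 panel)
ROLE_F2 = "f2"
MAL_ROLES = tuple(f"mal{c}" for c in range(1, N_CHROMOSOMES + 1))


class PanelKind(str, enum.Enum):
    MAL = "MAL"
    F2 = "F2"


@dataclass(frozen=True)
class Thresholds:
    """Filtering and mapping thresholds.

    mal_min_depth
        minimum read depth required in *all eight* MAL samples for a site to
        be usable for chromosome anchoring (default 4).
    f2_min_depth
        minimum read depth required in every F2 line (default 2).
    lod_threshold
        LOD cutoff for declaring two markers linked when grouping (default 5).
    max_block_mismatch
        maximum number of discordant lines tolerated when allocating an O/R
        marker to a genotype block (default 10).
    """

    mal_min_depth: int = 4
    f2_min_depth: int = 2
    lod_threshold: float = 5.0
    max_block_mismatch: int = 10

    def __post_init__(self) -> None:
        for name in ("mal_min_depth", "f2_min_depth", "lod_threshold", "max_block_mismatch"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be strictly positive")


@dataclass(frozen=True)
class SnpSite:
    """Calls and depths of every sample at one SNP site (a view row of a CallMatrix)."""

    unigene_id: str
    position: int
    calls: np.ndarray    # int8, one entry per sample in matrix order
    depths: np.ndarray   # int32


def genotypes_to_chars(values: np.ndarray) -> list[str]:
    """Encode an int8 genotype array as 'A'/'H'/'B'/'-' characters."""
    lut = {int(k): v for k, v in CALL_TO_CHAR.items()}
    return [lut[int(v)] for v in np.asarray(values).ravel()]


def chars_to_genotypes(chars) -> np.ndarray:
    """Decode 'A'/'H'/'B'/'-' characters into an int8 genotype array."""
    try:
        return np.array([int(CHAR_TO_CALL[c]) for c in chars], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"unknown genotype character {exc}") from exc


class CallMatrix:
    """Genotype calls and depths for one panel, sites grouped by unigene.

    Parameters
    ----------
    samples
        ordered sample names (columns of ``calls`` / ``depths``).
    roles
        mapping sample name -> role; roles are ``parent_ref``, ``parent_alt``
        and either ``mal1``..``mal8`` (MAL panel) or ``f2`` (F2 panel).
    sites
        DataFrame with columns ``unigene`` and ``position`` (1-based).
    calls, depths
        arrays of shape (n_sites, n_samples); calls use :class:`Call` codes.
    panel_kind
        which panel layout to validate against.
    """

    def __init__(
        self,
        samples: list[str],
        roles: dict[str, str],
        sites: pd.DataFrame,
        calls: np.ndarray,
        depths: np.ndarray,
        panel_kind: PanelKind,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        depths = np.asarray(depths, dtype=np.int32)
        if calls.shape != depths.shape or calls.shape != (len(sites), len(samples)):
            raise ConfigError("calls/depths shape must be (n_sites, n_samples)")
        if (depths < 0).any():
            raise FormatError("negative read depth")
        unknown = set(roles) - set(samples)
        if unknown:
            raise ConfigError(f"role declared for unknown sample(s): {sorted(unknown)}")
        self.samples = list(samples)
        self.roles = dict(roles)
        self.panel_kind = PanelKind(panel_kind)
        # depth 0 can never support a call
        calls = np.where(depths == 0, np.int8(Call.MISSING), calls)
        # canonical site order: by unigene, then ascending position
        sites = sites.reset_index(drop=True)
        order = sites.sort_values(["unigene", "position"], kind="mergesort").index.to_numpy()
        self.sites = sites.iloc[order].reset_index(drop=True)
        self.calls = calls[order]
        self.depths = depths[order]
        self._validate_roles()

    def _validate_roles(self) -> None:
        by_role: dict[str, list[str]] = {}
        for s, r in self.roles.items():
            by_role.setdefault(r, []).append(s)
        for role in (ROLE_PARENT_REF, ROLE_PARENT_ALT):
            if len(by_role.get(role, [])) != 1:
                raise ConfigError(f"panel needs exactly one sample with role {role!r}")
        if self.panel_kind is PanelKind.MAL:
            for role in MAL_ROLES:
                if len(by_role.get(role, [])) != 1:
                    raise ConfigError(f"MAL panel needs exactly one sample with role {role!r}")
        else:
            if not by_role.get(ROLE_F2):
                raise ConfigError("F2 panel needs at least one sample with role 'f2'")

    # -- sample access -----------------------------------------------------

    def sample_index(self, role: str) -> int:
        """Index of the unique sample holding ``role``."""
        hits = [i for i, s in enumerate(self.samples) if self.roles.get(s) == role]
        if len(hits) != 1:
            raise ConfigError(f"expected exactly one sample with role {role!r}")
        return hits[0]

    def role_indices(self, role: str) -> np.ndarray:
        """Indices of all samples holding ``role``, in column order."""
        return np.array([i for i, s in enumerate(self.samples) if self.roles.get(s) == role],
                        dtype=np.intp)

    @property
    def mal_indices(self) -> np.ndarray:
        """Column indices of MAL1..MAL8 in chromosome order."""
        return np.array([self.sample_index(r) for r in MAL_ROLES], dtype=np.intp)

    @property
    def f2_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_F2)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, i: int) -> SnpSite:
        row = self.sites.iloc[i]
        return SnpSite(str(row["unigene"]), int(row["position"]),
                       self.calls[i], self.depths[i])

    def by_unigene(self):
        """Yield ``(unigene_id, row_indices)`` in canonical order."""
        unigenes = self.sites["unigene"].to_numpy()
        start = 0
        for i in range(1, len(unigenes) + 1):
            if i == len(unigenes) or unigenes[i] != unigenes[start]:
                yield str(unigenes[start]), np.arange(start, i)
                start = i
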