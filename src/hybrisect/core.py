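"""Core data structures for hybrid-ancestry dissection of SNP panels.

The central object is the :class:`GenotypePanel`: a loci x samples matrix of
diploid genotype calls (optionally with per-allele read depths) together with
a sample manifest assigning each sample a role -- one of the two progenitor
species, an optional outgroup species, or a cultivar with a growth-habit
label.  All downstream stages (genotype re-calling, origin classification,
diversity statistics, map projection, enrichment) consume this object.

Genotype calls are stored as allele *indices* into each locus' allele list
(index 0 is the reference allele, indices 1.. are the alternative alleles in
VCF order).  A missing call is encoded as ``(-1, -1)``.  Call pairs are kept
sorted, so genotypes compare as unordered allele multisets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

MISSING = None
"""Sentinel for a missing genotype call at the symbolic (allele-tuple) API."""


class Role(str, enum.Enum):
    """Role of a sample in the panel."""

    PROGENITOR_A = "progenitor_a"
    PROGENITOR_B = "progenitor_b"
    OUTGROUP_SPECIES = "outgroup_species"
    CULTIVAR = "cultivar"


class Habit(str, enum.Enum):
    """Growth habit of a cultivar (``NONE`` for non-cultivar samples)."""

    TRAILING = "trailing"
    MOUNDED = "mounded"
    MOUNDING_TRAILING = "mounding_trailing"
    UPRIGHT = "upright"
    NONE = "none"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: Role
    habit: Habit = Habit.NONE

    def __post_init__(self) -> None:
        if (self.habit is Habit.NONE) != (self.role is not Role.CULTIVAR):
            raise ValueError(
                f"sample {self.sample_id!r}: habit must be 'none' exactly for "
                f"non-cultivar roles (got role={self.role.value}, habit={self.habit.value})"
            )


def validate_manifest(samples: Sequence[Sample]) -> None:
    """Check panel-level manifest invariants.

    Exactly one ``progenitor_a`` and one ``progenitor_b`` are required; sample
    ids must be unique.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in manifest")
    for role in (Role.PROGENITOR_A, Role.PROGENITOR_B):
        n = sum(1 for s in samples if s.role is role)
        if n != 1:
            raise ValueError(f"manifest must contain exactly one {role.value} (found {n})")


@dataclass(frozen=True)
class SnpLocus:
    """A SNP locus on the reference transcriptome.

    Positions are 1-based; ``scaffold``/``scaffold_pos`` are the optional
    genomic anchor of the transcript-relative position.
    """

    transcript_id: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    scaffold: Optional[str] = None
    scaffold_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError(f"{self.transcript_id}:{self.pos}: alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"{self.transcript_id}:{self.pos}: ref allele repeated in alts")
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise ValueError(f"{self.transcript_id}:{self.pos}: duplicate alt alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles


@dataclass
class GenotypePanel:
    """Loci x samples genotype matrix with roles and optional allele depths.

    Parameters
    ----------
    loci
        The SNP loci, one per matrix row.
    samples
        Sample manifest; column order of the matrix.
    calls
        ``(n_loci, n_samples, 2)`` int8 array of allele indices into each
        locus' allele list; ``-1`` marks a missing call.  Pairs are sorted.
    depths
        Optional ``(n_loci, n_samples, max_alleles)`` array of per-allele
        read counts (zero-padded beyond each locus' allele count).
    """

    loci: list[SnpLocus]
    samples: list[Sample]
    calls: np.ndarray
    depths: Optional[np.ndarray] = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        validate_manifest(self.samples)
        keys = {(l.transcript_id, l.pos) for l in self.loci}
        if len(keys) != len(self.loci):
            raise ValueError("duplicate (transcript_id, pos) locus in panel")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.samples), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        # normalise: sorted pairs, missing == (-1,-1)
        self.calls = np.sort(self.calls, axis=2)
        miss = (self.calls < 0).any(axis=2)
        self.calls[miss] = -1
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape[:2] != (len(self.loci), len(self.samples)):
                raise ValueError("depths shape inconsistent with panel")
        self._index = {s.sample_id: j for j, s in enumerate(self.samples)}

    # ------------------------------------------------------------------ sizes
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # ---------------------------------------------------------------- lookups
    def sample_index(self, sample_id: str) -> int:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def sample(self, sample_id: str) -> Sample:
        return self.samples[self.sample_index(sample_id)]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def progenitor_a(self) -> Sample:
        return next(s for s in self.samples if s.role is Role.PROGENITOR_A)

    @property
    def progenitor_b(self) -> Sample:
        return next(s for s in self.samples if s.role is Role.PROGENITOR_B)

    @property
    def cultivars(self) -> list[Sample]:
        return [s for s in self.samples if s.role is Role.CULTIVAR]

    def call(self, locus_i: int, sample_id: str) -> Optional[tuple[str, str]]:
        """Symbolic genotype of one cell, or :data:`MISSING`."""
        j = self.sample_index(sample_id)
        a, b = self.calls[locus_i, j]
        if a < 0:
            return MISSING
        alleles = self.loci[locus_i].alleles
        return (alleles[a], alleles[b])

    # ------------------------------------------------------------- operations
    def subset_loci(self, keep: np.ndarray | Sequence[int]) -> "GenotypePanel":
        """New panel restricted to the given locus mask or index list."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            loci=[self.loci[i] for i in keep],
            samples=list(self.samples),
            calls=self.calls[keep].copy(),
            depths=None if self.depths is None else self.depths[keep].copy(),
        )

    def with_calls(self, calls: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            loci=list(self.loci),
            samples=list(self.samples),
            calls=calls,
            depths=None if self.depths is None else self.depths.copy(),
        )

    def call_codes(self) -> np.ndarray:
        """Encode each genotype as one int: ``a1 * 16 + a2`` (-1 = missing).

        Allele indices fit in 4 bits (SNP loci carry at most 4 alleles), so
        codes compare equal exactly when the unordered genotypes are equal.
        """
        c = self.calls.astype(np.int16)
        code = c[..., 0] * 16 + c[..., 1]
        code[c[..., 0] < 0] = -1
        return code


class Category(enum.IntEnum):
    """The 12-way progenitor-origin classification of one cultivar genotype.

    ``AX`` denotes the progenitor-A (reference species) origin, ``INT`` the
    progenitor-B origin, ``SHARED`` an allele common to both progenitors and
    ``OUT`` an allele found in neither (putative third-species introgression).
    The "out" categories are exactly {6, 7, 8, 9, 10}; category 7 is the
    heterozygote pairing the progenitors' common allele with a novel allele.
    """

    AX_HOM = 1
    INT_HOM = 2
    SHARED_HOM = 3
    AX_INT_HET = 4
    SHARED_HET = 5
    AX_OUT_HET = 6
    SHARED_OUT_HET = 7
    INT_OUT_HET = 8
    OUT_HOM = 9
    OUT_OUT_HET = 10
    UNKNOWN = 11
    MISSING = 12


OUT_CATEGORIES = frozenset(
    {Category.AX_OUT_HET, Category.SHARED_OUT_HET, Category.INT_OUT_HET,
     Category.OUT_HOM, Category.OUT_OUT_HET}
)

#: Per-category similarity-with-progenitor-A rates used for map projection.
#: ``None`` marks categories excluded from similarity averaging.
SIMILARITY_RATES: Mapping[Category, Optional[float]] = {
    Category.AX_HOM: 1.0,
    Category.INT_HOM: 0.0,
    Category.SHARED_HOM: 1.0,
    Category.AX_INT_HET: 0.5,
    Category.SHARED_HET: 0.5,
    Category.AX_OUT_HET: 0.5,
    Category.SHARED_OUT_HET: 0.5,
    Category.INT_OUT_HET: 0.0,
    Category.OUT_HOM: 0.0,
    Category.OUT_OUT_HET: 0.0,
    Category.UNKNOWN: None,
    Category.MISSING: None,
}


def genotype_from_symbols(
    genotype: Optional[Iterable[str]], locus: SnpLocus
) -> tuple[int, int]:
    """Translate a symbolic genotype into sorted allele indices (-1,-1 = missing)."""
    if genotype is None:
        return (-1, -1)
    pair = tuple(genotype)
    if len(pair) != 2:
        raise ValueError(f"genotype must have two alleles, got {pair!r}")
    alleles = locus.alleles
    try:
        idx = sorted(alleles.index(a) for a in pair)
    except ValueError:
        raise ValueError(f"allele not in locus {locus.transcript_id}:{locus.pos}: {pair!r}")
    return (idx[0], idx[1])
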