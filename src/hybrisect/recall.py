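"""Genotype re-calling from per-allele read depths, plus locus-level filters.

Initial GT calls from a variant caller can miscall heterozygotes as
homozygotes at moderate coverage.  Genotypes are therefore re-defined from
the allele read percentages with three threshold rules (applied after a
minimum-total-depth gate, default 5 reads):

1. hom-ref  -- reference reads >= 80% of total reads;
2. hom-alt  -- reads of the single most-supported alternative allele > 80%;
3. het      -- both the reference ratio and that alternative's ratio > 0.3
               and their sum >= 0.8 (called ref/alt);

anything else is missing.  The inequality strictness differs between the
rules on purpose and is preserved exactly.  For multiallelic loci only the
single most-supported alternative allele is considered (ties broken by VCF
alt order), so re-calling never produces a heterozygote between two
alternative alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import MISSING, GenotypePanel, Role, SnpLocus


@dataclass(frozen=True)
class RecallThresholds:
    """Allele-ratio and depth thresholds for genotype re-calling."""

    hom_ref_min: float = 0.80   # inclusive
    hom_alt_min: float = 0.80   # exclusive
    het_each_min: float = 0.30  # exclusive, applied to both ratios
    het_sum_min: float = 0.80   # inclusive
    min_depth: int = 5

    def __post_init__(self) -> None:
        for name in ("hom_ref_min", "hom_alt_min", "het_each_min", "het_sum_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")


DEFAULT_THRESHOLDS = RecallThresholds()


def recall_genotype(
    depths: Mapping[str, int],
    locus: SnpLocus,
    thresholds: RecallThresholds = DEFAULT_THRESHOLDS,
) -> Optional[tuple[str, str]]:
    """Re-call one genotype from its allele read counts.

    Returns a symbolic allele pair or :data:`~hybrisect.core.MISSING`.
    """
    alleles = locus.alleles
    unknown = set(depths) - set(alleles)
    if unknown:
        raise ValueError(
            f"depths for alleles not in locus {locus.transcript_id}:{locus.pos}: {sorted(unknown)}"
        )
    counts = np.array([depths.get(a, 0) for a in alleles], dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative read count")
    total = int(counts.sum())
    if total < thresholds.min_depth:
        return MISSING
    ref_ratio = counts[0] / total
    alt1 = 1 + int(np.argmax(counts[1:]))  # ties -> first alt in VCF order
    alt_ratio = counts[alt1] / total
    if ref_ratio >= thresholds.hom_ref_min:
        return (alleles[0], alleles[0])
    if alt_ratio > thresholds.hom_alt_min:
        return (alleles[alt1], alleles[alt1])
    if (
        ref_ratio > thresholds.het_each_min
        and alt_ratio > thresholds.het_each_min
        and ref_ratio + alt_ratio >= thresholds.het_sum_min
    ):
        return (alleles[0], alleles[alt1])
    return MISSING


def recall_panel(
    panel: GenotypePanel, thresholds: RecallThresholds = DEFAULT_THRESHOLDS
) -> GenotypePanel:
    """Re-call every cell of the panel from its depths; original GT discarded."""
    if panel.depths is None:
        raise ValueError("panel has no allele depths; cannot re-call genotypes")
    d = panel.depths.astype(np.float64)  # (n_loci, n_samples, A)
    n_alleles = np.array([len(l.alleles) for l in panel.loci])
    # zero out any padding columns defensively
    col = np.arange(d.shape[2])
    d = np.where(col[None, None, :] < n_alleles[:, None, None], d, 0.0)
    total = d.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_ratio = np.where(total > 0, d[:, :, 0] / np.maximum(total, 1), 0.0)
        alt1 = 1 + np.argmax(d[:, :, 1:], axis=2)
        alt_ratio = np.where(
            total > 0, np.take_along_axis(d, alt1[:, :, None], axis=2)[:, :, 0] / np.maximum(total, 1), 0.0
        )
    deep = total >= thresholds.min_depth
    is_aa = deep & (ref_ratio >= thresholds.hom_ref_min)
    is_bb = deep & ~is_aa & (alt_ratio > thresholds.hom_alt_min)
    is_ab = (
        deep
        & ~is_aa
        & ~is_bb
        & (ref_ratio > thresholds.het_each_min)
        & (alt_ratio > thresholds.het_each_min)
        & (ref_ratio + alt_ratio >= thresholds.het_sum_min)
    )
    calls = np.full(panel.calls.shape, -1, dtype=np.int8)
    a1 = alt1.astype(np.int8)
    calls[is_aa] = 0
    calls[..., 0][is_ab] = 0
    calls[..., 1][is_ab] = a1[is_ab]
    calls[..., 0][is_bb] = a1[is_bb]
    calls[..., 1][is_bb] = a1[is_bb]
    return panel.with_calls(calls)


def filter_informative(panel: GenotypePanel) -> GenotypePanel:
    """Keep loci where some cultivar differs from the progenitor-A genotype.

    This defines the working ("entire") dataset: loci with no polymorphism
    between the cultivars and the reference-species genotype carry no
    ancestry information and are dropped.  Calls compare as unordered allele
    multisets; missing cultivar calls never count as a difference.
    """
    codes = panel.call_codes()
    a_col = panel.sample_index(panel.progenitor_a.sample_id)
    cult_cols = [panel.sample_index(s.sample_id) for s in panel.cultivars]
    ref = codes[:, a_col][:, None]
    cult = codes[:, cult_cols]
    keep = ((cult >= 0) & (cult != ref)).any(axis=1)
    return panel.subset_loci(keep)


def subset_no_missing(panel: GenotypePanel) -> GenotypePanel:
    """Keep loci with a non-missing call in every sample ("no missing" set)."""
    keep = (panel.calls[..., 0] >= 0).all(axis=1)
    return panel.subset_loci(keep)
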