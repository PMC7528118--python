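"""Panel-level diversity statistics.

Per-sample transcriptome heterozygosity (heterozygous SNPs / total SNPs) and
the pairwise SNP-difference matrix between all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypePanel


@dataclass(frozen=True)
class HeterozygosityReport:
    sample_id: str
    dataset: str
    n_het: int
    n_total: int

    @property
    def rate(self) -> float:
        return self.n_het / self.n_total


def heterozygosity(
    panel: GenotypePanel,
    sample_id: str,
    dataset: str = "entire",
    denominator: str = "non_missing",
) -> HeterozygosityReport:
    """Heterozygosity rate of one sample.

    The denominator is the sample's non-missing calls by default ("total
    number of SNPs" is ambiguous under missing data; this avoids deflating
    rates for low-coverage samples).  ``denominator="all_loci"`` divides by
    the full locus count instead.
    """
    j = panel.sample_index(sample_id)
    c = panel.calls[:, j]
    ok = c[:, 0] >= 0
    n_het = int((ok & (c[:, 0] != c[:, 1])).sum())
    n_total = int(ok.sum()) if denominator == "non_missing" else panel.n_loci
    if n_total == 0:
        raise ValueError(f"sample {sample_id!r} has no called loci")
    return HeterozygosityReport(sample_id, dataset, n_het, n_total)


@dataclass
class PairwiseSnpMatrix:
    """Symmetric zero-diagonal matrix of pairwise SNP-difference counts."""

    samples: list[str]
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.samples)


def pairwise_snp_counts(
    panel: GenotypePanel, lenient: bool = False
) -> PairwiseSnpMatrix:
    """Count, for every sample pair, the loci where their genotypes differ.

    Only loci where both members are called enter a pair's count
    (pairwise-complete convention).  By default any inequality of the
    unordered allele pairs counts (hom vs het over the same allele is a
    difference); with ``lenient=True`` only pairs with disjoint allele sets
    count.
    """
    if panel.n_samples < 2:
        raise ValueError("pairwise counts need at least two samples")
    m = panel.n_samples
    out = np.zeros((m, m), dtype=np.int64)
    if lenient:
        from .ancestry import _allele_masks

        masks = np.stack([_allele_masks(panel.calls[:, j]) for j in range(m)], axis=1)
        for i in range(m):
            for j in range(i + 1, m):
                ok = (masks[:, i] > 0) & (masks[:, j] > 0)
                diff = ok & ((masks[:, i] & masks[:, j]) == 0)
                out[i, j] = out[j, i] = int(diff.sum())
    else:
        codes = panel.call_codes()
        for i in range(m):
            for j in range(i + 1, m):
                ok = (codes[:, i] >= 0) & (codes[:, j] >= 0)
                diff = ok & (codes[:, i] != codes[:, j])
                out[i, j] = out[j, i] = int(diff.sum())
    return PairwiseSnpMatrix(samples=panel.sample_ids, counts=out)
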