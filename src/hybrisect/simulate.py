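"""Synthetic SNP-panel generator with per-copy allele-origin ground truth.

The simulator emulates the statistical structure the ancestry analysis
assumes: two progenitor samples with contrasting heterozygosity (the
reference-species progenitor nearly homozygous, the other highly
heterozygous), cultivars whose two allele copies at each locus are drawn
independently from configurable origin proportions (progenitor A,
progenitor B, outgroup), loci where the progenitors share a common
homozygous allele, outgroup introgressions concentrated ("hotspots") in
designated linkage-map intervals for cultivars of a target growth habit,
missing data, and per-allele read depths from an overdispersed
(negative-binomial) coverage law with a symmetric binomial allele split and
uniform miscalls.

Every locus sits on its own synthetic scaffold carrying one transcript and
one map marker, so the map-projection stages are exercised end to end.
A single seed drives all randomness through one named generator; identical
configurations reproduce identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel, Habit, Role, Sample, SnpLocus
from .io import MAX_ALLELES, TranscriptAnchor
from .linkage import LinkageMap

_BASES = np.array(list("ACGT"))

#: internal allele codes before VCF compression
#: 0 = progenitor-A primary (reference), 1 = progenitor-B primary,
#: 2/3 = secondary (het) progenitor alleles or outgroup alleles
_TRUTH_LABELS = {0: "ax", 1: "int", 2: "shared", 3: "out", -1: "missing"}


@dataclass(frozen=True)
class CultivarSpec:
    """Origin proportions of one simulated cultivar's allele copies."""

    sample_id: str
    habit: Habit
    p_ax: float
    p_int: float
    p_out: float

    def __post_init__(self) -> None:
        probs = (self.p_ax, self.p_int, self.p_out)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"cultivar {self.sample_id!r}: (p_ax, p_int, p_out) must be a "
                f"probability vector, got {probs}"
            )


@dataclass(frozen=True)
class Hotspot:
    """Map interval where outgroup alleles are enriched for one habit group."""

    linkage_group: str
    cm_start: float
    cm_end: float
    out_multiplier: float = 10.0
    target_habit: Habit = Habit.TRAILING


def _default_cultivars() -> tuple[CultivarSpec, ...]:
    # three trailing cultivars rich in progenitor-B and outgroup alleles,
    # three upright cultivars dominated by the reference progenitor
    t, u = Habit.TRAILING, Habit.UPRIGHT
    return (
        CultivarSpec("trail1", t, 0.45, 0.45, 0.10),
        CultivarSpec("trail2", t, 0.47, 0.43, 0.10),
        CultivarSpec("trail3", t, 0.50, 0.43, 0.07),
        CultivarSpec("upright1", u, 0.65, 0.31, 0.04),
        CultivarSpec("upright2", u, 0.68, 0.29, 0.03),
        CultivarSpec("upright3", u, 0.62, 0.34, 0.04),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-simulation parameters.

    Defaults mirror the structure of a cultivated-petunia transcriptome
    panel: a nearly homozygous reference progenitor and a highly
    heterozygous second progenitor (het rate 0.593), roughly a third of
    loci progenitor-monomorphic, and trailing cultivars carrying more
    progenitor-B and outgroup alleles than upright ones.
    """

    n_transcripts: int = 400
    snps_per_transcript_mean: float = 5.0
    het_ax: float = 0.08
    het_int: float = 0.593
    shared_allele_prob: float = 0.35
    cultivars: tuple[CultivarSpec, ...] = field(default_factory=_default_cultivars)
    hotspots: tuple[Hotspot, ...] = ()
    missing_rate: float = 0.05
    depth_mean: float = 20.0
    depth_dispersion: float = 2.0
    error_rate: float = 0.005
    n_linkage_groups: int = 7
    lg_length_cm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_ax", "het_int", "shared_allele_prob", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_transcripts < 1 or self.snps_per_transcript_mean <= 0:
            raise ValueError("need at least one transcript and a positive SNP rate")
        if not self.cultivars:
            raise ValueError("need at least one cultivar")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated panel.

    ``origins`` holds, per (locus, cultivar, allele copy), the origin code
    (0 ax, 1 int, 2 shared, 3 out, -1 missing).  ``polymorphic`` flags loci
    where the progenitor allele sets differ; ``hotspot_index`` maps each
    locus to the hotspot containing it (-1 outside).
    """

    cultivar_ids: list[str]
    origins: np.ndarray  # (n_loci, n_cultivars, 2) int8
    polymorphic: np.ndarray  # (n_loci,) bool
    hotspot_index: np.ndarray  # (n_loci,) int32
    loci: list[SnpLocus]

    def origin_fractions(self, sample_id: str) -> dict[str, float]:
        """Realised origin fractions over the non-missing copies of a cultivar."""
        j = self.cultivar_ids.index(sample_id)
        o = self.origins[:, j].ravel()
        o = o[o >= 0]
        return {lab: float((o == code).sum()) / o.size for code, lab in _TRUTH_LABELS.items() if code >= 0}

    def to_frame(self) -> pd.DataFrame:
        n, m, _ = self.origins.shape
        rows = {
            "transcript_id": np.repeat([l.transcript_id for l in self.loci], m * 2),
            "pos": np.repeat([l.pos for l in self.loci], m * 2),
            "sample_id": np.tile(np.repeat(self.cultivar_ids, 2), n),
            "copy": np.tile([0, 1], n * m),
            "origin": [
                _TRUTH_LABELS[int(v)] for v in self.origins.reshape(-1)
            ],
            "polymorphic": np.repeat(self.polymorphic.astype(int), m * 2),
            "hotspot_index": np.repeat(self.hotspot_index, m * 2),
        }
        return pd.DataFrame(rows)


@dataclass
class SimulatedPanelBundle:
    panel: GenotypePanel
    linkage_map: LinkageMap
    anchors: list[TranscriptAnchor]
    truth: SimulationTruth
    config: SimulationConfig


def simulate_panel(config: SimulationConfig) -> SimulatedPanelBundle:
    """Simulate a genotype panel, its map/anchors and the origin ground truth."""
    rng = np.random.default_rng(config.seed)

    # ---------------------------------------------------------- map geometry
    n_t = config.n_transcripts
    snps_per = 1 + rng.poisson(max(config.snps_per_transcript_mean - 1.0, 0.0), size=n_t)
    n = int(snps_per.sum())
    tr_of_locus = np.repeat(np.arange(n_t), snps_per)
    lgs = [f"LG{k + 1}" for k in range(config.n_linkage_groups)]
    tr_lg = rng.integers(0, config.n_linkage_groups, size=n_t)
    tr_cm = np.round(rng.uniform(0.0, config.lg_length_cm, size=n_t), 4)
    tr_len = 1000 * snps_per + 1000
    snp_offsets = np.concatenate([np.sort(rng.choice(np.arange(1, L), size=k, replace=False))
                                  for k, L in zip(snps_per, tr_len)])

    anchors = [
        TranscriptAnchor(f"t{i:05d}", f"scf{i:05d}", 1, int(tr_len[i])) for i in range(n_t)
    ]
    lmap = LinkageMap.from_frame(
        pd.DataFrame(
            {
                "marker": [f"m{i:05d}" for i in range(n_t)],
                "linkage_group": [lgs[k] for k in tr_lg],
                "cM": tr_cm,
                "scaffold": [f"scf{i:05d}" for i in range(n_t)],
                "scaffold_pos": (tr_len // 2).astype(int),
            }
        )
    )

    # ------------------------------------------------------ progenitor draws
    shared = rng.random(n) < config.shared_allele_prob
    ax_het = ~shared & (rng.random(n) < config.het_ax)
    int_het = ~shared & (rng.random(n) < config.het_int)
    # internal codes: ax = {0} (+2 if het); int = {1, second}; shared loci:
    # both progenitors hom 0.  Half of progenitor-B het sites pair the B
    # allele with the reference allele (as transcriptome SNPs against a
    # progenitor-A-derived reference typically do), the rest with a third
    # nucleotide.
    int_ref = int_het & (rng.random(n) < 0.5)
    int_novel = int_het & ~int_ref
    int2_code = np.select([int_ref, int_novel & ax_het], [0, 3], default=2)
    ax_calls = np.stack([np.zeros(n, int), np.where(ax_het, 2, 0)], axis=1)
    int_calls = np.where(
        shared[:, None],
        0,
        np.stack([np.ones(n, int), np.where(int_het, int2_code, 1)], axis=1),
    )

    # out-allele pools per locus (codes unused by the progenitors)
    code2_used = ax_het | (int_novel & ~ax_het)
    code3_used = int_novel & ax_het
    pool = np.zeros((n, 3), dtype=np.int64)
    pool_size = np.zeros(n, dtype=np.int64)
    pool[shared] = [1, 2, 3]
    pool_size[shared] = 3
    poly = ~shared
    both_free = poly & ~code2_used & ~code3_used
    pool[both_free, 0], pool[both_free, 1], pool_size[both_free] = 2, 3, 2
    only3 = poly & code2_used & ~code3_used
    pool[only3, 0], pool_size[only3] = 3, 1
    # code2_used & code3_used -> pool empty (all four codes taken)

    # ------------------------------------------------------- cultivar draws
    habit_of = {c.sample_id: c.habit for c in config.cultivars}
    hot_idx = np.full(n, -1, dtype=np.int32)
    locus_lg = tr_lg[tr_of_locus]
    locus_cm = tr_cm[tr_of_locus]
    for h_i, h in enumerate(config.hotspots):
        lg_k = lgs.index(h.linkage_group)
        inside = (locus_lg == lg_k) & (locus_cm >= h.cm_start) & (locus_cm <= h.cm_end)
        hot_idx[inside] = h_i

    m = len(config.cultivars)
    calls = np.zeros((n, 2 + m, 2), dtype=np.int64)
    calls[:, 0] = ax_calls
    calls[:, 1] = int_calls
    origins = np.zeros((n, m, 2), dtype=np.int8)

    for j, cult in enumerate(config.cultivars):
        p_out = np.full(n, cult.p_out)
        for h_i, h in enumerate(config.hotspots):
            if h.target_habit is cult.habit:
                boost = hot_idx == h_i
                p_out[boost] = np.minimum(cult.p_out * h.out_multiplier, 0.9)
        denom = cult.p_ax + cult.p_int
        p_ax = (1.0 - p_out) * (cult.p_ax / denom if denom > 0 else 0.0)
        p_int_ = (1.0 - p_out) * (cult.p_int / denom if denom > 0 else 0.0)
        for k in (0, 1):
            u = rng.random(n)
            origin = np.select([u < p_ax, u < p_ax + p_int_], [0, 1], default=2)
            # out draw impossible where the progenitors exhaust all four
            # nucleotides; fall back to a progenitor origin
            blocked = (origin == 2) & (pool_size == 0)
            origin[blocked] = np.where(
                rng.random(int(blocked.sum())) < (cult.p_ax / denom if denom > 0 else 0.5),
                0,
                1,
            )
            # realised allele per copy
            allele = np.zeros(n, dtype=np.int64)
            is_ax = origin == 0
            allele[is_ax] = np.where(
                ax_het[is_ax] & (rng.random(int(is_ax.sum())) < 0.5), 2, 0
            )
            is_int = origin == 1
            int_second = int_calls[:, 1]
            allele[is_int] = np.where(
                shared[is_int],
                0,
                np.where(
                    int_het[is_int] & (rng.random(int(is_int.sum())) < 0.5),
                    int_second[is_int],
                    1,
                ),
            )
            is_out = origin == 2
            pick = rng.integers(0, np.maximum(pool_size[is_out], 1))
            allele[is_out] = pool[is_out, pick]
            calls[:, 2 + j, k] = allele
            # truth labels: progenitor draws at shared loci are 'shared'
            truth = origin.copy()
            truth[is_out] = 3
            truth[(origin <= 1) & shared] = 2
            origins[:, j, k] = truth

    # ------------------------------------------------------------- missing
    if config.missing_rate > 0:
        miss = rng.random((n, 2 + m)) < config.missing_rate
        calls[miss] = -1
        origins[miss[:, 2:]] = -1

    # ------------------------------------------- VCF allele-space compression
    # observed allele codes per locus; REF is always code 0
    present = np.zeros((n, 4), dtype=bool)
    present[:, 0] = True
    flat = calls.reshape(n, -1)
    for code in (1, 2, 3):
        present[:, code] = (flat == code).any(axis=1)
    # guarantee a non-empty ALT list: expose the progenitor-B allele (or the
    # first pool allele at monomorphic loci) even when no sample carries it
    none_alt = ~present[:, 1:].any(axis=1)
    first_alt = np.where(shared, pool[:, 0], int_calls[:, 0])
    present[np.flatnonzero(none_alt), first_alt[none_alt]] = True
    vcf_index = np.cumsum(present, axis=1) - 1  # code -> VCF allele index

    comp = np.where(flat >= 0, np.take_along_axis(
        np.repeat(vcf_index, 1, axis=0), np.maximum(flat, 0), axis=1), -1)
    comp_calls = comp.reshape(n, 2 + m, 2)

    # nucleotide assignment: per-locus random permutation of ACGT over codes
    perms = np.argsort(rng.random((n, 4)), axis=1)
    base_of_code = _BASES[perms]

    samples = [
        Sample("prog_ax", Role.PROGENITOR_A),
        Sample("prog_int", Role.PROGENITOR_B),
    ] + [Sample(c.sample_id, Role.CULTIVAR, c.habit) for c in config.cultivars]

    loci: list[SnpLocus] = []
    for i in range(n):
        codes = np.flatnonzero(present[i])
        alleles = tuple(base_of_code[i, c] for c in codes)
        loci.append(
            SnpLocus(
                transcript_id=f"t{tr_of_locus[i]:05d}",
                pos=int(snp_offsets[i]),
                ref_allele=alleles[0],
                alt_alleles=alleles[1:],
                scaffold=f"scf{tr_of_locus[i]:05d}",
                scaffold_pos=int(snp_offsets[i]),
            )
        )

    panel = GenotypePanel(
        loci=loci, samples=samples, calls=comp_calls.astype(np.int8)
    )
    truth = SimulationTruth(
        cultivar_ids=[c.sample_id for c in config.cultivars],
        origins=origins,
        polymorphic=poly,
        hotspot_index=hot_idx,
        loci=loci,
    )
    return SimulatedPanelBundle(panel=panel, linkage_map=lmap, anchors=anchors,
                                truth=truth, config=config)


def simulate_depths(
    panel: GenotypePanel, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypePanel:
    """Attach negative-binomial read depths consistent with the true calls.

    Total depth per cell ~ NB(mean ``depth_mean``, dispersion
    ``depth_dispersion``); reads split between the two true alleles by a
    symmetric binomial; each read miscalls to a uniformly chosen other
    allele of the locus with probability ``error_rate``.  Missing true calls
    yield zero reads.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, m = panel.n_loci, panel.n_samples
    r = config.depth_dispersion
    p_nb = r / (r + config.depth_mean)
    total = rng.negative_binomial(r, p_nb, size=(n, m))
    called = panel.calls[..., 0] >= 0
    total = np.where(called, total, 0)
    a1 = np.maximum(panel.calls[..., 0], 0).astype(np.int64)
    a2 = np.maximum(panel.calls[..., 1], 0).astype(np.int64)
    het = called & (a1 != a2)
    reads_a2 = np.where(het, rng.binomial(total, 0.5), 0)
    reads_a1 = total - reads_a2
    depths = np.zeros((n, m, MAX_ALLELES), dtype=np.int32)
    rows = np.repeat(np.arange(n), m)
    cols = np.tile(np.arange(m), n)
    np.add.at(depths, (rows, cols, a1.ravel()), reads_a1.ravel())
    np.add.at(depths, (rows, cols, a2.ravel()), reads_a2.ravel())
    if config.error_rate > 0:
        n_alleles = np.array([len(l.alleles) for l in panel.loci])
        err_able = n_alleles[:, None] > 1
        n_err = rng.binomial(total, config.error_rate) * err_able
        # move miscalled reads from their true allele to a uniform other one
        it = np.argwhere(n_err > 0)
        for i, j in it:
            k = int(n_err[i, j])
            na = int(n_alleles[i])
            src = rng.integers(0, 2, size=k)
            src_alleles = np.where(src == 0, a1[i, j], a2[i, j])
            shift = rng.integers(1, na, size=k)
            dst = (src_alleles + shift) % na
            for s, d in zip(src_alleles, dst):
                if depths[i, j, s] > 0:
                    depths[i, j, s] -= 1
                    depths[i, j, d] += 1
    return GenotypePanel(
        loci=list(panel.loci), samples=list(panel.samples), calls=panel.calls.copy(),
        depths=depths,
    )


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the per-copy origin truth as a long-format TSV."""
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
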