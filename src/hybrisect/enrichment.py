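"""Phenotype-group contrasts: category enrichment and introgression tracks.

Two cultivar groups (e.g. trailing vs upright growth habit) are contrasted:
loci polymorphic between the groups are dissected into the 12 origin
categories and each category's proportion in the subset is compared with its
proportion in the whole panel.  Outgroup-derived ("out") alleles -- and in
particular category 7, the shared-progenitor-allele/novel-allele
heterozygote -- are counted along the linkage map to locate introgression
hotspots associated with one phenotype group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ancestry import classify_sample
from .core import OUT_CATEGORIES, Category, GenotypePanel, Role
from .linkage import TranscriptPlacement


@dataclass(frozen=True)
class GroupContrast:
    """Two disjoint, non-empty cultivar groups to contrast."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both contrast groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")

    def validate(self, panel: GenotypePanel) -> None:
        for sid in self.group_a + self.group_b:
            if panel.sample(sid).role is not Role.CULTIVAR:
                raise ValueError(f"contrast sample {sid!r} is not a cultivar")


def _group_codes(panel: GenotypePanel, ids: Sequence[str]) -> np.ndarray:
    codes = panel.call_codes()
    cols = [panel.sample_index(s) for s in ids]
    return codes[:, cols]


def between_group_polymorphic(panel: GenotypePanel, contrast: GroupContrast) -> np.ndarray:
    """Mask of loci where some cross-group pair has differing non-missing calls.

    Equivalent to: both groups have a called member, and the called genotypes
    across the union of both groups are not all identical restricted to some
    cross pair -- i.e. at least two distinct called genotypes exist once both
    groups are represented (any two distinct values yield a differing cross
    pair).
    """
    contrast.validate(panel)
    ca = _group_codes(panel, contrast.group_a)
    cb = _group_codes(panel, contrast.group_b)
    has_a = (ca >= 0).any(axis=1)
    has_b = (cb >= 0).any(axis=1)
    both = np.concatenate([ca, cb], axis=1)
    masked = np.where(both >= 0, both, np.iinfo(np.int16).max)
    mn = masked.min(axis=1)
    mx = np.where(both >= 0, both, -1).max(axis=1)
    return has_a & has_b & (mn != mx)


def fixed_difference_loci(panel: GenotypePanel, contrast: GroupContrast) -> np.ndarray:
    """Mask of loci monomorphic within each group but differing between them.

    All group members must be called; a missing call breaks within-group
    monomorphism.
    """
    contrast.validate(panel)
    ca = _group_codes(panel, contrast.group_a)
    cb = _group_codes(panel, contrast.group_b)
    mono_a = (ca[:, :1] == ca).all(axis=1) & (ca[:, 0] >= 0)
    mono_b = (cb[:, :1] == cb).all(axis=1) & (cb[:, 0] >= 0)
    return mono_a & mono_b & (ca[:, 0] != cb[:, 0])


@dataclass
class EnrichmentReport:
    """Per-cultivar and group-level category proportions, subset vs whole."""

    per_sample: pd.DataFrame  # sample_id, group, category, n_subset, n_whole,
    #                           proportion_in_subset, proportion_in_whole, ratio
    group_summary: pd.DataFrame  # group, category, proportion_in_subset,
    #                              proportion_in_whole, ratio (means over members)


def category_enrichment(
    panel: GenotypePanel,
    contrast: GroupContrast,
    subset: np.ndarray,
    mode: str = "strict",
) -> EnrichmentReport:
    """Compare category proportions inside a locus subset against the whole panel."""
    subset = np.asarray(subset)
    if subset.dtype != bool:
        m = np.zeros(panel.n_loci, dtype=bool)
        m[subset] = True
        subset = m
    n_sub = int(subset.sum())
    if n_sub == 0:
        raise ValueError("empty locus subset")
    rows = []
    for group, ids in (("A", contrast.group_a), ("B", contrast.group_b)):
        for sid in ids:
            cats = classify_sample(panel, sid, mode=mode)
            for cat in Category:
                hit = cats == int(cat)
                ns, nw = int(hit[subset].sum()), int(hit.sum())
                p_sub = ns / n_sub
                p_whole = nw / panel.n_loci
                rows.append(
                    {
                        "sample_id": sid,
                        "group": group,
                        "category": int(cat),
                        "label": cat.name,
                        "n_subset": ns,
                        "n_whole": nw,
                        "proportion_in_subset": p_sub,
                        "proportion_in_whole": p_whole,
                        "ratio": p_sub / p_whole if p_whole > 0 else 0.0,
                    }
                )
    per_sample = pd.DataFrame(rows)
    group_summary = (
        per_sample.groupby(["group", "category", "label"], as_index=False)[
            ["proportion_in_subset", "proportion_in_whole", "ratio"]
        ]
        .mean()
        .sort_values(["group", "category"])
        .reset_index(drop=True)
    )
    return EnrichmentReport(per_sample=per_sample, group_summary=group_summary)


def permutation_pvalue(
    panel: GenotypePanel,
    contrast: GroupContrast,
    category: Category = Category.SHARED_OUT_HET,
    n_permutations: int = 200,
    seed: int = 0,
    mode: str = "strict",
) -> float:
    """Permutation-of-group-labels p-value for a category's group-A enrichment.

    Goes beyond the descriptive proportions of the core analysis; offered as
    an optional significance check.
    """
    ids = list(contrast.group_a) + list(contrast.group_b)
    k = len(contrast.group_a)
    rng = np.random.default_rng(seed)

    def ratio_for(a_ids: Sequence[str], b_ids: Sequence[str]) -> float:
        c = GroupContrast(tuple(a_ids), tuple(b_ids))
        sub = between_group_polymorphic(panel, c)
        if not sub.any():
            return 1.0
        rep = category_enrichment(panel, c, sub, mode=mode)
        g = rep.group_summary
        row = g[(g["group"] == "A") & (g["category"] == int(category))]
        return float(row["ratio"].iloc[0])

    observed = ratio_for(contrast.group_a, contrast.group_b)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ids)
        if ratio_for(perm[:k], perm[k:]) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def cat7_only_transcripts(
    panel: GenotypePanel, contrast: GroupContrast, mode: str = "strict"
) -> set[str]:
    """Transcripts with category-7 SNPs in every group-A cultivar and none in group B."""
    contrast.validate(panel)
    tids = np.array([l.transcript_id for l in panel.loci])
    all_tids = set(tids)
    required: Optional[set[str]] = None
    for sid in contrast.group_a:
        cats = classify_sample(panel, sid, mode=mode)
        has7 = set(tids[cats == int(Category.SHARED_OUT_HET)])
        required = has7 if required is None else required & has7
    assert required is not None
    for sid in contrast.group_b:
        cats = classify_sample(panel, sid, mode=mode)
        required -= set(tids[cats == int(Category.SHARED_OUT_HET)])
    return required & all_tids


@dataclass
class IntrogressionTrack:
    """Per-position out-allele and category-7 SNP counts along the map."""

    entries: pd.DataFrame  # track_id, linkage_group, cM, n_out_snps, n_cat7_snps


def introgression_track(
    panel: GenotypePanel,
    contrast: GroupContrast,
    placements: Sequence[TranscriptPlacement],
    mode: str = "strict",
) -> IntrogressionTrack:
    """Count out-category and category-7 SNPs per placed map position.

    Tracks are emitted per cultivar of the contrast plus pooled group tracks
    (``group_A``/``group_B``, summed member counts), restricted to loci
    polymorphic between the groups.
    """
    contrast.validate(panel)
    poly = between_group_polymorphic(panel, contrast)
    tids = np.array([l.transcript_id for l in panel.loci])
    out_codes = np.array(sorted(int(c) for c in OUT_CATEGORIES))
    place_by_tid: dict[str, list[TranscriptPlacement]] = {}
    for p in placements:
        place_by_tid.setdefault(p.transcript_id, []).append(p)

    def track_rows(track_id: str, n_out_by_tid: dict, n_cat7_by_tid: dict) -> list[dict]:
        agg: dict[tuple[str, float], list[int]] = {}
        for tid, plist in place_by_tid.items():
            n_out = n_out_by_tid.get(tid, 0)
            n7 = n_cat7_by_tid.get(tid, 0)
            if n_out == 0:
                continue
            for p in plist:
                key = (p.linkage_group, p.cM)
                cur = agg.setdefault(key, [0, 0])
                cur[0] += n_out
                cur[1] += n7
        return [
            {
                "track_id": track_id,
                "linkage_group": lg,
                "cM": cm,
                "n_out_snps": v[0],
                "n_cat7_snps": v[1],
            }
            for (lg, cm), v in sorted(agg.items())
        ]

    rows: list[dict] = []
    group_counts = {"group_A": ({}, {}), "group_B": ({}, {})}
    for group, ids in (("group_A", contrast.group_a), ("group_B", contrast.group_b)):
        for sid in ids:
            cats = classify_sample(panel, sid, mode=mode)
            is_out = poly & np.isin(cats, out_codes)
            is_7 = poly & (cats == int(Category.SHARED_OUT_HET))
            n_out_by_tid = {str(k): int(v) for k, v in zip(*np.unique(tids[is_out], return_counts=True))}
            n7_by_tid = {str(k): int(v) for k, v in zip(*np.unique(tids[is_7], return_counts=True))}
            rows.extend(track_rows(sid, n_out_by_tid, n7_by_tid))
            g_out, g7 = group_counts[group]
            for tid, n in n_out_by_tid.items():
                g_out[tid] = g_out.get(tid, 0) + n
            for tid, n in n7_by_tid.items():
                g7[tid] = g7.get(tid, 0) + n
    for group in ("group_A", "group_B"):
        g_out, g7 = group_counts[group]
        rows.extend(track_rows(group, g_out, g7))
    entries = pd.DataFrame(
        rows, columns=["track_id", "linkage_group", "cM", "n_out_snps", "n_cat7_snps"]
    )
    return IntrogressionTrack(entries=entries)
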