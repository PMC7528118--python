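"""Projection of per-transcript progenitor-A similarity onto a linkage map.

Transcripts carry SNPs in transcript coordinates; a genetic map carries
markers with linkage-group/cM positions anchored to genomic scaffolds.  A
transcript is placed at every map marker falling inside one of its genomic
anchors; placements on the same linkage group within a small radius
(default 1 cM) are merged to their mean position, while distant placements
(e.g. >20 cM apart) are all retained.  Each cultivar's per-SNP
similarity-with-progenitor-A rate (from its genotype category) is then
averaged per transcript and aggregated per placed position, skipping
low-recombination map intervals where sparse markers would bias the
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ancestry import classify_sample
from .core import SIMILARITY_RATES, Category, GenotypePanel
from .io import TranscriptAnchor


@dataclass
class LinkageMap:
    """Genetic map: markers with linkage group, cM and scaffold anchors."""

    markers: pd.DataFrame  # columns: marker, linkage_group, cM, scaffold, scaffold_pos

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkageMap":
        if (df["cM"] < 0).any():
            bad = df.loc[df["cM"] < 0, "marker"].iloc[0]
            raise ValueError(f"negative cM for marker {bad!r}")
        if df["marker"].duplicated().any():
            bad = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name {bad!r}")
        df = df.sort_values(["linkage_group", "cM"], kind="mergesort").reset_index(drop=True)
        return cls(markers=df)

    @property
    def linkage_groups(self) -> list[str]:
        return list(dict.fromkeys(self.markers["linkage_group"]))

    def span(self, linkage_group: str) -> float:
        cm = self.markers.loc[self.markers["linkage_group"] == linkage_group, "cM"]
        return float(cm.max() - cm.min())


@dataclass(frozen=True)
class TranscriptPlacement:
    transcript_id: str
    linkage_group: str
    cM: float
    supporting_markers: tuple[str, ...]


def place_transcripts(
    lmap: LinkageMap,
    anchors: Iterable[TranscriptAnchor],
    merge_radius_cm: float = 1.0,
) -> list[TranscriptPlacement]:
    """Place transcripts on the map via markers inside their genomic anchors.

    Per transcript and linkage group, marker hits are merged by
    single-linkage clustering at ``merge_radius_cm`` (merged position = mean
    cM of the cluster); clusters further apart are retained as separate
    placements.
    """
    by_scaffold: dict[str, pd.DataFrame] = {
        str(s): g.sort_values("scaffold_pos") for s, g in lmap.markers.groupby("scaffold")
    }
    hits: dict[str, list[tuple[str, float, str]]] = {}
    for a in anchors:
        g = by_scaffold.get(a.scaffold)
        if g is None:
            continue
        pos = g["scaffold_pos"].to_numpy()
        lo = np.searchsorted(pos, a.start, side="left")
        hi = np.searchsorted(pos, a.end, side="right")
        for _, row in g.iloc[lo:hi].iterrows():
            hits.setdefault(a.transcript_id, []).append(
                (str(row["linkage_group"]), float(row["cM"]), str(row["marker"]))
            )
    placements: list[TranscriptPlacement] = []
    for tid in sorted(hits):
        by_lg: dict[str, list[tuple[float, str]]] = {}
        for lg, cm, marker in hits[tid]:
            by_lg.setdefault(lg, []).append((cm, marker))
        for lg in sorted(by_lg):
            entries = sorted(set(by_lg[lg]))
            cluster: list[tuple[float, str]] = []
            for cm, marker in entries:
                if cluster and cm - cluster[-1][0] > merge_radius_cm:
                    placements.append(_mk_placement(tid, lg, cluster))
                    cluster = []
                cluster.append((cm, marker))
            if cluster:
                placements.append(_mk_placement(tid, lg, cluster))
    return placements


def _mk_placement(tid: str, lg: str, cluster: list[tuple[float, str]]) -> TranscriptPlacement:
    cms = [c for c, _ in cluster]
    return TranscriptPlacement(
        transcript_id=tid,
        linkage_group=lg,
        cM=float(np.mean(cms)),
        supporting_markers=tuple(m for _, m in cluster),
    )


def transcript_similarity(
    panel: GenotypePanel,
    sample_id: str,
    transcript_id: str,
    rates: Mapping[Category, Optional[float]] = SIMILARITY_RATES,
    mode: str = "strict",
) -> float:
    """Mean per-SNP similarity-with-progenitor-A over one transcript.

    Raises if the transcript has no classifiable SNP for the sample (such
    transcripts are skipped in track building).
    """
    cats = classify_sample(panel, sample_id, mode=mode)
    vals = [
        rates[Category(int(c))]
        for l, c in zip(panel.loci, cats)
        if l.transcript_id == transcript_id and rates[Category(int(c))] is not None
    ]
    if not vals:
        raise ValueError(f"no classifiable SNPs on {transcript_id!r} for {sample_id!r}")
    return float(np.mean(vals))


@dataclass
class SimilarityTrack:
    """Per-position mean similarity with progenitor A for one sample."""

    sample_id: str
    entries: pd.DataFrame  # columns: linkage_group, cM, similarity, n_snps


def low_recombination_mask(
    lmap: LinkageMap, gap_cm: float = 5.0, min_markers: int = 2
) -> list[tuple[str, float, float]]:
    """Intervals of the map with sparse marker coverage, to omit from tracks.

    A gap between consecutive markers of one linkage group wider than
    ``gap_cm`` with fewer than ``min_markers`` markers strictly inside is
    masked (with a plain marker list consecutive gaps contain none, so the
    gap width is the operative criterion).
    """
    out: list[tuple[str, float, float]] = []
    for lg, g in lmap.markers.groupby("linkage_group", sort=True):
        cms = np.unique(g["cM"].to_numpy())
        for a, b in zip(cms[:-1], cms[1:]):
            if b - a > gap_cm and 0 < min_markers:
                out.append((str(lg), float(a), float(b)))
    return out


def _in_mask(lg: str, cm: float, mask: Sequence[tuple[str, float, float]]) -> bool:
    return any(m_lg == lg and lo < cm < hi for m_lg, lo, hi in mask)


def similarity_track(
    panel: GenotypePanel,
    sample_id: str,
    placements: Sequence[TranscriptPlacement],
    rates: Mapping[Category, Optional[float]] = SIMILARITY_RATES,
    mask: Sequence[tuple[str, float, float]] = (),
    mode: str = "strict",
) -> SimilarityTrack:
    """SNP-weighted similarity per placed map position for one sample.

    Every classifiable SNP on every transcript placed at a position
    contributes its per-category rate; the entry value is the mean over
    SNPs (per-SNP, not per-transcript, weighting).  Positions inside masked
    intervals are omitted, as are positions with no classifiable SNP.
    """
    cats = classify_sample(panel, sample_id, mode=mode)
    rate_arr = np.array(
        [np.nan if rates[Category(c)] is None else rates[Category(c)] for c in range(1, 13)]
    )
    snp_rates = rate_arr[cats - 1]
    tids = np.array([l.transcript_id for l in panel.loci])
    per_transcript: dict[str, tuple[float, int]] = {}
    order = np.argsort(tids, kind="mergesort")
    sorted_tids = tids[order]
    sorted_rates = snp_rates[order]
    bounds = np.flatnonzero(np.r_[True, sorted_tids[1:] != sorted_tids[:-1], True])
    for s, e in zip(bounds[:-1], bounds[1:]):
        vals = sorted_rates[s:e]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            per_transcript[str(sorted_tids[s])] = (float(vals.sum()), int(vals.size))
    rows = []
    agg: dict[tuple[str, float], tuple[float, int]] = {}
    for p in placements:
        if p.transcript_id not in per_transcript:
            continue
        if _in_mask(p.linkage_group, p.cM, mask):
            continue
        tot, n = per_transcript[p.transcript_id]
        key = (p.linkage_group, p.cM)
        t0, n0 = agg.get(key, (0.0, 0))
        agg[key] = (t0 + tot, n0 + n)
    for (lg, cm), (tot, n) in sorted(agg.items()):
        rows.append({"linkage_group": lg, "cM": cm, "similarity": tot / n, "n_snps": n})
    entries = pd.DataFrame(rows, columns=["linkage_group", "cM", "similarity", "n_snps"])
    return SimilarityTrack(sample_id=sample_id, entries=entries)
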