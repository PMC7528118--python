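"""End-to-end pipeline: recall -> filters -> diversity, ancestry, map tracks.

A :class:`RunConfig` names the inputs, thresholds, dataset choice, models and
optional contrast groups; :func:`run_full_pipeline` executes the stages in
order, logs surviving locus counts per stage, and writes deterministic TSV
reports plus a JSON run manifest carrying the effective configuration and
its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import MODELS, Category, category_profile
from .core import GenotypePanel, Role
from .diversity import heterozygosity, pairwise_snp_counts
from .enrichment import (
    GroupContrast,
    between_group_polymorphic,
    cat7_only_transcripts,
    category_enrichment,
    introgression_track,
)
from .io import read_linkage_map, read_panel, read_transcript_anchors, write_panel_vcf
from .linkage import low_recombination_mask, place_transcripts, similarity_track
from .recall import RecallThresholds, filter_informative, recall_panel, subset_no_missing

log = logging.getLogger("hybrisect")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    vcf: str
    manifest: str
    out_prefix: str
    linkage_map: Optional[str] = None
    anchors: Optional[str] = None
    thresholds: RecallThresholds = field(default_factory=RecallThresholds)
    recall: bool = True
    dataset: str = "entire"  # "entire" or "no_missing"
    models: tuple[str, ...] = ("approach1_alleles", "pure_parents", "exact_parents")
    group_a: tuple[str, ...] = ()
    group_b: tuple[str, ...] = ()
    classify_mode: str = "strict"
    merge_radius_cm: float = 1.0
    mask_gap_cm: float = 5.0
    seed: int = 0
    log_level: str = "INFO"

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def prepare_panel(config: RunConfig) -> GenotypePanel:
    """Load, optionally re-call, and filter the panel per the configuration."""
    panel = read_panel(config.vcf, config.manifest)
    log.info("loaded %d loci x %d samples", panel.n_loci, panel.n_samples)
    if config.recall and panel.depths is not None:
        panel = recall_panel(panel, config.thresholds)
        log.info("re-called genotypes from allele depths")
    panel = filter_informative(panel)
    log.info("informative loci (entire dataset): %d", panel.n_loci)
    if config.dataset == "no_missing":
        panel = subset_no_missing(panel)
        log.info("no-missing loci: %d", panel.n_loci)
    return panel


def run_full_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns the output paths."""
    logging.basicConfig(level=config.log_level)
    out_prefix = Path(config.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    panel = prepare_panel(config)
    non_prog = [
        s.sample_id
        for s in panel.samples
        if s.role not in (Role.PROGENITOR_A, Role.PROGENITOR_B)
    ]

    # ---- diversity -------------------------------------------------------
    het_rows = [
        {
            "sample_id": s.sample_id,
            "dataset": config.dataset,
            "n_het": (r := heterozygosity(panel, s.sample_id, config.dataset)).n_het,
            "n_total": r.n_total,
            "rate": r.rate,
        }
        for s in panel.samples
    ]
    p = out_prefix.with_name(out_prefix.name + ".heterozygosity.tsv")
    _write_tsv(pd.DataFrame(het_rows), p)
    outputs["heterozygosity"] = p

    matrix = pairwise_snp_counts(panel)
    p = out_prefix.with_name(out_prefix.name + ".pairwise_snps.tsv")
    matrix.to_frame().to_csv(p, sep="\t")
    outputs["pairwise_snps"] = p

    # ---- ancestry --------------------------------------------------------
    prof_rows = []
    for sid in non_prog:
        prof = category_profile(panel, sid, mode=config.classify_mode)
        for cat in Category:
            prof_rows.append(
                {
                    "sample_id": sid,
                    "category": int(cat),
                    "label": cat.name,
                    "count": prof.counts.get(cat, 0),
                    "proportion": prof.proportions[cat],
                }
            )
    p = out_prefix.with_name(out_prefix.name + ".category_profiles.tsv")
    _write_tsv(pd.DataFrame(prof_rows), p)
    outputs["category_profiles"] = p

    est_rows = []
    for sid in (s.sample_id for s in panel.cultivars):
        for model in config.models:
            est = MODELS[model](panel, sid)
            row = {"sample_id": sid, "model": model, **est.as_dict()}
            row.update(est.extras)
            est_rows.append(row)
    p = out_prefix.with_name(out_prefix.name + ".ancestry.tsv")
    _write_tsv(pd.DataFrame(est_rows), p)
    outputs["ancestry"] = p

    # ---- map projection --------------------------------------------------
    placements = None
    if config.linkage_map and config.anchors:
        lmap = read_linkage_map(config.linkage_map)
        anchors = read_transcript_anchors(config.anchors)
        placements = place_transcripts(lmap, anchors, config.merge_radius_cm)
        mask = low_recombination_mask(lmap, gap_cm=config.mask_gap_cm)
        log.info("placed transcripts: %d placements", len(placements))
        track_rows = []
        for sid in non_prog:
            tr = similarity_track(
                panel, sid, placements, mask=mask, mode=config.classify_mode
            )
            df = tr.entries.copy()
            df.insert(0, "sample_id", sid)
            track_rows.append(df)
        p = out_prefix.with_name(out_prefix.name + ".similarity_track.tsv")
        _write_tsv(pd.concat(track_rows, ignore_index=True), p)
        outputs["similarity_track"] = p

    # ---- habit contrast --------------------------------------------------
    if config.group_a and config.group_b:
        contrast = GroupContrast(tuple(config.group_a), tuple(config.group_b))
        subset = between_group_polymorphic(panel, contrast)
        log.info("between-group polymorphic loci: %d", int(subset.sum()))
        report = category_enrichment(panel, contrast, subset, mode=config.classify_mode)
        p = out_prefix.with_name(out_prefix.name + ".enrichment.tsv")
        _write_tsv(report.per_sample, p)
        outputs["enrichment"] = p
        p = out_prefix.with_name(out_prefix.name + ".enrichment_groups.tsv")
        _write_tsv(report.group_summary, p)
        outputs["enrichment_groups"] = p

        cat7 = sorted(cat7_only_transcripts(panel, contrast, mode=config.classify_mode))
        p = out_prefix.with_name(out_prefix.name + ".cat7_only_transcripts.txt")
        p.write_text("".join(t + "\n" for t in cat7))
        outputs["cat7_only_transcripts"] = p

        if placements is not None:
            track = introgression_track(panel, contrast, placements, mode=config.classify_mode)
            p = out_prefix.with_name(out_prefix.name + ".introgression_track.tsv")
            _write_tsv(track.entries, p)
            outputs["introgression_track"] = p

    # ---- run manifest ----------------------------------------------------
    cfg = config.to_jsonable()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": digest,
        "hybrisect_version": __version__,
        "n_loci": panel.n_loci,
        "n_samples": panel.n_samples,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    p = out_prefix.with_name(out_prefix.name + ".run_manifest.json")
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["run_manifest"] = p
    return outputs
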