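"""Readers and writers for the formats the pipeline touches.

Inputs: a multi-sample VCF (GT, optionally AD) called against a transcriptome
reference, a TSV sample manifest, a TSV linkage map and TSV/GFF3 transcript
genomic anchors.  Outputs are VCF (re-called genotypes) and TSV/JSON tables.

All coordinates are 1-based inclusive (VCF/GFF convention).  Multiallelic
records are kept as single loci with the alt order of the VCF record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GenotypePanel, Habit, Role, Sample, SnpLocus, validate_manifest

PathType = Union[str, PathLike]

MAX_ALLELES = 8  # SNP loci: ref + up to 7 alts fit the int8/4-bit call encoding


@dataclass(frozen=True)
class TranscriptAnchor:
    """Genomic placement of a transcript on a scaffold (1-based inclusive)."""

    transcript_id: str
    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"anchor {self.transcript_id} on {self.scaffold}: start {self.start} > end {self.end}"
            )


# --------------------------------------------------------------------- manifest

def read_manifest(path: PathType) -> list[Sample]:
    """Read the sample manifest (TSV: sample_id, role[, habit])."""
    samples: list[Sample] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest needs a header with a sample_id column")
        for row in reader:
            habit = (row.get("habit") or "none").strip() or "none"
            samples.append(
                Sample(row["sample_id"].strip(), Role(row["role"].strip()), Habit(habit))
            )
    validate_manifest(samples)
    return samples


def write_manifest(samples: Sequence[Sample], path: PathType) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\thabit\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.role.value}\t{s.habit.value}\n")


# -------------------------------------------------------------------------- VCF

def read_panel(vcf_path: PathType, manifest_path: PathType) -> GenotypePanel:
    """Read a multi-sample VCF plus manifest into a :class:`GenotypePanel`.

    Sample order in the panel follows the manifest, independent of the VCF
    column order.  GT populates calls; AD (when present) populates depths.
    Duplicate (CHROM, POS) records are an error.
    """
    samples = read_manifest(manifest_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    vcf_col = {name: j for j, name in enumerate(vcf_samples)}
    missing = [s.sample_id for s in samples if s.sample_id not in vcf_col]
    if missing:
        raise ValueError(f"manifest samples absent from VCF: {missing}")
    order = np.array([vcf_col[s.sample_id] for s in samples])

    loci: list[SnpLocus] = []
    calls_rows: list[np.ndarray] = []
    depth_rows: list[Optional[np.ndarray]] = []
    seen: set[tuple[str, int]] = set()
    any_ad = False
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"duplicate locus {var.CHROM}:{var.POS} in VCF")
        seen.add(key)
        alts = tuple(a for a in var.ALT if a != "<NON_REF>")
        loci.append(SnpLocus(var.CHROM, var.POS, var.REF, alts))
        gts = np.array(var.genotypes, dtype=np.int16)[:, :2]  # (n_vcf_samples, 2)
        calls_rows.append(gts[order])
        try:
            ad = var.format("AD")
        except KeyError:  # AD absent from the VCF header
            ad = None
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad, dtype=np.int32)
            ad[ad < 0] = 0
            n_all = 1 + len(alts)
            if ad.shape[1] > n_all and np.any(ad[:, n_all:] > 0):
                raise ValueError(
                    f"{var.CHROM}:{var.POS}: AD reports reads for an allele "
                    f"not in the locus definition"
                )
            row = np.zeros((len(vcf_samples), MAX_ALLELES), dtype=np.int32)
            row[:, : min(ad.shape[1], MAX_ALLELES)] = ad[:, :MAX_ALLELES]
            depth_rows.append(row[order])
        else:
            depth_rows.append(None)
    vcf.close()

    n = len(loci)
    calls = (
        np.stack(calls_rows).astype(np.int8)
        if n
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    depths = None
    if any_ad:
        depths = np.zeros((n, len(samples), MAX_ALLELES), dtype=np.int32)
        for i, row in enumerate(depth_rows):
            if row is not None:
                depths[i] = row
    return GenotypePanel(loci=loci, samples=samples, calls=calls, depths=depths)


def write_panel_vcf(panel: GenotypePanel, path: PathType) -> None:
    """Write the panel as a plain-text VCF 4.2 file (GT, and AD when present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if panel.depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
        for chrom in dict.fromkeys(l.transcript_id for l in panel.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        fmt = "GT" if panel.depths is None else "GT:AD"
        for i, locus in enumerate(panel.loci):
            n_all = len(locus.alleles)
            fields = [
                locus.transcript_id,
                str(locus.pos),
                ".",
                locus.ref_allele,
                ",".join(locus.alt_alleles),
                ".",
                ".",
                ".",
                fmt,
            ]
            for j in range(panel.n_samples):
                a, b = panel.calls[i, j]
                gt = "./." if a < 0 else f"{a}/{b}"
                if panel.depths is None:
                    fields.append(gt)
                else:
                    ad = ",".join(str(int(d)) for d in panel.depths[i, j, :n_all])
                    fields.append(f"{gt}:{ad}")
            fh.write("\t".join(fields) + "\n")


# ------------------------------------------------------------------ linkage map

def read_linkage_map(path: PathType) -> "LinkageMap":
    """Read a linkage map TSV (marker, linkage_group, cM, scaffold, scaffold_pos)."""
    from .linkage import LinkageMap  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "linkage_group": str, "scaffold": str})
    required = {"marker", "linkage_group", "cM", "scaffold", "scaffold_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: linkage map needs columns {sorted(required)}")
    return LinkageMap.from_frame(df)


# ------------------------------------------------------------------ anchors

def read_transcript_anchors(path: PathType) -> list[TranscriptAnchor]:
    """Read transcript genomic anchors from TSV or GFF3-like rows.

    A transcript may carry several anchors (a few transcripts map to multiple
    genomic locations); all are retained.
    """
    path = Path(path)
    anchors: list[TranscriptAnchor] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff") or (
            len(first.rstrip("\n").split("\t")) == 9 and not first.startswith("transcript")
        ):
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                seqid, start, end, attrs = cols[0], int(cols[3]), int(cols[4]), cols[8]
                tid = None
                for kv in attrs.split(";"):
                    k, _, v = kv.strip().partition("=")
                    if k in ("ID", "Parent", "transcript_id"):
                        tid = v
                        break
                if tid is None:
                    raise ValueError(f"{path}: GFF3 row without ID/Parent attribute")
                anchors.append(TranscriptAnchor(tid, seqid, start, end))
        else:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                anchors.append(
                    TranscriptAnchor(
                        row["transcript"], row["scaffold"], int(row["start"]), int(row["end"])
                    )
                )
    return anchors


def write_transcript_anchors(anchors: Sequence[TranscriptAnchor], path: PathType) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tscaffold\tstart\tend\n")
        for a in anchors:
            fh.write(f"{a.transcript_id}\t{a.scaffold}\t{a.start}\t{a.end}\n")
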