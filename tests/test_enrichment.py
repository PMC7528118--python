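"""Group contrasts: polymorphic subsets, category enrichment, introgression."""

import itertools

import numpy as np
import pytest

from hybrisect.core import Category, SnpLocus
from hybrisect.enrichment import (
    GroupContrast,
    between_group_polymorphic,
    cat7_only_transcripts,
    category_enrichment,
    fixed_difference_loci,
    introgression_track,
)
from hybrisect.io import TranscriptAnchor
from hybrisect.linkage import place_transcripts
from hybrisect.simulate import Hotspot, SimulationConfig, simulate_panel

from conftest import build_panel, make_samples, random_panel

AA, GG, AG, AT = ("A", "A"), ("G", "G"), ("A", "G"), ("A", "T")
CONTRAST = GroupContrast(("c1", "c2", "c3"), ("c4", "c5", "c6"))


def _panel(rows):
    loci = [SnpLocus(f"t{i}", 1, "A", ("G", "T")) for i in range(len(rows))]
    genotypes = [[AA, GG] + row for row in rows]
    return build_panel(loci, make_samples(6), genotypes)


def brute_between(panel, contrast):
    out = []
    for i in range(panel.n_loci):
        hit = False
        for a, b in itertools.product(contrast.group_a, contrast.group_b):
            ga, gb = panel.call(i, a), panel.call(i, b)
            if ga is not None and gb is not None and sorted(ga) != sorted(gb):
                hit = True
        out.append(hit)
    return np.array(out)


def brute_fixed(panel, contrast):
    out = []
    for i in range(panel.n_loci):
        ga = [panel.call(i, s) for s in contrast.group_a]
        gb = [panel.call(i, s) for s in contrast.group_b]
        ok = (
            all(g is not None for g in ga + gb)
            and len({tuple(sorted(g)) for g in ga}) == 1
            and len({tuple(sorted(g)) for g in gb}) == 1
            and tuple(sorted(ga[0])) != tuple(sorted(gb[0]))
        )
        out.append(ok)
    return np.array(out)


def test_between_group_polymorphic_examples():
    panel = _panel(
        [
            [AA, AA, AA, AA, AA, AA],   # monomorphic across cultivars -> excluded
            [AG, AA, AA, AA, AA, AA],   # one trailing differs from uprights -> included
            [AG, AG, AG, AG, AG, AG],   # same het everywhere -> excluded
            [AA, None, AA, None, GG, AA],  # cross pair differs -> included
        ]
    )
    mask = between_group_polymorphic(panel, CONTRAST)
    assert mask.tolist() == [False, True, False, True]


def test_fixed_difference_examples():
    panel = _panel(
        [
            [AT, AT, AT, AA, AA, AA],  # fixed difference
            [AT, AA, AT, AA, AA, AA],  # within-A polymorphism -> excluded
            [AA, AA, AA, AA, AA, AA],  # identical -> excluded
            [AT, AT, None, AA, AA, AA],  # missing breaks monomorphism
        ]
    )
    mask = fixed_difference_loci(panel, CONTRAST)
    assert mask.tolist() == [True, False, False, False]


def test_subsets_match_brute_force_and_are_symmetric():
    rng = np.random.default_rng(23)
    for _ in range(10):
        panel = random_panel(rng, n_loci=25, n_cultivars=6, missing_rate=0.25)
        contrast = GroupContrast(("c1", "c2", "c3"), ("c4", "c5", "c6"))
        swapped = GroupContrast(("c4", "c5", "c6"), ("c1", "c2", "c3"))
        between = between_group_polymorphic(panel, contrast)
        fixed = fixed_difference_loci(panel, contrast)
        assert np.array_equal(between, brute_between(panel, contrast))
        assert np.array_equal(fixed, brute_fixed(panel, contrast))
        # fixed differences are a subset of between-group polymorphism
        assert not np.any(fixed & ~between)
        # group order is irrelevant
        assert np.array_equal(between, between_group_polymorphic(panel, swapped))
        assert np.array_equal(fixed, fixed_difference_loci(panel, swapped))


def test_contrast_validation():
    with pytest.raises(ValueError, match="disjoint"):
        GroupContrast(("c1",), ("c1",))
    with pytest.raises(ValueError, match="non-empty"):
        GroupContrast((), ("c1",))
    panel = _panel([[AA] * 6])
    with pytest.raises(ValueError, match="not a cultivar"):
        between_group_polymorphic(panel, GroupContrast(("AX",), ("c1",)))


def test_enrichment_whole_subset_gives_unit_ratios():
    panel = _panel([[AA, AG, AA, GG, AA, AG], [AG, AA, AA, AA, GG, AA]])
    report = category_enrichment(panel, CONTRAST, np.ones(2, dtype=bool))
    assert np.allclose(
        report.per_sample["proportion_in_subset"], report.per_sample["proportion_in_whole"]
    )
    nz = report.per_sample["proportion_in_whole"] > 0
    assert np.allclose(report.per_sample.loc[nz, "ratio"], 1.0)
    assert (report.per_sample.loc[~nz, "ratio"] == 0).all()


def test_enrichment_detects_planted_category7_excess():
    """Category-7 loci over-represented among group-A between-group SNPs."""
    rows = []
    # 30 background loci identical everywhere (shared hom)
    rows += [[AA, AA] + [AA] * 6] * 30
    # 12 loci where trailing cultivars carry a shared/novel het, uprights do not
    rows += [[AA, AA, AT, AT, AT, AA, AA, AA]] * 12
    # 12 progenitor-polymorphic neutral loci varying within both groups
    rows += [[AA, GG, AG, AA, AA, AG, AA, AA]] * 12
    loci = [SnpLocus(f"t{i}", 1, "A", ("G", "T")) for i in range(len(rows))]
    panel = build_panel(loci, make_samples(6), rows)
    subset = between_group_polymorphic(panel, CONTRAST)
    report = category_enrichment(panel, CONTRAST, subset)
    g = report.group_summary.set_index(["group", "category"])
    cat7 = int(Category.SHARED_OUT_HET)
    assert g.loc[("A", cat7), "ratio"] > 1.0
    assert g.loc[("B", cat7), "ratio"] <= 1.0


def test_cat7_only_transcripts_rules():
    # t0: cat7 in all three trailing, none in uprights -> included
    # t1: cat7 in only two trailing -> excluded
    # t2: cat7 in one upright -> excluded
    rows = [
        ("t0", [AT, AT, AT, AA, AA, AA]),
        ("t1", [AT, AT, AA, AA, AA, AA]),
        ("t2", [AT, AT, AT, AT, AA, AA]),
    ]
    loci = [SnpLocus(t, 1, "A", ("G", "T")) for t, _ in rows]
    panel = build_panel(loci, make_samples(6), [[AA, AA] + r for _, r in rows])
    assert cat7_only_transcripts(panel, CONTRAST) == {"t0"}


def test_introgression_track_counts_and_subset_property():
    cfg = SimulationConfig(
        n_transcripts=120,
        snps_per_transcript_mean=4.0,
        missing_rate=0.0,
        hotspots=(Hotspot("LG1", 20.0, 40.0, out_multiplier=10.0),),
        seed=42,
    )
    bundle = simulate_panel(cfg)
    placements = place_transcripts(bundle.linkage_map, bundle.anchors)
    contrast = GroupContrast(
        ("trail1", "trail2", "trail3"), ("upright1", "upright2", "upright3")
    )
    track = introgression_track(bundle.panel, contrast, placements)
    df = track.entries
    assert (df["n_cat7_snps"] <= df["n_out_snps"]).all()
    assert (df["n_out_snps"] >= 0).all()
    # pooled group track equals the sum of member tracks
    a_members = df[df["track_id"].isin(contrast.group_a)]
    pooled = df[df["track_id"] == "group_A"]
    assert pooled["n_out_snps"].sum() == a_members["n_out_snps"].sum()


def test_no_out_snps_gives_empty_track():
    panel = _panel([[AA, AA, AA, GG, GG, GG]])
    placements = place_transcripts(
        __import__("hybrisect").LinkageMap.from_frame(
            __import__("pandas").DataFrame(
                {"marker": ["m1"], "linkage_group": ["LG1"], "cM": [0.0],
                 "scaffold": ["s"], "scaffold_pos": [1]}
            )
        ),
        [TranscriptAnchor("t0", "s", 1, 10)],
    )
    track = introgression_track(panel, CONTRAST, placements)
    assert track.entries.empty
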