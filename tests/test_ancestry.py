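"""Origin classification into the 12 categories and the three ancestry models."""

import itertools

import numpy as np
import pytest

from hypothesis import given, settings
from hypothesis import strategies as st

from hybrisect.ancestry import (
    allele_proportions_approach1,
    category_profile,
    classify_locus,
    classify_sample,
    exact_parents_model,
    progenitor_polymorphic,
    pure_parents_model,
)
from hybrisect.core import MISSING, Category, OUT_CATEGORIES, SnpLocus

from conftest import build_panel, make_samples, random_panel

AA, GG, TT, CC = ("A", "A"), ("G", "G"), ("T", "T"), ("C", "C")
AG, AT, TC = ("A", "G"), ("A", "T"), ("T", "C")


@pytest.mark.parametrize(
    "ax,intg,cult,expected",
    [
        (AA, GG, AG, Category.AX_INT_HET),
        (AA, AA, AT, Category.SHARED_OUT_HET),   # common allele + novel = category 7
        (AA, MISSING, AA, Category.UNKNOWN),
        (AA, GG, TT, Category.OUT_HOM),
        (AA, GG, TC, Category.OUT_OUT_HET),
        (AA, GG, AA, Category.AX_HOM),
        (AA, GG, GG, Category.INT_HOM),
        (AA, AA, AA, Category.SHARED_HOM),
        (AG, AG, AG, Category.SHARED_HET),       # common heterozygous progenitor genotype
        (AA, GG, AT, Category.AX_OUT_HET),
        (AA, GG, ("G", "T"), Category.INT_OUT_HET),
        (AA, GG, MISSING, Category.MISSING),
        (AG, GG, AG, Category.UNKNOWN),          # strict: het progenitor, differing sets
    ],
)
def test_classify_locus_strict(ax, intg, cult, expected):
    assert classify_locus(ax, intg, cult, mode="strict") == expected


def test_classify_locus_containment_matches_by_allele_sets():
    # het progenitor A/G vs hom G: cultivar A/G is fully contained in A's set
    assert classify_locus(AG, GG, AG, mode="containment") == Category.AX_HOM
    assert classify_locus(AG, GG, AA, mode="containment") == Category.AX_HOM
    assert classify_locus(AG, GG, GG, mode="containment") == Category.SHARED_HOM
    assert classify_locus(AG, GG, ("G", "T"), mode="containment") == Category.SHARED_OUT_HET
    assert classify_locus(AG, GG, AT, mode="containment") == Category.AX_OUT_HET


def _all_genotypes(alleles):
    pairs = [MISSING] + [
        tuple(sorted(p)) for p in itertools.combinations_with_replacement(alleles, 2)
    ]
    return pairs


@pytest.mark.parametrize("mode", ["strict", "containment"])
def test_classify_locus_total_and_image_over_four_alleles(mode):
    """Exhaustive enumeration over <=4 alleles: classification is total, covers
    all 12 categories, fires category 7 exactly on shared/novel heterozygotes,
    and uses {6..10} exactly for genotypes carrying out alleles."""
    genotypes = _all_genotypes("ACGT")
    seen = set()
    for ax, intg, cult in itertools.product(genotypes, repeat=3):
        cat = classify_locus(ax, intg, cult, mode=mode)
        assert isinstance(cat, Category)
        seen.add(cat)
        if ax is MISSING or intg is MISSING or cult is MISSING:
            continue
        A, B = set(ax), set(intg)
        if mode == "strict" and (len(A) > 1 or len(B) > 1) and A != B:
            assert cat is Category.UNKNOWN
            continue
        # category 7 <=> het pairing a progenitor-shared allele with a novel one
        x, y = cult
        is_cat7 = (
            x != y
            and (
                (x in A and x in B and y not in A and y not in B)
                or (y in A and y in B and x not in A and x not in B)
            )
        )
        assert (cat is Category.SHARED_OUT_HET) == is_cat7, (ax, intg, cult)
        # out categories fire iff the cultivar carries an allele outside A u B
        has_out_allele = any(a not in A and a not in B for a in cult)
        assert (cat in OUT_CATEGORIES) == has_out_allele, (ax, intg, cult)
    assert seen == set(Category)


def test_classify_sample_agrees_with_scalar_rule():
    rng = np.random.default_rng(11)
    for mode in ("strict", "containment"):
        for trial in range(5):
            panel = random_panel(rng, n_loci=40, n_cultivars=2, n_alleles=4)
            cats = classify_sample(panel, "c1", mode=mode)
            for i in range(panel.n_loci):
                expected = classify_locus(
                    panel.call(i, "AX"), panel.call(i, "INT"), panel.call(i, "c1"), mode=mode
                )
                assert Category(int(cats[i])) == expected, (mode, trial, i)


def _ten_locus_panel():
    """4 AX_HOM, 2 INT_HOM, 2 AX_INT_HET, 1 SHARED_HOM, 1 SHARED_OUT_HET."""
    loci = [SnpLocus(f"t{i}", 1, "A", ("G", "T")) for i in range(10)]
    samples = make_samples(1)
    genotypes = (
        [[AA, GG, AA]] * 4 + [[AA, GG, GG]] * 2 + [[AA, GG, AG]] * 2
        + [[AA, AA, AA], [AA, AA, AT]]
    )
    return build_panel(loci, samples, genotypes)


def test_category_profile_on_hand_counted_panel():
    prof = category_profile(_ten_locus_panel(), "c1")
    p = prof.proportions
    assert p[Category.AX_HOM] == pytest.approx(0.4)
    assert p[Category.INT_HOM] == pytest.approx(0.2)
    assert p[Category.AX_INT_HET] == pytest.approx(0.2)
    assert p[Category.SHARED_HOM] == pytest.approx(0.1)
    assert p[Category.SHARED_OUT_HET] == pytest.approx(0.1)
    assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)


def test_category_profile_rejects_progenitors():
    with pytest.raises(ValueError, match="progenitor"):
        category_profile(_ten_locus_panel(), "AX")


def test_all_missing_cultivar_is_all_missing_category(biallelic_locus):
    panel = build_panel([biallelic_locus], make_samples(1), [[AA, GG, None]])
    prof = category_profile(panel, "c1")
    assert prof.proportions[Category.MISSING] == 1.0


def test_approach1_headline_numbers_on_hand_counted_panel():
    """Allele counting: ax = 10/16, int = 6/16 over the 8 progenitor-polymorphic
    loci; out = 1/20 allele copies over all 10 classified loci."""
    est = allele_proportions_approach1(_ten_locus_panel(), "c1")
    assert est.extras["p_ax_polymorphic"] == pytest.approx(10 / 16)
    assert est.extras["p_int_polymorphic"] == pytest.approx(6 / 16)
    assert est.extras["p_out_overall"] == pytest.approx(1 / 20)
    assert sum(est.as_dict().values()) == pytest.approx(1.0, abs=1e-9)


def test_approach1_pure_ax_cultivar():
    loci = [SnpLocus(f"t{i}", 1, "A", ("G",)) for i in range(5)]
    panel = build_panel(loci, make_samples(1), [[AA, GG, AA]] * 5)
    est = allele_proportions_approach1(panel, "c1")
    assert est.p_ax == 1.0 and est.p_int == 0.0 and est.p_out == 0.0


def test_pure_parents_counts_allele_codes():
    """0/0, 0/1, 1/1, 0/2 over 4 loci -> p_ax 4/8, p_int 3/8, p_out 1/8."""
    loci = [SnpLocus(f"t{i}", 1, "A", ("G", "T")) for i in range(4)]
    genotypes = [[AA, GG, AA], [AA, GG, AG], [AA, GG, GG], [AA, GG, AT]]
    panel = build_panel(loci, make_samples(1), genotypes)
    est = pure_parents_model(panel, "c1")
    assert est.p_ax == pytest.approx(4 / 8)
    assert est.p_int == pytest.approx(3 / 8)
    assert est.p_out == pytest.approx(1 / 8)
    assert est.p_shared == 0.0


def test_pure_parents_identity_cases():
    loci = [SnpLocus(f"t{i}", 1, "A", ("G",)) for i in range(3)]
    panel = build_panel(loci, make_samples(1), [[AA, GG, AA]] * 3)
    assert pure_parents_model(panel, "c1").p_ax == 1.0
    panel = build_panel(loci, make_samples(1), [[AA, GG, GG]] * 3)
    assert pure_parents_model(panel, "c1").p_int == 1.0


def test_pure_parents_ignores_progenitor_genotypes():
    loci = [SnpLocus(f"t{i}", 1, "A", ("G",)) for i in range(3)]
    g1 = [[AA, GG, AG]] * 3
    g2 = [[GG, AA, AG]] * 3  # progenitor genotypes swapped
    e1 = pure_parents_model(build_panel(loci, make_samples(1), g1), "c1")
    e2 = pure_parents_model(build_panel(loci, make_samples(1), g2), "c1")
    assert e1.as_dict() == e2.as_dict()


def test_exact_parents_containment():
    loci = [SnpLocus("t0", 1, "A", ("G",))]
    panel = build_panel(loci, make_samples(1), [[AG, GG, AG]])
    est = exact_parents_model(panel, "c1")
    assert est.p_ax == pytest.approx(0.5)       # A is in the het progenitor-A set only
    assert est.p_shared == pytest.approx(0.5)   # G is in both sets
    # an allele absent from both progenitors counts as out
    loci = [SnpLocus("t0", 1, "A", ("G", "T"))]
    panel = build_panel(loci, make_samples(1), [[AA, GG, ("G", "T")]])
    est = exact_parents_model(panel, "c1")
    assert est.p_out == pytest.approx(0.5) and est.p_int == pytest.approx(0.5)


def test_exact_parents_identity_case():
    loci = [SnpLocus(f"t{i}", 1, "A", ("G",)) for i in range(4)]
    panel = build_panel(loci, make_samples(1), [[AA, GG, AA]] * 4)
    assert exact_parents_model(panel, "c1").p_ax == 1.0


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_proportions_sum_to_one_on_random_panels(seed):
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, n_loci=30, n_cultivars=2, missing_rate=0.2)
    prof = category_profile(panel, "c1")
    assert sum(prof.proportions.values()) == pytest.approx(1.0, abs=1e-9)
    for model in (allele_proportions_approach1, pure_parents_model, exact_parents_model):
        try:
            est = model(panel, "c1")
        except ValueError:
            continue  # no classified loci
        assert sum(est.as_dict().values()) == pytest.approx(1.0, abs=1e-9)


def test_progenitor_polymorphic_flags():
    panel = _ten_locus_panel()
    poly = progenitor_polymorphic(panel)
    assert poly.sum() == 8
    assert not poly[8] and not poly[9]
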