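"""Progenitor-origin classification and allele-proportion estimation.

Every cultivar genotype is classified against the two progenitor genotypes
into 12 categories (hom-A, hom-B, shared, A/B het, the five "out" classes
carrying alleles found in neither progenitor, unknown, missing).  From the
per-category counts three ancestry computations are offered:

``approach1_alleles``
    Direct allele counting over the classified loci: homozygous categories
    contribute two allele copies of their origin, heterozygous categories one
    copy of each.  The headline progenitor percentages follow the field's
    convention of restricting the A/B denominators to progenitor-polymorphic
    loci (``p_ax_polymorphic`` / ``p_int_polymorphic``) while the "out"
    percentage is taken over all classified loci (``p_out_overall``).

``pure_parents``
    Boundary model assuming idealised fully homozygous, fully polymorphic
    progenitors: the reference allele is A-derived, the first alternative
    allele B-derived, everything else "out" -- independent of the observed
    progenitor genotypes.

``exact_parents``
    Boundary model taking the observed progenitor genotypes as the exact
    ancestral ones: each cultivar allele copy is assigned by set containment
    (A only / B only / both = shared / neither = out).

The five primary fields of every :class:`AncestryEstimate` share a single
denominator (two allele copies per panel locus) and therefore always sum
to 1; the two boundary models bracket the direct estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import (
    MISSING,
    Category,
    GenotypePanel,
    Role,
)

Symbolic = Optional[tuple[str, str]]


def classify_locus(
    ax: Symbolic, int_: Symbolic, cultivar: Symbolic, mode: str = "strict"
) -> Category:
    """Classify one cultivar genotype against the two progenitor genotypes.

    Total function over symbolic genotypes (unordered allele pairs, or
    :data:`~hybrisect.core.MISSING`).

    In ``strict`` mode (default) the progenitors are assumed homozygous: a
    heterozygous progenitor whose allele set differs from the other
    progenitor's makes the locus UNKNOWN.  In ``containment`` mode genotypes
    are matched by allele-set containment: a cultivar genotype fully
    contained in both progenitor sets is shared, fully in one set is
    assigned to that progenitor, and otherwise alleles are assigned
    per copy (A-only / B-only / neither = out).
    """
    if mode not in ("strict", "containment"):
        raise ValueError(f"mode must be 'strict' or 'containment', got {mode!r}")
    if ax is MISSING or int_ is MISSING:
        return Category.UNKNOWN
    if cultivar is MISSING:
        return Category.MISSING
    A, B = frozenset(ax), frozenset(int_)
    if mode == "strict" and (len(A) > 1 or len(B) > 1) and A != B:
        return Category.UNKNOWN
    x, y = cultivar
    hom = x == y
    cult = frozenset(cultivar)
    if A == B:
        in1, in2 = x in A, y in A
        if in1 and in2:
            if hom:
                return Category.SHARED_HOM
            return Category.SHARED_HET  # het genotype equal to the common progenitor het
        if in1 or in2:
            return Category.SHARED_OUT_HET
        return Category.OUT_HOM if hom else Category.OUT_OUT_HET
    # progenitor-polymorphic locus
    if cult <= A and cult <= B:
        return Category.SHARED_HOM if hom else Category.SHARED_HET
    if cult <= A:
        return Category.AX_HOM
    if cult <= B:
        return Category.INT_HOM
    orig = []
    for a in (x, y):
        if a in A and a in B:
            orig.append("s")
        elif a in A:
            orig.append("a")
        elif a in B:
            orig.append("b")
        else:
            orig.append("o")
    pair = frozenset(orig) if orig[0] != orig[1] else frozenset({orig[0] + orig[0]})
    if pair == {"a", "b"}:
        return Category.AX_INT_HET
    if pair == {"a", "o"}:
        return Category.AX_OUT_HET
    if pair == {"b", "o"}:
        return Category.INT_OUT_HET
    if pair == {"s", "o"}:
        return Category.SHARED_OUT_HET
    # both alleles outside A and B
    return Category.OUT_HOM if hom else Category.OUT_OUT_HET


def _allele_masks(calls: np.ndarray) -> np.ndarray:
    """Bitmask of the allele set of each call; 0 for missing."""
    a, b = calls[..., 0].astype(np.int32), calls[..., 1].astype(np.int32)
    ok = a >= 0
    mask = np.where(ok, (1 << np.where(ok, a, 0)) | (1 << np.where(ok, b, 0)), 0)
    return mask


def classify_sample(
    panel: GenotypePanel, sample_id: str, mode: str = "strict"
) -> np.ndarray:
    """Vectorised classification of one sample at every panel locus.

    Returns an int array of :class:`~hybrisect.core.Category` values,
    cell-wise identical to :func:`classify_locus`.
    """
    if mode not in ("strict", "containment"):
        raise ValueError(f"mode must be 'strict' or 'containment', got {mode!r}")
    ja = panel.sample_index(panel.progenitor_a.sample_id)
    jb = panel.sample_index(panel.progenitor_b.sample_id)
    jc = panel.sample_index(sample_id)
    ax, bx, cx = panel.calls[:, ja], panel.calls[:, jb], panel.calls[:, jc]
    A, B = _allele_masks(ax), _allele_masks(bx)
    cat = np.full(panel.n_loci, int(Category.UNKNOWN), dtype=np.int8)
    prog_present = (A > 0) & (B > 0)
    prog_ok = prog_present.copy()
    if mode == "strict":
        het_prog = (ax[:, 0] != ax[:, 1]) | (bx[:, 0] != bx[:, 1])
        prog_ok &= ~(het_prog & (A != B))
    cult_missing = cx[:, 0] < 0
    cat[prog_present & cult_missing] = int(Category.MISSING)
    live = prog_ok & ~cult_missing

    x, y = cx[:, 0].astype(np.int32), cx[:, 1].astype(np.int32)
    bx1, bx2 = 1 << np.maximum(x, 0), 1 << np.maximum(y, 0)
    hom = x == y
    cmask = bx1 | bx2
    mono = A == B
    in_both = (cmask & ~(A & B)) == 0   # cultivar set ⊆ A∩B
    in_A = (cmask & ~A) == 0
    in_B = (cmask & ~B) == 0

    def put(cond: np.ndarray, category: Category) -> None:
        cat[live & cond] = int(category)

    # monomorphic progenitors (A == B)
    put(mono & in_A & hom, Category.SHARED_HOM)
    put(mono & in_A & ~hom, Category.SHARED_HET)
    one_in = ((bx1 & A) > 0) ^ ((bx2 & A) > 0)
    put(mono & ~in_A & one_in, Category.SHARED_OUT_HET)
    none_in = ((bx1 & A) == 0) & ((bx2 & A) == 0)
    put(mono & none_in & hom, Category.OUT_HOM)
    put(mono & none_in & ~hom, Category.OUT_OUT_HET)

    # polymorphic progenitors (A != B); containment tiers first
    poly = ~mono
    put(poly & in_both & hom, Category.SHARED_HOM)
    put(poly & in_both & ~hom, Category.SHARED_HET)
    put(poly & in_A & ~in_both, Category.AX_HOM)
    put(poly & in_B & ~in_both, Category.INT_HOM)
    rest = poly & ~in_A & ~in_B

    def origin(bits: np.ndarray) -> np.ndarray:
        # 0 shared, 1 ax-only, 2 int-only, 3 out
        inA, inB = (bits & A) > 0, (bits & B) > 0
        return np.select([inA & inB, inA, inB], [0, 1, 2], default=3)

    o1, o2 = origin(bx1), origin(bx2)
    lo, hi = np.minimum(o1, o2), np.maximum(o1, o2)
    put(rest & (lo == 1) & (hi == 2), Category.AX_INT_HET)
    put(rest & (lo == 1) & (hi == 3), Category.AX_OUT_HET)
    put(rest & (lo == 2) & (hi == 3), Category.INT_OUT_HET)
    put(rest & (lo == 0) & (hi == 3), Category.SHARED_OUT_HET)
    both_out = rest & (lo == 3)
    put(both_out & hom, Category.OUT_HOM)
    put(both_out & ~hom, Category.OUT_OUT_HET)
    return cat


def progenitor_polymorphic(panel: GenotypePanel, mode: str = "strict") -> np.ndarray:
    """Boolean mask of loci where the progenitor allele sets differ.

    Loci with a missing (or, in strict mode, unusable heterozygous)
    progenitor genotype are False.
    """
    ja = panel.sample_index(panel.progenitor_a.sample_id)
    jb = panel.sample_index(panel.progenitor_b.sample_id)
    ax, bx = panel.calls[:, ja], panel.calls[:, jb]
    A, B = _allele_masks(ax), _allele_masks(bx)
    ok = (A > 0) & (B > 0)
    if mode == "strict":
        het_prog = (ax[:, 0] != ax[:, 1]) | (bx[:, 0] != bx[:, 1])
        ok &= ~(het_prog & (A != B))
    return ok & (A != B)


@dataclass
class CategoryProfile:
    """Per-sample distribution of loci over the 12 categories."""

    sample_id: str
    counts: Mapping[Category, int]
    n_loci: int

    @property
    def proportions(self) -> dict[Category, float]:
        return {c: self.counts.get(c, 0) / self.n_loci for c in Category}


def category_profile(
    panel: GenotypePanel, sample_id: str, mode: str = "strict"
) -> CategoryProfile:
    """Category counts/proportions of one non-progenitor sample over all loci."""
    role = panel.sample(sample_id).role
    if role in (Role.PROGENITOR_A, Role.PROGENITOR_B):
        raise ValueError(f"category profile undefined for progenitor sample {sample_id!r}")
    cats = classify_sample(panel, sample_id, mode=mode)
    vals, cnts = np.unique(cats, return_counts=True)
    counts = {Category(int(v)): int(c) for v, c in zip(vals, cnts)}
    return CategoryProfile(sample_id=sample_id, counts=counts, n_loci=panel.n_loci)


@dataclass
class AncestryEstimate:
    """Allele-origin proportions of one cultivar under one model.

    The five ``p_*`` fields share one denominator (two allele copies per
    panel locus) and sum to 1.  ``extras`` carries the model's
    convention-specific headline numbers (see module docstring).
    """

    sample_id: str
    model: str
    p_ax: float
    p_int: float
    p_shared: float
    p_out: float
    p_unknown: float
    n_loci: int
    extras: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "p_ax": self.p_ax,
            "p_int": self.p_int,
            "p_shared": self.p_shared,
            "p_out": self.p_out,
            "p_unknown": self.p_unknown,
        }


#: allele copies of each origin contributed by one locus of each category
_COPY_TABLE = {
    Category.AX_HOM: (2, 0, 0, 0),
    Category.INT_HOM: (0, 2, 0, 0),
    Category.SHARED_HOM: (0, 0, 2, 0),
    Category.AX_INT_HET: (1, 1, 0, 0),
    Category.SHARED_HET: (0, 0, 2, 0),
    Category.AX_OUT_HET: (1, 0, 0, 1),
    Category.SHARED_OUT_HET: (0, 0, 1, 1),
    Category.INT_OUT_HET: (0, 1, 0, 1),
    Category.OUT_HOM: (0, 0, 0, 2),
    Category.OUT_OUT_HET: (0, 0, 0, 2),
}


def allele_proportions_approach1(
    panel: GenotypePanel, sample_id: str, mode: str = "strict"
) -> AncestryEstimate:
    """Approach-1 ancestry estimate by allele counting over categories.

    Homozygous categories contribute two allele copies of their origin,
    heterozygous ones a single copy each (a het A/B locus carries 50% of the
    A alleles of a hom-A locus, and a het out locus 50% of the out alleles of
    a hom out locus).  ``extras`` carries the headline percentages:
    progenitor fractions over progenitor-polymorphic classified loci and the
    out fraction over all classified loci.
    """
    cats = classify_sample(panel, sample_id, mode=mode)
    poly = progenitor_polymorphic(panel, mode=mode)
    vals, cnts = np.unique(cats, return_counts=True)
    counts = {Category(int(v)): int(c) for v, c in zip(vals, cnts)}
    n_classified = sum(c for cat, c in counts.items() if cat in _COPY_TABLE)
    if n_classified == 0:
        raise ValueError(f"no classified loci for sample {sample_id!r}")
    ax = intg = shared = out = 0
    for cat, (ca, cb, cs, co) in _COPY_TABLE.items():
        n = counts.get(cat, 0)
        ax += ca * n
        intg += cb * n
        shared += cs * n
        out += co * n
    total = 2 * panel.n_loci
    unknown = total - 2 * n_classified
    # reporting-convention denominators (see module docstring)
    classified = np.isin(cats, [int(c) for c in _COPY_TABLE])
    n_poly_classified = int((classified & poly).sum())
    poly_cats = cats[classified & poly]
    ax_p = intg_p = out_p = 0
    for cat, (ca, cb, _, co) in _COPY_TABLE.items():
        n = int((poly_cats == int(cat)).sum())
        ax_p += ca * n
        intg_p += cb * n
        out_p += co * n
    extras = {
        "p_out_overall": out / (2 * n_classified),
        "n_polymorphic_loci": float(n_poly_classified),
    }
    if n_poly_classified:
        extras["p_ax_polymorphic"] = ax_p / (2 * n_poly_classified)
        extras["p_int_polymorphic"] = intg_p / (2 * n_poly_classified)
    return AncestryEstimate(
        sample_id=sample_id,
        model="approach1_alleles",
        p_ax=ax / total,
        p_int=intg / total,
        p_shared=shared / total,
        p_out=out / total,
        p_unknown=unknown / total,
        n_loci=panel.n_loci,
        extras=extras,
    )


def pure_parents_model(panel: GenotypePanel, sample_id: str) -> AncestryEstimate:
    """"Pure parents" boundary: idealised homozygous, fully polymorphic parents.

    The reference allele is progenitor-A-derived ("0/0"), the first
    alternative allele progenitor-B-derived ("1/1"), any other allele "out".
    The observed progenitor genotypes are never consulted, so the estimate is
    invariant to them.  Missing cultivar calls count as unknown (two copies).
    """
    j = panel.sample_index(sample_id)
    calls = panel.calls[:, j].astype(np.int32)
    flat = calls.ravel()
    miss = flat < 0
    total = flat.size
    p_ax = int((flat == 0).sum()) / total
    p_int = int((flat == 1).sum()) / total
    p_out = int((flat >= 2).sum()) / total
    return AncestryEstimate(
        sample_id=sample_id,
        model="pure_parents",
        p_ax=p_ax,
        p_int=p_int,
        p_shared=0.0,
        p_out=p_out,
        p_unknown=int(miss.sum()) / total,
        n_loci=panel.n_loci,
    )


def exact_parents_model(panel: GenotypePanel, sample_id: str) -> AncestryEstimate:
    """"Exact parents" boundary: the sampled progenitor genotypes are ancestral.

    Each cultivar allele copy is assigned by containment in the observed
    progenitor allele sets: A only, B only, both (shared) or neither (out).
    Loci with a missing progenitor or cultivar call count as unknown.
    """
    ja = panel.sample_index(panel.progenitor_a.sample_id)
    jb = panel.sample_index(panel.progenitor_b.sample_id)
    jc = panel.sample_index(sample_id)
    A = _allele_masks(panel.calls[:, ja])
    B = _allele_masks(panel.calls[:, jb])
    cx = panel.calls[:, jc].astype(np.int32)
    usable = (A > 0) & (B > 0) & (cx[:, 0] >= 0)
    total = 2 * panel.n_loci
    n_ax = n_int = n_shared = n_out = 0
    for k in (0, 1):
        bits = 1 << np.maximum(cx[:, k], 0)
        inA = usable & ((bits & A) > 0)
        inB = usable & ((bits & B) > 0)
        n_shared += int((inA & inB).sum())
        n_ax += int((inA & ~inB).sum())
        n_int += int((inB & ~inA).sum())
        n_out += int((usable & ~inA & ~inB).sum())
    return AncestryEstimate(
        sample_id=sample_id,
        model="exact_parents",
        p_ax=n_ax / total,
        p_int=n_int / total,
        p_shared=n_shared / total,
        p_out=n_out / total,
        p_unknown=(total - 2 * int(usable.sum())) / total,
        n_loci=panel.n_loci,
    )


MODELS = {
    "approach1_alleles": allele_proportions_approach1,
    "pure_parents": pure_parents_model,
    "exact_parents": exact_parents_model,
}
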