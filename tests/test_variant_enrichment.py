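import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from grmkit import variant_enrichment as ve
from grmkit.chromatin_landscape import AnnotatedROC
from grmkit.io_formats import GeneModel, GenomicInterval, VariantRecord

from _oracles import burden_scan


def _variant(pos, carriers=("p1",), depth=40, af=0.001, csq="missense_variant", chrom="chr1"):
    return VariantRecord(chrom, pos, "A", "T", af, csq, depth, frozenset(carriers))


def _roc(chrom, start, end, iid, gene):
    return AnnotatedROC(GenomicInterval(chrom, start, end, iid), gene, 0)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs,passes",
    [
        (dict(depth=29), False),  # coverage below 30x
        (dict(depth=30), True),  # boundary is inclusive
        (dict(csq="synonymous_variant", depth=50, af=0.001), False),
        (dict(af=0.01), False),  # rarity gate is strict
        (dict(af=0.0099), True),
        (dict(af=None), True),  # missing frequency treated as rare
    ],
)
def test_variant_filters(kwargs, passes):
    passing = ve.filter_variants([_variant(100, **kwargs)])
    assert bool(passing) is passes


def test_drop_missing_af_flag():
    assert ve.filter_variants([_variant(100, af=None)], drop_missing_af=True) == []


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------

def test_locus_merges_overlapping_roc():
    genes = [GeneModel("g1", "chr1", "+", 0, 1000)]
    rocs = [_roc("chr1", 500, 1500, "r1", "g1")]
    (locus,) = ve.build_loci(genes, rocs, ["g1"])
    assert locus.intervals == ((0, 1500),)
    assert locus.total_length == 1500


def test_locus_keeps_disjoint_roc_pieces():
    genes = [GeneModel("g1", "chr1", "+", 0, 1000)]
    rocs = [_roc("chr1", 2000, 2100, "r1", "g1")]
    (locus,) = ve.build_loci(genes, rocs, ["g1"])
    assert locus.intervals == ((0, 1000), (2000, 2100))
    assert locus.total_length == 1100


def test_locus_without_roc_is_gene_span():
    genes = [GeneModel("g1", "chr1", "+", 0, 1000)]
    (locus,) = ve.build_loci(genes, [], ["g1"])
    assert locus.intervals == ((0, 1000),)


def test_missing_gene_in_models_errors():
    with pytest.raises(ValueError, match="gX"):
        ve.build_loci([GeneModel("g1", "chr1", "+", 0, 10)], [], ["gX"])


def test_merge_idempotent_and_order_invariant(rng):
    pieces = [(int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 1000, 20), rng.integers(1, 300, 20))]
    merged = ve.merge_intervals(pieces)
    assert ve.merge_intervals(merged) == merged
    rng.shuffle(pieces)
    assert ve.merge_intervals(pieces) == merged
    # disjointness
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        assert e1 < s2


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

def _three_gene_loci():
    genes = [GeneModel(f"g{i}", "chr1", "+", i * 100_000, i * 100_000 + 50_000) for i in range(3)]
    return ve.build_loci(genes, [], [g.gene_id for g in genes])


def test_burden_fraction_and_rate():
    loci = _three_gene_loci()
    variants = [
        _variant(10_001, carriers=("p1",)),
        _variant(10_501, carriers=("p1",)),
        _variant(20_001, carriers=("p1",)),
        _variant(30_001, carriers=("p1",)),
    ]
    (rec,) = ve.burden(variants, loci, ["p1"], "set")
    assert rec.fraction_mutated == pytest.approx(1 / 3)  # all hits in g0
    assert rec.snv_per_100kb == pytest.approx(1e5 * 4 / 150_000)


def test_burden_zero_for_variant_free_individual():
    loci = _three_gene_loci()
    (rec,) = ve.burden([_variant(10, carriers=("p2",))], loci, ["p1"], "set")
    assert rec.fraction_mutated == 0 and rec.snv_per_100kb == 0


def test_burden_empty_gene_set_errors():
    with pytest.raises(ValueError):
        ve.burden([], [], ["p1"], "set")


def test_burden_matches_scan_oracle(rng):
    genes = [GeneModel(f"g{i}", "chr1", "+", i * 10_000, i * 10_000 + 4_000) for i in range(20)]
    rocs = [
        _roc("chr1", int(s), int(s) + 500, f"r{i}", f"g{rng.integers(20)}")
        for i, s in enumerate(rng.integers(0, 200_000, 40))
    ]
    loci = ve.build_loci(genes, rocs, [g.gene_id for g in genes])
    people = [f"p{i}" for i in range(8)]
    variants = [
        _variant(int(p), carriers=(people[rng.integers(8)],))
        for p in rng.integers(1, 200_000, 800)
    ]
    records = ve.burden(variants, loci, people, "set")
    oracle = burden_scan(variants, loci, people)
    for rec in records:
        frac, rate = oracle[rec.individual_id]
        assert rec.fraction_mutated == pytest.approx(frac)
        assert rec.snv_per_100kb == pytest.approx(rate)


def test_fraction_mutated_monotone_in_variants(rng):
    loci = _three_gene_loci()
    variants = [_variant(int(p), carriers=("p1",)) for p in rng.integers(1, 250_000, 30)]
    fractions = []
    for n in (10, 20, 30):
        (rec,) = ve.burden(variants[:n], loci, ["p1"], "set")
        fractions.append(rec.fraction_mutated)
    assert fractions == sorted(fractions)


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

def test_prevalence_fraction_of_carriers():
    loci = _three_gene_loci()
    cohort = [f"p{i}" for i in range(35)]
    variants = [_variant(10_001, carriers=tuple(cohort[:7]))]
    prev = ve.per_gene_prevalence(variants, loci, cohort)
    assert prev["g0"] == pytest.approx(0.2)
    assert prev["g1"] == 0.0


def test_paired_prevalence_drops_double_zero_genes():
    a = pd.Series({"g0": 0.2, "g1": 0.0, "g2": 0.1})
    b = pd.Series({"g0": 0.1, "g1": 0.0, "g2": 0.0})
    paired = ve.paired_prevalence(a, b)
    assert set(paired.index) == {"g0", "g2"}


def test_prevalence_order_invariant(rng):
    loci = _three_gene_loci()
    cohort = [f"p{i}" for i in range(10)]
    variants = [
        _variant(int(p), carriers=(cohort[rng.integers(10)],))
        for p in rng.integers(1, 250_000, 50)
    ]
    prev1 = ve.per_gene_prevalence(variants, loci, cohort)
    prev2 = ve.per_gene_prevalence(list(reversed(variants)), loci, list(reversed(cohort)))
    pd.testing.assert_series_equal(prev1, prev2)


# ---------------------------------------------------------------------------
# Cohort comparison
# ---------------------------------------------------------------------------

def test_identical_distributions_not_rejected(rng):
    values = rng.uniform(0, 1, 30)
    (comp,) = ve.compare_cohorts([("null", values, values.copy(), "mannwhitney")])
    assert comp.p_adjusted > 0.9


def test_bh_family_hand_example(rng):
    a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
    comps = ve.compare_cohorts(
        [(f"c{i}", a, b, "mannwhitney") for i in range(4)]
    )
    # adjusted values must reproduce the step-up on the raw family
    from _oracles import bh_stepup

    raw = [c.p_raw for c in comps]
    assert np.allclose([c.p_adjusted for c in comps], bh_stepup(raw))
    assert np.allclose(
        bh_stepup([0.001, 0.02, 0.03, 0.8]), [0.004, 0.04, 0.04, 0.8]
    )


def test_all_tied_inputs_return_one():
    (comp,) = ve.compare_cohorts([("tied", [1.0] * 5, [1.0] * 5, "mannwhitney")])
    assert comp.p_adjusted == 1.0


def test_all_tied_paired_inputs_return_one():
    (comp,) = ve.compare_cohorts([("tied", [1.0] * 5, [1.0] * 5, "wilcoxon")])
    assert comp.p_adjusted == 1.0


def test_paired_wilcoxon_detects_within_cohort_shift(rng):
    base = rng.uniform(0.1, 0.3, 20)
    (comp,) = ve.compare_cohorts([("paired", base + 0.2, base, "wilcoxon")])
    assert comp.p_adjusted < 0.01


def test_too_few_individuals_error():
    with pytest.raises(ValueError):
        ve.compare_cohorts([("tiny", [1, 2], [1, 2, 3], "mannwhitney")])


# ---------------------------------------------------------------------------
# Patient clustering
# ---------------------------------------------------------------------------

def test_first_split_separates_groups_when_contrast_dominates():
    # the other gene sets carry no between-patient variance and are dropped
    n = 20
    matrix = pd.DataFrame(
        {
            "ap1_up": [0.6] * (n // 2) + [0.1] * (n // 2),
            "ets_down": [0.2] * n,
            "klf_up": [0.3] * n,
        },
        index=[f"p{i:02d}" for i in range(n)],
    )
    matrix["ap1_up"] += np.linspace(0, 0.01, n)  # tiny jitter, keeps sd > 0
    clusters = ve.cluster_patients(matrix)
    assert set(clusters.first_split[0]) in (
        {f"p{i:02d}" for i in range(n // 2)},
        {f"p{i:02d}" for i in range(n // 2, n)},
    )


def test_first_split_mostly_recovers_planted_groups():
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        m = np.clip(rng.normal(0.2, 0.02, (70, 2)), 0, 1)
        m[:35, 0] += 0.5
        matrix = pd.DataFrame(m, index=[f"p{i:02d}" for i in range(70)], columns=["a", "b"])
        clusters = ve.cluster_patients(matrix)
        labels = [0 if i in set(clusters.first_split[0]) else 1 for i in matrix.index]
        aris.append(adjusted_rand_score([0] * 35 + [1] * 35, labels))
    assert np.mean(aris) >= 0.85


def test_duplicated_individuals_merge_at_zero_height(rng):
    row = rng.uniform(0, 1, 4)
    matrix = pd.DataFrame(
        [row, row, rng.uniform(0, 1, 4), rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)],
        index=["dup1", "dup2", "x", "y", "z"],
    )
    clusters = ve.cluster_patients(matrix, k=2)
    assert clusters.linkage[0, 2] == pytest.approx(0.0)
    assert clusters.labels["dup1"] == clusters.labels["dup2"]


def test_constant_matrix_errors():
    matrix = pd.DataFrame(np.full((5, 3), 0.2), index=list("abcde"))
    with pytest.raises(ValueError, match="structure"):
        ve.cluster_patients(matrix)


def test_newick_covers_all_individuals(rng):
    matrix = pd.DataFrame(rng.uniform(0, 1, (8, 3)), index=[f"p{i}" for i in range(8)])
    clusters = ve.cluster_patients(matrix, k=2)
    for pid in matrix.index:
        assert pid in clusters.newick
    assert clusters.newick.endswith(";")


# ---------------------------------------------------------------------------
# Variant / TFBS overlap
# ---------------------------------------------------------------------------

def test_variant_tfbs_overlap_boundaries(tfbs_factory):
    site = tfbs_factory("T1", "g1", 1.0, start=149)  # [149, 159)
    inside = _variant(150)
    at_boundary = _variant(149)
    assert len(ve.tfbs_variant_overlap([inside], [site])) == 1
    assert ve.tfbs_variant_overlap([at_boundary], [site]) == []


def test_duplicate_tf_site_gives_one_row_per_tf(tfbs_factory):
    sites = [tfbs_factory("T1", "g1", 1.0, start=149), tfbs_factory("T2", "g1", 1.0, start=149)]
    rows = ve.tfbs_variant_overlap([_variant(150)], sites)
    assert sorted(tf for _, _, tf in rows) == ["T1", "T2"]
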