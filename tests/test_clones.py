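"""Tests of phylotype clustering, diversity estimators, LIBSHUFF, fragment
prediction and fingerprint <-> clone cross-matching."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icefp.clones import (
    chao1,
    cluster_phylotypes,
    delta_c,
    designate_subtypes,
    diversity_estimate,
    estimate_dye_offset,
    goods_coverage,
    identity_distance_matrix,
    libshuff,
    match_subtypes_to_otus,
    pairwise_identity,
    predict_fragment_length,
    shannon,
)
from icefp.synth import (
    CommunityModel,
    CloneSequence,
    OTUSpec,
    PhylotypeSpec,
    sample_clone_library,
)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_single_mismatch_in_hundred_columns(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert pairwise_identity(a, b) == pytest.approx(0.99)

    def test_gap_and_n_columns_excluded(self):
        # 20-column toy alignment, hand count:
        # columns with '-' or 'N' in either: 1,2 (gaps), 5 (N), 11 (gap), 18 (N)
        a = "A-CGTNACGT-ACGTACNGT"
        b = "AAC-TAACGTAACGAACNGT"
        # comparable columns: 0,3?,... hand: exclude idx 1,3,5,10,17
        # remaining 15 columns; mismatches at idx 13 (G vs G?) count by hand:
        comparable = [
            (x, y) for x, y in zip(a, b) if x not in "-N" and y not in "-N"
        ]
        expected = sum(x == y for x, y in comparable) / len(comparable)
        assert pairwise_identity(a, b) == pytest.approx(expected)
        assert len(comparable) == 15

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_identity("--NN", "AAAA")

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            pairwise_identity("ACGT", "ACG")


class TestClusterPhylotypes:
    def test_identical_clones_form_one_phylotype(self):
        clones = [
            CloneSequence(id=f"c{i}", library_id="L", gene_region="ACGT" * 50)
            for i in range(6)
        ]
        assert len(cluster_phylotypes(clones, 0.98)) == 1

    def test_two_distant_groups_split_at_98_percent(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=200))
        other = list(base)
        for i in range(0, 200, 10):  # 10% divergence
            other[i] = "A" if other[i] != "A" else "C"
        clones = [
            CloneSequence(id=f"a{i}", library_id="L", gene_region=base)
            for i in range(3)
        ] + [
            CloneSequence(id=f"b{i}", library_id="L",
                          gene_region="".join(other))
            for i in range(3)
        ]
        phylos = cluster_phylotypes(clones, 0.98)
        assert len(phylos) == 2
        assert {frozenset(p.member_ids) for p in phylos} == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"}),
        }

    def test_planted_partition_recovered_exactly(self):
        model = CommunityModel(
            otus=[OTUSpec(420.0 + 40 * j, 0.2, True) for j in range(5)],
            n_samples=3, core_signal_fraction=1.0,
            transient_presence_prob=0.0, abundance_dispersion=0.2, seed=0,
        )
        clones = sample_clone_library(model, 60, seed=13)
        phylos = cluster_phylotypes(clones, 0.98)
        truth: dict = {}
        for c in clones:
            truth.setdefault(c.true_phylotype, set()).add(c.id)
        assert {frozenset(p.member_ids) for p in phylos} == {
            frozenset(v) for v in truth.values()
        }

    def test_raising_threshold_only_refines_partition(self):
        model = CommunityModel(
            otus=[OTUSpec(420.0 + 40 * j, 0.25, True) for j in range(4)],
            n_samples=3, core_signal_fraction=1.0,
            transient_presence_prob=0.0, abundance_dispersion=0.2, seed=1,
        )
        clones = sample_clone_library(model, 40, seed=3)
        coarse = cluster_phylotypes(clones, 0.90)
        fine = cluster_phylotypes(clones, 0.99)
        coarse_map = {
            cid: p.id for p in coarse for cid in p.member_ids
        }
        # every fine phylotype sits entirely inside one coarse phylotype
        for p in fine:
            assert len({coarse_map[cid] for cid in p.member_ids}) == 1

    def test_partition_property_every_clone_in_exactly_one(self):
        model = CommunityModel(
            otus=[OTUSpec(420.0 + 40 * j, 1 / 3, True) for j in range(3)],
            n_samples=3, core_signal_fraction=1.0,
            transient_presence_prob=0.0, abundance_dispersion=0.2, seed=2,
        )
        clones = sample_clone_library(model, 30, seed=4)
        phylos = cluster_phylotypes(clones, 0.98)
        all_ids = [cid for p in phylos for cid in p.member_ids]
        assert sorted(all_ids) == sorted(c.id for c in clones)


class TestDiversityEstimators:
    def test_chao1_examples(self):
        assert chao1([5, 4, 3]) == 3.0  # no singletons
        assert chao1([1, 1, 2]) == 5.0  # 3 + 4/2
        assert chao1([1]) == 1.0  # bias-corrected, F2 = 0

    def test_shannon_examples(self):
        assert shannon([10]) == 0.0
        assert shannon([3, 3, 3, 3, 3]) == pytest.approx(np.log(5))
        assert shannon([70, 30]) == pytest.approx(0.6109, abs=1e-4)

    def test_goods_coverage_examples(self):
        assert goods_coverage([5, 5, 2]) == 1.0
        assert goods_coverage([1, 1, 1]) == 0.0
        assert goods_coverage([1, 1, 8]) == pytest.approx(0.8)

    def test_empty_library_rejected(self):
        for fn in (chao1, shannon, goods_coverage):
            with pytest.raises(ValueError, match="empty|positive"):
                fn([])

    def test_matches_independent_skbio_oracle(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = [12, 7, 3, 2, 2, 1, 1, 1]
        assert chao1(counts) == pytest.approx(
            float(skbio_alpha.chao1(counts, bias_corrected=False))
        )
        assert shannon(counts) == pytest.approx(
            float(skbio_alpha.shannon(counts, base=np.e))
        )
        assert goods_coverage(counts) == pytest.approx(
            float(skbio_alpha.goods_coverage(counts))
        )

    counts = st.lists(st.integers(1, 40), min_size=1, max_size=25)

    @given(counts=counts)
    def test_chao1_never_below_observed_richness(self, counts):
        est = chao1(counts)
        assert est >= len(counts)
        f1 = sum(c == 1 for c in counts)
        if f1 == 0:
            assert est == len(counts)

    @given(n=st.integers(2, 10), total=st.integers(20, 200))
    def test_shannon_maximal_at_uniform_counts(self, n, total):
        uniform = [total] * n
        rng = np.random.default_rng(total * n)
        skew = rng.multinomial(total * n, np.ones(n) / n) + 1
        assert shannon(uniform) >= shannon(skew.tolist()) - 1e-12

    def test_diversity_estimate_invariants(self):
        est = diversity_estimate([4, 2, 1, 1])
        assert est.observed_richness == 4
        assert est.chao1 >= 4
        assert 0 <= est.goods_coverage <= 1


class TestLibshuff:
    def test_self_comparison_delta_c_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10)) * 0.2
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        idx = np.arange(10)
        assert delta_c(d, idx, idx) == 0.0

    def test_disjoint_planted_libraries_significant_both_directions(self):
        model = CommunityModel(
            otus=[OTUSpec(420.0 + 30 * j, 0.1, True) for j in range(10)],
            n_samples=3, core_signal_fraction=1.0,
            transient_presence_prob=0.0, abundance_dispersion=0.2, seed=0,
        )
        hits = 0
        for rep in range(10):
            a = sample_clone_library(
                model, 15, seed=rep * 2 + 1, library_id="A",
                subtype_spec=[PhylotypeSpec(f"P{j}", (j,)) for j in range(5)],
            )
            b = sample_clone_library(
                model, 15, seed=rep * 2 + 2, library_id="B",
                subtype_spec=[PhylotypeSpec(f"Q{j}", (j,))
                              for j in range(5, 10)],
            )
            d = identity_distance_matrix([c.gene_region for c in a + b])
            res = libshuff(d, ["A"] * 15 + ["B"] * 15, n_perm=100, seed=rep)
            hits += (res.p_xy <= 0.05) and (res.p_yx <= 0.05)
        assert hits >= 9

    def test_tiny_library_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="at least 2"):
            libshuff(d, ["A", "A", "B"], n_perm=100)

    def test_low_permutation_count_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="n_perm"):
            libshuff(d, ["A", "A", "B", "B"], n_perm=10)


class TestPredictFragmentLength:
    def test_arisa_length_by_construction(self):
        model = CommunityModel(
            otus=[OTUSpec(500.0, 1.0, True)], n_samples=2,
            core_signal_fraction=1.0, transient_presence_prob=0.0,
            abundance_dispersion=0.0, seed=0,
        )
        clone = sample_clone_library(model, 1, seed=0)[0]
        assert predict_fragment_length(clone, "ARISA").length_bp == 500.0

    def test_trflp_matches_brute_force_site_scan(self):
        model = CommunityModel(
            otus=[OTUSpec(230.0, 1.0, True)], n_samples=2,
            core_signal_fraction=1.0, transient_presence_prob=0.0,
            abundance_dispersion=0.0, seed=0,
        )
        clone = sample_clone_library(model, 1, seed=1, assay="TRFLP")[0]
        pred = predict_fragment_length(clone, "TRFLP")
        # brute-force scan for AC[ACGT]GT, cut after the 3rd site base
        seq = clone.amplicon
        first = None
        for i in range(len(seq) - 4):
            w = seq[i: i + 5]
            if w[0] == "A" and w[1] == "C" and w[3] == "G" and w[4] == "T":
                first = i + 3
                break
        assert pred.length_bp == first == 230

    def test_sequence_without_site_flagged_uncut(self):
        clone = CloneSequence(
            id="x", library_id="L",
            gene_region="GTACACACCGCCCGTCACAC" + "A" * 200,
        )
        pred = predict_fragment_length(clone, "TRFLP")
        assert pred.uncut and pred.length_bp == 220.0


class TestSubtypesAndMatching:
    def test_two_its_lengths_give_two_subtypes(self):
        model = CommunityModel(
            otus=[OTUSpec(500.0, 0.5, True), OTUSpec(506.0, 0.5, True)],
            n_samples=2, core_signal_fraction=1.0,
            transient_presence_prob=0.0, abundance_dispersion=0.0, seed=0,
        )
        clones = sample_clone_library(
            model, 20, subtype_spec=[PhylotypeSpec("P1", (0, 1))], seed=2
        )
        phylos = cluster_phylotypes(clones, 0.98)
        preds = {c.id: predict_fragment_length(c, "ARISA") for c in clones}
        subtypes = designate_subtypes(phylos, preds)
        assert len(phylos) == 1 and len(subtypes) == 2
        assert sorted(s.predicted_fragment_length for s in subtypes) == [
            500.0, 506.0,
        ]

    def test_match_classes_by_distance(self):
        from icefp.clones import Subtype

        subtypes = [
            Subtype("P1", 500.0, ("a",)),
            Subtype("P2", 500.0, ("b",)),
            Subtype("P3", 500.0, ("c",)),
        ]
        table = match_subtypes_to_otus(subtypes, [500.8])
        assert table.loc[0, "match"] == "tight"  # 0.8 <= 1
        table = match_subtypes_to_otus(subtypes, [502.0])
        assert table.loc[0, "match"] == "putative"  # 1 < 2 <= 2.5
        table = match_subtypes_to_otus(subtypes, [503.0])
        assert table.loc[0, "match"] == "unmatched"


class TestDyeOffset:
    def test_identical_histograms_give_zero(self):
        hist = [(420.0, 5.0), (500.0, 3.0), (610.0, 2.0)]
        est = estimate_dye_offset(hist, hist)
        assert est.offset_bp == 0 and not est.flat

    def test_plus_seven_shift_recovered_as_minus_seven(self):
        preds = [(420.0, 5.0), (500.0, 3.0), (610.0, 2.0), (700.0, 1.0)]
        otus = [(length + 7.0, h) for length, h in preds]
        assert estimate_dye_offset(otus, preds).offset_bp == -7

    def test_single_peaks_three_bp_apart(self):
        assert estimate_dye_offset([(503.0, 1.0)], [(500.0, 1.0)]).offset_bp == -3
        assert estimate_dye_offset([(497.0, 1.0)], [(500.0, 1.0)]).offset_bp == 3

    def test_flat_covariance_flagged(self):
        est = estimate_dye_offset([(500.0, 0.0)], [(600.0, 0.0)])
        assert est.flat and est.offset_bp == 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            estimate_dye_offset([], [(500.0, 1.0)])
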