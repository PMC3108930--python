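import numpy as np
import pytest
from scipy import stats

from domainprio.net_kernels import sg_kernel
from domainprio.profiles import (
    AssociationSet,
    PhenotypeSimilarity,
    RankTransform,
    SimilarityProfile,
    build_proximity_profile,
    build_similarity_profile,
    domain_phenotype_proximity,
    inverse_normal_transform,
    shuffle_associations,
    shuffle_similarity_profile,
)


@pytest.fixture(scope="module")
def toy_prox(toy_network):
    return sg_kernel(toy_network, beta=1.0)


class TestAssociationSet:
    def test_seed_phenotypes_sorted_with_counts(self, toy_assoc):
        assert toy_assoc.seed_phenotypes == ["p1", "p2", "p3", "p4"]
        assert toy_assoc.m == 4
        assert toy_assoc.domains_for("p1") == {"a", "b"}

    def test_without_drops_pairs(self, toy_assoc):
        eff = toy_assoc.without({("a", "p1")})
        assert eff.domains_for("p1") == {"b"}
        assert ("a", "p1") not in eff.pairs

    def test_without_unknown_pair_rejected(self, toy_assoc):
        with pytest.raises(ValueError):
            toy_assoc.without({("zz", "p1")})


class TestDomainPhenotypeProximity:
    def test_sums_proximities_over_known_domains(self, toy_prox, toy_assoc):
        # D(p1) = {a, b}; SG(a,a)=1, SG(a,b)=e^-1
        got = domain_phenotype_proximity("a", "p1", toy_prox, toy_assoc)
        assert got == pytest.approx(1.0 + np.exp(-1.0))

    def test_self_association_gives_kernel_diagonal(self, toy_prox, toy_assoc):
        assert domain_phenotype_proximity("e", "p4", toy_prox, toy_assoc) == 1.0

    def test_matches_explicit_loop_oracle(self, toy_prox, toy_assoc):
        for d in toy_prox.node_ids:
            for p in toy_assoc.seed_phenotypes:
                expect = sum(
                    toy_prox.values[toy_prox.index_of(d), toy_prox.index_of(d2)]
                    for d2 in toy_assoc.domains_for(p)
                )
                assert domain_phenotype_proximity(d, p, toy_prox, toy_assoc) == \
                    pytest.approx(expect)

    def test_unknown_domain_rejected(self, toy_prox, toy_assoc):
        with pytest.raises(KeyError, match="not in network"):
            domain_phenotype_proximity("zz", "p1", toy_prox, toy_assoc)

    def test_domain_missing_from_network_contributes_zero(self, toy_prox):
        assoc = AssociationSet([("a", "p1"), ("ghost", "p1"),
                                ("b", "p2"), ("c", "p3")])
        got = domain_phenotype_proximity("a", "p1", toy_prox, assoc)
        assert got == pytest.approx(1.0)  # only SG(a,a)


class TestBuildProximityProfile:
    def test_consistent_with_pointwise_values(self, toy_prox, toy_assoc):
        prof = build_proximity_profile("c", toy_assoc, toy_prox)
        assert prof.phenotype_ids == toy_assoc.seed_phenotypes
        for p, v in zip(prof.phenotype_ids, prof.values):
            assert v == pytest.approx(
                domain_phenotype_proximity("c", p, toy_prox, toy_assoc))

    def test_excluding_only_pair_drops_phenotype(self, toy_prox, toy_assoc):
        prof = build_proximity_profile("c", toy_assoc, toy_prox,
                                       exclude_pairs={("e", "p4")})
        assert "p4" not in prof.phenotype_ids

    def test_exclusion_equals_rebuild_from_scratch(self, toy_prox, toy_assoc):
        excl = {("a", "p1")}
        prof = build_proximity_profile("d", toy_assoc, toy_prox, exclude_pairs=excl)
        rebuilt = build_proximity_profile("d", toy_assoc.without(excl), toy_prox)
        assert prof.phenotype_ids == rebuilt.phenotype_ids
        assert np.allclose(prof.values, rebuilt.values)

    def test_too_few_phenotypes_rejected(self, toy_prox):
        assoc = AssociationSet([("a", "p1"), ("b", "p2")])
        with pytest.raises(ValueError, match="insufficient seed phenotypes"):
            build_proximity_profile("c", assoc, toy_prox)


class TestBuildSimilarityProfile:
    def test_non_seed_query_gets_all_seed_phenotypes(self, toy_similarity, toy_assoc):
        prof = build_similarity_profile("p5", toy_similarity, toy_assoc)
        assert prof.phenotype_ids == toy_assoc.seed_phenotypes

    def test_seed_query_excluded_by_default(self, toy_similarity, toy_assoc):
        prof = build_similarity_profile("p2", toy_similarity, toy_assoc)
        assert "p2" not in prof.phenotype_ids
        assert len(prof.phenotype_ids) == toy_assoc.m - 1

    def test_values_match_matrix_row(self, toy_similarity, toy_assoc):
        prof = build_similarity_profile("p3", toy_similarity, toy_assoc,
                                        exclude_query=False)
        i = toy_similarity.index_of("p3")
        for q, v in zip(prof.phenotype_ids, prof.values):
            assert v == toy_similarity.values[i, toy_similarity.index_of(q)]

    def test_unknown_phenotype_rejected(self, toy_similarity, toy_assoc):
        with pytest.raises(KeyError, match="not in similarity"):
            build_similarity_profile("nope", toy_similarity, toy_assoc)


class TestInverseNormalTransform:
    def test_three_values_blom(self):
        z = inverse_normal_transform(np.array([10.0, -3.0, 4.0]))
        # Blom c=3/8, m=3: plotting positions 0.625/3.25, 1.625/3.25, 2.625/3.25
        assert z[1] == pytest.approx(-0.86942, abs=1e-4)
        assert z[2] == pytest.approx(0.0, abs=1e-12)
        assert z[0] == pytest.approx(0.86942, abs=1e-4)

    def test_order_isomorphic_to_input(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        z = inverse_normal_transform(x)
        r = stats.spearmanr(x, z).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_ties_get_averaged_ranks(self):
        z = inverse_normal_transform(np.array([0.0, 0.0, 1.0, 2.0]))
        assert z[0] == z[1]

    def test_mean_near_zero_for_distinct_inputs(self):
        rng = np.random.default_rng(3)
        z = inverse_normal_transform(rng.uniform(size=101))
        assert abs(z.mean()) < 1e-6

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            inverse_normal_transform(np.ones(5))

    def test_custom_offset(self):
        z = inverse_normal_transform(np.array([1.0, 2.0, 3.0]), RankTransform(0.5))
        assert z[0] == pytest.approx(stats.norm.ppf(0.5 / 3.0))

    def test_invalid_offset(self):
        with pytest.raises(ValueError):
            RankTransform(0.7)


class TestShuffleAssociations:
    @pytest.mark.parametrize("mode", ["permute", "random_replace"])
    def test_per_phenotype_counts_preserved(self, scenario, mode):
        assoc = scenario.assoc
        out = shuffle_associations(assoc, list(scenario.network.node_ids), mode, 9)
        for p in assoc.seed_phenotypes:
            assert len(out.domains_for(p)) == len(assoc.domains_for(p))

    def test_permute_preserves_domain_multiset(self, toy_assoc):
        out = shuffle_associations(toy_assoc, ["a", "b", "c", "d", "e"], "permute", 4)
        assert sorted(d for d, _ in out.pairs) == sorted(d for d, _ in toy_assoc.pairs)

    def test_deterministic_given_seed(self, toy_assoc):
        doms = ["a", "b", "c", "d", "e", "x", "y"]
        a = shuffle_associations(toy_assoc, doms, "random_replace", 7)
        b = shuffle_associations(toy_assoc, doms, "random_replace", 7)
        assert a.pairs == b.pairs

    def test_unknown_mode_rejected(self, toy_assoc):
        with pytest.raises(ValueError, match="mode"):
            shuffle_associations(toy_assoc, ["a"], "bogus", 0)


class TestShuffleSimilarityProfile:
    def test_value_multiset_preserved(self):
        prof = SimilarityProfile(["a", "b", "c", "d"], np.array([0.1, 0.4, 0.2, 0.9]))
        out = shuffle_similarity_profile(prof, 3)
        assert sorted(out.values) == sorted(prof.values)
        assert out.phenotype_ids == prof.phenotype_ids

    def test_deterministic_given_seed(self):
        prof = SimilarityProfile(list("abcdef"), np.arange(6.0))
        assert np.array_equal(shuffle_similarity_profile(prof, 5).values,
                              shuffle_similarity_profile(prof, 5).values)

    def test_both_orders_of_length_two_occur(self):
        prof = SimilarityProfile(["a", "b"], np.array([0.0, 1.0]))
        firsts = {shuffle_similarity_profile(prof, s).values[0] for s in range(10)}
        assert firsts == {0.0, 1.0}


class TestPhenotypeSimilarity:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            PhenotypeSimilarity(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="similarity"):
            PhenotypeSimilarity(["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]))


def test_profile_indices_align(toy_prox, toy_similarity, toy_assoc):
    """Proximity and similarity profiles share one phenotype index."""
    sprof = build_similarity_profile("p5", toy_similarity, toy_assoc)
    xprof = build_proximity_profile("c", toy_assoc, toy_prox)
    assert sprof.phenotype_ids == xprof.phenotype_ids
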