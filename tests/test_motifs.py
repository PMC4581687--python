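import pytest

from dignet import motifs
from dignet.errors import ParameterError
from dignet.regnet import RegNetwork
from dignet.synthetic_data import random_typed_network


def _keys(instances):
    return {m.key() for m in instances}


class TestFindTriplets:
    def test_empty_network(self):
        assert motifs.find_triplets(RegNetwork()) == []

    def test_minimal_ffl(self, tiny_net):
        found = motifs.find_triplets(tiny_net)
        assert _keys(found) == {("triplet", "m3", "t3", ("g5",))}

    def test_cotargeting_without_regulator_edge_is_not_an_ffl(self, tiny_net):
        # m1/t1 co-target g1 and g2 but share no miRNA-TF edge
        strict = _keys(motifs.find_triplets(tiny_net))
        assert ("triplet", "m1", "t1", ("g1",)) not in strict
        loose = _keys(motifs.find_triplets(tiny_net, require_regulator_edge=False))
        assert ("triplet", "m1", "t1", ("g1",)) in loose


class TestFindJointAndCrosstalk:
    def test_minimal_joint(self, tiny_net):
        assert _keys(motifs.find_joint(tiny_net)) == {("joint", "m1", "t1", ("g1", "g2"))}

    def test_partial_co_regulation_is_not_joint(self):
        net = RegNetwork(
            mirnas={"m"},
            tfs={"t"},
            genes={"g1", "g2"},
            mirna_gene={("m", "g1")},
            tf_gene={("t", "g1"), ("t", "g2")},
            gene_gene={("g1", "g2")},
        )
        assert motifs.find_joint(net) == []

    def test_minimal_crosstalk_with_role_order(self, tiny_net):
        found = _keys(motifs.find_crosstalk(tiny_net))
        assert ("crosstalk", "m2", "t2", ("g3", "g4")) in found

    def test_full_pattern_is_joint_not_crosstalk(self, tiny_net):
        # m1/t1 both regulate both g1 and g2
        cross = _keys(motifs.find_crosstalk(tiny_net))
        assert not any(k[1] == "m1" and k[2] == "t1" for k in cross)
        relaxed = _keys(motifs.find_crosstalk(tiny_net, exclusive=False))
        assert ("crosstalk", "m1", "t1", ("g1", "g2")) in relaxed

    def test_no_gene_gene_edge_no_4_node_motif(self):
        net = RegNetwork(
            mirnas={"m"},
            tfs={"t"},
            genes={"g1", "g2"},
            mirna_gene={("m", "g2"), ("m", "g1")},
            tf_gene={("t", "g1"), ("t", "g2")},
        )
        assert motifs.find_crosstalk(net) == []
        assert motifs.find_joint(net) == []

    def test_joint_and_crosstalk_are_disjoint_but_nested_without_exclusivity(self):
        net = random_typed_network(8, 6, 20, 0.25, 0.25, 0.1, 0.05, 0.2, seed=5)
        joint = _keys(motifs.find_joint(net))
        cross = _keys(motifs.find_crosstalk(net))
        joint_quads = {(k[1], k[2], frozenset(k[3])) for k in joint}
        cross_quads = {(k[1], k[2], frozenset(k[3])) for k in cross}
        assert not joint_quads & cross_quads
        relaxed = _keys(motifs.find_crosstalk(net, exclusive=False))
        relaxed_quads = {(k[1], k[2], frozenset(k[3])) for k in relaxed}
        # every joint quadruple also matches the crosstalk edge pattern
        assert joint_quads <= relaxed_quads

    def test_oracle_equivalence_on_random_networks(self):
        for seed in range(6):
            net = random_typed_network(10, 8, 25, 0.15, 0.15, 0.08, 0.04, 0.12, seed=seed)
            for mtype in motifs.MOTIF_TYPES:
                fast = _keys(motifs.find_motifs(net, mtype))
                slow = _keys(motifs.brute_force_enumerate(net, mtype))
                assert fast == slow, f"{mtype} mismatch at seed {seed}"


class TestSubnetAndHubs:
    def test_single_triplet_subnet(self, tiny_net):
        sub = motifs.build_subnet(motifs.find_triplets(tiny_net))
        assert sub.nodes == {"m3", "t3", "g5"}
        assert len(sub.edges) == 3

    def test_shared_edges_counted_once(self):
        net = RegNetwork(
            mirnas={"m1", "m2"},
            tfs={"t"},
            genes={"g1", "g2"},
            mirna_gene={("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")},
            tf_gene={("t", "g1"), ("t", "g2")},
            gene_gene={("g1", "g2")},
        )
        sub = motifs.build_subnet(motifs.find_joint(net))
        assert sub.nodes == {"m1", "m2", "t", "g1", "g2"}
        # t's edges and the gene-gene edge shared by both joints appear once
        assert len(sub.edges) == 7

    def test_mixed_types_rejected_and_empty_allowed(self, tiny_net):
        mixed = motifs.find_triplets(tiny_net) + motifs.find_joint(tiny_net)
        with pytest.raises(ParameterError):
            motifs.build_subnet(mixed)
        assert motifs.build_subnet([]).nodes == set()

    def test_hub_ranking_degree_then_lexicographic(self):
        net = RegNetwork(
            mirnas={"mA", "mB", "mC"},
            tfs={"t"},
            genes={"g1", "g2", "g3"},
            mirna_gene={
                ("mA", "g1"),
                ("mA", "g2"),
                ("mB", "g1"),
                ("mB", "g2"),
                ("mC", "g3"),
            },
            tf_gene={("t", "g1"), ("t", "g2"), ("t", "g3")},
            mirna_tf={("mA", "t"), ("mB", "t"), ("mC", "t")},
        )
        sub = motifs.build_subnet(motifs.find_triplets(net))
        ranked = motifs.rank_hubs(sub, "miRNA", top_k=2)
        assert [n for n, _ in ranked] == ["mA", "mB"]  # tie broken by id
        full = motifs.rank_hubs(sub, "miRNA", top_k=10)
        assert len(full) == 3  # top_k larger than the pool returns everyone


class TestExtractCachets:
    def _triplets(self, spec):
        return [
            motifs.MotifInstance("triplet", m, t, (g,)) for m, t, g in spec
        ]

    def test_distinct_gene_counting(self):
        inst = [
            motifs.MotifInstance("joint", "m", "t", ("a", "b")),
            motifs.MotifInstance("joint", "m", "t", ("b", "c")),
            motifs.MotifInstance("joint", "m", "t", ("c", "d")),
        ]
        cachets = motifs.extract_cachets(inst)
        assert cachets.ranked == [("m", "t", 4)]

    def test_top_one_percent_of_100_pairs_is_one_pair(self):
        spec = [(f"m{i}", f"t{i}", "g0") for i in range(99)] + [("mX", "tX", "gA")]
        inst = self._triplets(spec) + [motifs.MotifInstance("triplet", "mX", "tX", ("gB",))]
        cachets = motifs.extract_cachets(inst, quantile=0.01)
        assert cachets.cutoff_rank == 1
        assert cachets.ranked[0] == ("mX", "tX", 2)
        assert len(cachets.ranked) == 1  # everyone else has count 1, below cutoff count 2

    def test_total_tie_returns_everyone(self):
        inst = self._triplets([("m1", "t1", "g1"), ("m2", "t2", "g2"), ("m3", "t3", "g3")])
        cachets = motifs.extract_cachets(inst, quantile=0.01)
        assert len(cachets.ranked) == 3

    def test_empty_instances_is_an_error(self):
        with pytest.raises(ParameterError):
            motifs.extract_cachets([])
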