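import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonemark.clonality import (
    build_tree,
    compare_baf,
    cross_patient_overlap,
    partition_mutations,
    td_shared_count,
)

from conftest import make_snv


def key(i):
    return ("1", i, "C", "T")


def brute_force_partition(sets):
    """Venn membership evaluated key by key over all regions."""
    names = list(sets)
    universe = set().union(*sets.values())
    trunk, branch, private = set(), {}, {n: set() for n in names}
    for k in universe:
        members = tuple(n for n in names if k in sets[n])
        if len(members) == len(names):
            trunk.add(k)
        elif len(members) == 2:
            branch.setdefault(frozenset(members), set()).add(k)
        elif len(members) == 1:
            private[members[0]].add(k)
    return trunk, branch, private


class TestPartition:
    def test_three_set_example(self):
        part = partition_mutations(
            {"T": [key(1), key(2), key(3)], "LN": [key(1), key(2)], "D": [key(1)]}
        )
        assert part.trunk == {key(1)}
        assert part.branch[frozenset(("T", "LN"))] == {key(2)}
        assert part.private["T"] == {key(3)}
        assert part.trunk_fraction == pytest.approx(1 / 3)

    def test_two_different_tp53_mutations_are_not_trunk(self):
        # T and LN carry one TP53 hotspot, D a different one: no trunk,
        # a T&LN branch, and a D-private mutation
        r273h = ("17", 7577120, "G", "A")
        y163c = ("17", 7578442, "A", "G")
        part = partition_mutations({"T": [r273h], "LN": [r273h], "D": [y163c]})
        assert part.trunk == set()
        assert part.branch[frozenset(("T", "LN"))] == {r273h}
        assert part.private["D"] == {y163c}
        assert td_shared_count(part, "T", "D") == 0

    def test_identical_callsets_give_trunk_fraction_one(self):
        ks = [key(i) for i in range(50)]
        part = partition_mutations({"T": ks, "LN": ks, "D": ks})
        assert part.trunk_fraction == 1.0
        assert td_shared_count(part, "T", "D") == 50

    def test_two_sample_patient_trunk_is_pairwise_intersection(self):
        part = partition_mutations({"T": [key(1), key(2)], "D": [key(1), key(3)]})
        assert part.trunk == {key(1)}
        assert not part.branch
        assert td_shared_count(part, "T", "D") == 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            partition_mutations({"T": [key(1)]})

    @given(st.data())
    def test_matches_brute_force_venn(self, data):
        universe = list(range(30))
        sets = {
            n: set(data.draw(st.sets(st.sampled_from(universe), max_size=20)))
            for n in ("T", "LN", "D")
        }
        sets = {n: {key(i) for i in s} for n, s in sets.items()}
        if sum(len(s) for s in sets.values()) == 0:
            return
        part = partition_mutations(sets)
        trunk, branch, private = brute_force_partition(sets)
        assert part.trunk == trunk
        assert {p: s for p, s in part.branch.items() if s} == branch
        assert part.private == private
        part.check()  # disjoint cover

    def test_invariant_to_sample_relabeling(self):
        sets = {"T": {key(1), key(2)}, "LN": {key(2)}, "D": {key(1), key(3)}}
        a = partition_mutations(sets)
        b = partition_mutations({"D": sets["D"], "T": sets["T"], "LN": sets["LN"]})
        assert a.trunk == b.trunk and a.private == b.private and a.branch == b.branch


class TestTree:
    def test_path_lengths_from_gene_counts(self):
        keys = {f"set{i}": [("1", 100 * i + j, "C", "T") for j in range(n)]
                for i, n in enumerate([10, 5, 2, 3])}
        part = partition_mutations(
            {
                "T": keys["set0"] + keys["set1"],
                "LN": keys["set0"] + keys["set2"],
                "D": keys["set0"] + keys["set3"],
            }
        )
        gene_of = {k: f"g{k[1]}" for ks in keys.values() for k in ks}
        tree = build_tree(part, gene_of)
        assert tree.trunk_genes == 10
        assert tree.path_length("T") == 15
        assert tree.path_length("LN") == 12
        assert tree.path_length("D") == 13

    def test_empty_trunk_gives_star_tree(self):
        part = partition_mutations({"T": [key(1)], "LN": [key(2)], "D": [key(3)]})
        tree = build_tree(part, {key(i): f"g{i}" for i in range(1, 4)})
        assert tree.trunk_genes == 0
        assert tree.newick.endswith(":0)germline;")

    def test_two_variants_in_one_gene_count_once(self):
        ks = [("1", 1, "C", "T"), ("1", 9, "C", "A"), ("2", 5, "C", "T")]
        part = partition_mutations({"T": ks, "D": ks})
        tree = build_tree(part, {ks[0]: "TP53", ks[1]: "TP53", ks[2]: "KMT2D"})
        assert tree.trunk_genes == 2

    def test_newick_parses_with_dendropy(self):
        import dendropy

        part = partition_mutations({"T": [key(1), key(2)], "LN": [key(1)], "D": [key(3)]})
        tree = build_tree(part, {key(i): f"g{i}" for i in range(1, 4)})
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {"T", "LN", "D"}


class TestBafComparison:
    def test_identical_callsets_statistic_one(self):
        calls = [make_snv(pos=i, t_depth=50, t_alt=20) for i in range(1, 21)]
        cmp = compare_baf(calls, calls)
        assert cmp.shared_cluster_statistic == 1.0

    def test_disjoint_callsets_statistic_zero(self):
        a = [make_snv(pos=i, t_alt=20) for i in range(1, 11)]
        b = [make_snv(pos=i, t_alt=20) for i in range(100, 110)]
        cmp = compare_baf(a, b)
        assert cmp.shared_cluster_statistic == 0.0
        assert len(cmp.table) == 20

    def test_partial_overlap_counts_shared_fraction(self):
        shared = [make_snv(pos=i, t_depth=100, t_alt=40) for i in range(1, 5)]
        a = shared + [make_snv(pos=50, t_alt=20)]
        b = shared + [make_snv(pos=60, t_alt=20)]
        cmp = compare_baf(a, b)
        assert cmp.shared_cluster_statistic == pytest.approx(4 / 6)


class TestCrossPatientOverlap:
    def test_disjoint_patients_all_zero(self):
        cohort = {
            "P1": {"T": [key(1)], "D": [key(2)]},
            "P2": {"T": [key(10)], "D": [key(11)]},
        }
        mat = cross_patient_overlap(cohort)
        vals = mat.to_numpy()
        assert np.nansum(vals) == 0

    def test_planted_common_key_counts_one(self):
        cohort = {
            "P1": {"T": [key(1), key(7)]},
            "P2": {"T": [key(7)]},
        }
        mat = cross_patient_overlap(cohort)
        assert mat.loc[("P1", "T"), ("P2", "T")] == 1
        # same-patient cells excluded
        assert np.isnan(mat.loc[("P1", "T"), ("P1", "T")])
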