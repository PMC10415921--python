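import itertools
import random

import pytest

from wgt import (
    MSA,
    FormatError,
    LabeledDigraph,
    SolverConfig,
    brute_force_recognize,
    check_wheeler,
    detect_label_conflict,
    e_max,
    find_roots,
    gen_complete_wg,
    gen_debruijn,
    gen_dnfa_wg,
    gen_pseudo_debruijn,
    gen_random_wg,
    gen_revdet,
    gen_trie,
    max_same_label_outdegree,
    random_dna_msa,
    read_msa,
    recognize,
    solve_dnfa_profile,
    take_rows,
    truncate_columns,
    write_dot,
    write_msa,
)


class TestMsa:
    def test_read_two_records(self):
        msa = read_msa(">a\nACG-T\n>b\nAC--T\n")
        assert len(msa.records) == 2 and msa.length == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="unequal"):
            read_msa(">a\nACGTT\n>b\nACGGTA\n")

    def test_empty_input_rejected(self):
        with pytest.raises(FormatError):
            read_msa("")

    def test_lowercase_uppercased_round_trip(self):
        msa = read_msa(">a\nacgt\n")
        assert msa.records[0][1] == "ACGT"
        assert read_msa(write_msa(msa)).records == msa.records

    def test_truncate_columns(self):
        msa = read_msa(">a\n" + "ACGT" * 25 + "\n")
        assert truncate_columns(msa, 1, 100).records == msa.records
        assert truncate_columns(msa, 2, 41).length == 40
        with pytest.raises(ValueError):
            truncate_columns(msa, 5, 4)
        with pytest.raises(ValueError):
            truncate_columns(msa, 0, 10)

    def test_take_rows(self):
        msa = read_msa(">a\nAC\n>b\nAG\n>c\nAT\n")
        assert len(take_rows(msa, 2).records) == 2

    def test_gap_only_columns_do_not_change_kmer_graphs(self):
        plain = MSA(records=[("a", "ACGTAC"), ("b", "TTGTAC")])
        gappy = MSA(records=[("a", "ACG--TAC"), ("b", "TTG--TAC")])
        for k in (3, 4):
            g1, g2 = gen_debruijn(plain, k), gen_debruijn(gappy, k)
            assert g1.nodes == g2.nodes and sorted(g1.edges) == sorted(g2.edges)
        t1, t2 = gen_trie(plain), gen_trie(gappy)
        assert t1.nodes == t2.nodes and sorted(t1.edges) == sorted(t2.edges)


class TestTrie:
    def test_single_sequence(self):
        trie = gen_trie(MSA(records=[("a", "A")]))
        assert (trie.n, trie.e) == (2, 1) and trie.alphabet == ["A"]

    def test_shared_prefix(self):
        trie = gen_trie(MSA(records=[("a", "AC"), ("b", "AG")]))
        assert (trie.n, trie.e) == (4, 3)
        assert sorted(a for _, _, a in trie.edges) == ["A", "C", "G"]

    def test_single_root_and_bfs_names(self):
        trie = gen_trie(MSA(records=[("a", "AC"), ("b", "AG")]))
        assert find_roots(trie) == ["1"]
        assert trie.nodes == {"1", "2", "3", "4"}

    @pytest.mark.parametrize("seed", range(4))
    def test_outputs_are_wheeler_one_nfas(self, seed):
        trie = gen_trie(random_dna_msa(4, 30, seed=seed))
        assert max_same_label_outdegree(trie) == 1
        assert recognize(trie, SolverConfig()).verdict == "wheeler"


class TestDeBruijn:
    def test_worked_example_unpadded(self):
        g = gen_debruijn(MSA(records=[("a", "ACGT")]), 3, sentinel=False)
        assert g.nodes == {"AC", "CG", "GT"}
        assert g.edges == [("AC", "CG", "G"), ("CG", "GT", "T")]

    def test_homopolymer_self_loop_unpadded(self):
        g = gen_debruijn(MSA(records=[("a", "AAAA")]), 3, sentinel=False)
        assert g.nodes == {"AA"} and g.edges == [("AA", "AA", "A")]

    def test_sentinel_padding_gives_single_root(self):
        g = gen_debruijn(random_dna_msa(5, 30, seed=0), 4)
        assert find_roots(g) == ["$$$"]
        assert all("$" not in a for _, _, a in g.edges)

    def test_rows_too_short_rejected(self):
        with pytest.raises(ValueError, match="k-1"):
            gen_debruijn(MSA(records=[("a", "AC")]), 5, sentinel=False)

    @pytest.mark.parametrize("seed", range(4))
    def test_padded_outputs_are_wheeler_one_nfas(self, seed):
        g = gen_debruijn(random_dna_msa(4, 50, seed=seed), 4)
        assert detect_label_conflict(g) is None
        assert max_same_label_outdegree(g) == 1
        assert recognize(g, SolverConfig()).verdict == "wheeler"

    def test_first_character_convention_differs(self):
        msa = MSA(records=[("a", "ACGT")])
        g = gen_debruijn(msa, 3, label_convention="first", sentinel=False)
        assert g.edges == [("AC", "CG", "C"), ("CG", "GT", "G")]


class TestPseudoDeBruijn:
    def test_never_merges(self):
        g = gen_pseudo_debruijn(MSA(records=[("a", "ACGT")]), 3)
        assert (g.n, g.e) == (3, 2)

    def test_homopolymer_chain_instead_of_self_loop(self):
        g = gen_pseudo_debruijn(MSA(records=[("a", "AAAA")]), 3)
        assert g.n == 3 and all(u != v for u, v, _ in g.edges)

    def test_verdict_can_differ_from_debruijn(self):
        # shared k-mers across rows merge in one graph but not the other
        msa = MSA(records=[("a", "ACGT"), ("b", "TCGT")])
        db = gen_debruijn(msa, 3, sentinel=False)
        pdb = gen_pseudo_debruijn(msa, 3)
        assert pdb.n > db.n


class TestRevDet:
    def test_single_row(self):
        g = gen_revdet(MSA(records=[("a", "AC")]))
        assert g.n == 2 and g.edges == [("c1A", "c2C", "C")]

    def test_identical_rows_deduplicate(self):
        one = gen_revdet(MSA(records=[("a", "ACG")]))
        two = gen_revdet(MSA(records=[("a", "ACG"), ("b", "ACG")]))
        assert one.nodes == two.nodes and one.edges == two.edges

    def test_shared_column_character_merges(self):
        g = gen_revdet(MSA(records=[("a", "AC"), ("b", "GC")]))
        assert g.n == 3 and g.e == 2
        assert detect_label_conflict(g) is None
        assert brute_force_recognize(g).verdict == "wheeler"

    def test_gaps_skipped_per_row(self):
        g = gen_revdet(MSA(records=[("a", "A-C")]))
        assert g.edges == [("c1A", "c3C", "C")]


class TestEMax:
    def test_reference_point(self):
        assert e_max(7, 2, 1) == 18

    def test_two_node_single_label(self):
        assert e_max(2, 1, 1) == 2
        # brute-force maximal edge search on 2 nodes, 1 label, exactly one
        # 0-indegree node (the bound is a function of the root count r)
        best = 0
        nodes = {"a", "b"}
        all_edges = [(u, v, "A") for u in nodes for v in nodes]
        for size in range(len(all_edges), 0, -1):
            for subset in itertools.combinations(all_edges, size):
                g = LabeledDigraph(nodes=nodes, edges=list(subset))
                if len(find_roots(g)) != 1:
                    continue
                if brute_force_recognize(g).verdict == "wheeler":
                    best = max(best, size)
            if best:
                break
        assert best == 2

    def test_both_printed_forms_agree(self):
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(1, 50)
            sigma = rng.randint(1, 10)
            r = rng.randint(0, n)
            assert e_max(n, sigma, r) == (n - 1) * (sigma + 1) - r + 1

    def test_argument_range(self):
        with pytest.raises(ValueError):
            e_max(0, 1, 0)
        with pytest.raises(ValueError):
            e_max(5, 1, 6)


class TestCompleteWheelerGraph:
    def test_reference_edge_count(self):
        g, ordering = gen_complete_wg(7, 2, 1, seed=3)
        assert g.e == 18
        assert check_wheeler(g, ordering)[0]

    def test_three_nodes_single_label(self):
        g, ordering = gen_complete_wg(3, 1, 1, seed=0)
        assert g.e == e_max(3, 1, 1) == 4
        assert check_wheeler(g, ordering)[0]

    @pytest.mark.parametrize("n,sigma,r", [(5, 1, 1), (6, 2, 1), (8, 3, 2), (12, 4, 3)])
    def test_edge_count_and_validity(self, n, sigma, r):
        for seed in range(3):
            g, ordering = gen_complete_wg(n, sigma, r, seed=seed)
            assert g.e == e_max(n, sigma, r)
            assert check_wheeler(g, ordering)[0]
            assert len(find_roots(g)) == r

    def test_no_root_preserving_edge_addable(self):
        # completeness at fixed root count: adding any missing labeled edge
        # whose destination already has an in-edge breaks the ordering.
        # (Edges into a root lower r, and e_max grows as r shrinks, so such
        # additions can legitimately remain Wheeler.)
        for n, sigma, r, seed in [(4, 1, 1, 0), (5, 2, 1, 1), (5, 2, 2, 2)]:
            g, ordering = gen_complete_wg(n, sigma, r, seed=seed)
            present = set(g.edges)
            roots = set(find_roots(g))
            for u in sorted(g.nodes):
                for v in sorted(g.nodes - roots):
                    for a in g.alphabet:
                        if (u, v, a) in present:
                            continue
                        g2 = LabeledDigraph(nodes=g.nodes, edges=g.edges + [(u, v, a)])
                        assert not check_wheeler(g2, ordering)[0]

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_complete_wg(3, 3, 1, seed=0)


class TestRandomWheelerGraph:
    def test_near_complete(self):
        n, sigma = 10, 2
        e = e_max(n, sigma, 1) - 1
        g = gen_random_wg(n, e, sigma, seed=4)
        assert g.e == e
        assert recognize(g, SolverConfig()).verdict == "wheeler"

    def test_spanning_skeleton_only(self):
        g = gen_random_wg(8, 7, 2, seed=1)
        assert g.e == 7
        assert len(find_roots(g)) == 1
        assert recognize(g, SolverConfig()).verdict == "wheeler"

    def test_byte_identical_dot_for_same_seed(self):
        a = write_dot(gen_random_wg(20, 40, 3, seed=9))
        b = write_dot(gen_random_wg(20, 40, 3, seed=9))
        assert a == b
        c = write_dot(gen_random_wg(20, 40, 3, seed=10))
        assert a != c

    def test_edge_range_validated(self):
        with pytest.raises(ValueError):
            gen_random_wg(5, e_max(5, 2, 1), 2, seed=0)
        with pytest.raises(ValueError):
            gen_random_wg(5, 3, 2, seed=0)


class TestDnfaProfile:
    def test_even_split(self):
        p = solve_dnfa_profile(13, 12, 2, 3)
        # e_i = 6, d = 3: x = (1, 1, 1)
        assert p.x[0] == {1: 1, 2: 1, 3: 1}

    def test_residual_to_x1(self):
        p = solve_dnfa_profile(15, 14, 2, 3)
        # e_i = 7: residual 1 goes to x_1
        assert p.x[0] == {1: 2, 2: 1, 3: 1}

    def test_degenerate_d1(self):
        p = solve_dnfa_profile(9, 10, 2, 1)
        assert p.x[0] == {1: 5} and p.n_min(0) == 1

    def test_conservation_exact(self):
        for n, e, sigma, d in [(50, 60, 2, 3), (100, 150, 3, 2), (1000, 1200, 4, 4)]:
            p = solve_dnfa_profile(n, e, sigma, d)
            for li in range(sigma):
                assert sum(k * c for k, c in p.x[li].items()) == p.e_i[li]
                assert p.n_min(li) <= p.n_i[li]

    def test_infeasibility_named(self):
        with pytest.raises(ValueError, match="n_min"):
            solve_dnfa_profile(50, 120, 2, 3)


class TestDnfaGenerator:
    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_d_attained_exactly_and_wheeler(self, d):
        g = gen_dnfa_wg(60, 80, 2, d, seed=d)
        assert max_same_label_outdegree(g) == d
        assert recognize(g, SolverConfig()).verdict == "wheeler"

    def test_every_block_node_has_an_in_edge(self):
        g = gen_dnfa_wg(40, 50, 2, 2, seed=7)
        assert find_roots(g) == ["v1"]

    def test_deterministic_output(self):
        assert write_dot(gen_dnfa_wg(30, 40, 2, 2, seed=5)) == write_dot(
            gen_dnfa_wg(30, 40, 2, 2, seed=5)
        )
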