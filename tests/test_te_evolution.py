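"""Identity networks, Dollo parsimony, back-translation and NG86 Ka/Ks,
each checked against an independent brute-force oracle."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from temeth import simulate, te_evolution
from temeth.te_evolution import kaks_ng86

# ---------------------------------------------------------------- identity


def levenshtein(a, b):
    """Textbook DP edit distance (the identity oracle)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert te_evolution.sequence_identity("MKVLL", "MKVLL") == 1.0

    def test_hand_example(self):
        assert te_evolution.sequence_identity("MKV", "MKL") \
            == pytest.approx(2 / 3)

    def test_matches_dp_oracle(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(20, 60))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(20, 60))))
            expected = 1 - levenshtein(a, b) / max(len(a), len(b))
            assert te_evolution.sequence_identity(a, b) \
                == pytest.approx(expected)

    def test_hit_table_mode_symmetrised(self):
        hits = pd.DataFrame([
            ("a", "b", 90.0, 500), ("b", "a", 85.0, 480),
            ("a", "a", 100.0, 999),
        ], columns=["qseqid", "sseqid", "pident", "bitscore"])
        g = te_evolution.pairwise_identity(hit_table=hits)
        assert g["a"]["b"]["weight"] == pytest.approx(0.9)
        assert not g.has_edge("a", "a")

    def test_duplicate_ids_rejected_and_dedup(self):
        seqs = {"x": "MKV", "y": "MKV", "z": "MML"}
        assert set(te_evolution.dedup_identical(seqs)) == {"x", "z"}


class TestClusterComponents:
    def _graph(self, edges):
        import networkx as nx

        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        return g

    def test_threshold_examples(self):
        g = self._graph([("A", "B", 0.9), ("B", "C", 0.7)])
        assert te_evolution.cluster_components(g, 0.8) \
            == [["A", "B"], ["C"]]
        assert te_evolution.cluster_components(g, 0.6) == [["A", "B", "C"]]

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            nodes = [f"s{i}" for i in range(n)]
            edges = [(nodes[i], nodes[j], float(rng.uniform(0, 1)))
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.3]
            g = self._graph(edges)
            g.add_nodes_from(nodes)
            t = 0.5
            comps = te_evolution.cluster_components(g, t)
            # oracle: repeated merging until fixpoint
            groups = {n: {n} for n in nodes}
            changed = True
            while changed:
                changed = False
                for u, v, w in edges:
                    if w >= t and groups[u] is not groups[v]:
                        merged = groups[u] | groups[v]
                        for m in merged:
                            groups[m] = merged
                        changed = True
            oracle = {frozenset(s) for s in groups.values()}
            assert {frozenset(c) for c in comps} == oracle

    def test_raising_threshold_only_splits(self, rng):
        nodes = [f"s{i}" for i in range(8)]
        edges = [(a, b, float(rng.uniform(0, 1)))
                 for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if rng.random() < 0.4]
        g = self._graph(edges)
        g.add_nodes_from(nodes)
        coarse = te_evolution.cluster_components(g, 0.3)
        fine = te_evolution.cluster_components(g, 0.7)
        for comp in fine:
            assert any(set(comp) <= set(c) for c in coarse)


class TestPresenceMatrix:
    def test_single_species_cluster(self):
        pres, cnt = te_evolution.build_presence_matrix(
            [["x1", "x2"]], {"x1": "speciesA", "x2": "speciesA"},
            all_species=["speciesA", "speciesB", "speciesC", "speciesD"])
        assert pres.loc["sf1"].tolist() == [1, 0, 0, 0]
        assert cnt.loc["sf1", "speciesA"] == 2

    def test_unlabeled_sequence_rejected(self):
        with pytest.raises(ValueError, match="species"):
            te_evolution.build_presence_matrix([["x1"]], {})

    def test_empty_components_give_empty_matrix(self):
        pres, _ = te_evolution.build_presence_matrix([], {"x": "sp"})
        assert pres.empty


# ---------------------------------------------------------------- Dollo

TREE4 = "((A,B),(C,D));"
TREE6 = "(((A,B),(C,D)),(E,F));"


def dollo_oracle(newick, pattern, tips):
    """Exhaustive minimisation over single-gain + loss-edge assignments."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted")
    nodes = list(tree.preorder_node_iter())

    def tips_below(node):
        return {l.taxon.label for l in node.leaf_iter()}

    present = {t for t, s in zip(tips, pattern) if s}
    if not present:
        return 0, 0  # no gain, no losses
    best = None
    for gain in nodes:
        if not present <= tips_below(gain):
            continue
        below = [n for n in gain.preorder_iter() if n is not gain]
        for r in range(len(below) + 1):
            if best is not None and 1 + r >= best[0]:
                break
            for lost in itertools.combinations(below, r):
                lost_set = set(lost)
                reach = set()

                def walk(n):
                    if n in lost_set:
                        return
                    if n.is_leaf():
                        reach.add(n.taxon.label)
                    for c in n.child_nodes():
                        walk(c)

                walk(gain)
                if reach == present:
                    cand = (1 + r, r)
                    if best is None or cand < best:
                        best = cand
                    break
    return best


class TestDolloParsimony:
    def test_all_present_gain_at_root_no_loss(self):
        matrix = pd.DataFrame([[1, 1, 1, 1]], index=["sf1"],
                              columns=list("ABCD"))
        per, totals = te_evolution.dollo_parsimony(TREE4, matrix)
        assert per.loc[0, "n_losses"] == 0
        assert totals["gains"].sum() == 1

    def test_clade_gain(self):
        matrix = pd.DataFrame([[1, 1, 0, 0]], index=["sf1"],
                              columns=list("ABCD"))
        per, _ = te_evolution.dollo_parsimony(TREE4, matrix)
        assert per.loc[0, "n_losses"] == 0
        # gain at the A+B ancestor, not the root
        t = te_evolution._load_tree(TREE4)
        ab = {l.taxon.label for l in t.mrca(
            taxa=[x for x in t.taxon_namespace if x.label in "AB"]
        ).leaf_iter()}
        assert ab == {"A", "B"}

    def test_single_loss_pattern(self):
        matrix = pd.DataFrame([[1, 0, 1, 1]], index=["sf1"],
                              columns=list("ABCD"))
        per, _ = te_evolution.dollo_parsimony(TREE4, matrix)
        assert per.loc[0, "n_losses"] == 1
        assert per.loc[0, "loss_edges"] == ("B",)

    @pytest.mark.parametrize("newick,tips", [
        (TREE4, list("ABCD")), (TREE6, list("ABCDEF"))])
    def test_matches_exhaustive_oracle(self, newick, tips):
        for bits in itertools.product([0, 1], repeat=len(tips)):
            matrix = pd.DataFrame([list(bits)], index=["sf"], columns=tips)
            per, _ = te_evolution.dollo_parsimony(newick, matrix)
            oracle = dollo_oracle(newick, bits, tips)
            if not any(bits):
                assert per.loc[0, "gain_node"] is None
                continue
            assert (1 + per.loc[0, "n_losses"], per.loc[0, "n_losses"]) \
                == oracle

    def test_unrooted_polytomy_rejected(self):
        t = dendropy.Tree.get(data="(A,B,C,D);", schema="newick")
        t.is_rooted = False
        matrix = pd.DataFrame([[1, 0, 1, 0]], index=["sf"],
                              columns=list("ABCD"))
        with pytest.raises(ValueError, match="rooted"):
            te_evolution.dollo_parsimony(t, matrix)


# ------------------------------------------------------- codon alignments


class TestBacktranslate:
    def test_gap_becomes_triple_gap(self):
        out = te_evolution.backtranslate_alignment(
            {"s": "M-K"}, {"s": "ATGAAA"})
        assert out["s"] == "ATG---AAA"

    def test_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 1"):
            te_evolution.backtranslate_alignment(
                {"s": "M-K"}, {"s": "TTGAAA"})

    def test_terminal_stop_tolerated(self):
        out = te_evolution.backtranslate_alignment(
            {"s": "MK"}, {"s": "ATGAAATAA"})
        assert out["s"] == "ATGAAA"

    def test_translation_round_trip(self):
        pairs = simulate.simulate_codon_pair_set(3, 60, omega=0.5, seed=8)
        for i, (a, b) in enumerate(pairs):
            prot = str(Seq(a).translate())
            aln = {"x": prot[:20] + "-" * 5 + prot[20:]}
            # alignment gaps do not disturb the codon threading
            out = te_evolution.backtranslate_alignment(aln, {"x": a})
            assert out["x"].replace("-", "") == a

    def test_gap_rich_filter(self):
        aln = {"good": "ATGAAA", "bad": "ATG---"}
        kept = te_evolution.filter_gap_rich(aln, min_occupancy=0.6)
        assert set(kept) == {"good"}


# ---------------------------------------------------------------- NG86

STOPS = {"TAA", "TAG", "TGA"}


def ng86_oracle(a, b):
    """Independent NG86: direct fractional site counts and explicit
    enumeration of all mutational pathways per codon."""
    def aa(c):
        return str(Seq(c).translate())

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut not in STOPS and aa(mut) == aa(codon):
                    syn += 1 / 3
        return syn

    N = S = Nd = Sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        S += (sites(ca) + sites(cb)) / 2
        N += 3 - (sites(ca) + sites(cb)) / 2
        diff = [k for k in range(3) if ca[k] != cb[k]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOPS:
                    ok = False
                    break
                if aa(nxt) == aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if not paths:  # fall back to counting through stops
            for order in itertools.permutations(diff):
                cur, sd, nd = ca, 0, 0
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if nxt in STOPS or cur in STOPS or aa(nxt) != aa(cur):
                        nd += 1
                    else:
                        sd += 1
                    cur = nxt
                paths.append((sd, nd))
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    return N, S, Nd, Sd


class TestKaksNg86:
    def test_identical_sequences(self):
        cp = kaks_ng86("ATGAAACCC", "ATGAAACCC")
        assert cp.ka == 0 and cp.ks == 0
        assert np.isnan(cp.ratio)

    def test_single_synonymous_change(self):
        a = "GGG" * 100
        b = "GGA" + "GGG" * 99
        cp = kaks_ng86(a, b)
        assert cp.ka == 0
        assert cp.ks > 0
        assert cp.Sd == 1 and cp.Nd == 0

    def test_counts_match_enumeration_oracle(self):
        pairs = simulate.simulate_codon_pair_set(
            20, 100, omega=0.5, seed=21, branch_length=0.25)
        for a, b in pairs:
            cp = kaks_ng86(a, b)
            N, S, Nd, Sd = ng86_oracle(a, b)
            assert cp.N == pytest.approx(N)
            assert cp.S == pytest.approx(S)
            assert cp.Nd == pytest.approx(Nd)
            assert cp.Sd == pytest.approx(Sd)

    def test_site_counts_sum_to_three_per_codon(self):
        pairs = simulate.simulate_codon_pair_set(5, 80, omega=1.0, seed=4)
        for a, b in pairs:
            cp = kaks_ng86(a, b)
            assert cp.N + cp.S == pytest.approx(3 * cp.n_codons)

    def test_order_swap_invariance(self):
        (a, b), = simulate.simulate_codon_pair_set(1, 100, omega=0.8, seed=6)
        cp1, cp2 = kaks_ng86(a, b), kaks_ng86(b, a)
        assert cp1.ka == pytest.approx(cp2.ka)
        assert cp1.ks == pytest.approx(cp2.ks)

    def test_saturation_flag(self):
        # every codon pair carries two synonymous differences (TTA vs CTG,
        # both leucine), so pS far exceeds the correction's domain
        cp = kaks_ng86("TTA" * 200, "CTG" * 200)
        assert cp.saturated
        assert np.isnan(cp.ks) and np.isnan(cp.ratio)

    def test_in_frame_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            kaks_ng86("ATGTAAAAA", "ATGAAAAAA")

    def test_gapped_codons_excluded(self):
        cp = kaks_ng86("ATG---AAA", "ATGCCCAAA")
        assert cp.n_codons == 2

    def test_agrees_with_seqinr_reference(self):
        """Cross-method check against a frozen seqinr::kaks result
        (LWL-family estimator) on one generated pair: same order of
        magnitude for both rates."""
        (a, b), = simulate.simulate_codon_pair_set(1, 120, omega=0.2, seed=42)
        cp = kaks_ng86(a, b)
        seqinr_ka, seqinr_ks = 0.06866435, 0.3173273
        assert cp.ka == pytest.approx(seqinr_ka, rel=0.5)
        assert cp.ks == pytest.approx(seqinr_ks, rel=0.5)


class TestBestInterspeciesHit:
    HITS = pd.DataFrame([
        ("q", "x", 95.0, 500.0), ("q", "y", 80.0, 300.0),
        ("q", "z", 90.0, 300.0),
    ], columns=["qseqid", "sseqid", "pident", "bitscore"])

    def test_same_species_top_hit_skipped(self):
        species = {"x": "sp1", "y": "sp2", "z": "sp2"}
        assert te_evolution.best_interspecies_hit(
            self.HITS, "q", "sp1", species) == "z"  # bitscore tie -> pident

    def test_no_cross_species_hit(self):
        species = {"x": "sp1", "y": "sp1", "z": "sp1"}
        assert te_evolution.best_interspecies_hit(
            self.HITS, "q", "sp1", species) is None
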