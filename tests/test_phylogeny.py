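import math

import numpy as np
import pytest

from hsfkit.phylogeny import (
    DistanceMatrix,
    MultipleAlignment,
    assign_subclass,
    bootstrap_supports,
    build_nj,
    center_star_align,
    poisson_distance,
)


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(("a", "b"), ("ACDEF", "ACDEF"))
        assert poisson_distance(aln).values[0, 1] == 0.0

    def test_half_differing_sites(self):
        aln = MultipleAlignment(("a", "b"), ("AAAA", "AACC"))
        assert poisson_distance(aln).values[0, 1] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_pairwise_deletion_hand_count(self):
        # 10 columns, one row gapped at 2 -> 8 comparable, 2 of them differ
        aln = MultipleAlignment(("a", "b"), ("ACDEFGHIKL", "-CDEFGAAK-"))
        d = poisson_distance(aln)
        assert d.values[0, 1] == pytest.approx(-math.log(0.75), abs=1e-4)

    def test_zero_comparable_sites_flagged(self):
        aln = MultipleAlignment(("a", "b"), ("AA--", "--AA"))
        d = poisson_distance(aln)
        assert d.undefined_pairs == (("a", "b"),)

    def test_saturated_pair_flagged_infinite(self):
        aln = MultipleAlignment(("a", "b"), ("AAAA", "CCCC"))
        d = poisson_distance(aln)
        assert d.infinite_pairs == (("a", "b"),)

    def test_distance_dominates_p_and_converges_for_small_p(self):
        """d >= p always, and d -> p as p -> 0 (within 1% at p <= 0.01)."""
        for n_diff, length in [(1, 100), (1, 200), (5, 100), (50, 100)]:
            row_a = "A" * length
            row_b = "C" * n_diff + "A" * (length - n_diff)
            d = poisson_distance(MultipleAlignment(("a", "b"), (row_a, row_b))).values[0, 1]
            p = n_diff / length
            assert d >= p
            if p <= 0.01:
                assert d == pytest.approx(p, rel=0.01)


def _random_additive_tree(n_taxa, rng):
    """Random binary tree by sequential attachment; returns (edges-as-paths
    distance matrix, set of expected bipartitions, names)."""
    import itertools

    from skbio import TreeNode

    names = [f"t{i}" for i in range(n_taxa)]
    tree = TreeNode.read([f"({names[0]}:{rng.uniform(0.05, 0.5):.6f},"
                          f"{names[1]}:{rng.uniform(0.05, 0.5):.6f},"
                          f"{names[2]}:{rng.uniform(0.05, 0.5):.6f});"])
    for name in names[3:]:
        tips_and_edges = [t for t in tree.traverse() if t.parent is not None]
        target = tips_and_edges[int(rng.integers(len(tips_and_edges)))]
        parent = target.parent
        split = rng.uniform(0.2, 0.8) * target.length
        inner = type(tree)(length=target.length - split)
        target.length = split
        parent.remove(target)
        inner.append(target)
        new_tip = type(tree)(name=name, length=float(rng.uniform(0.05, 0.5)))
        inner.append(new_tip)
        parent.append(inner)
    dists = tree.tip_tip_distances()
    mat = np.array([[0.0 if a == b else dists[a, b] for b in names] for a in names])
    all_tips = frozenset(names)
    bps = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n_taxa - 2:
            bps.add(frozenset((side, all_tips - side)))
    return mat, bps, names


def _bipartitions_of(ptree):
    all_tips = frozenset(ptree.tip_names())
    out = set()
    for node in ptree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(frozenset((side, all_tips - side)))
    return out


class TestBuildNj:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = build_nj(dm).tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_recovery_vs_enumeration_oracle(self):
        """NJ must pick the unique additive topology among the three
        possible unrooted quartets (least-squares enumeration oracle)."""
        # quartet ((A,B),(C,D)) with internal edge 0.2
        d = {"AB": 0.3, "CD": 0.5, "AC": 0.6, "AD": 0.7, "BC": 0.7, "BD": 0.8}
        names = list("ABCD")
        mat = np.zeros((4, 4))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    mat[i, j] = mat[j, i] = d["".join(sorted(a + b))]
        # oracle: evaluate the three quartet splits by the four-point condition
        sums = {
            "AB|CD": d["AB"] + d["CD"],
            "AC|BD": d["AC"] + d["BD"],
            "AD|BC": d["AD"] + d["BC"],
        }
        oracle_split = min(sums, key=sums.get)
        assert oracle_split == "AB|CD"
        ptree = build_nj(DistanceMatrix(tuple(names), mat))
        assert frozenset((frozenset("AB"), frozenset("CD"))) in _bipartitions_of(ptree)
        dists = ptree.tree.tip_tip_distances()
        for (a, b), expected in [(("A", "B"), 0.3), (("C", "D"), 0.5), (("A", "D"), 0.7)]:
            assert dists[a, b] == pytest.approx(expected, abs=1e-9)

    def test_additive_matrices_recovered_exactly(self):
        """Topology and all path lengths of random 5-8 taxon additive
        matrices are reproduced to 1e-9 (50 random trees)."""
        rng = np.random.default_rng(7)
        for rep in range(50):
            n = int(rng.integers(5, 9))
            mat, bps, names = _random_additive_tree(n, rng)
            ptree = build_nj(DistanceMatrix(tuple(names), mat))
            assert _bipartitions_of(ptree) == bps
            dists = ptree.tree.tip_tip_distances()
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i < j:
                        assert abs(dists[a, b] - mat[i, j]) < 1e-9

    def test_leaf_order_permutation_preserves_topology(self):
        rng = np.random.default_rng(3)
        mat, bps, names = _random_additive_tree(6, rng)
        perm = list(rng.permutation(len(names)))
        mat_p = mat[np.ix_(perm, perm)]
        names_p = [names[i] for i in perm]
        assert _bipartitions_of(build_nj(DistanceMatrix(tuple(names_p), mat_p))) == bps

    def test_agrees_with_skbio_nj(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(9)
        mat, bps, names = _random_additive_tree(7, rng)
        sk_tree = sknj(SkDM(mat, names))
        sk_bps = set()
        all_tips = frozenset(names)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(names) - 2:
                sk_bps.add(frozenset((side, all_tips - side)))
        assert _bipartitions_of(build_nj(DistanceMatrix(tuple(names), mat))) == sk_bps

    def test_negative_entry_rejected(self):
        mat = np.array([[0, -0.1, 0.2], [-0.1, 0, 0.3], [0.2, 0.3, 0]])
        with pytest.raises(ValueError, match="negative"):
            build_nj(DistanceMatrix(("a", "b", "c"), mat))

    def test_undefined_distances_listed(self):
        aln = MultipleAlignment(("a", "b", "c"), ("AA--", "--AA", "AAAA"))
        dm = poisson_distance(aln)
        with pytest.raises(ValueError, match="a.*b"):
            build_nj(dm)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def structured_alignment(self):
        const = "D" * 100  # shared block keeps every pair below saturation
        rows = ("A" * 200 + "C" * 100 + const, "A" * 200 + "G" * 100 + const,
                "T" * 200 + "C" * 100 + const, "T" * 200 + "G" * 100 + const)
        return MultipleAlignment(("w", "x", "y", "z"), rows)

    def test_same_seed_reproducible(self, structured_alignment):
        t1 = bootstrap_supports(structured_alignment, reps=50, seed=5)
        t2 = bootstrap_supports(structured_alignment, reps=50, seed=5)
        assert t1.newick() == t2.newick()

    def test_clean_synapomorphies_supported(self):
        """200 clean synapomorphies for one split give support >= 95."""
        const = "D" * 50
        rows = ("A" * 200 + "CGTA" * 10 + const, "A" * 200 + "GTAC" * 10 + const,
                "T" * 200 + "ACGT" * 10 + const, "T" * 200 + "TGCA" * 10 + const)
        aln = MultipleAlignment(("w", "x", "y", "z"), rows)
        tree = bootstrap_supports(aln, reps=100, seed=1)
        supports = [n.bootstrap_support for n in tree.tree.non_tips(include_self=False)
                    if hasattr(n, "bootstrap_support")]
        assert supports and max(supports) >= 95

    def test_supports_within_bounds(self, structured_alignment):
        tree = bootstrap_supports(structured_alignment, reps=30, seed=2)
        for node in tree.tree.non_tips(include_self=False):
            if hasattr(node, "bootstrap_support"):
                assert 0.0 <= node.bootstrap_support <= 100.0

    def test_zero_reps_rejected(self, structured_alignment):
        with pytest.raises(ValueError):
            bootstrap_supports(structured_alignment, reps=0)

    def test_structured_beats_random_alignment(self):
        rng = np.random.default_rng(11)
        random_rows = tuple("".join(rng.choice(list("ACDEFGHIKL"), size=120)) for _ in range(6))
        ids = tuple(f"s{i}" for i in range(6))
        rand_tree = bootstrap_supports(MultipleAlignment(ids, random_rows), reps=50, seed=3)
        block = "".join(rng.choice(list("ACDEFGHIKL"), size=120))
        structured_rows = []
        for i in range(6):
            row = list(block)
            for p in range(0, 120, 4):
                row[p] = "ACDEFG"[i // 2]  # three clean pairs
            structured_rows.append("".join(row))
        struct_tree = bootstrap_supports(MultipleAlignment(ids, tuple(structured_rows)), reps=50, seed=3)

        def _median_support(ptree):
            vals = [n.bootstrap_support for n in ptree.tree.non_tips(include_self=False)
                    if hasattr(n, "bootstrap_support")]
            return np.median(vals) if vals else 0.0

        assert _median_support(struct_tree) > _median_support(rand_tree)


class TestAssignSubclass:
    def test_query_identical_to_reference(self):
        refs = {"rA1": "MKWLEDAFGHIKLRSTV" * 4, "rB1": "MNPQRSTVWYACDEFGH" * 4}
        labels = {"rA1": "A1", "rB1": "B1"}
        out = assign_subclass({"q": refs["rA1"]}, refs, labels)
        assert out[0].subclass == "A1"
        assert out[0].method == "clade-majority"
        assert out[0].confidence == 1.0

    def test_partial_query_uses_homology_fallback(self):
        refs = {"rA1": "MKWLEDAFGHIKLRSTV" * 4, "rB1": "MNPQRSTVWYACDEFGH" * 4,
                "rC1": "GGGGSPQRSTYWACDEF" * 4}
        labels = {"rA1": "A1", "rB1": "B1", "rC1": "C1"}
        out = assign_subclass(
            {"q": None}, refs, labels,
            query_full={"q": refs["rB1"][30:]},
            ref_full=refs,
        )
        assert out[0].method == "homology-fallback"
        assert out[0].subclass == "B1"

    def test_unalignable_query_reported_unclassified(self):
        refs = {"rA1": "MKWLEDAFGHIKLRSTV" * 4, "rB1": "MNPQRSTVWYACDEFGH" * 4}
        labels = {"rA1": "A1", "rB1": "B1"}
        out = assign_subclass({"q": None}, refs, labels, query_full={})
        assert out[0].method == "unclassified"
        assert out[0].subclass is None

    def test_simulated_family_recovery(self, small_family):
        fam = small_family
        ref_regions = {rid: region for rid, region, _ in fam.references}
        ref_labels = {rid: label for rid, _, label in fam.references}
        start, end = next(iter(fam.region_spans.values()))
        queries = {p.id: p.residues[start:end] for p in fam.proteins}
        out = assign_subclass(queries, ref_regions, ref_labels)
        truth = fam.truth.set_index("entity")["subclass"]
        correct = sum(a.subclass == truth[a.query_id] for a in out)
        assert correct == len(out)


def test_center_star_alignment_of_equal_length_identities():
    seqs = ["MKWLEDAFGH", "MKWLEDAFGH", "MKWLEDAYGH"]
    aln = center_star_align(["a", "b", "c"], seqs)
    assert aln.rows[0] == aln.rows[1]
    assert len(set(len(r) for r in aln.rows)) == 1
    assert all("-" not in r for r in aln.rows)
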