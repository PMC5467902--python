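"""Composition vectors, CV distance, and neighbor joining."""

import itertools
from collections import Counter

import numpy as np
import pytest

from genomine.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    Proteome,
    cv_distance,
    distance_matrix,
    kstring_counts,
    nj_tree,
    proteome_vector,
    root_with_outgroup,
)


class TestKstringCounts:
    def test_basic_overlapping_windows(self):
        assert kstring_counts(Proteome("t", ["MKV"]), 2) == Counter({"MK": 1, "KV": 1})
        assert kstring_counts(Proteome("t", ["AAAA"]), 3) == Counter({"AAA": 2})

    def test_no_windows_across_protein_boundaries(self):
        assert kstring_counts(Proteome("t", ["MK", "VW"]), 2) == Counter({"MK": 1, "VW": 1})

    def test_ambiguous_residue_windows_skipped(self):
        counts = kstring_counts(Proteome("t", ["MKXVW"]), 2)
        assert counts == Counter({"MK": 1, "VW": 1})
        total = sum(counts.values())
        assert total == (5 - 2 + 1) - 2  # two windows touch the X

    def test_k_out_of_range(self):
        with pytest.raises(PhylogenyError):
            kstring_counts(Proteome("t", ["MKV"]), 0)
        with pytest.raises(PhylogenyError):
            kstring_counts(Proteome("t", ["MKV"]), 10)


def brute_force_components(proteome: Proteome, k: int) -> dict[str, float]:
    """Independent evaluation of the deviation formula over all strings."""

    def freq(length: int) -> dict[str, float]:
        c: Counter = Counter()
        for s in proteome.sequences:
            for i in range(len(s) - length + 1):
                c[s[i : i + length]] += 1
        total = sum(c.values())
        return {w: n / total for w, n in c.items()}

    pk, pk1, pk2 = freq(k), freq(k - 1), freq(k - 2)
    out = {}
    for w, p in pk.items():
        p0 = pk1[w[:-1]] * pk1[w[1:]] / pk2[w[1:-1]]
        out[w] = (p - p0) / p0 if p0 > 0 else 0.0
    return out


class TestCompositionVector:
    def test_homopolymer_deviation_is_zero(self):
        # one protein "AAAAA": every string at every length has frequency 1
        vec = proteome_vector(Proteome("t", ["AAAAA"]), 3)
        assert vec.components == {"AAA": 0.0}

    @pytest.mark.parametrize("seqs", [["MKVMKW", "KVMK"], ["ACDEFA", "CDE", "DEFAC"]])
    def test_matches_brute_force_formula(self, seqs):
        proteome = Proteome("t", seqs)
        vec = proteome_vector(proteome, 3)
        expected = brute_force_components(proteome, 3)
        assert set(vec.components) == set(expected)
        for w, v in expected.items():
            assert vec.components[w] == pytest.approx(v)

    def test_unobserved_kstrings_absent(self):
        vec = proteome_vector(Proteome("t", ["MKVMKV"]), 3)
        assert "AAA" not in vec.components

    def test_k_below_three_rejected(self):
        with pytest.raises(PhylogenyError):
            proteome_vector(Proteome("t", ["MKVMKV"]), 2)


class TestCvDistance:
    def test_identical_proteomes_give_zero(self):
        a = proteome_vector(Proteome("a", ["MKVWCEDH"]), 3)
        b = proteome_vector(Proteome("b", ["MKVWCEDH"]), 3)
        assert cv_distance(a, b) == pytest.approx(0.0)

    def test_negated_vectors_give_one(self):
        a = proteome_vector(Proteome("a", ["MKVWCEDH"]), 3)
        neg = type(a)("neg", a.k, {w: -v for w, v in a.components.items()})
        assert cv_distance(a, neg) == pytest.approx(1.0)

    def test_disjoint_supports_give_half(self):
        va = proteome_vector(Proteome("a", ["MKVWMKVW"]), 3)
        vb = type(va)("b", 3, {"YYY": 1.0, "GGG": -0.5})
        assert set(va.components).isdisjoint(vb.components)
        assert cv_distance(va, vb) == pytest.approx(0.5)

    def test_degenerate_zero_norm_vector_rejected(self):
        va = proteome_vector(Proteome("a", ["AAAAA"]), 3)  # all-zero deviations
        vb = proteome_vector(Proteome("b", ["MKVWCEDH"]), 3)
        with pytest.raises(PhylogenyError):
            cv_distance(va, vb)

    def test_k_mismatch_rejected(self):
        va = proteome_vector(Proteome("a", ["MKVWCEDH"]), 3)
        vb = proteome_vector(Proteome("b", ["MKVWCEDH"]), 4)
        with pytest.raises(PhylogenyError):
            cv_distance(va, vb)

    def test_is_a_dissimilarity(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        prots = [
            Proteome(f"t{i}", ["".join(rng.choice(list(aa), size=60)) for _ in range(3)])
            for i in range(4)
        ]
        vecs = [proteome_vector(p, 3) for p in prots]
        for va, vb in itertools.combinations(vecs, 2):
            assert cv_distance(va, vb) == pytest.approx(cv_distance(vb, va))
            assert 0 <= cv_distance(va, vb) <= 1
        for v in vecs:
            assert cv_distance(v, v) == pytest.approx(0.0)


# --- tree oracle machinery -------------------------------------------------

def enumerate_unrooted(taxa: list[str]):
    """All unrooted binary topologies as (edges, tipsets) structures."""
    from skbio.tree import TreeNode

    def attach_everywhere(tree):
        # yield deep copies with the next taxon attached to each edge
        edges = [n for n in tree.traverse() if not n.is_root()]
        for idx in range(len(edges)):
            t = tree.copy()
            target = [n for n in t.traverse() if not n.is_root()][idx]
            parent = target.parent
            new = TreeNode()
            parent.remove(target)
            parent.append(new)
            new.append(target)
            tip = TreeNode(name=None)
            new.append(tip)
            yield t, tip

    base = TreeNode()
    for name in taxa[:3]:
        base.append(TreeNode(name=name))
    trees = [base]
    for name in taxa[3:]:
        nxt = []
        for tree in trees:
            for t, tip in attach_everywhere(tree):
                tip.name = name
                nxt.append(t)
        trees = nxt
    return trees


def fit_branch_lengths(tree, d: DistanceMatrix):
    """OLS branch lengths from the edge-path incidence system."""
    taxa = d.taxon_ids
    edges = [n for n in tree.traverse() if not n.is_root()]
    tipsets = [frozenset(t.name for t in e.tips()) | ({e.name} if e.is_tip() else set())
               for e in edges]
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d.values[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, ts in enumerate(tipsets):
            if (taxa[i] in ts) != (taxa[j] in ts):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.linalg.norm(A @ x - y))
    return x, residual


def brute_force_best_tree(d: DistanceMatrix):
    """Minimum-evolution search over every unrooted topology."""
    best = None
    for tree in enumerate_unrooted(d.taxon_ids):
        x, res = fit_branch_lengths(tree, d)
        score = (round(res, 9), float(np.sum(np.abs(x))))
        if best is None or score < best[0]:
            best = (score, tree)
    return best[1]


def additive_matrix_from(newick: str) -> DistanceMatrix:
    from skbio.tree import TreeNode
    import io

    tree = TreeNode.read(io.StringIO(newick))
    names = sorted(t.name for t in tree.tips())
    tipdm = tree.tip_tip_distances()
    values = np.array([[tipdm[a, b] for b in names] for a in names])
    return DistanceMatrix(names, values)


def rf_zero(t1, t2) -> bool:
    return t1.compare_rfd(t2) == 0


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        # a = (dAB+dAC-dBC)/2 etc.
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_recovers_four_taxon_additive_tree(self):
        newick = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.07);"
        d = additive_matrix_from(newick)
        tree = nj_tree(d)
        import io
        from skbio.tree import TreeNode

        truth = TreeNode.read(io.StringIO(newick))
        assert rf_zero(tree, truth)
        # branch lengths recovered up to arithmetic tolerance
        got = {t.name: t.length for t in tree.tips()}
        assert got["A"] == pytest.approx(0.1)
        assert got["D"] == pytest.approx(0.15)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_minimum_evolution_oracle_five_taxa(self, seed):
        rng = np.random.default_rng(seed)
        bl = rng.uniform(0.05, 0.5, size=7)
        newick = (
            f"((A:{bl[0]},B:{bl[1]}):{bl[2]},(C:{bl[3]},D:{bl[4]}):{bl[5]},E:{bl[6]});"
        )
        d = additive_matrix_from(newick)
        assert rf_zero(nj_tree(d), brute_force_best_tree(d))

    def test_equal_distances_give_nonnegative_branches(self):
        n = 4
        values = np.full((n, n), 0.4)
        np.fill_diagonal(values, 0.0)
        tree = nj_tree(DistanceMatrix(list("ABCD"), values))
        assert all((node.length or 0) >= -1e-12 for node in tree.traverse() if not node.is_root())

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhylogenyError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]])))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(PhylogenyError):
            DistanceMatrix(list("ABC"), np.array([[0, 0.1, 0.2], [0.3, 0, 0.1], [0.2, 0.1, 0]]))


class TestRooting:
    def _tree(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        return nj_tree(d)

    def test_outgroup_bipartition(self):
        rooted = root_with_outgroup(self._tree(), "C")
        sides = [sorted(t.name for t in child.tips()) or [child.name] for child in rooted.children]
        assert sorted(map(tuple, sides)) == [("A", "B"), ("C",)]

    def test_rooting_is_idempotent(self):
        once = root_with_outgroup(self._tree(), "C")
        twice = root_with_outgroup(once, "C")
        assert str(once) == str(twice)

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(PhylogenyError):
            root_with_outgroup(self._tree(), "Z")


class TestDistanceMatrixIO:
    def test_phylip_roundtrip_shape(self, tmp_path):
        d = distance_matrix(
            [proteome_vector(Proteome(t, ["MKVWCEDHMKVW", "ACDEFGHIKL"]), 3) for t in "ab"]
            + [proteome_vector(Proteome("c", ["YYWWMMKKVV"]), 3)]
        )
        p = tmp_path / "d.phylip"
        d.to_phylip(p)
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4
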