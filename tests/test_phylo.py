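"""Alignment, distances, neighbor joining, bootstrap, clade composition."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from cannatype.phylo import (
    Alignment,
    DistanceMatrix,
    align_progressive,
    bipartitions,
    bootstrap_support,
    compute_distances,
    concatenate,
    group_mean_distance,
    has_split,
    jc69_transform,
    nj_tree,
)


class TestAlignProgressive:
    def test_identical_sequences_have_no_gaps(self):
        seq = "ATGCGTACGTTAGCATGCA"
        aln = align_progressive([("a", seq), ("b", seq), ("c", seq)])
        assert aln.rows == [seq] * 3
        assert aln.n_columns == len(seq)

    def test_single_insertion_makes_one_gap_run(self):
        rng = np.random.default_rng(2)
        s1 = "".join(rng.choice(list("ACGT"), 60))
        s2 = s1[:30] + "GGG" + s1[30:]
        aln = align_progressive([("a", s1), ("b", s2)])
        assert aln.n_columns == 63
        gaps_a = aln.rows[0].count("-")
        assert gaps_a == 3
        # one contiguous run
        assert "-" * 3 in aln.rows[0]
        assert aln.rows[1].count("-") == 0

    def test_alignment_at_least_longest_input(self, small_panel):
        panel, _ = small_panel
        aln = align_progressive([(s.sample_id, s.thcas_seq) for s in panel])
        assert aln.n_columns >= max(len(s.thcas_seq) for s in panel)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_progressive([])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            align_progressive([("a", "ACGT" * 5), ("a", "ACGT" * 5)])


class TestDistances:
    def test_jc69_closed_form_at_p_010(self):
        import math

        # independent evaluation of d = -(3/4) ln(1 - 4p/3)
        assert jc69_transform(0.10) == pytest.approx(
            -0.75 * math.log(1 - 0.4 / 3), abs=1e-12
        )
        assert round(jc69_transform(0.10), 5) == 0.10733

    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACGT" * 25] * 2)
        dm = compute_distances(aln)
        assert dm.data[0, 1] == 0.0

    def test_ten_percent_mismatch(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        dm = compute_distances(Alignment(["a", "b"], [row_a, row_b]))
        assert dm.data[0, 1] == pytest.approx(0.1073256, abs=1e-6)
        dm_p = compute_distances(Alignment(["a", "b"], [row_a, row_b]), model="p")
        assert dm_p.data[0, 1] == pytest.approx(0.10)

    def test_saturated_pair_capped_and_flagged(self):
        aln = Alignment(["a", "b"], ["A" * 50, "C" * 50])
        dm = compute_distances(aln, max_distance=5.0)
        assert dm.data[0, 1] == 5.0
        assert ("a", "b") in dm.saturated_pairs

    def test_zero_overlap_names_the_pair(self):
        aln = Alignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="a and b"):
            compute_distances(aln)


def _path_distances(edges, leaves):
    """Brute-force path lengths on an explicit weighted tree (oracle)."""
    import collections

    graph = collections.defaultdict(dict)
    for u, v, w in edges:
        graph[u][v] = w
        graph[v][u] = w
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in graph[node].items():
                if nbr not in seen:
                    seen[nbr] = seen[node] + w
                    stack.append(nbr)
        for dst in leaves:
            dist[(src, dst)] = seen[dst]
    return dist


class TestNeighborJoining:
    # ((A,B),(C,D),(E)) with explicit internal nodes u, v
    EDGES = [
        ("A", "u", 1.0), ("B", "u", 2.0), ("u", "r", 3.0),
        ("C", "v", 4.0), ("D", "v", 5.0), ("v", "r", 6.0),
        ("E", "r", 7.0),
    ]
    LEAVES = ["A", "B", "C", "D", "E"]

    def _matrix(self):
        dist = _path_distances(self.EDGES, self.LEAVES)
        n = len(self.LEAVES)
        D = np.zeros((n, n))
        for i, a in enumerate(self.LEAVES):
            for j, b in enumerate(self.LEAVES):
                D[i, j] = dist[(a, b)]
        return DistanceMatrix(self.LEAVES, D, model="p")

    def test_additive_matrix_recovered_exactly(self):
        """NJ consistency: path distances of the inferred tree equal the
        additive input distances."""
        dm = self._matrix()
        tree = nj_tree(dm)
        assert has_split(tree, {"A", "B"})
        assert has_split(tree, {"C", "D"})
        tt = tree.tip_tip_distances()
        for i, a in enumerate(self.LEAVES):
            for j, b in enumerate(self.LEAVES):
                if a != b:
                    assert tt[a, b] == pytest.approx(dm.data[i, j], abs=1e-9)

    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D, model="p"))
        tips = sorted(t.name for t in tree.tips())
        assert tips == ["a", "b", "c"]
        tt = tree.tip_tip_distances()
        assert tt["a", "b"] == pytest.approx(3.0)
        assert tt["b", "c"] == pytest.approx(5.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), model="p"))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], D, model="p")

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining on a
        noisy (non-additive) matrix."""
        rng = np.random.default_rng(9)
        dm = self._matrix()
        noise = rng.uniform(0, 0.05, dm.data.shape)
        noisy = dm.data + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        ours = nj_tree(DistanceMatrix(self.LEAVES, noisy, model="p"))
        theirs = skbio_nj(SkbioDM(noisy, ids=self.LEAVES))
        assert bipartitions(ours) == bipartitions(theirs)

    def test_newick_round_trip_preserves_topology(self):
        tree = nj_tree(self._matrix())
        buf = io.StringIO()
        tree.write(buf, format="newick")
        buf.seek(0)
        reread = TreeNode.read(buf, format="newick")
        assert bipartitions(tree) == bipartitions(reread)


class TestConcatenate:
    def test_column_widths_and_round_trip(self):
        a = Alignment(["x", "y"], ["A" * 10, "C" * 10])
        b = Alignment(["x", "y"], ["G" * 10, "T" * 10])
        conc = concatenate([("g1", a), ("g2", b)])
        assert conc.n_columns == 20
        assert conc.partitions == [("g1", 0, 10), ("g2", 10, 20)]
        assert conc.subalignment("g1").rows == a.rows
        assert conc.subalignment("g2").rows == b.rows

    def test_missing_sample_rejected_by_default(self):
        a = Alignment(["x", "y"], ["AAAA", "CCCC"])
        b = Alignment(["x"], ["GGGG"])
        with pytest.raises(ValueError, match="missing"):
            concatenate([("g1", a), ("g2", b)])

    def test_gap_fill_policy(self):
        a = Alignment(["x", "y"], ["AAAA", "CCCC"])
        b = Alignment(["x"], ["GGGG"])
        conc = concatenate([("g1", a), ("g2", b)], on_missing="gap")
        assert conc.rows[conc.ids.index("y")] == "CCCC----"


@pytest.fixture(scope="module")
def pooled(small_panel):
    """Alignment of every gene copy of the 10-sample panel (one leaf per
    gene per sample) and its bootstrap NJ tree."""
    panel, _ = small_panel
    entries = [
        (f"{s.sample_id}|{g}", getattr(s, f"{g.lower()}_seq"))
        for s in panel
        for g in ("THCAS", "CBDAS")
    ]
    aln = align_progressive(entries)
    tree = bootstrap_support(aln, n_replicates=100, seed=7)
    return panel, aln, tree


class TestPanelPhylogeny:
    def _groups(self, panel):
        return {
            "THCAS_active": {
                f"{s.sample_id}|THCAS" for s in panel if s.true_chemotype in ("I", "II")
            },
            "THCAS_inactive": {
                f"{s.sample_id}|THCAS" for s in panel if s.true_chemotype == "III"
            },
            "CBDAS_active": {
                f"{s.sample_id}|CBDAS" for s in panel if s.true_chemotype in ("II", "III")
            },
            "CBDAS_inactive": {
                f"{s.sample_id}|CBDAS" for s in panel if s.true_chemotype == "I"
            },
        }

    def test_four_activity_clades(self, pooled):
        panel, _, tree = pooled
        for name, group in self._groups(panel).items():
            assert has_split(tree, group), name

    def test_activity_clades_bootstrap_support(self, pooled):
        panel, _, tree = pooled
        groups = self._groups(panel)
        leaves = sorted(t.name for t in tree.tips())
        ref, total = leaves[0], set(leaves)
        supports = {}
        for node in tree.non_tips():
            side = {t.name for t in node.tips()}
            canon = frozenset(total - side if ref in side else side)
            for name, group in groups.items():
                want = frozenset(total - group if ref in group else group)
                if canon == want:
                    supports[name] = node.support
        assert set(supports) == set(groups)
        assert all(v >= 0.9 for v in supports.values()), supports

    def test_bootstrap_deterministic_given_seed(self, pooled):
        panel, aln, tree = pooled
        tree2 = bootstrap_support(aln, n_replicates=100, seed=7)
        sup = sorted(
            n.support for n in tree.non_tips() if getattr(n, "support", None) is not None
        )
        sup2 = sorted(
            n.support for n in tree2.non_tips() if getattr(n, "support", None) is not None
        )
        assert sup == sup2

    def test_single_replicate_supports_are_binary(self):
        aln = Alignment(
            ["a", "b", "c", "d"],
            ["A" * 40, "A" * 40, "C" * 40, "C" * 30 + "G" * 10],
        )
        tree = bootstrap_support(aln, n_replicates=1, seed=3)
        sups = [
            n.support for n in tree.non_tips() if getattr(n, "support", None) is not None
        ]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_intermediates_between_drug_and_fiber(self, small_panel):
        """On the concatenated per-sample data, the intermediate group is
        closer to both the drug and fiber groups than those are to each
        other."""
        panel, _ = small_panel
        conc = concatenate(
            [
                ("THCAS", align_progressive([(s.sample_id, s.thcas_seq) for s in panel])),
                ("CBDAS", align_progressive([(s.sample_id, s.cbdas_seq) for s in panel])),
            ]
        )
        dm = compute_distances(conc)
        by_class = {
            c: [s.sample_id for s in panel if s.true_chemotype == c]
            for c in ("I", "II", "III")
        }
        d_II_I = group_mean_distance(dm, by_class["II"], by_class["I"])
        d_II_III = group_mean_distance(dm, by_class["II"], by_class["III"])
        d_I_III = group_mean_distance(dm, by_class["I"], by_class["III"])
        assert d_II_I < d_I_III
        assert d_II_III < d_I_III
        tree = nj_tree(dm)
        assert has_split(tree, set(by_class["I"]))
        assert has_split(tree, set(by_class["III"]))
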