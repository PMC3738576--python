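"""Anchored alignment, NJ reconstruction, bootstrap supports and grouping."""
import numpy as np
import pytest
from skbio import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from helpers import (
    random_additive_tree,
    recover_group_count,
    scan_entries,
    tree_bipartitions,
    tree_path_distances,
)
from zfp import phylo, synthetic
from zfp.phylo import DistanceMatrix


class TestAnchoredAlignment:
    def test_identical_domains_give_identical_rows(self, default_sim):
        entries = scan_entries(default_sim)
        first = entries[0]
        twin = ("twin", first[1], first[2], first[3])
        aln = phylo.build_anchored_alignment([first, twin, entries[1]])
        assert aln.rows[0] == aln.rows[1]

    def test_spacer_padding_arithmetic(self, default_sim):
        entries = scan_entries(default_sim)
        aln = phylo.build_anchored_alignment(entries)
        spacers = {e[2].gap_signature[1] for e in entries if e[2]}
        max_spacer = max(spacers)
        for entry, row in zip(entries, aln.rows):
            d = entry[2].gap_signature[1]
            segment = row[4 : 4 + max_spacer]
            assert segment.count("-") == max_spacer - d

    def test_rows_equal_length_and_anchors_hold(self, default_sim):
        # anchor residues are validated by the constructor; reaching here
        # means every anchor column holds its C/H in every row
        aln = phylo.build_anchored_alignment(scan_entries(default_sim))
        assert len({len(r) for r in aln.rows}) == 1
        assert len(aln.anchor_columns) == 12

    def test_sequences_missing_matches_are_excluded(self, default_sim, caplog):
        entries = scan_entries(default_sim)
        entries[0] = (entries[0][0], entries[0][1], None, entries[0][3])
        with caplog.at_level("WARNING"):
            aln = phylo.build_anchored_alignment(entries)
        assert entries[0][0] not in aln.ids
        assert "missing BZF" in caplog.text


class TestDistances:
    def test_identical_rows_zero(self, default_sim):
        entries = scan_entries(default_sim)
        twin = ("twin", entries[0][1], entries[0][2], entries[0][3])
        aln = phylo.build_anchored_alignment([entries[0], twin, entries[1]])
        dm = phylo.distances(aln)
        assert dm.matrix[0, 1] == 0.0

    def test_poisson_closed_forms(self):
        chars = np.array([list("AAAA"), list("AARR"), list("RRRR")])
        dm = phylo._distances_from_chars(chars, ("a", "b", "c"), "poisson")
        assert dm.matrix[0, 1] == pytest.approx(np.log(2))  # p = 0.5
        assert dm.matrix[0, 0] == 0.0
        p_dm = phylo._distances_from_chars(chars, ("a", "b", "c"), "p")
        assert p_dm.matrix[0, 2] == pytest.approx(1.0)

    def test_zero_shared_columns_error(self):
        chars = np.array([list("AA--"), list("--RR"), list("AARR")])
        with pytest.raises(ValueError, match="no shared"):
            phylo._distances_from_chars(chars, ("a", "b", "c"), "p")

    def test_needs_three_rows(self, default_sim):
        entries = scan_entries(default_sim)[:2]
        aln = phylo.build_anchored_alignment(entries)
        with pytest.raises(ValueError, match="at least 3"):
            phylo.distances(aln)


class TestNeighborJoining:
    ADDITIVE = DistanceMatrix(
        ids=("A", "B", "C", "D"),
        matrix=np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        ),
    )

    def test_four_taxon_additive_example(self):
        tree = phylo.neighbor_joining(self.ADDITIVE)
        assert tree_bipartitions(tree, ["A", "B", "C", "D"]) == {
            frozenset({"A", "B"})
        }
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = next(tree.non_tips(include_self=False))
        assert internal.length == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ids=("a", "b", "c"),
            matrix=np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float),
        )
        tree = phylo.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_input_order_invariance(self):
        perm = [2, 0, 3, 1]
        ids = tuple(self.ADDITIVE.ids[i] for i in perm)
        matrix = self.ADDITIVE.matrix[np.ix_(perm, perm)]
        tree = phylo.neighbor_joining(DistanceMatrix(ids=ids, matrix=matrix))
        assert tree_bipartitions(tree, list(ids)) == {frozenset({"A", "B"})}

    def test_rejects_asymmetric_matrix(self):
        m = self.ADDITIVE.matrix.copy()
        m[0, 1] = 99
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=self.ADDITIVE.ids, matrix=m)

    def test_exact_on_random_additive_matrices(self):
        """NJ recovers topology and all path lengths of random additive
        matrices (n <= 8) to 1e-9."""
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            names, mat, parts = random_additive_tree(rng, n)
            tree = phylo.neighbor_joining(
                DistanceMatrix(ids=tuple(names), matrix=mat)
            )
            assert tree_bipartitions(tree, names) == parts
            recon = tree_path_distances(tree, names)
            assert np.abs(recon - mat).max() < 1e-9

    def test_topology_agrees_with_skbio_nj(self):
        """Independent-implementation cross-check on additive inputs."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            names, mat, parts = random_additive_tree(rng, 7)
            ours = phylo.neighbor_joining(
                DistanceMatrix(ids=tuple(names), matrix=mat)
            )
            sym = (mat + mat.T) / 2  # exact symmetry for skbio's validator
            theirs = skbio_nj(SkbioDM(sym, names))
            assert tree_bipartitions(ours, names) == tree_bipartitions(
                theirs, names
            )


@pytest.fixture(scope="module")
def two_clade_sim():
    """Two groups with zero within-group substitution: clean diagnostic
    columns separate them."""
    cfg = synthetic.SimConfig(
        seed=13, n_groups=2, substitution_prob=0.0, n_tandem_arrays=0
    )
    return synthetic.simulate(cfg)


class TestBootstrap:
    def test_planted_split_gets_full_support(self, two_clade_sim):
        aln = phylo.build_anchored_alignment(scan_entries(two_clade_sim))
        tree = phylo.bootstrap_supports(aln, n_reps=200, seed=0)
        g1 = {
            pid
            for pid, e in two_clade_sim.truth["proteins"].items()
            if e["group"] == "g1"
        }
        found = False
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if side == g1 or side == frozenset(aln.ids) - g1:
                found = True
                assert node.support >= 0.99
        assert found, "planted split absent from NJ tree"

    def test_single_replicate_supports_are_binary(self, two_clade_sim):
        aln = phylo.build_anchored_alignment(scan_entries(two_clade_sim))
        tree = phylo.bootstrap_supports(aln, n_reps=1, seed=4)
        supports = [
            n.support for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        ]
        assert supports and set(supports) <= {0.0, 1.0}

    def test_same_seed_reproduces_supports(self, two_clade_sim):
        aln = phylo.build_anchored_alignment(scan_entries(two_clade_sim))
        t1 = phylo.bootstrap_supports(aln, n_reps=50, seed=9)
        t2 = phylo.bootstrap_supports(aln, n_reps=50, seed=9)
        s1 = sorted(
            n.support for n in t1.non_tips(include_self=False)
            if n.support is not None
        )
        s2 = sorted(
            n.support for n in t2.non_tips(include_self=False)
            if n.support is not None
        )
        assert s1 == s2
        assert all(0 <= s <= 1 for s in s1)


def _toy_supported_tree():
    tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1,e:1);"])
    inner = list(tree.non_tips(include_self=False))
    inner[0].support = 0.79
    inner[1].support = 0.80
    return tree


class TestCollapse:
    def test_strictly_below_threshold_contracts(self):
        collapsed = phylo.collapse_tree(_toy_supported_tree(), 0.80)
        sides = {
            frozenset(t.name for t in n.tips())
            for n in collapsed.non_tips(include_self=False)
        }
        assert frozenset({"a", "b"}) not in sides  # 0.79 < 0.80 collapsed
        assert frozenset({"c", "d"}) in sides      # 0.80 retained

    def test_threshold_zero_keeps_tree_and_above_one_stars(self):
        tree = _toy_supported_tree()
        kept = phylo.collapse_tree(tree, 1e-9)
        assert len(list(kept.non_tips(include_self=False))) == 2
        star = phylo.collapse_tree(tree, 1.01)
        assert len(list(star.non_tips(include_self=False))) == 0

    def test_unmixed_clade_unclassified(self):
        tree = _toy_supported_tree()
        labels = {"a": "eudicot", "b": "eudicot", "c": "monocot",
                  "d": "eudicot", "e": "monocot"}
        groups = phylo.collapse_and_group(tree, 0.5, labels)
        assert groups["c"] == "A" and groups["d"] == "A"
        # eudicot-only pair stays unclassified once its clade collapses
        collapsed_groups = phylo.collapse_and_group(tree, 0.80, labels)
        assert collapsed_groups["a"] == phylo.UNCLASSIFIED

    def test_six_planted_groups_recovered(self, default_sim):
        assert recover_group_count(default_sim, seed=3) == 6

    def test_group_members_form_clades_with_both_clades_present(self, default_sim):
        aln = phylo.build_anchored_alignment(scan_entries(default_sim))
        tree = phylo.bootstrap_supports(aln, n_reps=200, seed=3)
        outgroup = [
            i for i, c in default_sim.clades.items()
            if c not in ("monocot", "eudicot")
        ]
        groups = phylo.collapse_and_group(tree, 0.80, default_sim.clades, outgroup)
        by_label = {}
        for leaf, label in groups.items():
            by_label.setdefault(label, set()).add(leaf)
        for label, members in by_label.items():
            if label == phylo.UNCLASSIFIED:
                continue
            kinds = {default_sim.clades[m] for m in members}
            assert {"monocot", "eudicot"} <= kinds
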