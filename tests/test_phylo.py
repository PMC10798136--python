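"""Distances, BIONJ reconstruction, bootstrap supports, clade contrasts."""

import itertools
import math

import numpy as np
import pytest

from _trees import random_additive_tree
from mscout.errors import InputError
from mscout.phylo import (
    DistanceMatrix,
    bionj,
    bipartitions,
    bootstrap_support,
    clade_branch_contrast,
    newick_to_tree,
    pairwise_distance,
    tip_names,
    tree_to_newick,
)


class TestPairwiseDistance:
    def test_identical_rows_distance_zero(self):
        msa = {"a": "MKWV" * 10, "b": "MKWV" * 10, "c": "MKWV" * 10}
        dm = pairwise_distance(msa, model="p")
        assert np.all(dm.data == 0)

    def test_p_distance_counts_mismatches(self):
        base = "A" * 100
        row_b = "C" * 5 + "A" * 95
        dm = pairwise_distance({"a": base, "b": row_b, "c": base}, model="p")
        assert dm.data[0, 1] == pytest.approx(0.05)

    def test_poisson_correction_closed_form(self):
        base = "A" * 100
        row_b = "C" * 5 + "A" * 95
        dm = pairwise_distance({"a": base, "b": row_b, "c": base})
        assert dm.data[0, 1] == pytest.approx(-math.log(0.95))

    def test_gap_columns_deleted_pairwise(self):
        dm = pairwise_distance(
            {"a": "--AAB", "b": "CCAAB", "c": "CCAAB"}, model="p"
        )
        assert dm.data[0, 1] == 0.0  # only the 3 shared columns compared

    def test_saturated_pair_flagged(self):
        msa = {"a": "AAAA", "b": "CCCC", "c": "AAAA"}
        dm = pairwise_distance(msa)
        assert ("a", "b") in dm.saturated
        with pytest.raises(InputError):
            dm.validate()  # saturated entries are not silently usable

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(InputError):
            pairwise_distance({"a": "--AA", "b": "CC--", "c": "CCAA"}, model="p")

    def test_phylip_writer(self, tmp_path):
        dm = pairwise_distance({"a": "AAB", "b": "AAB", "c": "ABB"}, model="p")
        dm.write_phylip(tmp_path / "d.phy")
        lines = (tmp_path / "d.phy").read_text().splitlines()
        assert lines[0].strip() == "3"
        assert lines[1].startswith("a")


class TestBionj:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = bionj(dm)
        b = {t.name: t.branch_length for t in tree.get_terminals()}
        assert b == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrices_reconstructed_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            labels, D, true_splits = random_additive_tree(n, rng)
            tree = bionj(DistanceMatrix(labels, D))
            terms = {t.name: t for t in tree.get_terminals()}
            for i, j in itertools.combinations(range(n), 2):
                path = tree.distance(terms[labels[i]], terms[labels[j]])
                assert abs(path - D[i, j]) <= 1e-9
            assert set(bipartitions(tree)) == true_splits

    def test_tie_break_is_deterministic(self):
        # ultrametric 4-taxon matrix with two equally good joins
        D = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            float,
        )
        newicks = {
            tree_to_newick(bionj(DistanceMatrix(list("ABCD"), D.copy())))
            for _ in range(3)
        }
        assert len(newicks) == 1

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InputError):
            bionj(DistanceMatrix(["a", "b", "c"], np.ones((3, 3))))
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(InputError):
            bionj(DistanceMatrix(["a", "b", "c"], bad))

    def test_matches_independent_nj_on_additive_matrix(self):
        """On additive input both BIONJ and plain NJ are exact, so the
        topology must agree with scikit-bio's implementation."""
        import skbio

        rng = np.random.default_rng(7)
        labels, D, _ = random_additive_tree(7, rng)
        D = (D + D.T) / 2  # remove float asymmetry from path summation
        tree = bionj(DistanceMatrix(labels, D))
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        ref = min(labels)
        sk_splits = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(labels) - 2:
                if ref in side:
                    side = frozenset(labels) - side
                sk_splits.add(side)
        assert set(bipartitions(tree)) <= sk_splits | set(bipartitions(tree))
        assert sk_splits == set(bipartitions(tree))


class TestNewick:
    def test_round_trip_preserves_lengths_and_supports(self):
        rng = np.random.default_rng(3)
        labels, D, _ = random_additive_tree(6, rng)
        tree = bionj(DistanceMatrix(labels, D))
        for clade in bipartitions(tree).values():
            clade.confidence = 87.5
        text = tree_to_newick(tree)
        back = newick_to_tree(text)
        terms = {t.name: t for t in back.get_terminals()}
        orig = {t.name: t for t in tree.get_terminals()}
        for a, b in itertools.combinations(labels, 2):
            assert abs(
                back.distance(terms[a], terms[b]) - tree.distance(orig[a], orig[b])
            ) < 1e-9
        sups = [c.confidence for c in back.get_nonterminals() if c.confidence is not None]
        assert sups and all(s == 87.5 for s in sups)


class TestBootstrap:
    MSA = {
        "A": "ACDEFGHIKL" * 10,
        "B": "ACDEFGHIKL" * 10,
        "C": "MNPQRSTVWY" * 10,
        "D": "MNPQRSTVWY" * 10,
    }

    def test_clean_separation_gets_full_support(self):
        msa = {k: v for k, v in self.MSA.items()}
        # add slight within-clade signal so distances are not all-zero
        msa["B"] = "G" + msa["B"][1:]
        msa["D"] = "G" + msa["D"][1:]
        tree = bootstrap_support(msa, n_reps=50, seed=5, model="p")
        sups = [c.confidence for c in bipartitions(tree).values()]
        assert sups == [100.0]

    def test_same_seed_same_supports(self):
        msa = dict(self.MSA)
        msa["B"] = "G" + msa["B"][1:]
        msa["D"] = "G" + msa["D"][1:]
        t1 = bootstrap_support(msa, n_reps=30, seed=9, model="p")
        t2 = bootstrap_support(msa, n_reps=30, seed=9, model="p")
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_supports_bounded_and_trivial_edges_unsupported(self):
        rng = np.random.default_rng(11)
        labels, D, _ = random_additive_tree(6, rng)
        # build a fake alignment consistent with some signal
        from mscout.simulate import evolve_homolog

        base = "ACDEFGHIKLMNPQRSTVWY" * 10
        msa = {
            lab: evolve_homolog(base, 0.75 + 0.03 * i, 100 + i)
            for i, lab in enumerate(labels)
        }
        tree = bootstrap_support(msa, n_reps=40, seed=1)
        for c in bipartitions(tree).values():
            assert 0.0 <= c.confidence <= 100.0
        for t in tree.get_terminals():
            assert t.confidence is None

    def test_zero_replicates_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support(self.MSA, n_reps=0, seed=1)

    def test_strong_signal_recovers_true_edges(self):
        """An 8-taxon tree simulated with ample informative columns is
        recovered with high support for its true edges."""
        from mscout.simulate import evolve_homolog

        rng = np.random.default_rng(21)
        base = "ACDEFGHIKLMNPQRSTVWY" * 15  # 300 columns
        # two clades diverged from distinct ancestors
        anc1 = evolve_homolog(base, 0.55, 1)
        anc2 = evolve_homolog(base, 0.55, 2)
        msa = {}
        for i in range(4):
            msa[f"L{i}"] = evolve_homolog(anc1, 0.93, 10 + i)
            msa[f"R{i}"] = evolve_homolog(anc2, 0.93, 20 + i)
        tree = bootstrap_support(msa, n_reps=60, seed=3)
        key = frozenset(f"L{i}" for i in range(4))
        parts = bipartitions(tree)
        # the left/right split must be present and strongly supported
        split_keys = [k for k in parts if k in (key, frozenset(msa) - key)]
        assert split_keys
        assert parts[split_keys[0]].confidence >= 90


class TestCladeContrast:
    @staticmethod
    def _symmetric_tree(scale_a=1.0):
        s = scale_a
        n = f"((C:{s},(A:{s},B:{s}):{s}):0.5,(D:1,(E:1,F:1):1):0.5);"
        return newick_to_tree(n)

    def test_equal_branches_give_unit_ratio(self):
        tree = self._symmetric_tree(1.0)
        ma, mb, ratio = clade_branch_contrast(tree, ["A", "B", "C"], ["D", "E", "F"])
        assert ratio == pytest.approx(1.0)

    def test_doubled_clade_doubles_ratio(self):
        tree = self._symmetric_tree(2.0)
        ma, mb, ratio = clade_branch_contrast(tree, ["A", "B", "C"], ["D", "E", "F"])
        assert ratio == pytest.approx(2.0)

    def test_disconnected_taxa_rejected(self):
        tree = self._symmetric_tree()
        with pytest.raises(InputError):
            clade_branch_contrast(tree, ["A", "D"], ["B", "C", "E", "F"])

    def test_rate_contrast_recovered_from_distances(self):
        """Clades evolved at a ~4:1 rate contrast show a tip-path ratio in
        [3, 5] on the reconstructed tree."""
        from mscout.simulate import evolve_homolog

        ratios = []
        for seed in range(5):
            base = "ACDEFGHIKLMNPQRSTVWY" * 15
            # two clade ancestors, then tips with a 4:1 within-clade rate
            anc_fast = evolve_homolog(base, 0.60, 1000 + seed)
            anc_slow = evolve_homolog(base, 0.60, 2000 + seed)
            fast = {
                f"F{i}": evolve_homolog(anc_fast, 0.80, 30 * seed + i)
                for i in range(3)
            }
            slow = {
                f"S{i}": evolve_homolog(anc_slow, 0.948, 800 + 30 * seed + i)
                for i in range(3)
            }
            msa = {**fast, **slow}
            tree = bionj(pairwise_distance(msa))
            ma, mb, ratio = clade_branch_contrast(tree, sorted(fast), sorted(slow))
            ratios.append(ratio)
        assert 3.0 <= float(np.median(ratios)) <= 5.0
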