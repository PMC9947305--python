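import numpy as np
import pandas as pd
import pytest

from beetol import assoc_tree as at


class TestSplitSearch:
    def test_gini_impurity_values(self):
        assert at._gini(10, 6) == pytest.approx(0.48)
        assert at._gini(10, 10) == 0.0
        assert at._gini(0, 0) == 0.0

    def test_constant_outcome_single_leaf(self):
        df = pd.DataFrame({"survived": [1.0] * 30, "g": ["a", "b", "c"] * 10})
        model = at.grow_tree(df, ["g"], min_split=5, min_bucket=2)
        assert model.root.is_leaf

    def test_scan_equals_exhaustive_subset_oracle(self, rng, gini_subset_oracle):
        """Ordered-category scan is optimal for binary outcomes: its best
        gain equals exhaustive search over all label subsets (<= 8 labels)."""
        for trial in range(300):
            k = int(rng.integers(2, 9))
            n = int(rng.integers(2 * k, 80))
            labels = rng.choice([f"h{i}" for i in range(k)], n)
            y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
            if y.sum() in (0, n):
                continue
            found = at._best_split(y, {"g": labels}, ["g"], min_bucket=1)
            oracle_gain, _ = gini_subset_oracle(y, labels)
            if found is None:
                assert oracle_gain <= 1e-12
                continue
            split, mask = found
            nL, sL = mask.sum(), y[mask].sum()
            nR, sR = n - nL, y.sum() - sL
            gain = (at._gini(n, int(y.sum())) - nL / n * at._gini(int(nL), int(sL))
                    - nR / n * at._gini(int(nR), int(sR)))
            assert gain == pytest.approx(oracle_gain, abs=1e-12)

    def test_tie_break_prefers_first_gene(self):
        # two identical predictive genes: config order decides
        df = pd.DataFrame({
            "survived": [1.0] * 10 + [0.0] * 10,
            "g1": ["a"] * 10 + ["b"] * 10,
            "g2": ["x"] * 10 + ["y"] * 10,
        })
        model = at.grow_tree(df, ["g2", "g1"], min_split=4, min_bucket=2)
        assert model.root.split.gene == "g2"


class TestPlantedStructure:
    def test_root_split_isolates_low_survival_haplotypes(self, planted_tree_data):
        df = planted_tree_data(seed=42)
        model = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        assert model.root.split.gene == "CYP9Q3"
        assert model.root.split.left_labels == frozenset({"L", "N", "P"})
        # second split on CYP9Q1 inside the low-survival node
        assert model.root.left.split is not None
        assert model.root.left.split.gene == "CYP9Q1"

    def test_low_survival_node_has_low_rate(self, planted_tree_data):
        df = planted_tree_data(seed=7)
        model = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        assert model.root.left.p_survive < 0.5 < model.root.right.p_survive


class TestPruning:
    def test_pure_noise_prunes_to_root(self, rng):
        df = pd.DataFrame({
            "survived": (rng.random(400) < 0.5).astype(float),
            "g1": rng.choice(list("abcd"), 400),
            "g2": rng.choice(list("wxyz"), 400),
        })
        grown = at.grow_tree(df, ["g1", "g2"])
        pruned = at.prune_tree(grown, df, folds=10, seed=0)
        assert pruned.root.is_leaf

    def test_planted_two_split_structure_retained(self, planted_tree_data):
        df = planted_tree_data(seed=11)
        grown = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        pruned = at.prune_tree(grown, df, folds=10, seed=1)
        assert pruned.n_splits == 2
        assert pruned.root.split.gene == "CYP9Q3"

    def test_cp_above_sequence_gives_root_leaf(self, planted_tree_data):
        df = planted_tree_data(seed=11)
        grown = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        r_root = grown.root.misclassified / grown.root.n
        solo = at._prune_at(grown.root, 1e9, grown.root.n, r_root)
        assert solo.is_leaf

    def test_pruning_sequence_is_nested(self, planted_tree_data):
        df = planted_tree_data(seed=3)
        grown = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"],
                             min_split=10, min_bucket=3)
        n = grown.root.n
        r_root = grown.root.misclassified / n
        seq = at._cp_sequence(grown.root, n, r_root)

        def node_ids(t):
            return {id_ for id_ in (nd.id for nd in t.internal())}

        alphas = [a for a, _ in seq]
        assert alphas == sorted(alphas)
        for (_, big), (_, small) in zip(seq, seq[1:]):
            assert node_ids(small) <= node_ids(big)

    def test_resubstitution_error_non_increasing_in_size(self, planted_tree_data):
        df = planted_tree_data(seed=3)
        grown = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"],
                             min_split=10, min_bucket=3)
        pruned = at.prune_tree(grown, df, folds=5, seed=2)
        tab = pruned.cp_table.sort_values("n_splits")
        assert (tab["rel_error"].diff().dropna() <= 1e-12).all()


class TestPredict:
    def test_training_rows_get_their_leaf_rate(self, planted_tree_data):
        df = planted_tree_data(seed=9)
        model = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        preds = at.predict_tree(model, df)
        leaves = {l.id: l for l in model.root.leaves()}
        for leaf_id, grp in preds.groupby("leaf_id"):
            assert grp["p_survive"].iloc[0] == pytest.approx(leaves[leaf_id].p_survive)
        assert not preds["unseen_label"].any()

    def test_all_wildtype_bee_routed_high_survival(self, planted_tree_data):
        df = planted_tree_data(seed=9)
        grown = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        pruned = at.prune_tree(grown, df, folds=5, seed=0)
        row = {"CYP9Q1": "wt", "CYP9Q2": "wt", "CYP9Q3": "Q"}
        out = at.predict_tree(pruned, row)
        assert out["p_survive"].iloc[0] > 0.8

    def test_unseen_label_flagged_majority_direction(self, planted_tree_data):
        df = planted_tree_data(seed=9)
        model = at.grow_tree(df, ["CYP9Q1", "CYP9Q2", "CYP9Q3"])
        out = at.predict_tree(
            model, {"CYP9Q1": "wt", "CYP9Q2": "wt", "CYP9Q3": "NEVER_SEEN"}
        )
        assert bool(out["unseen_label"].iloc[0])


class TestHaplotypeGlm:
    def _patriline_rows(self, rng, effect_gene=None):
        rows = []
        for i in range(24):
            g1 = rng.choice(["wt", "A", "B"])
            g3 = rng.choice(["Q", "L", "N"])
            p = 0.8
            if effect_gene == "g3" and g3 in ("L", "N"):
                p = 0.25
            n = int(rng.integers(5, 15))
            rows.append({
                "colony": "C1" if i < 12 else "C2",
                "patriline": f"P{i}",
                "g1": g1, "g3": g3,
                "tested_n": n,
                "survived_n": int(rng.binomial(n, p)),
            })
        return pd.DataFrame(rows)

    def test_planted_gene_dominates(self, rng):
        df = self._patriline_rows(rng, effect_gene="g3")
        rows = {r.term: r for r in at.haplotype_glm(df, ["g1", "g3"])}
        assert rows["g3"].lr_chi2 > 10 * max(rows["g1"].lr_chi2, 1e-9)
        assert rows["g3"].pvalue < 0.001

    def test_no_effect_all_near_zero(self, rng):
        df = self._patriline_rows(rng, effect_gene=None)
        rows = at.haplotype_glm(df, ["g1", "g3"])
        for r in rows:
            assert r.pvalue > 0.01

    def test_constant_gene_flagged(self, rng):
        df = self._patriline_rows(rng)
        df["g1"] = "wt"
        rows = {r.term: r for r in at.haplotype_glm(df, ["g1", "g3"])}
        assert rows["g1"].flagged and rows["g1"].df == 0
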