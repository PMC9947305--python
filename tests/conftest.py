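import itertools

import numpy as np
import pandas as pd
import pytest

from beetol import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_colony():
    """One paper-sized colony: 249 workers, 21 patrilines, 11 loci."""
    cfg = simulate.SimConfig(
        n_colonies=1, workers_per_colony=249, k_patrilines=21, seed=7
    )
    queen, drones, workers = simulate.simulate_colony(cfg, 0)
    return cfg, queen, drones, workers


@pytest.fixture(scope="session")
def gini_subset_oracle():
    """Exhaustive categorical-split search: best Gini gain over all subsets."""

    def oracle(y: np.ndarray, labels: np.ndarray, min_bucket: int = 1):
        n = len(y)
        s = y.sum()
        p = s / n
        parent = 1 - p * p - (1 - p) * (1 - p)
        uniq = sorted(set(labels))
        best_gain, best_subset = -np.inf, None
        for r in range(1, len(uniq)):
            for subset in itertools.combinations(uniq, r):
                mask = np.isin(labels, subset)
                nL = int(mask.sum())
                nR = n - nL
                if nL < min_bucket or nR < min_bucket:
                    continue
                sL = y[mask].sum()
                sR = s - sL
                pL, pR = sL / nL, sR / nR
                gL = 1 - pL * pL - (1 - pL) * (1 - pL)
                gR = 1 - pR * pR - (1 - pR) * (1 - pR)
                gain = parent - (nL / n) * gL - (nR / n) * gR
                if gain > best_gain:
                    best_gain, best_subset = gain, frozenset(subset)
        return best_gain, best_subset

    return oracle


@pytest.fixture(scope="session")
def planted_tree_data():
    """Factory for bee-level data with a two-split haplotype structure.

    gene3 labels {L,N,P} mark a low-survival group; within it gene1 labels
    {B,E} lower survival further; gene2 is pure noise.  Effects are strong
    and both splits flip the majority class, so cost-complexity pruning on
    misclassification error can retain exactly the two planted splits.
    """

    def make(seed: int, n: int = 800) -> pd.DataFrame:
        r = np.random.default_rng(seed)
        g3 = r.choice(["Q", "K", "O", "M", "L", "N", "P"],
                      p=[0.25, 0.1, 0.15, 0.1, 0.14, 0.13, 0.13], size=n)
        g1 = r.choice(["wt", "A", "B", "E", "D"],
                      p=[0.3, 0.2, 0.2, 0.15, 0.15], size=n)
        g2 = r.choice(["wt", "A", "B", "C"], p=[0.4, 0.25, 0.2, 0.15], size=n)
        low3 = np.isin(g3, ["L", "N", "P"])
        low1 = np.isin(g1, ["B", "E"])
        p_surv = np.where(low3, np.where(low1, 0.05, 0.70), 0.95)
        y = (r.random(n) < p_surv).astype(float)
        return pd.DataFrame(
            {"survived": y, "CYP9Q1": g1, "CYP9Q2": g2, "CYP9Q3": g3}
        )

    return make
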