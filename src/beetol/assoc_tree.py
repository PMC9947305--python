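"""CYP9Q haplotype–survival association: weighted GLMs and a classification tree.

Two complementary views of the same question — do amino-acid haplotypes of
the CYP9Q detoxification genes predict whether a bee survives an acute
clothianidin dose?

* :func:`haplotype_glm`: per-patriline binomial GLM weighted by the number
  of bees tested, with type-II likelihood-ratio tests per gene.
* :func:`grow_tree` / :func:`prune_tree`: binary recursive partitioning of
  bee-level survival on categorical gene haplotypes, Gini impurity split
  criterion, with cost-complexity (weakest-link) pruning selected by v-fold
  cross-validation at the complexity value with minimum CV error.

Categorical splits use the ordered-category shortcut: for a binary outcome,
ordering a gene's labels by node survival rate and scanning the k-1 ordered
cut points finds the Gini-optimal label subset without enumerating all
2^(k-1)-1 subsets (the classical result for two-class impurity measures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .herit_stats import AnodevRow, anodev_type2

log = logging.getLogger("beetol")

__all__ = [
    "Split",
    "TreeNode",
    "TreeModel",
    "haplotype_glm",
    "grow_tree",
    "prune_tree",
    "predict_tree",
    "render_tree",
]


def haplotype_glm(
    patriline_table: pd.DataFrame,
    genes: Sequence[str],
    successes: str = "survived_n",
    trials: str = "tested_n",
    colony: str | None = "colony",
) -> list[AnodevRow]:
    """Type-II LR test per gene from a bee-count-weighted binomial GLM.

    One row per patriline: number surviving, number tested, one haplotype
    label column per gene, plus colony.  The model has colony and gene main
    effects; each gene's LR χ² compares the model without that gene against
    the full model.  Returns only the gene rows (colony is an adjustment
    term).  A gene with a single observed label is flagged inestimable.
    """
    terms = list(genes)
    if colony is not None and patriline_table[colony].nunique() > 1:
        terms = [colony] + terms
    rows = anodev_type2(
        patriline_table, terms, response=successes, trials=trials
    )
    return [r for r in rows if r.term in genes]


# ---------------------------------------------------------------------------
# classification tree


@dataclass(frozen=True)
class Split:
    gene: str
    left_labels: frozenset[str]
    right_labels: frozenset[str]


@dataclass
class TreeNode:
    id: int
    n: int
    n_survived: int
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def p_survive(self) -> float:
        return self.n_survived / self.n if self.n else float("nan")

    @property
    def prediction(self) -> int:
        """Majority class: 1 = survived."""
        return int(self.n_survived * 2 >= self.n)

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def misclassified(self) -> int:
        return min(self.n_survived, self.n - self.n_survived)

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()

    def internal(self) -> Iterator["TreeNode"]:
        if not self.is_leaf:
            yield self
            yield from self.left.internal()
            yield from self.right.internal()

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def subtree_misclassified(self) -> int:
        return sum(l.misclassified for l in self.leaves())

    def copy(self) -> "TreeNode":
        return TreeNode(
            id=self.id,
            n=self.n,
            n_survived=self.n_survived,
            split=self.split,
            left=self.left.copy() if self.left else None,
            right=self.right.copy() if self.right else None,
        )


@dataclass
class TreeModel:
    root: TreeNode
    genes: tuple[str, ...]
    min_split: int
    min_bucket: int
    cp_table: pd.DataFrame | None = None  # cp, n_splits, rel_error, xerror, xstd
    chosen_cp: float | None = None

    @property
    def n_splits(self) -> int:
        return sum(1 for _ in self.root.internal())


def _gini(n: int, s: int) -> float:
    if n == 0:
        return 0.0
    p = s / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _best_split(
    y: np.ndarray,
    labels: dict[str, np.ndarray],
    genes: Sequence[str],
    min_bucket: int,
) -> tuple[Split, np.ndarray] | None:
    """Gini-optimal categorical split over all genes, deterministic tie-break.

    Ties in impurity decrease break by gene order, then smaller left subset,
    then lexicographic left labels.
    """
    n = len(y)
    s = int(y.sum())
    parent = _gini(n, s)
    best: tuple[float, int, int, tuple[str, ...], Split, np.ndarray] | None = None
    for g_idx, gene in enumerate(genes):
        lab = labels[gene]
        uniq, inv = np.unique(lab, return_inverse=True)
        if len(uniq) < 2:
            continue
        counts = np.bincount(inv, minlength=len(uniq))
        surv = np.bincount(inv, weights=y, minlength=len(uniq))
        rate = surv / counts
        # order labels by survival rate (ties by label) and scan cut points
        order = np.lexsort((uniq, rate))
        c_n = np.cumsum(counts[order])
        c_s = np.cumsum(surv[order])
        for j in range(len(uniq) - 1):
            nL, sL = int(c_n[j]), int(c_s[j])
            nR, sR = n - nL, s - sL
            if nL < min_bucket or nR < min_bucket:
                continue
            gain = parent - (nL / n) * _gini(nL, sL) - (nR / n) * _gini(nR, sR)
            if gain <= 1e-12:
                continue
            left_set = tuple(sorted(uniq[order[: j + 1]]))
            key = (-gain, g_idx, len(left_set), left_set)
            if best is None or key < (-best[0], best[1], best[2], best[3]):
                split = Split(
                    gene=gene,
                    left_labels=frozenset(left_set),
                    right_labels=frozenset(uniq) - frozenset(left_set),
                )
                mask = np.isin(lab, left_set)
                best = (gain, g_idx, len(left_set), left_set, split, mask)
    if best is None:
        return None
    return best[4], best[5]


def grow_tree(
    data: pd.DataFrame,
    genes: Sequence[str],
    outcome: str = "survived",
    min_split: int = 20,
    min_bucket: int = 7,
    max_depth: int = 30,
) -> TreeModel:
    """Grow an unpruned classification tree of survival on gene haplotypes.

    Rows are individual bees (outcome 0/1) with one categorical label column
    per gene; growth stops at ``min_split`` node size, ``min_bucket`` child
    size, zero impurity or ``max_depth``.
    """
    y = data[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    labels = {g: data[g].astype(str).to_numpy() for g in genes}
    counter = iter(range(10_000_000))

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(id=next(counter), n=len(idx), n_survived=int(y[idx].sum()))
        if (
            len(idx) < min_split
            or depth >= max_depth
            or node.n_survived in (0, node.n)
        ):
            return node
        found = _best_split(
            y[idx], {g: labels[g][idx] for g in genes}, genes, min_bucket
        )
        if found is None:
            return node
        split, left_mask = found
        node.split = split
        node.left = build(idx[left_mask], depth + 1)
        node.right = build(idx[~left_mask], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return TreeModel(
        root=root, genes=tuple(genes), min_split=min_split, min_bucket=min_bucket
    )


def _weakest_links(root: TreeNode, n_total: int, r_root: float) -> dict[int, float]:
    """Relative complexity g(t)/R(root) per internal node."""
    out = {}
    for node in root.internal():
        r_node = node.misclassified / n_total
        r_sub = node.subtree_misclassified / n_total
        g = (r_node - r_sub) / (node.n_leaves - 1)
        out[node.id] = g / r_root if r_root > 0 else np.inf
    return out


def _prune_at(root: TreeNode, cp: float, n_total: int, r_root: float) -> TreeNode:
    """Smallest optimal subtree for relative complexity ``cp`` (weakest-link)."""
    tree = root.copy()
    while True:
        links = _weakest_links(tree, n_total, r_root)
        if not links:
            return tree
        g_min = min(links.values())
        if g_min > cp + 1e-12:
            return tree
        collapse = {nid for nid, g in links.items() if g <= g_min + 1e-12}

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.id in collapse:
                node.split = None
                node.left = None
                node.right = None
                return
            walk(node.left)
            walk(node.right)

        walk(tree)


def _cp_sequence(root: TreeNode, n_total: int, r_root: float) -> list[tuple[float, TreeNode]]:
    """Nested pruning sequence [(alpha_rel, subtree)], alpha ascending from 0."""
    seq: list[tuple[float, TreeNode]] = [(0.0, root.copy())]
    current = root
    while not current.is_leaf:
        links = _weakest_links(current, n_total, r_root)
        g_min = min(links.values())
        current = _prune_at(current, g_min, n_total, r_root)
        seq.append((float(g_min), current.copy()))
    return seq


def _route(node: TreeNode, row: dict) -> tuple[TreeNode, bool]:
    unseen = False
    while not node.is_leaf:
        lab = str(row[node.split.gene])
        if lab in node.split.left_labels:
            node = node.left
        elif lab in node.split.right_labels:
            node = node.right
        else:  # unseen label: majority direction
            unseen = True
            node = node.left if node.left.n >= node.right.n else node.right
    return node, unseen


def prune_tree(
    model: TreeModel,
    data: pd.DataFrame,
    outcome: str = "survived",
    folds: int = 10,
    cp_floor: float = 0.01,
    seed: int | np.random.Generator | None = 0,
) -> TreeModel:
    """Cost-complexity pruning with v-fold cross-validated CP selection.

    The weakest-link sequence of the grown tree gives candidate complexity
    values (relative to the root misclassification error, the rpart CP
    convention); candidates below ``cp_floor`` are discarded.  Each
    candidate is evaluated at the geometric mean of adjacent sequence values
    on stratified, seeded CV folds (trees regrown per fold), and the subtree
    at the CP with minimum cross-validated error is returned (ties favour
    the smaller tree).  A degenerate root (constant outcome) returns the
    root leaf.
    """
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    root = model.root
    r_root_abs = root.misclassified / n
    if r_root_abs == 0 or root.is_leaf:
        pruned = TreeNode(id=root.id, n=root.n, n_survived=root.n_survived)
        return TreeModel(
            root=pruned,
            genes=model.genes,
            min_split=model.min_split,
            min_bucket=model.min_bucket,
            cp_table=pd.DataFrame(
                {"cp": [np.inf], "n_splits": [0], "rel_error": [1.0],
                 "xerror": [1.0], "xstd": [0.0]}
            ),
            chosen_cp=cp_floor,
        )

    seq = _cp_sequence(root, n, r_root_abs)
    # restrict to candidates at or above the floor, keeping the tree that the
    # floor itself selects (the last subtree whose alpha <= floor)
    alphas = [a for a, _ in seq]
    start = max(i for i, a in enumerate(alphas) if a <= cp_floor)
    cand = seq[start:]
    cand_alphas = [max(a, cp_floor) for a, _ in cand]
    # geometric-mean evaluation points between adjacent candidate alphas
    betas = []
    for i in range(len(cand)):
        lo = cand_alphas[i]
        hi = cand_alphas[i + 1] if i + 1 < len(cand) else None
        betas.append(lo if hi is None else float(np.sqrt(lo * hi)))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = min(folds, n)
    fold_id = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds

    cv_err = np.zeros(len(cand))
    for f in range(folds):
        train = data[fold_id != f]
        test = data[fold_id == f]
        if train[outcome].nunique() < 2 or test.empty:
            continue
        sub = grow_tree(
            train,
            model.genes,
            outcome=outcome,
            min_split=model.min_split,
            min_bucket=model.min_bucket,
        )
        sub_rroot = sub.root.misclassified / sub.root.n
        test_rows = test.to_dict("records")
        y_test = test[outcome].to_numpy(dtype=float)
        for i, beta in enumerate(betas):
            pruned = (
                _prune_at(sub.root, beta, sub.root.n, sub_rroot)
                if sub_rroot > 0
                else sub.root
            )
            preds = np.array(
                [_route(pruned, row)[0].prediction for row in test_rows], dtype=float
            )
            cv_err[i] += float((preds != y_test).sum())

    xerror = cv_err / (n * r_root_abs)
    xstd = np.sqrt(np.maximum(xerror * (1 - xerror * r_root_abs), 0) / (n * r_root_abs))
    rel_error = np.array(
        [t.subtree_misclassified / root.misclassified for _, t in cand]
    )
    table = pd.DataFrame(
        {
            "cp": cand_alphas,
            "n_splits": [sum(1 for _ in t.internal()) for _, t in cand],
            "rel_error": rel_error,
            "xerror": xerror,
            "xstd": xstd,
        }
    )
    # minimum CV error; ties favour the smaller tree (larger cp)
    best_i = int(max(np.flatnonzero(xerror <= xerror.min() + 1e-12)))
    chosen_cp = float(cand_alphas[best_i])
    pruned_root = cand[best_i][1].copy()
    return TreeModel(
        root=pruned_root,
        genes=model.genes,
        min_split=model.min_split,
        min_bucket=model.min_bucket,
        cp_table=table,
        chosen_cp=chosen_cp,
    )


def predict_tree(model: TreeModel, rows: pd.DataFrame | dict) -> pd.DataFrame:
    """Route rows to leaves: predicted class, leaf survival rate, flags.

    Labels unseen at a split are routed in the majority direction and
    flagged in the ``unseen_label`` column.
    """
    if isinstance(rows, dict):
        rows = pd.DataFrame([rows])
    records = rows.to_dict("records")
    out = {"prediction": [], "p_survive": [], "leaf_id": [], "unseen_label": []}
    for row in records:
        leaf, unseen = _route(model.root, row)
        if unseen:
            log.warning("unseen haplotype label routed by majority direction")
        out["prediction"].append(leaf.prediction)
        out["p_survive"].append(leaf.p_survive)
        out["leaf_id"].append(leaf.id)
        out["unseen_label"].append(unseen)
    return pd.DataFrame(out, index=rows.index)


def render_tree(model: TreeModel) -> str:
    """Text rendering with per-node survival percentages."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, tag: str) -> None:
        pct = 100.0 * node.p_survive
        lines.append(f"{prefix}{tag}n={node.n}  survival={pct:.0f}%")
        if not node.is_leaf:
            left = ",".join(sorted(node.split.left_labels))
            right = ",".join(sorted(node.split.right_labels))
            walk(node.left, prefix + "  ", f"[{node.split.gene} in {{{left}}}] ")
            walk(node.right, prefix + "  ", f"[{node.split.gene} in {{{right}}}] ")

    walk(model.root, "", "")
    return "\n".join(lines)
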