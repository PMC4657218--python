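"""Support for named topological hypotheses across tree sets.

Two complementary tools: mapping the frequency of a bipartition (split)
over a collection of trees — e.g. bootstrap or locus-jackknife
replicates — and comparing marginal log-likelihoods of constrained
topological hypotheses on the Bayes-factor scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Tuple

import dendropy
import numpy as np

__all__ = [
    "BayesComparison",
    "bipartition_support",
    "bayes_factor_compare",
    "stepping_stone_generations",
    "tree_splits",
]

#: Kass–Raftery-style interpretation thresholds on 2*|log-likelihood
#: difference|: (lower bound, category).
DEFAULT_STRENGTH_SCALE: Tuple[Tuple[float, str], ...] = (
    (10.0, "very strong"),
    (6.0, "strong"),
    (2.0, "positive"),
    (0.0, "barely worth mentioning"),
)


@dataclass
class BayesComparison:
    """A pair of marginal log-likelihoods with their verbal interpretation.

    ``verdict`` is ``"supported"`` when the constrained hypothesis has
    the higher marginal likelihood, else ``"rejected"``; ``strength``
    categorizes ``2 * diff`` on the interpretation scale.
    """

    lnl_for: float
    lnl_against: float
    diff: float
    verdict: str
    strength: str


def tree_splits(tree: dendropy.Tree) -> List[FrozenSet[str]]:
    """All splits of an unrooted tree, one per edge, as leaf-label sets.

    Each split is reported as the leaf set on one side of the edge
    (pendant edges included); the complement denotes the same split.
    """
    splits = []
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            splits.append(below[node])
    return splits


def bipartition_support(
    trees: Sequence[dendropy.Tree], side: Sequence[str], roster: Sequence[str]
) -> float:
    """Percent of trees containing the split ``side`` vs its complement.

    Every tree must have exactly the roster as its leaf set (trees with
    missing taxa are rejected, since restricting them would silently
    change split semantics).  A single-taxon side is present in every
    tree (its pendant edge).
    """
    roster_set = frozenset(roster)
    target = frozenset(side)
    if not 1 <= len(target) <= len(roster_set) - 1:
        raise ValueError("side must be a proper non-empty subset of the roster")
    if not target <= roster_set:
        raise ValueError(f"side taxa not in roster: {sorted(target - roster_set)}")
    complement = roster_set - target
    if not trees:
        raise ValueError("empty tree set")
    hits = 0
    for index, tree in enumerate(trees):
        leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if leaves != roster_set:
            raise ValueError(
                f"tree {index}: leaf set differs from roster "
                f"(missing: {sorted(roster_set - leaves)}, "
                f"extra: {sorted(leaves - roster_set)})"
            )
        splits = tree_splits(tree)
        if any(split == target or split == complement for split in splits):
            hits += 1
    return 100.0 * hits / len(trees)


def bayes_factor_compare(
    lnl_for: float,
    lnl_against: float,
    strength_scale: Sequence[Tuple[float, str]] = DEFAULT_STRENGTH_SCALE,
) -> BayesComparison:
    """Compare marginal log-likelihoods of a hypothesis and its negation.

    ``diff`` is the absolute difference in log units; the verdict is
    "supported" iff the hypothesis's marginal likelihood exceeds that of
    its negation, and the strength category is read from
    ``strength_scale`` applied to ``2 * diff``.
    """
    if not (np.isfinite(lnl_for) and np.isfinite(lnl_against)):
        raise ValueError("marginal log-likelihoods must be finite")
    diff = abs(lnl_for - lnl_against)
    verdict = "supported" if lnl_for > lnl_against else "rejected"
    strength = strength_scale[-1][1]
    for lower_bound, category in strength_scale:
        if 2.0 * diff > lower_bound:
            strength = category
            break
    return BayesComparison(
        lnl_for=lnl_for,
        lnl_against=lnl_against,
        diff=diff,
        verdict=verdict,
        strength=strength,
    )


def stepping_stone_generations(
    steps: int, generations_per_step: int, burnin_steps: int = 1
) -> int:
    """MCMC generations contributing to a stepping-stone marginal likelihood.

    A run of ``steps`` power-posterior steps of
    ``generations_per_step`` generations each, with ``burnin_steps``
    discarded, estimates the marginal likelihood from
    ``(steps - burnin_steps) * generations_per_step`` generations.
    """
    if steps <= burnin_steps:
        raise ValueError("steps must exceed burnin_steps")
    if generations_per_step <= 0:
        raise ValueError("generations_per_step must be positive")
    return (steps - burnin_steps) * generations_per_step
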