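"""Synthetic locus collections with known, controllable structure.

The generator emulates the statistical features the locus-scoring
pipeline keys on — heterogeneous per-locus evolutionary rates, planted
long-branch taxa, variable taxon occupancy and missing data — while
staying simple enough that every expectation has a closed form.  Sites
evolve independently down the (rate-scaled) tree under the simplest
exchangeable 20-state substitution process (all exchanges equal,
uniform frequencies), for which the probability that the two ends of a
branch of length ``t`` differ is ``(19/20) * (1 - exp(-20 t / 19))``.

Branch lengths are drawn lognormal with median
:data:`BASE_BRANCH_MEDIAN` substitutions/site and a modest log-scale
spread :data:`BRANCH_LOG_SD`; the bulk of rate heterogeneity is carried
by the per-locus rate multipliers, not by within-tree branch-length
noise.  Returned trees carry the *true* scaled branch lengths (gene
tree inference is out of scope), and everything is reproducible from an
integer seed through a single ``numpy`` generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from phylosieve.io_formats import AMINO_ACIDS, Alignment, write_alignment, write_trees

__all__ = [
    "BASE_BRANCH_MEDIAN",
    "BRANCH_LOG_SD",
    "SimulationParams",
    "random_unrooted_tree",
    "simulate_locus",
    "simulate_locus_set",
    "write_locus_set",
    "expected_p_distance",
]

#: Median branch length (substitutions/site) of simulated trees.
BASE_BRANCH_MEDIAN = 0.1
#: Log-scale standard deviation of simulated branch lengths.
BRANCH_LOG_SD = 0.15

_N_STATES = 20


@dataclass
class SimulationParams:
    """Parameters of a simulated locus collection.

    ``rate_multipliers`` may list one multiplier per locus, or a pool to
    draw from uniformly (default ``(0.25, 1.0, 4.0)`` — slow, average
    and fast loci).  ``long_branch_plants`` maps a 0-based locus index
    to ``(taxon, pendant scale factor)`` or to a list of such pairs;
    each named taxon's terminal branch is stretched by its factor in
    that locus (a list emulates a locus where a group of taxa is
    long-branched jointly).
    """

    roster: Sequence[str]
    n_loci: int
    locus_length_range: Tuple[int, int] = (100, 300)
    base_tree: Optional[dendropy.Tree] = None
    rate_multipliers: Sequence[float] = (0.25, 1.0, 4.0)
    long_branch_plants: Dict[int, object] = field(default_factory=dict)
    missing_cell_rate: float = 0.0
    taxon_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.roster) < 4:
            raise ValueError("roster must contain at least 4 taxa")
        if any(rate < 0 for rate in self.rate_multipliers):
            raise ValueError("rate multipliers must be non-negative")
        if not 0 <= self.missing_cell_rate < 1:
            raise ValueError("missing_cell_rate must be in [0, 1)")
        if not 0 <= self.taxon_dropout_rate < 1:
            raise ValueError("taxon_dropout_rate must be in [0, 1)")
        lo, hi = self.locus_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid locus_length_range {self.locus_length_range}")


def expected_p_distance(t: float) -> float:
    """Expected per-site difference between the ends of a branch of length ``t``."""
    k = _N_STATES
    return (k - 1) / k * (1.0 - math.exp(-k * t / (k - 1)))


def _draw_length(rng: np.random.Generator) -> float:
    return float(rng.lognormal(math.log(BASE_BRANCH_MEDIAN), BRANCH_LOG_SD))


def _normalize_plants(plant) -> List[Tuple[str, float]]:
    """Accept one ``(taxon, factor)`` pair or a sequence of them."""
    if plant is None:
        return []
    if (
        len(plant) == 2
        and isinstance(plant[0], str)
        and isinstance(plant[1], (int, float))
    ):
        return [(plant[0], float(plant[1]))]
    return [(taxon, float(factor)) for taxon, factor in plant]


def random_unrooted_tree(
    labels: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    """A random unrooted topology (trifurcating root) over ``labels``.

    Built by repeatedly joining two uniformly chosen subtrees; every
    edge gets an independent lognormal length.
    """
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    items = list(labels)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        right = items.pop(j)
        left = items.pop(i)
        joined = f"({left}:{_draw_length(rng):.8f},{right}:{_draw_length(rng):.8f})"
        items.append(joined)
    newick = (
        "("
        + ",".join(f"{item}:{_draw_length(rng):.8f}" for item in items)
        + ");"
    )
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def _evolve(tree: dendropy.Tree, length: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Simulate one state per site per leaf down ``tree``; returns leaf states."""
    states: Dict[dendropy.Node, np.ndarray] = {}
    leaf_states: Dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = rng.integers(0, _N_STATES, size=length)
        else:
            t = float(node.edge.length or 0.0)
            parent = states[node.parent_node]
            p_same = 1.0 / _N_STATES + (1.0 - 1.0 / _N_STATES) * math.exp(
                -_N_STATES * t / (_N_STATES - 1)
            )
            child = parent.copy()
            mask = rng.random(length) >= p_same
            n_changed = int(mask.sum())
            if n_changed:
                offsets = rng.integers(1, _N_STATES, size=n_changed)
                child[mask] = (child[mask] + offsets) % _N_STATES
            states[node] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = states[node]
    return leaf_states


def simulate_locus(
    roster: Sequence[str],
    length: int,
    rate_multiplier: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    base_tree: Optional[dendropy.Tree] = None,
    plant=None,
    missing_cell_rate: float = 0.0,
    drop_taxa: Sequence[str] = (),
    name: str = "locus",
    simulate_supports: bool = True,
) -> Tuple[Alignment, dendropy.Tree]:
    """Simulate one locus: an alignment and the true gene tree.

    The tree (``base_tree`` scaled by ``rate_multiplier``, or a fresh
    random topology) carries the true branch lengths, with the optional
    ``plant`` — one ``(taxon, factor)`` pair or a list of pairs —
    stretching the named pendant edges.  Taxa in
    ``drop_taxa`` are pruned before simulation; missing cells are
    injected as ``?`` at ``missing_cell_rate``.

    When ``simulate_supports`` is set, internal nodes are annotated
    with synthetic bootstrap values (integers drawn uniformly from
    50-100) so the information-content machinery downstream has labels
    to consume; the values carry no mechanistic signal.
    """
    if len(roster) < 4:
        raise ValueError("roster must contain at least 4 taxa")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if base_tree is not None:
        tree = base_tree.clone(depth=1)
    else:
        tree = random_unrooted_tree(roster, rng)
    kept = [t for t in roster if t not in set(drop_taxa)]
    if len(kept) < 4:
        raise ValueError("fewer than 4 taxa left after dropout")
    if len(kept) < len(roster):
        tree.retain_taxa_with_labels(kept)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * rate_multiplier
    for taxon, factor in _normalize_plants(plant):
        node = tree.find_node_with_taxon_label(taxon)
        if node is not None and node.edge.length is not None:
            node.edge.length = node.edge.length * factor
    leaf_states = _evolve(tree, length, rng)
    if simulate_supports:
        for node in tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            value = int(rng.integers(50, 101))
            node.label = str(value)
            node.support = float(value)
    alphabet = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype="S1")
    rows = []
    for taxon in kept:
        seq = alphabet[leaf_states[taxon]].tobytes().decode("ascii")
        if missing_cell_rate > 0:
            mask = rng.random(length) < missing_cell_rate
            chars = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
            chars[mask] = b"?"
            seq = chars.tobytes().decode("ascii")
        rows.append((taxon, seq))
    return Alignment(name=name, rows=rows), tree


def simulate_locus_set(
    params: SimulationParams,
) -> Tuple[List[Tuple[Alignment, dendropy.Tree]], pd.DataFrame]:
    """Simulate ``params.n_loci`` loci plus a per-locus truth table.

    The truth table records, per locus, the true rate multiplier, any
    planted long-branch taxon and its scale factor, the realized taxon
    count, the realized percent of missing cells over the full roster
    grid, and the true mean edge length of the returned tree.
    """
    rng = np.random.default_rng(params.seed)
    per_locus_rates = (
        list(params.rate_multipliers)
        if len(params.rate_multipliers) == params.n_loci
        else None
    )
    loci = []
    truth_rows = []
    lo, hi = params.locus_length_range
    for index in range(params.n_loci):
        name = f"locus{index:04d}"
        length = int(rng.integers(lo, hi + 1))
        if per_locus_rates is not None:
            rate = float(per_locus_rates[index])
        else:
            rate = float(params.rate_multipliers[rng.integers(len(params.rate_multipliers))])
        plant = _normalize_plants(params.long_branch_plants.get(index))
        drop: List[str] = []
        if params.taxon_dropout_rate > 0:
            while True:
                mask = rng.random(len(params.roster)) < params.taxon_dropout_rate
                if len(params.roster) - int(mask.sum()) >= 4:
                    break
            drop = [t for t, m in zip(params.roster, mask) if m]
            for taxon, _factor in plant:
                if taxon in drop:
                    drop.remove(taxon)  # keep planted taxa observable
        aln, tree = simulate_locus(
            params.roster,
            length,
            rate_multiplier=rate,
            rng=rng,
            base_tree=params.base_tree,
            plant=plant,
            missing_cell_rate=params.missing_cell_rate,
            drop_taxa=drop,
            name=name,
        )
        n_missing = sum(seq.count("?") for _, seq in aln.rows)
        n_missing += (len(params.roster) - len(aln.rows)) * length
        edges = [
            float(e.length)
            for e in tree.preorder_edge_iter()
            if e.length is not None
        ]
        truth_rows.append(
            {
                "locus": name,
                "n_cols": length,
                "rate_multiplier": rate,
                "planted_taxon": ",".join(taxon for taxon, _ in plant),
                "plant_scale": plant[0][1] if plant else np.nan,
                "n_taxa": len(aln.rows),
                "pct_missing": 100.0 * n_missing / (len(params.roster) * length),
                "tree_length": sum(edges),
                "mean_edge_length": sum(edges) / len(edges),
            }
        )
        loci.append((aln, tree))
    truth = pd.DataFrame(truth_rows)
    return loci, truth


def write_locus_set(
    loci: Sequence[Tuple[Alignment, dendropy.Tree]],
    truth: pd.DataFrame,
    out_dir,
) -> None:
    """Write one FASTA + Newick pair per locus and the truth table (TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for aln, tree in loci:
        write_alignment(aln, out_dir / f"{aln.name}.fasta", "fasta")
        write_trees([tree], out_dir / f"{aln.name}.nwk")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
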