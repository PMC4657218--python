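"""The five per-locus selection criteria and the long-branch mode ranking.

Each locus (one alignment plus its gene tree) is scored for:

* taxon occupancy and percent missing data,
* rate of evolution (mean edge length of the gene tree),
* substitution saturation (OLS of uncorrected p-distance on patristic
  distance: a shallow slope or poor fit indicates multiple hits),
* information content (average nodal bootstrap support), and
* long-branch (LB) signal: each taxon's mean patristic distance to all
  other taxa expressed as percent deviation from the all-taxon average,
  LB_i = (PD_i / PD_bar - 1) * 100.

Because LB scores are taxon-specific, loci are compared through a set of
*focal* long-branched taxa: the modal LB score of each focal taxon is
estimated across all loci by kernel density, and each locus is ranked by
how many focal taxa it places at or below their mode (i.e. NOT
long-branched in that locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from phylosieve.io_formats import MISSING_CHARS, Alignment
from phylosieve.tree_metrics import (
    DistanceMatrix,
    edge_stats,
    average_support,
    patristic_matrix,
)

__all__ = [
    "SaturationFit",
    "LBProfile",
    "STATS_COLUMNS",
    "p_distance_matrix",
    "saturation_fit",
    "occupancy",
    "lb_scores",
    "lb_mode_ranking",
    "lb_score_matrix",
    "score_loci",
    "write_stats",
    "read_stats",
]

#: Fixed column order of the per-locus statistics table.
STATS_COLUMNS = [
    "locus",
    "n_taxa",
    "n_cols",
    "pct_missing",
    "rate",
    "total_tree_length",
    "avg_support",
    "saturation_slope",
    "saturation_r2",
    "saturation_n_pairs",
    "n_focal_present",
    "focal_under_mode",
]


@dataclass
class SaturationFit:
    """OLS fit of p-distance on patristic distance for one locus."""

    slope: float
    r2: float
    n_pairs: int


@dataclass
class LBProfile:
    """Per-taxon long-branch scores for one gene tree.

    ``scores[t] = (mean_distances[t] / grand_mean - 1) * 100``; the mean
    of the scores over taxa is exactly zero.
    """

    mean_distances: Dict[str, float]
    grand_mean: float
    scores: Dict[str, float]


def _missing_mask(rows: Sequence[Tuple[str, str]]) -> Tuple[List[str], np.ndarray]:
    """Labels plus a boolean (taxon x column) matrix of missing cells."""
    labels = [taxon for taxon, _ in rows]
    if not rows:
        return labels, np.zeros((0, 0), dtype=bool)
    arr = np.frombuffer(
        "".join(seq.upper() for _, seq in rows).encode("ascii"), dtype="S1"
    ).reshape(len(rows), -1)
    mask = np.isin(arr, [c.encode() for c in MISSING_CHARS])
    return labels, mask


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise p-distances with pairwise deletion.

    Entry (i, j) = mismatches / comparable sites, where a site is
    comparable when both rows carry a non-missing residue.  A pair with
    no comparable sites gets ``nan``.
    """
    if len(aln.rows) < 2:
        raise ValueError(f"alignment {aln.name!r}: need >= 2 taxa for p-distances")
    labels = aln.taxa
    seqs = np.frombuffer(
        "".join(seq.upper() for _, seq in aln.rows).encode("ascii"), dtype="S1"
    ).reshape(len(labels), -1)
    missing = np.isin(seqs, [c.encode() for c in MISSING_CHARS])
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~missing[i] & ~missing[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            mismatches = int((seqs[i][comparable] != seqs[j][comparable]).sum())
            values[i, j] = values[j, i] = mismatches / n_comp
    return DistanceMatrix(labels=tuple(labels), values=values)


def saturation_fit(pd_matrix: DistanceMatrix, patristic: DistanceMatrix) -> SaturationFit:
    """Simple linear regression of p-distance on patristic distance.

    Fits ordinary least squares with intercept over all taxon pairs
    shared by the two matrices; pairs with an undefined p-distance are
    dropped listwise.  In the absence of saturation the points fall on a
    line; saturation flattens the curve, lowering slope and R^2.
    """
    shared = [label for label in patristic.labels if label in pd_matrix.labels]
    if len(shared) < 3:
        raise ValueError("insufficient pairs: fewer than 3 shared taxa")
    xs, ys = [], []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            y = pd_matrix.get(shared[i], shared[j])
            if np.isnan(y):
                continue
            xs.append(patristic.get(shared[i], shared[j]))
            ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"insufficient pairs: {len(xs)} usable pairs")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in patristic distances")
    if np.ptp(y) == 0:
        # flat response: slope 0 and nothing explained
        return SaturationFit(slope=0.0, r2=0.0, n_pairs=len(xs))
    fit = scipy_stats.linregress(x, y)
    return SaturationFit(slope=float(fit.slope), r2=float(fit.rvalue**2), n_pairs=len(xs))


def occupancy(aln: Alignment, roster: Sequence[str]) -> Tuple[int, float]:
    """Taxon occupancy and percent missing cells over the full roster.

    ``n_taxa`` counts roster taxa with at least one non-missing residue
    in the alignment; ``pct_missing`` counts missing cells over the full
    ``len(roster) x aln.length`` grid, so taxa absent from the alignment
    contribute all-missing rows.  This makes locus-level and
    concatenated-matrix missingness directly comparable.
    """
    roster_set = set(roster)
    extra = [t for t in aln.taxa if t not in roster_set]
    if extra:
        raise ValueError(f"alignment {aln.name!r}: taxa not in roster: {sorted(extra)}")
    labels, mask = _missing_mask(aln.rows)
    present = 0
    data_missing = 0
    for i, _label in enumerate(labels):
        row_missing = int(mask[i].sum())
        data_missing += row_missing
        if row_missing < aln.length:
            present += 1
    total_cells = len(roster) * aln.length
    absent_cells = (len(roster) - len(labels)) * aln.length
    pct = 100.0 * (data_missing + absent_cells) / total_cells if total_cells else 0.0
    return present, pct


def lb_scores(tree: dendropy.Tree) -> LBProfile:
    """Long-branch score of every taxon on one gene tree.

    PD_i is the mean patristic distance from taxon i to all other taxa,
    PD_bar the mean of the PD_i over taxa, and the score the percent
    deviation LB_i = (PD_i / PD_bar - 1) * 100.  High scores mark
    long-branched taxa; the scores average to zero by construction.
    """
    dm = patristic_matrix(tree)
    n = len(dm)
    if n < 3:
        raise ValueError("need >= 3 taxa for LB scores")
    mean_d = dm.values.sum(axis=1) / (n - 1)
    grand = float(mean_d.mean())
    if grand == 0:
        raise ValueError("degenerate tree: all distances zero")
    scores = (mean_d / grand - 1.0) * 100.0
    return LBProfile(
        mean_distances=dict(zip(dm.labels, mean_d.astype(float))),
        grand_mean=grand,
        scores=dict(zip(dm.labels, scores.astype(float))),
    )


def _kde_mode(values: np.ndarray, grid_size: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a fixed grid.

    The grid spans the observed range; a degenerate (zero-variance)
    sample returns its single value.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    kde = scipy_stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def lb_mode_ranking(
    profiles: Dict[str, LBProfile],
    focal: Sequence[str],
    min_loci: int = 10,
) -> Tuple[Dict[str, float], Dict[str, int]]:
    """Modal LB score per focal taxon and per-locus under-mode counts.

    For each focal taxon, its LB scores are pooled across all loci where
    it is present and the mode of their density is located.  Each locus
    is then scored by the number of focal taxa present whose LB score is
    at or below their modal value — loci where the focal taxa are *not*
    long-branched.  A focal taxon must occur in at least ``min_loci``
    loci for its mode to be considered reliable.
    """
    modes: Dict[str, float] = {}
    for taxon in focal:
        pooled = [
            profile.scores[taxon]
            for profile in profiles.values()
            if taxon in profile.scores
        ]
        if not pooled:
            raise ValueError(f"focal taxon {taxon!r} absent from all loci")
        if len(pooled) < min_loci:
            raise ValueError(
                f"focal taxon {taxon!r} present in only {len(pooled)} loci "
                f"(< {min_loci}); mode unreliable"
            )
        modes[taxon] = _kde_mode(np.asarray(pooled))
    counts = {
        locus: sum(
            1
            for taxon in focal
            if taxon in profile.scores and profile.scores[taxon] <= modes[taxon]
        )
        for locus, profile in profiles.items()
    }
    return modes, counts


def lb_score_matrix(
    profiles: Dict[str, LBProfile], z_scale: bool = False
) -> pd.DataFrame:
    """Loci-by-taxa matrix of LB scores (NaN where a taxon is absent).

    With ``z_scale`` each taxon's column is centered and scaled to unit
    variance across loci, the form used for heat-map visualization of
    among-taxon long-branch variability; zero-variance columns are
    centered only.
    """
    matrix = pd.DataFrame(
        {locus: profile.scores for locus, profile in profiles.items()}
    ).T.sort_index()
    if z_scale:
        centered = matrix - matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=0).replace(0.0, 1.0)
        matrix = centered / sd
    return matrix


def score_loci(
    loci: Iterable[Tuple[Alignment, dendropy.Tree]],
    roster: Sequence[str],
    focal: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, LBProfile]]:
    """Score every locus and return the per-locus statistics table.

    Each element of ``loci`` pairs an alignment with its gene tree; the
    taxa of the two must agree.  Returns a DataFrame with columns
    :data:`STATS_COLUMNS` (one row per locus) plus the per-locus LB
    profiles.  When ``focal`` is given, the LB mode ranking columns are
    populated; saturation columns are NaN for loci where the regression
    is undefined (too few usable pairs).
    """
    rows = []
    profiles: Dict[str, LBProfile] = {}
    for aln, tree in loci:
        tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        aln_taxa = set(aln.taxa)
        if tree_taxa != aln_taxa:
            raise ValueError(
                f"locus {aln.name!r}: alignment/tree taxon mismatch "
                f"(alignment-only: {sorted(aln_taxa - tree_taxa)}, "
                f"tree-only: {sorted(tree_taxa - aln_taxa)})"
            )
        n_taxa, pct_missing = occupancy(aln, roster)
        estats = edge_stats(tree)
        support = average_support(tree)
        patristic = patristic_matrix(tree)
        try:
            sat = saturation_fit(p_distance_matrix(aln), patristic)
            sat_slope, sat_r2, sat_n = sat.slope, sat.r2, sat.n_pairs
        except ValueError:
            sat_slope = sat_r2 = np.nan
            sat_n = 0
        profiles[aln.name] = lb_scores(tree)
        rows.append(
            {
                "locus": aln.name,
                "n_taxa": n_taxa,
                "n_cols": aln.length,
                "pct_missing": pct_missing,
                "rate": estats.mean_edge_length,
                "total_tree_length": estats.total_length,
                "avg_support": np.nan if support is None else support,
                "saturation_slope": sat_slope,
                "saturation_r2": sat_r2,
                "saturation_n_pairs": sat_n,
                "n_focal_present": np.nan,
                "focal_under_mode": np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=STATS_COLUMNS)
    if focal:
        _modes, counts = lb_mode_ranking(profiles, focal)
        focal_set = set(focal)
        table["focal_under_mode"] = [counts[name] for name in table["locus"]]
        table["n_focal_present"] = [
            len(focal_set & set(profiles[name].scores)) for name in table["locus"]
        ]
    return table, profiles


def write_stats(table: pd.DataFrame, path) -> None:
    """Write the statistics table as tab-separated values in fixed column order."""
    table.loc[:, STATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_stats(path) -> pd.DataFrame:
    """Read a statistics table written by :func:`write_stats`."""
    return pd.read_csv(path, sep="\t")
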