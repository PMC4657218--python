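"""Assembly of concatenated matrices from scored loci.

Turns a per-locus statistics table into the family of supermatrices
used for sensitivity analyses: threshold-filtered subsets, the
best-fraction composite-rank subset, progressive (slowest-first)
concatenation series, non-overlapping rate bins, random locus-jackknife
replicates, and reduced-alphabet recodings of assembled matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from phylosieve.io_formats import (
    AMINO_ACIDS,
    MISSING_CHARS,
    Alignment,
    PartitionEntry,
    PartitionTable,
)

__all__ = [
    "SupermatrixSpec",
    "SelectionCriteria",
    "RECODING_SCHEMES",
    "BEST_RANK_CRITERIA",
    "filter_loci",
    "rank_and_select_best",
    "concatenate",
    "progressive_series",
    "rate_bins",
    "jackknife_replicates",
    "write_jackknife_manifest",
    "recode",
]


@dataclass
class SupermatrixSpec:
    """A concatenation plan: member loci, coordinate ranges, roster.

    ``loci`` keeps the selection order (e.g. rate-ascending for a
    progressive matrix); ``ranges`` are in concatenation order
    (lexicographic by locus name) and tile ``1..total length``.
    """

    loci: List[str]
    ranges: PartitionTable
    roster: List[str]
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci in supermatrix spec")

    @property
    def total_length(self) -> int:
        return self.ranges.total_length


@dataclass
class SelectionCriteria:
    """Thresholds and ranking parameters for locus selection.

    Thresholds are inclusive (keep when >= min / <= max) except where
    ``support_strict`` requests the strict reading of the bootstrap
    cut-off ("higher than" rather than "or more").
    """

    min_taxa: Optional[int] = None
    max_pct_missing: Optional[float] = None
    min_avg_support: Optional[float] = None
    support_strict: bool = False
    focal_presence_min: Optional[int] = None
    min_focal_under_mode: Optional[int] = None
    best_fraction: Optional[float] = None
    #: per-criterion better-is-higher flags for composite ranking
    criterion_directions: Dict[str, bool] = field(
        default_factory=lambda: dict(BEST_RANK_CRITERIA)
    )

    def __post_init__(self) -> None:
        if self.best_fraction is not None and not 0 < self.best_fraction <= 1:
            raise ValueError(f"best_fraction must be in (0, 1], got {self.best_fraction}")


#: The five composite-rank criteria and their default directions
#: (True = higher is better).  Rate is lower-better (slow loci retain
#: signal); a steeper saturation slope means less saturated.
BEST_RANK_CRITERIA: Dict[str, bool] = {
    "n_taxa": True,
    "avg_support": True,
    "rate": False,
    "saturation_slope": True,
    "focal_under_mode": True,
}


def _require_column(stats: pd.DataFrame, column: str) -> pd.Series:
    if column not in stats.columns:
        raise ValueError(f"criterion references absent statistic {column!r}")
    series = stats[column]
    if series.isna().any():
        missing = stats.loc[series.isna(), "locus"].tolist()
        raise ValueError(f"statistic {column!r} absent for loci {missing}")
    return series


def filter_loci(stats: pd.DataFrame, criteria: SelectionCriteria) -> List[str]:
    """Loci satisfying every set threshold of ``criteria``.

    The missing-data cut follows the "discard when more than X%" rule,
    so a locus at exactly the threshold is retained; the bootstrap cut
    defaults to inclusive (>=) with ``support_strict`` switching to the
    strict reading.
    """
    keep = pd.Series(True, index=stats.index)
    any_set = False
    if criteria.min_taxa is not None:
        keep &= _require_column(stats, "n_taxa") >= criteria.min_taxa
        any_set = True
    if criteria.max_pct_missing is not None:
        keep &= _require_column(stats, "pct_missing") <= criteria.max_pct_missing
        any_set = True
    if criteria.min_avg_support is not None:
        support = _require_column(stats, "avg_support")
        if criteria.support_strict:
            keep &= support > criteria.min_avg_support
        else:
            keep &= support >= criteria.min_avg_support
        any_set = True
    if criteria.focal_presence_min is not None:
        keep &= _require_column(stats, "n_focal_present") >= criteria.focal_presence_min
        any_set = True
    if criteria.min_focal_under_mode is not None:
        keep &= _require_column(stats, "focal_under_mode") >= criteria.min_focal_under_mode
        any_set = True
    if not any_set:
        raise ValueError("no selection criterion set")
    return stats.loc[keep, "locus"].tolist()


def rank_and_select_best(
    stats: pd.DataFrame,
    criteria: SelectionCriteria,
    weights: Optional[Mapping[str, float]] = None,
) -> List[str]:
    """The best-fraction loci by composite rank across the five criteria.

    Each locus is ranked per criterion (rank 1 = best, direction per
    ``criteria.criterion_directions``, ties share the average rank) and
    the composite score is the (optionally weighted) sum of ranks.  The
    ``ceil(best_fraction * n)`` loci with the smallest composite score
    are returned, ties broken lexicographically by locus name.
    """
    if criteria.best_fraction is None:
        raise ValueError("best_fraction not set")
    directions = criteria.criterion_directions
    composite = pd.Series(0.0, index=stats.index)
    for column, higher_better in directions.items():
        series = _require_column(stats, column)
        rank = series.rank(ascending=not higher_better, method="average")
        composite += rank * (1.0 if weights is None else float(weights.get(column, 1.0)))
    n_select = math.ceil(criteria.best_fraction * len(stats))
    order = pd.DataFrame(
        {"locus": stats["locus"].values, "composite": composite.values}
    ).sort_values(["composite", "locus"], kind="mergesort")
    return order["locus"].head(n_select).tolist()


def concatenate(
    loci: Iterable[Alignment],
    roster: Sequence[str],
    model: str = "AUTO",
    provenance: Optional[Dict] = None,
) -> Tuple[Alignment, SupermatrixSpec]:
    """Concatenate loci into a supermatrix over the full roster.

    Column blocks are ordered lexicographically by locus name; a taxon
    absent from a locus gets an all-``?`` block.  Returns the matrix and
    its :class:`SupermatrixSpec` (with the partition table).
    """
    members = sorted(loci, key=lambda aln: aln.name)
    if not members:
        raise ValueError("no loci to concatenate")
    names = [aln.name for aln in members]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate locus names: {dupes}")
    roster = list(roster)
    roster_set = set(roster)
    for aln in members:
        extra = set(aln.taxa) - roster_set
        if extra:
            raise ValueError(
                f"locus {aln.name!r}: taxa not in roster: {sorted(extra)}"
            )
    blocks: Dict[str, List[str]] = {taxon: [] for taxon in roster}
    entries = []
    position = 1
    for aln in members:
        seqs = dict(aln.rows)
        filler = "?" * aln.length
        for taxon in roster:
            blocks[taxon].append(seqs.get(taxon, filler))
        entries.append(
            PartitionEntry(model, aln.name, position, position + aln.length - 1)
        )
        position += aln.length
    matrix = Alignment(
        name="supermatrix",
        rows=[(taxon, "".join(blocks[taxon])) for taxon in roster],
    )
    spec = SupermatrixSpec(
        loci=names,
        ranges=PartitionTable(entries),
        roster=roster,
        provenance=provenance or {},
    )
    return matrix, spec


def _rate_sorted(stats: pd.DataFrame) -> pd.DataFrame:
    _require_column(stats, "rate")
    return stats.sort_values(["rate", "locus"], kind="mergesort")


def _spec_from_rows(
    rows: pd.DataFrame, roster: Sequence[str], provenance: Dict, model: str = "AUTO"
) -> SupermatrixSpec:
    lengths = dict(zip(rows["locus"], rows["n_cols"].astype(int)))
    entries = []
    position = 1
    for name in sorted(lengths):
        entries.append(PartitionEntry(model, name, position, position + lengths[name] - 1))
        position += lengths[name]
    return SupermatrixSpec(
        loci=rows["locus"].tolist(),
        ranges=PartitionTable(entries),
        roster=list(roster),
        provenance=provenance,
    )


def progressive_series(
    stats: pd.DataFrame, sizes: Sequence[int], roster: Sequence[str]
) -> List[SupermatrixSpec]:
    """Nested matrices of the k slowest-evolving loci for each k in ``sizes``.

    Loci are ordered by rate ascending (ties by name); the k-th spec
    holds the first ``sizes[k]`` of that order, so the specs are nested.
    """
    ordered = _rate_sorted(stats)
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    specs = []
    for size in sizes:
        if size > len(ordered):
            raise ValueError(f"size {size} exceeds number of loci {len(ordered)}")
        specs.append(
            _spec_from_rows(
                ordered.head(size),
                roster,
                provenance={"strategy": "progressive", "size": int(size)},
            )
        )
    return specs


def rate_bins(
    stats: pd.DataFrame, bin_size: int, roster: Sequence[str]
) -> List[SupermatrixSpec]:
    """Non-overlapping rate-sorted bins of ``bin_size`` loci, slowest first.

    When ``bin_size`` does not divide the locus count, the final bin
    holds the remainder (total coverage is preferred over equal size).
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    ordered = _rate_sorted(stats)
    specs = []
    for start in range(0, len(ordered), bin_size):
        chunk = ordered.iloc[start : start + bin_size]
        specs.append(
            _spec_from_rows(
                chunk,
                roster,
                provenance={"strategy": "rate_bin", "bin": start // bin_size + 1},
            )
        )
    return specs


def jackknife_replicates(
    loci: Sequence[str], k: int, reps: int, seed: int
) -> Iterator[List[str]]:
    """Random ``k``-locus subsets drawn without replacement, ``reps`` times.

    Each replicate samples k distinct loci uniformly; the whole series
    is reproducible from ``seed``.
    """
    loci = list(loci)
    if k > len(loci):
        raise ValueError(f"k={k} exceeds number of loci {len(loci)}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        idx = rng.choice(len(loci), size=k, replace=False)
        yield [loci[i] for i in idx]


def write_jackknife_manifest(
    replicates: Iterable[List[str]], path, seed: int
) -> None:
    """Write a tab-separated manifest: replicate index, seed, locus names."""
    with open(path, "w") as handle:
        for index, names in enumerate(replicates, start=1):
            handle.write("\t".join([str(index), str(seed)] + list(names)) + "\n")


def _build_scheme(groups: Sequence[str], unassigned_to_missing: bool = False) -> Dict[str, str]:
    table = {}
    for group in groups:
        representative = group[0]
        for residue in group:
            table[residue] = representative
    if unassigned_to_missing:
        for residue in AMINO_ACIDS:
            table.setdefault(residue, "?")
    return table


#: Reduced-alphabet recoding tables.  Each group is written to its first
#: (representative) letter so recoding is idempotent.  ``dayhoff4``
#: leaves cysteine unassigned (recoded to missing).
RECODING_SCHEMES: Dict[str, Dict[str, str]] = {
    "dayhoff6": _build_scheme(["AGPST", "DENQ", "HKR", "ILMV", "FWY", "C"]),
    "dayhoff4": _build_scheme(["AGPST", "DENQ", "HKR", "FWYILMV"], unassigned_to_missing=True),
    "hp": _build_scheme(["ACFGILMVW", "DEHKNPQRSTY"]),
}


def recode(aln: Alignment, scheme: str) -> Alignment:
    """Recode amino acids into the reduced alphabet of ``scheme``.

    ``scheme`` is one of ``dayhoff6``, ``dayhoff4`` or ``hp``
    (hydrophobic/polar).  Gap and missing symbols pass through
    unchanged; any other residue outside the 20-letter alphabet is an
    error naming the position.
    """
    if scheme not in RECODING_SCHEMES:
        raise ValueError(
            f"unknown recoding scheme {scheme!r}; choose from {sorted(RECODING_SCHEMES)}"
        )
    table = RECODING_SCHEMES[scheme]
    rows = []
    for taxon, seq in aln.rows:
        out = []
        for pos, residue in enumerate(seq.upper(), start=1):
            if residue in MISSING_CHARS:
                out.append(residue)
            elif residue in table:
                out.append(table[residue])
            else:
                raise ValueError(
                    f"locus {aln.name!r}, taxon {taxon!r}, position {pos}: "
                    f"residue {residue!r} outside the amino-acid alphabet"
                )
        rows.append((taxon, "".join(out)))
    return Alignment(name=aln.name, rows=rows)
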