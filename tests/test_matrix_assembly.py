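"""Matrix assembly: filtering, composite ranking, concatenation, resampling, recoding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylosieve.io_formats import Alignment
from phylosieve.locus_stats import occupancy
from phylosieve.matrix_assembly import (
    BEST_RANK_CRITERIA,
    RECODING_SCHEMES,
    SelectionCriteria,
    concatenate,
    filter_loci,
    jackknife_replicates,
    progressive_series,
    rank_and_select_best,
    rate_bins,
    recode,
    write_jackknife_manifest,
)


def _stats_frame(rng, n=20):
    """A synthetic per-locus statistics table with all rank columns."""
    return pd.DataFrame(
        {
            "locus": [f"locus{i:03d}" for i in range(n)],
            "n_taxa": rng.integers(5, 21, size=n),
            "n_cols": rng.integers(50, 300, size=n),
            "pct_missing": rng.uniform(0, 60, size=n),
            "rate": rng.uniform(0.01, 0.5, size=n),
            "avg_support": rng.uniform(30, 100, size=n),
            "saturation_slope": rng.uniform(0.1, 1.2, size=n),
            "focal_under_mode": rng.integers(0, 5, size=n),
            "n_focal_present": rng.integers(0, 5, size=n),
        }
    )


class TestFilterLoci:
    def test_min_taxa_threshold(self, rng):
        stats = _stats_frame(rng)
        selected = filter_loci(stats, SelectionCriteria(min_taxa=15))
        expected = stats.loc[stats["n_taxa"] >= 15, "locus"].tolist()
        assert selected == expected

    def test_exactly_at_missing_threshold_retained(self):
        stats = pd.DataFrame(
            {"locus": ["a", "b"], "pct_missing": [40.0, 40.0001]}
        )
        selected = filter_loci(stats, SelectionCriteria(max_pct_missing=40.0))
        assert selected == ["a"]

    def test_support_threshold_inclusive_by_default_strict_on_request(self):
        stats = pd.DataFrame({"locus": ["a", "b"], "avg_support": [60.0, 60.5]})
        assert filter_loci(stats, SelectionCriteria(min_avg_support=60)) == ["a", "b"]
        strict = SelectionCriteria(min_avg_support=60, support_strict=True)
        assert filter_loci(stats, strict) == ["b"]

    def test_conjunction_equals_intersection(self, rng):
        stats = _stats_frame(rng)
        both = filter_loci(
            stats, SelectionCriteria(min_taxa=12, max_pct_missing=35.0)
        )
        only_taxa = filter_loci(stats, SelectionCriteria(min_taxa=12))
        only_missing = filter_loci(stats, SelectionCriteria(max_pct_missing=35.0))
        assert set(both) == set(only_taxa) & set(only_missing)

    def test_monotone_in_thresholds(self, rng):
        stats = _stats_frame(rng)
        tight = filter_loci(stats, SelectionCriteria(min_taxa=16, max_pct_missing=30.0))
        relaxed = filter_loci(stats, SelectionCriteria(min_taxa=12, max_pct_missing=45.0))
        assert set(tight) <= set(relaxed)

    def test_absent_statistic_rejected(self, rng):
        stats = _stats_frame(rng).drop(columns=["avg_support"])
        with pytest.raises(ValueError, match="avg_support"):
            filter_loci(stats, SelectionCriteria(min_avg_support=60))

    def test_no_criterion_set_rejected(self, rng):
        with pytest.raises(ValueError, match="criterion"):
            filter_loci(_stats_frame(rng), SelectionCriteria())


class TestRankAndSelectBest:
    def test_fraction_of_1080_gives_108(self, rng):
        stats = _stats_frame(rng, n=1080)
        selected = rank_and_select_best(stats, SelectionCriteria(best_fraction=0.10))
        assert len(selected) == 108

    def test_dominant_locus_always_selected(self, rng):
        stats = _stats_frame(rng, n=30)
        stats.loc[0, ["n_taxa", "avg_support", "saturation_slope", "focal_under_mode"]] = [
            99,
            100.0,
            5.0,
            4,
        ]
        stats.loc[0, "rate"] = 1e-6
        for fraction in (0.05, 0.2, 0.5):
            selected = rank_and_select_best(
                stats, SelectionCriteria(best_fraction=fraction)
            )
            assert stats.loc[0, "locus"] in selected

    def test_matches_brute_force_composite(self, rng):
        stats = _stats_frame(rng, n=15)
        selected = rank_and_select_best(stats, SelectionCriteria(best_fraction=0.4))
        # independent oracle: explicit rank computation per criterion
        composite = np.zeros(len(stats))
        for column, higher_better in BEST_RANK_CRITERIA.items():
            values = stats[column].to_numpy(dtype=float)
            order = -values if higher_better else values
            ranks = pd.Series(order).rank(method="average").to_numpy()
            composite += ranks
        expected = (
            pd.DataFrame({"locus": stats["locus"], "score": composite})
            .sort_values(["score", "locus"])
            .head(int(np.ceil(0.4 * len(stats))))["locus"]
            .tolist()
        )
        assert selected == expected

    def test_output_size_is_ceiling(self, rng):
        stats = _stats_frame(rng, n=7)
        selected = rank_and_select_best(stats, SelectionCriteria(best_fraction=0.5))
        assert len(selected) == 4  # ceil(3.5)


def _random_loci(rng, n_loci, roster, min_len=5, max_len=30):
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-?"))
    loci = []
    for i in range(n_loci):
        length = int(rng.integers(min_len, max_len + 1))
        members = [t for t in roster if rng.random() > 0.3] or list(roster[:2])
        rows = [(t, "".join(rng.choice(alphabet, size=length))) for t in members]
        loci.append(Alignment(f"locus{i:03d}", rows))
    return loci


class TestConcatenate:
    def test_lengths_and_ranges(self):
        roster = ["A", "B"]
        loci = [
            Alignment("g2", [("A", "C" * 100), ("B", "D" * 100)]),
            Alignment("g1", [("A", "A" * 250), ("B", "C" * 250)]),
        ]
        matrix, spec = concatenate(loci, roster)
        assert matrix.length == 350
        assert [(e.name, e.start, e.end) for e in spec.ranges.entries] == [
            ("g1", 1, 250),
            ("g2", 251, 350),
        ]

    def test_absent_taxon_block_filled(self):
        roster = ["A", "B", "C"]
        loci = [Alignment("g1", [("A", "AAAA"), ("B", "CCCC")])]
        matrix, _ = concatenate(loci, roster)
        assert matrix.sequence("C") == "????"

    def test_duplicate_locus_names_rejected(self):
        loci = [
            Alignment("g1", [("A", "AA")]),
            Alignment("g1", [("A", "CC")]),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            concatenate(loci, ["A"])

    def test_missingness_is_length_weighted_mean(self, rng):
        roster = [f"t{i}" for i in range(8)]
        loci = _random_loci(rng, 6, roster)
        matrix, _ = concatenate(loci, roster)
        _, pct_concat = occupancy(matrix, roster)
        per_locus = [occupancy(aln, roster)[1] for aln in loci]
        lengths = [aln.length for aln in loci]
        expected = np.average(per_locus, weights=lengths)
        assert pct_concat == pytest.approx(expected)

    def test_length_conservation_randomized(self, rng):
        roster = [f"t{i}" for i in range(6)]
        for _ in range(10):
            loci = _random_loci(rng, int(rng.integers(2, 10)), roster)
            matrix, spec = concatenate(loci, roster)
            assert matrix.length == sum(aln.length for aln in loci)
            assert spec.ranges.total_length == matrix.length


class TestProgressiveAndBins:
    def test_progressive_nested_prefixes(self, rng):
        stats = _stats_frame(rng, n=20)
        specs = progressive_series(stats, [5, 10], roster=["A"])
        assert len(specs[0].loci) == 5 and len(specs[1].loci) == 10
        assert set(specs[0].loci) < set(specs[1].loci)

    def test_full_size_is_identity(self, rng):
        stats = _stats_frame(rng, n=12)
        (spec,) = progressive_series(stats, [12], roster=["A"])
        assert set(spec.loci) == set(stats["locus"])

    def test_membership_matches_independent_sort(self, rng):
        stats = _stats_frame(rng, n=25)
        specs = progressive_series(stats, [7, 13], roster=["A"])
        expected = stats.sort_values(["rate", "locus"])["locus"].tolist()
        assert specs[0].loci == expected[:7]
        assert specs[1].loci == expected[:13]

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            progressive_series(_stats_frame(rng, n=5), [6], roster=["A"])

    def test_bins_partition_the_loci(self, rng):
        stats = _stats_frame(rng, n=20)
        specs = rate_bins(stats, 6, roster=["A"])
        assert [len(s.loci) for s in specs] == [6, 6, 6, 2]
        seen = list(itertools.chain.from_iterable(s.loci for s in specs))
        assert sorted(seen) == sorted(stats["locus"])
        assert len(set(seen)) == len(seen)

    def test_bin_rate_medians_nondecreasing(self, rng):
        stats = _stats_frame(rng, n=40)
        specs = rate_bins(stats, 10, roster=["A"])
        rate_of = dict(zip(stats["locus"], stats["rate"]))
        medians = [np.median([rate_of[l] for l in s.loci]) for s in specs]
        assert all(a <= b for a, b in zip(medians, medians[1:]))

    def test_bad_bin_size_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            rate_bins(_stats_frame(rng), 0, roster=["A"])


class TestJackknife:
    def test_replicate_shape_and_uniqueness(self):
        names = [f"locus{i:04d}" for i in range(100)]
        reps = list(jackknife_replicates(names, k=20, reps=50, seed=11))
        assert len(reps) == 50
        for rep in reps:
            assert len(rep) == 20
            assert len(set(rep)) == 20

    def test_seed_determinism_and_divergence(self, tmp_path):
        names = [f"locus{i}" for i in range(40)]
        first = list(jackknife_replicates(names, 5, 10, seed=3))
        second = list(jackknife_replicates(names, 5, 10, seed=3))
        other = list(jackknife_replicates(names, 5, 10, seed=4))
        assert first == second
        assert first != other
        path_a, path_b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_jackknife_manifest(first, path_a, seed=3)
        write_jackknife_manifest(second, path_b, seed=3)
        assert path_a.read_bytes() == path_b.read_bytes()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            list(jackknife_replicates(["a", "b"], k=3, reps=1, seed=0))

    def test_single_locus_inclusion_frequencies_uniform(self):
        names = [f"locus{i}" for i in range(12)]
        reps = 10_000
        counts = {name: 0 for name in names}
        for rep in jackknife_replicates(names, k=1, reps=reps, seed=5):
            counts[rep[0]] += 1
        p = 1 / len(names)
        sd = np.sqrt(reps * p * (1 - p))
        for count in counts.values():
            assert abs(count - reps * p) <= 3 * sd


class TestRecode:
    def test_dayhoff6_groups(self):
        aln = Alignment("x", [("A", "AGPSTC")])
        out = recode(aln, "dayhoff6")
        seq = out.sequence("A")
        assert len(set(seq[:5])) == 1  # AGPST in one group
        assert seq[5] == "C"  # cysteine alone

    def test_hp_two_groups(self):
        aln = Alignment("x", [("A", "ACFGILMVWDEHKNPQRSTY")])
        seq = recode(aln, "hp").sequence("A")
        assert len(set(seq[:9])) == 1
        assert len(set(seq[9:])) == 1
        assert set(seq[:9]) != set(seq[9:])

    def test_dayhoff4_cysteine_to_missing(self):
        aln = Alignment("x", [("A", "CAD")])
        assert recode(aln, "dayhoff4").sequence("A")[0] == "?"

    @pytest.mark.parametrize("scheme", sorted(RECODING_SCHEMES))
    def test_idempotent(self, scheme, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-?X"))
        rows = [(f"t{i}", "".join(rng.choice(alphabet, size=50))) for i in range(4)]
        once = recode(Alignment("x", rows), scheme)
        twice = recode(once, scheme)
        assert once.rows == twice.rows

    @pytest.mark.parametrize("scheme", sorted(RECODING_SCHEMES))
    def test_shape_and_missing_preserved(self, scheme, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-?X"))
        rows = [(f"t{i}", "".join(rng.choice(alphabet, size=30))) for i in range(5)]
        aln = Alignment("x", rows)
        out = recode(aln, scheme)
        assert out.taxa == aln.taxa
        assert out.length == aln.length
        if scheme != "dayhoff4":  # dayhoff4 adds missing for cysteine
            for (_, before), (_, after) in zip(aln.rows, out.rows):
                for b, a in zip(before, after):
                    assert (b in "-?X") == (a in "-?X")

    def test_unknown_residue_position_named(self):
        aln = Alignment("x", [("A", "ACB")])
        with pytest.raises(ValueError, match="position 3"):
            recode(aln, "dayhoff6")

    @given(st.sampled_from(sorted(RECODING_SCHEMES)))
    @settings(max_examples=3, deadline=None, derandomize=True)
    def test_group_tables_cover_alphabet(self, scheme):
        table = RECODING_SCHEMES[scheme]
        assert set(table) == set("ACDEFGHIKLMNPQRSTVWY")
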