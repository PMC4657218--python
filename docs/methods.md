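# Methods

This note documents the statistical definitions, conventions and
design choices behind `phylosieve`, in the order a locus travels
through the pipeline.

## Tree conventions

Gene trees are read as Newick with optional internal-node labels
interpreted as support values.  Support scale is detected per file: if
every numeric label in a file is ≤ 1 the values are treated as
proportions and normalized to percent, so RAxML bootstrap (0–100) and
PhyloBayes posterior (0–1) inputs are comparable.  A file mixing both
conventions cannot be disambiguated; values are then taken at face
value on the percent scale.

All edge-based quantities use **unrooted edge semantics**.  When a tree
arrives in rooted-binary form (root of degree two), the two
root-adjacent edges are artifacts of the rooting of what is really one
edge of the unrooted tree; they are merged (lengths summed) for edge
counts, mean edge length, and pendant-edge identification.  Path
lengths are unaffected by rooting, so patristic distances need no
special handling.  Trees with multifurcations are accepted throughout.

## Per-locus statistics

**Occupancy and missingness.**  `n_taxa` counts roster taxa with at
least one non-missing residue (`-`, `?`, `X` are all missing, for
trimAl/RAxML interoperability).  `pct_missing` is computed over the
full `|roster| × length` grid with absent taxa as all-missing rows.
This convention makes the missingness of a concatenation equal the
length-weighted mean of its members' missingness, so locus-level and
matrix-level numbers can be compared directly.

**Rate.**  Mean edge length of the gene tree — total tree length in
substitutions/site divided by the number of edges.  It is a deliberate,
cheap proxy: it ignores differences in taxon sampling between loci,
which is acceptable for *ranking* loci drawn from one roster but should
not be read as an absolute rate.

**Saturation.**  Uncorrected p-distances (mismatches over comparable
sites, pairwise deletion; a pair with no comparable sites is dropped)
are regressed on patristic distances by ordinary least squares with
intercept.  Without saturation the points are linear; multiple hits
flatten the curve, shrinking slope and R².  Degenerate cases: fewer
than three usable pairs or zero variance in the patristic distances are
errors; a constant p-distance response returns slope 0, R² 0 (nothing
explained).  Within `score_loci` a failed regression yields NaN
saturation columns rather than aborting the whole table.

**Information content.**  Arithmetic mean of internal-node support
values; absent (NaN in the table) when no internal node carries
support.

**Long-branch score.**  For taxon *i*, `PD_i` is the mean patristic
distance to all other taxa and `LB_i = (PD_i / PD̄ − 1) × 100`, the
percent deviation from the taxon-averaged mean `PD̄`.  The scores sum
to zero on every tree by construction — an identity the test suite
checks to 1e−9 on a thousand random trees.

Because LB scores are relative *within* a locus, they are compared
*across* loci through a set of focal (long-branch-suspect) taxa.  For
each focal taxon its LB scores are pooled over all loci where it is
present (at least 10 required, configurable) and the mode of the
pooled density is located: Gaussian KDE with Silverman bandwidth,
argmax on a 512-point grid spanning the observed range; a
zero-variance pool returns its single value directly.  A locus is then
scored by the number of focal taxa present with `LB ≤ mode` — focal
taxa *not* long-branched in that locus.  "At or below the mode" is the
operative reading because lower LB means a shorter branch, and the
whole point is to find loci where the suspects behave.

An important structural property discovered while validating this
statistic: LB scores are zero-sum within a locus, so elongating a
*single* taxon's branch mechanically depresses every other taxon's
score.  If only one focal taxon is elongated, the remaining focal taxa
drop below their modes and the under-mode count barely changes.  The
count is therefore a diagnostic for loci where the focal group is
long-branched *jointly* — which is the scenario it is meant to flag —
and the synthetic validation plants joint elongations accordingly.

**Spurious-sequence flag.**  A terminal branch strictly longer than
`factor` (default 5) times the tree's mean edge length marks a suspect
sequence.  The mean is single-pass and includes the candidate edge
itself; flagged taxa are not removed iteratively.  This flag targets a
single aberrant sequence: several simultaneously elongated pendants
inflate the mean and raise the threshold against themselves.

## Locus selection and matrix assembly

**Threshold filtering.**  All set thresholds must hold simultaneously.
Boundary semantics follow the usual "discard when more than X%"
phrasing: a locus at exactly the maximum missingness is retained.  The
bootstrap threshold is inclusive (≥) by default with a strict (>)
variant available, since both readings circulate.

**Composite best-fraction ranking.**  Each locus is ranked on five
criteria — occupancy (higher better), mean bootstrap (higher), rate
(lower), saturation slope (higher = less saturated), focal-under-mode
count (higher) — with ties sharing the average rank.  The composite
score is the unweighted sum of ranks (weights configurable), and the
`ceil(fraction × n)` smallest-composite loci win, ties broken
lexicographically by name.  The choice of slope rather than R² for the
saturation criterion, and of an unweighted sum, are genuinely open
choices; both are exposed as parameters
(`SelectionCriteria.criterion_directions`, the `weights` argument).

**Concatenation.**  Column blocks are ordered lexicographically by
locus name (downstream partitioned analyses are order-insensitive, but
a fixed order makes outputs reproducible); absent taxa get all-`?`
blocks; partition coordinates are 1-based inclusive in RAxML syntax
(`MODEL, name = start-end`).

**Progressive series and rate bins.**  Loci sorted by rate ascending,
ties broken by name for determinism.  Progressive matrices are nested
prefixes of that order; bins are consecutive non-overlapping slices
(slowest first), the final bin holding any remainder — full coverage
is preferred over equal bin size.

**Locus jackknife.**  Each replicate draws `k` distinct loci uniformly
without replacement from a single `numpy` PCG64 generator seeded by the
user; manifests are byte-identical across runs with the same seed.

**Recoding.**  Reduced alphabets `dayhoff6`
(AGPST / DENQ / HKR / ILMV / FWY / C), `hp` (ACFGILMVW / DEHKNPQRSTY)
and `dayhoff4` (AGPST / DENQ / HKR / FWYILMV, cysteine recoded to
missing).  Each group maps to its first letter, making recoding
idempotent; gap and missing symbols pass through.  The exact
composition of the four-state scheme varies between software
implementations; the grouping above merges the two hydrophobic Dayhoff
classes and drops cysteine, and is emitted in the run's provenance
record so downstream users can verify it.

## Hypothesis support

**Bipartition support** is the percent of trees in a set containing an
edge that splits the roster into the hypothesized side vs its
complement (unrooted semantics; a single-taxon side is trivially
present).  Trees whose leaf set differs from the roster are rejected
rather than restricted: replicate tree sets share a fixed roster, and
silently restricting a tree changes what a split means.

**Bayes-factor comparison** takes two externally estimated marginal
log-likelihoods (e.g. from stepping-stone integration) and reports
their absolute difference in log units, a supported/rejected verdict,
and a strength category from thresholds on `2·diff` (defaults: > 10
very strong, > 6 strong, > 2 positive).  Estimating marginal
likelihoods is out of scope; only the comparison arithmetic lives
here, including the bookkeeping
`(steps − burnin) × generations_per_step` for stepping-stone runs.

## The synthetic generator

`phylosieve.simulate` emulates exactly the features the pipeline keys
on and nothing more:

* **Substitution process**: the simplest exchangeable 20-state model —
  all exchanges equal, uniform frequencies, sites i.i.d.  The
  probability that the two ends of a branch of length *t* differ is
  `(19/20)(1 − exp(−20t/19))`, which the test suite verifies
  empirically against 10,000-site simulations.
* **Trees**: random unrooted topologies built by uniform joins, or a
  user-supplied base tree; branch lengths lognormal with median 0.1
  substitutions/site and log-sd 0.15.  The spread is deliberately
  modest: within-locus branch-length noise is kept small so that
  between-locus rate heterogeneity is carried cleanly by the per-locus
  rate multipliers (default pool 0.25 / 1 / 4 — slow, average, fast),
  and so that an 8× planted pendant is reliably separable from
  background variation by the 5× filter on a 20-taxon roster.
* **Planted long branches**: a locus can stretch one pendant (the
  spurious-sequence scenario) or several jointly (the
  long-branch-prone-locus scenario; see the zero-sum note above).
* **Occupancy**: whole-taxon dropout (re-drawn until at least four
  taxa remain; planted taxa are never dropped, so plants stay
  observable) plus i.i.d. missing cells written as `?`.
* **Supports**: internal nodes get synthetic bootstrap integers drawn
  uniformly from 50–100.  These carry no mechanistic signal — they
  exist so the information-content machinery runs end to end.
* **Truth tables** record per locus the true rate multiplier, planted
  taxa and scale, realized taxon count and missingness, and the true
  tree length and mean edge length, enabling parameter-recovery tests.

The returned trees are the *true* trees — gene-tree inference is out
of scope — so statistics that would use inferred ML trees on real data
are exercised on truth here.  Consequences: passing tests demonstrate
that the statistics recover what they are defined to measure, not that
they are robust to gene-tree estimation error; and the simulated
bootstrap values cannot validate any claim about information content
beyond plumbing.  The generator also omits indels, among-site rate
variation, compositional heterogeneity and empirical exchangeabilities
— the recoding module transforms data but nothing in the generator
creates the compositional bias recoding exists to absorb.

## Problem sizes

The default test suite validates identities on 1,000 random trees
(LB zero-mean), 200 trees (patristic vs graph-path oracle), 500 random
regressions (OLS closed form), and recovers parameters on a 300-locus,
20-taxon collection.  The acceptance script runs the full pipeline on
1080 loci over 36 taxa with four focal taxa and a quarter of loci
long-branch-prone, plus a 200-locus single-plant collection — the scale
of the study design it mirrors, chosen so a complete run stays in the
tens of seconds on one core.

## Known limitations

* The rate proxy conflates taxon sampling with rate when loci differ
  strongly in occupancy.
* KDE mode estimation on strongly bimodal pooled LB distributions
  selects the denser cluster; with clusters of near-equal density the
  mode can flip between them under small perturbations.
* Support-scale autodetection is heuristic for files whose supports
  are all exactly 1 or 100.
* Relaxed PHYLIP output is sequential one-line-per-taxon; interleaved
  PHYLIP and NEXUS are not supported.
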