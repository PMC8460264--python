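# Methods

This note documents the models and procedures implemented in `riboevo`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinates, sequences, and mutation notation

All positions are 1-based and inclusive, following the standard nucleotide
numbering of the 52-2 polymerase ribozyme lineage. Sequences are validated
RNA over {A, C, G, U}; DNA-alphabet input (sequencing reads of RNA
products) is upcased and T→U converted silently. Reads containing
ambiguity codes (N, R, Y, …) are dropped with a logged count — the
analyses operate on called bases only, and no downstream statistic is
defined for partial calls.

Mutations are written `C12G` (substitution), `del17A` (deletion), and
`ins88_89:CA` (insertion of CA between positions 88 and 89). Insertions
are anchored to the reference position they *follow*; this anchor
convention is stated in output headers wherever junction counts appear.

## Read-to-template alignment

Product reads are aligned to the reference template with a semi-global
dynamic program: match +1, mismatch −1, gap −2 (linear), with 3′-terminal
reference gaps free. The free 3′ end encodes the biology of primer
extension — products are 5′-anchored at the primer, so a short read is a
*truncation* (uncovered template, contributing nothing to coverage), not a
run of deletions. This is the simplest scoring that separates partial-
from full-length products.

Determinism is guaranteed by a lexicographic objective rather than a
traceback convention alone: the DP maximizes `score·K − gap_columns` with
`K` larger than any possible gap count, so among equal-scoring alignments
the one with the fewest gap columns (i.e. mismatches over indel pairs)
always wins; remaining ties resolve to the left-most gap placement, and
the alignment ends at the smallest reference position achieving the
optimum (trailing ambiguity resolves to truncation). The kernel is JIT-
compiled with numba; tests check score equality against an independent
exhaustive-search oracle on thousands of short sequence pairs.

**Known limitation — high error rates.** A maximum-score aligner will
occasionally reinterpret clustered substitutions as a higher-scoring
shifted alignment containing an indel pair. At the error rates the
polymerase exhibits when copying the hammerhead (5.6–8.3% per position)
this biases the fidelity estimate upward by less than 0.05 percentage
points, below sampling noise at the read depths used. At ~16% per-position
error (ligase-synthesis conditions) the bias reaches ~0.2 percentage
points and exceeds 3 binomial standard errors at n = 50,000 reads; a
characterization test pins this bound. Any aligner with this scoring
shares the behavior; quality-aware or probabilistic alignment is out of
scope.

## Fidelity tables and summaries

Aligned columns accumulate into a per-position table (coverage, matches,
mismatches keyed by incorporated base, deletions; conservation
`matches + mismatches + deletions = coverage` is asserted on every tally).
Insertions accumulate on junctions and are excluded from the positional
denominator; the headline *average fidelity per nucleotide position* is
total matches over total covered positions (coverage-weighted — stable
when partial-length products are included). Alternatives are exposed as
flags: `--fidelity-mode=with-insertions` folds inserted bases into the
error numerator, and `--per-position-mean` averages per-position
fidelities unweighted. For ligase-style analyses `--full-length-only`
keeps only reads whose alignment reaches the final reference position.

The mutation spectrum divides each template→incorporated count by the
total coverage of positions carrying that template base; the
`wobble_fraction` is the share of all mismatches attributable to G•U
wobble templating (template U read as G, template G read as U).
Levenshtein distances are unit-cost edit distances (computed with edlib)
of each read from the reference, histogrammed; they are computed on the
product region as aligned — whether primer-derived bases should be
included is not specified by any convention we know of, so they are not.

## Population tracking

Per round: reads longer than 150 nt with mean Phred above 33 are kept
(both strict inequalities; a per-base minimum reading is available as
`--phred-mode=min`, but at Q33 it would discard essentially everything,
so the mean reading is the default). Each read is aligned to the
reference and trimmed to the region spanning the P7 and P8 stems
(nucleotides 9–17 and 83–95): bases aligned within the intervals are
concatenated, insertions anchored strictly inside an interval are kept,
deletions shorten the key, and reads that do not span the whole region
are discarded with a logged count. This reference-anchored projection
replaces a multiple-alignment-plus-manual-trimming step; for extracting a
fixed region the two are equivalent, and the projection needs no external
tools.

Keys are clustered greedily at 100% identity with terminal slack
(cd-hit-est `-c 1.0 -U 2 -S 2` semantics): a key joins a cluster iff one
of key/representative is a contiguous substring of the other and their
lengths differ by at most 2. Keys are processed in descending abundance
(ties lexicographic) — abundance order is more stable than length order
for fixed-length keys and makes the representative the most abundant
member by construction. Cross-round identity uses the same join rule on
representatives.

Clusters are merged as the same biological variant when their
representatives differ only by (a) the length of the A run at the 17/18
junction between the region's two strands (the aligner left-shifts indels
within a homopolymer, so any placement within the reference A run is
accepted), or (b) a single substitution at one position outside the
conserved core (11–16 and 84–89).

Retention: clusters exceeding 1% frequency in at least one round are kept,
except clusters observed in exactly one round that never reach 5%.
Cluster ids are `<round>.<rank>`: the first round of >1% appearance, then
abundance rank within that round. The per-round retained fraction (reads
covered by kept clusters) is reported. Before retention filtering,
cluster frequencies sum to 1 in every round.

For strand covariation, each representative key is split at its recorded
interval boundary into 5′- and 3′-strand variants; frequencies of clusters
sharing a strand variant are summed and paired trajectories are correlated
(Pearson, across rounds; reported as NaN for zero-variance trajectories).

## Structure models, covariation, and probing

Structure models are declarative data (`data/structure_models.json`), not
predictions: the *old* model has the distal P7 pairs (80,89), (81,88),
(82,87) and single-stranded J1/3; the *pseudoknot* model has the P8 stem
(11,89), (12,88), (13,87), (14,86), (15,85), (16,84) plus the shared
proximal P7 stem (73–78 paired with 91–96). Pair registers are editable in
the data file without code changes.

Pairs classify as Watson–Crick {AU, UA, GC, CG}, wobble {GU, UG}, or
unpaired. `validate_stem` counts Watson–Crick pairs of a stem in any
sequence variant. The covariation constructs for a putative pair
transvert each base to its complement (C→G, G→C, A→U, U→A), so the
combined double mutation swaps the pair and restores complementarity. A
pair's verdict from relative activities: informative only if both single
mutants fall below wt/50; then `covariation_supported` if the double
restores ≥50% of reference activity, `partially_restored` above 10%,
`not_restored` otherwise.

In-line probing lanes are background-corrected
(`max(raw − background, 0)`; over-subtraction clamps to zero) and scaled
to the position with the highest corrected cleavage within the region of
interest; an all-zero region normalizes to zeros with a warning.
Structure concordance is the point-biserial correlation between model
pairedness (1 = in a stem pair) and protection (1 − normalized cleavage)
over the region — a deliberately simple proxy with no mechanistic
flexibility model; it is antisymmetric under complementing the pairedness
vector.

## Kinetics

Burst-exponential fits use bounded least squares
(`scipy.optimize.least_squares`) on `F(t) = A_b + A_s·(1 − e^(−k_obs·t))`
with all parameters ≥ 0 and `A_b + A_s ≤ 1.1`. Initialization: `A_b` from
the earliest observation, `A_s` from the rise to the final observation,
`k_obs = ln 2 / t_half` from the interpolated half-rise, multi-started
over `k_obs × {0.1, 1, 10}` to escape flat regions; with tight tolerances
this recovers noiseless generating parameters to better than 1e−6
relative error and makes the fit deterministic. Fixing the burst at zero
reduces the model to a plain exponential (nested-model consistency is
tested). Time units (s, min, hr) are explicit on every time course and
converted to an internal canonical scale of minutes; initial rates are
reported per minute and ligation rates per hour. The linear-fit window is
an explicit argument defaulting to the full range. Fold rate
accelerations require both rates in the same unit and round to a chosen
number of significant figures (default 2).

Burst amplitude reporting: "fraction extended within the first seconds"
can mean the fitted `A_b` or the model value at a chosen early time;
both readouts are exposed (`KineticFit.burst_amplitude` and
`KineticFit.value_at`).

## Synthetic data: what it emulates, what it does not

All generators take explicit seeds and are bit-for-bit reproducible.

* `simulate_products` draws reads independently: per template position a
  deletion (rate `del_rate`), otherwise a substitution (rate `sub_rate`,
  base from `sub_matrix` — uniform over the three mismatches by default,
  or wobble-biased via `ErrorModel.with_wobble_bias`); per junction an
  insertion (`ins_rate`); synthesis stops geometrically (`truncation`).
  Qualities are constant Q40, since nothing downstream is quality-aware
  beyond the filter. Not modeled: PCR bias, chimeras, sequencer-specific
  error profiles, condition-dependent length ladders.
* `simulate_rounds` applies a deterministic selection update
  (p′ᵢ ∝ pᵢ·wᵢ), moves a fraction `mut_rate` of each lineage uniformly
  onto the other listed genotypes (a closed genotype set — no de novo
  variants), and samples reads multinomially (or by largest-remainder
  rounding in infinite-population mode). Genotypes are full-length
  sequences rather than bare region keys, so simulated reads exercise the
  same filter→align→extract path as real data; embedding indel-bearing
  keys into a backbone would otherwise be ambiguous.
* `simulate_probing` sets per-position flexibility from a structure model
  (`flex_paired` vs `flex_unpaired`, with per-position overrides such as a
  hyperflexible unpaired linker), scales linearly with incubation time,
  and applies multiplicative lognormal noise of a given CV over a constant
  background.
* `simulate_timecourse` evaluates a kinetic model and adds Gaussian noise,
  clipping fraction data to [0, 1].

Fixtures are synthetic: a 33-nt hammerhead-like target, a 122-nt
ligase-like reference, and a 182-nt polymerase-like reference that
satisfies the structural constraints the analyses rely on (six
Watson–Crick P8 pairs, an A at position 17, an unpaired A90 linker, the
proximal P7 stem paired, the old distal P7 pairing broken). They make the
pipeline runnable and testable; they are not the laboratory sequences,
and passing tests demonstrates correct computation on data with known
truth, not agreement with any particular experiment.

## Problem sizes used in tests and the acceptance script

Fidelity recovery runs at 50,000 reads of the 33-nt fixture (binomial SE
on the fidelity ≈ 0.02 percentage points); population tracking at 14
rounds × 10,000 reads with 6 genotypes plus planted single-round
edge-case clusters at 4% and 6%; kinetic noise robustness at 200
replicates of σ = 0.01; probing concordance at 100 seeded replicates.
These sizes give comfortable statistical margins for every 3-SE check
while keeping a full run to seconds.
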