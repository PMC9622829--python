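# Methods

This note documents the models and procedures implemented in `huntdiv`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Data model

The atomic observation is a *dash*: one attack pass, with a timestamp
(seconds from the start of the recording) and a capture flag. A *dash
sequence* is a maximal run of consecutive dashes by the same individual. It
is defined purely by interruption — a different individual attacking — never
by elapsed time; an optional `max_gap_s` splitter exists but is off by
default. Event logs are delimited text with header `time_s,individual,capture`
(capture 0/1); events are stably sorted by time so coincident video
frame-times keep file order. Sequence indices are 0-based with inclusive
endpoints. Truncating a hunt at a cutoff keeps events with `time_s <= cutoff`
and re-derives sequences, so a sequence straddling the cutoff is cut at its
last retained dash.

## Arrival-subgroup segmentation

For the ordered first appearances m_1..m_M, the gap statistic is
r_i = d_i / i, where d_i counts dash sequences strictly between the first
sequences of m_i and m_{i+1} (both boundary sequences excluded — "between"
is read exclusively, and the rule is self-consistent under this choice).
m_{i+1} founds a new subgroup iff r_i ≥ h and r_{i+1} ≤ min(1, r_i), with
ties at h founding. Two guards enforce the method's minimum subgroup size of
2: the last appearer never founds, and a founding that would leave the
current group with a single member is suppressed (this matters only in
degenerate cases, e.g. the second appearer founding, or thresholds h ≤ 1).
The segmentation is a heuristic with no single correct h; analyses carry a
threshold grid forward, and group counts are non-increasing in h.

## Equal-access null model

The null hypothesis is that every individual present at the school has the
same chance of performing the next dash. Presence starts at the first attack
of an individual's subgroup and is assumed to last until the end of the hunt
(no early departures are modelled). Opportunities are the observed dashes
themselves, so in an epoch with n present individuals and D dashes each
present individual expects D/n dashes and expectations conserve the observed
total exactly. Percentile bands (2.5/97.5, nearest-rank) come from
simulating each dash as a uniform draw among those present — per epoch, a
symmetric multinomial, which is how it is sampled. For a newly arrived
subgroup the display statistic is the mean dash count per member during the
epoch between its arrival and the next subgroup's; the group total under the
null is Binomial(D, m/n), the exact marginal of that multinomial. The first
epoch's group matches its expectation identically because its members are
the only ones present.

## Sequence-length statistics

Lengths are modelled as Geometric on {1, 2, ...}; the MLE of the
termination probability is p̂ = 1/mean. Because every sequence contributes
exactly one terminating dash, the per-stratum proportion
(sequences / dashes) estimates p, and a time trend in p is tested with the
Cochran–Armitage trend chi-square (scores 1..K, df 1). If the termination
proportion has no variation at all (every dash terminates), the statistic is
defined as 0. Strata partition the *ordered dash-sequence list* into K
blocks of near-equal sequence counts (sizes differ by at most 1); an
alternative partition at near-equal cumulative dash counts is available via
`unit="dashes"`. K defaults to 4, matching quartering a full-length
recording; thirds are appropriate for shorter hunts.

Inter-individual differences in mean sequence length are tested by
permutation: lengths are shuffled among sequence slots *within each
stratum*, keeping each individual's number of sequences and the overall
time profile fixed. The statistic is the sample variance (n−1 denominator)
of per-individual mean lengths over individuals with at least 5 sequences
(fewer make the mean unstable). p-values use the add-one convention
(b+1)/(m+1) and are therefore never zero and slightly conservative.

## Attack-order statistics

On the identity order of dash sequences, an ABA pattern is a triple
(j, j+1, j+2) with the same individual at j and j+2 and a different one at
j+1; overlapping triples all count. The return-gap histogram generalizes
this: for each consecutive pair of one individual's sequences, the number of
intervening sequences (ABA = gap 1), with gaps ≥ 40 pooled. The null
shuffles identity labels uniformly within each arrival epoch, preserving
per-individual counts per epoch and presence constraints. Permuted orders
may contain adjacent equal labels; they are retained slot-for-slot rather
than re-merged, because re-merging would change the slot count and break
count conservation. Such artifacts land in a dedicated gap-0 bin so that
every replicate's histogram sums to Σ(nᵢ−1). The ABA test is upper-tailed
with add-one correction.

## Prey division

Individuals are ranked by descending dash-sequence count (ties broken by
descending captures, then ID, for determinism); the share curve accumulates
capture percentages along this ranking, and the headline statistic is the
share of captures taken by the ⌈N/2⌉ most frequent attackers. Uniformity of
attack counts within a subgroup uses Pearson's chi-square against equal
expectations (a flag marks expected counts below 5); attack–capture
association uses tie-corrected Spearman correlation. Capture efficiencies
(captures / dashes per individual) are tested with a Monte-Carlo Fisher
exact test on the 2×N table: conditional on margins the capture row is
multivariate hypergeometric; sampled tables are compared to the observed
table's probability with a 1e-7 relative tolerance for floating-point ties,
and degenerate margins (no captures, or nothing but captures) return p = 1
with a flag. The captures-per-minute series uses 60-s bins; all bins,
including a trailing partial bin with its raw count, enter the OLS trend
regression with df = (1, n_bins − 2), and the partial bin's coverage
fraction is reported so summaries can rescale it.

## Synthetic hunts

The generator emulates: staggered subgroup arrivals (arrival times per
group), attacker selection among present individuals proportional to
per-individual motivation weights, geometric sequence lengths with a
per-stratum termination probability (an increasing sequence plants a time
trend), exponential inter-dash intervals, independent per-dash captures, and
a fixed recording duration. The immediately preceding attacker is excluded
from the next draw, which enforces the no-adjacent-repeat property every
observed sequence log has; with a lone present individual the exclusion is
relaxed and flagged. A side effect of the exclusion is a mild genuine ABA
excess in generated hunts relative to the slot-shuffling null (the just-
interrupted individual is again eligible two slots later with probability
1/(n−1) rather than ≈1/n), so equal-weight hunts are *not* draws from the
attack-order null — which is why ABA calibration samples observed orders
from the permutation scheme itself. Defaults mirror the scale of the longer recorded hunt:
34 individuals in three waves (14/11/9) arriving at 0/900/1800 s over
2789 s, mean inter-dash interval 3.9 s, termination probabilities
(0.33, 0.40, 0.46, 0.52) across quarters (overall mean ≈ 0.42, i.e. mean
sequence length ≈ 2.4), and capture probability 0.155 per dash — chosen so
a default hunt yields ≈ 700 dashes, ≈ 300 sequences and ≈ 110 captures.

What the generator does *not* emulate: spatial predator–prey dynamics, prey
depletion feeding back on capture probability, early departures,
within-sequence behavioural correlation, or observation error. Passing
calibration tests therefore shows the statistics behave correctly under the
stated stochastic structure, not that real hunts satisfy that structure.

A consequence worth stating explicitly: the equal-access null treats dashes
as independent opportunities, so its calibration is evaluated on hunts
generated with termination probability 1 (each sequence one dash), which is
exactly the null's exchangeability structure. Hunts with clustered
sequences have over-dispersed per-individual dash counts relative to that
null — by design, since the clustering is what the other tests measure.
Calibration of the variance permutation test uses a single shared geometric
p (its null), and calibration of the ABA test draws observed orders from
the within-epoch permutation scheme itself.

## Numerical choices

- All Monte-Carlo routines take an explicit seed and record it with the
  replicate count in their result objects; identical seeds give identical
  results.
- Percentiles are nearest-rank (inverted CDF), so bands are achievable
  values of the discrete null statistic.
- Permutation/Monte-Carlo p-values use (b+1)/(m+1).
- Variances use the n−1 denominator.
- Default replicates: 10⁶ for access bands, 10⁴ for permutation and
  efficiency tests; the pipeline's `--fast` flag scales all of them down
  100× for smoke runs.
- Weight is computed once from the mean EFL, not averaged over per-frame
  weights, matching how the allometric endpoints round-trip to 1 d.p.

## Problem sizes in the test suite and acceptance script

Tests generate their data at runtime. The calibration studies use 200 null
hunts for access-band coverage (three waves of 8/7/6), 500 for the variance
test's type-I error, and 200 for ABA p-value uniformity (two waves of 5,
~600 sequences each, 1999 permutations); oracle-equivalence checks run 1000
randomized small instances per statistic; parameter recovery uses one
~10⁴-sequence hunt for the geometric MLE and 100 hunts each for wave
recovery and motivation detection. `scripts/acceptance.py` analyses one
default-scale hunt with 10⁵ access replicates and 10⁴ permutation
replicates. These sizes keep every estimate's Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The segmentation heuristic is sensitive to stragglers: a wave member that
  first attacks shortly before the next wave arrives shrinks the boundary
  gap statistic and can merge two true waves at any threshold.
- The variance permutation statistic depends on the chosen stratification;
  reported values should state K and the partition unit.
- The trend test's dash-count partition assigns whole sequences to strata by
  their first dash, so stratum dash counts are only approximately equal.
- With very small subgroups the chi-square uniformity test's asymptotics are
  poor (flagged), and the Spearman p-value is unreliable below ~9 members.
- The capture-rate regression keeps a trailing partial bin; its raw count
  slightly biases the last design point low.
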