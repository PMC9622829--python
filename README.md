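# huntdiv

Event-sequence analysis of how a shared prey resource is divided among
individually identified group-hunting predators.

The motivating system is striped marlin (*Kajikia audax*) hunting schooling
fish: a group surrounds the school, but individuals attack one at a time in
high-speed passes ("dashes"). A **dash sequence** — a maximal run of
consecutive dashes by one individual, ended the moment another individual
attacks — is the unit of turn-taking. From a time-stamped log of dashes
(time, individual, capture flag), `huntdiv` quantifies who got access to the
prey, who captured it, and whether the observed turn order is compatible
with everyone having an equal chance.

## What it computes

- **Arrival subgroups.** Predator groups in the open ocean have fluid
  membership; individuals join the hunt in waves. For consecutive first
  appearances (m_i, m_{i+1}), the gap statistic d_i/i counts the dash
  sequences between the two appearances, normalized by the i individuals
  already present (under equal access a newcomer waits ~i sequences).
  m_{i+1} founds a new subgroup when d_i/i ≥ h and
  d_{i+1}/(i+1) ≤ min(1, d_i/i); minimum subgroup size is 2. The threshold
  h is carried as a grid, not auto-selected.
- **Equal-access null model.** Every individual present at the school is
  equally likely to perform the next dash; individuals are present from the
  first attack of their subgroup. Expected dashes per individual in an
  epoch with n present and D dashes is D/n (conserving the observed total),
  with 2.5th/97.5th percentile bands from a multinomial Monte-Carlo
  simulation. Newly arrived subgroups are scored on the epoch between their
  own arrival and the next.
- **Sequence-length model.** Lengths follow a geometric distribution with
  termination probability p (MLE p̂ = 1/mean); a Cochran–Armitage trend
  test detects drift in p across strata of the hunt; a stratified
  permutation test (lengths shuffled within strata, identities fixed) tests
  inter-individual differences in mean sequence length via the variance of
  per-individual means.
- **Attack order.** ABA patterns (individual A returns immediately after a
  single interruption by B) and the full return-gap histogram, tested
  against a null that shuffles identities within each arrival epoch.
- **Prey division.** Cumulative capture-share (Lorenz-style) curves against
  attack-frequency rank, the share of the top 50% of attackers, chi-squared
  uniformity tests of attack counts, Spearman correlation of attacks vs
  captures, a Monte-Carlo Fisher exact test on capture efficiencies, and
  the captures-per-minute series with a linear trend F test.
- **Morphometrics.** Pixel lengths calibrated by a same-frame reference to
  eye-fork length (EFL, cm), converted to weight by the allometric power
  law W = 1.33263·10⁻⁶ · EFL^3.41344 (kg).
- **Synthetic hunts.** A generator with known ground truth (staggered
  arrival waves, per-individual motivation weights, geometric sequence
  lengths with an optional time trend, per-dash capture probability) so the
  whole pipeline is testable without field data.

## Worked example

```python
from huntdiv import (HuntConfig, generate_hunt, summarize, segment_hunt,
                     identity_order, aba_permutation_test, tally, top_share,
                     true_group_assignment)

hunt, truth = generate_hunt(HuntConfig(seed=1))   # 2018-scale synthetic hunt
print(summarize(hunt))
groups = true_group_assignment(hunt, truth)
aba = aba_permutation_test(identity_order(hunt), groups, replicates=10_000, seed=1)
print(aba.observed, round(aba.null_mean, 1), aba.p_value)
print(round(top_share(tally(hunt, groups), 0.5), 1))
```

prints

```
HuntSummary(n_individuals=34, n_dashes=691, n_sequences=296, n_captures=104,
            mean_sequence_length=2.3344594594594597, ...)
25.0 12.0 0.0004
79.8
```

i.e. this hunt has 691 dashes in 296 sequences (mean turn length 2.33
dashes); 25 ABA returns were observed against a null mean of ~12, an excess
with permutation p = 0.0004; and the 50% most frequently attacking
individuals took 79.8% of the captures.

The same analyses run from the shell:

```sh
huntdiv simulate --seed 1 --out hunt.csv --truth-out truth.json
huntdiv segment hunt.csv --threshold-grid 1.0,1.5,2.0,3.0
huntdiv all hunt.csv --seed 1 --fast --skip-morphometrics --out report.json
```

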