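# Methods

## The experimental designs and their scoring

Four objects are selectable; exactly one (the metal strip) is the
trained exchangeable *target*, the rest are distractors. Trials come in
two designs.

**Forced one-item selection.** One tray presentation per trial; the
subject touches or grabs one item, or refuses. After a delay, at a
different location, a human requests the item. Scoring per trial list:

- *correct selection* — the selected item is the target; refusals stay
  in the denominator (they are failures to select the target);
- *correct exchange* — the target is handed over at the exchange;
- *incorrect exchange* — something other than the target was involved
  at the exchange: a wrong item, a foreign object (the `OTHER` sentinel,
  annotated in the trial note), or a failure to deliver the selected
  target. The bundled records encode exactly the published per-subject
  totals under this rule;
- *complete behavioral sequence* — target selected **and** exchanged in
  the same trial (selection, transportation, exchange).

**Free multi-item selection.** The subject may enter a baited
compartment and remove any subset of items; no human is present during
selection. Additional per-trial fields: `entered`, the `removed` set,
`first_touch`. Scoring adds:

- *entered* trials and the *k-profile*: the removal counts
  `k_t = |removed_t| ≥ 1` of entered trials, in trial order;
- *correct behavior* (joint rule) — an entered trial is correct when
  the target was offered, or when the target had not been removed and
  nothing was offered (refusing to trade junk is correct behavior);
- *incorrect selections* — counted as the total number of distractor
  items removed. One published overview cell (the male orangutan's
  free-design incorrect selections) prints 1 where this rule gives 2
  (he removed two distractors in his single failed trial); no single
  counting rule reproduces every published cell, the replication report
  carries a note on that cell, and no statistic consumes the number.

## Null models

**Forced design (chance level 1/4).** With `m = 4` equally available
items the conservative per-trial chance of success is `1/m`. All tests
are one-tailed upper tails `P(X ≥ x)`, `X ~ Bin(n, 1/m)` — the question
is always whether the subject performed *above* chance. The tail is
accumulated in exact rational arithmetic (the float chance value is an
exact binary rational), so the result is correctly rounded; above
n = 200 a log-space summation takes over (absolute error ≪ 1e-12).
Exchange *accuracy* (correct exchanges / trials with the target in
hand) is reported as a proportion; a binomial tail for it is available
but flagged interpretation-dependent, since no principled chance level
exists for the exchange alone.

**Free design, selection.** Conditioning on the observed k-profile, the
chance agent draws `k_t` of the `m` items uniformly without replacement
in trial `t`, so the target is included with probability `k_t/m`,
independently across trials. The retrieval count is Poisson-binomial;
its distribution is computed by iterative convolution (dynamic
programming over the count, O(n²) float64, verified against 2ⁿ
enumeration to 1e-12). The Monte Carlo route — the construction used in
the original analysis — simulates 50,000 replicate profiles and reports
the plain proportion of replicates reaching the observed count (an
optional `(b+1)/(n+1)` estimator is available by flag but non-default,
because the plain proportion is what reproduces the published 0.094).

**Free design, joint selection-and-exchange.** The chance agent removes
`k_t` random items and then offers exactly one of them, uniformly at
random; it never refuses. A trial is jointly correct iff the target is
offered (when the target was not removed, the agent offers a distractor,
which is incorrect), giving per-trial probability
`(k_t/m)·(1/k_t) = 1/m` exactly — the exact tail is `Bin(n, 1/m)`. The
agent's exchange behavior is not pinned down by the published
description; the always-offer policy was chosen as the simplest chance
agent, and it reproduces every reproducible published bound. A
configurable alternative (`offer_or_refuse`: `k_t + 1` equally likely
options, per-trial correct probability `1/(k_t+1)`) is provided but
non-default. The Monte Carlo branch simulates the mechanism (inclusion
draw, then offer draw) rather than the collapsed probability, so it
remains a genuine cross-check of the exact branch.

Defaults: `n_sims = 50,000`, documented default seed 1729; every
randomized entry point takes an explicit seed and is reproducible.

## Fixture reconstruction

The bundled records carry the complete published trial-by-trial
outcomes. Details that are *not* statistic-bearing and were not printed
are reconstructed deterministically and annotated in the trial notes:
the ordering of preference-test trials, the identities of incorrectly
selected distractors in the forced design, and the placement of
first-touch exceptions. One chimpanzee's free-design exchange outcomes
are known only in aggregate (6 correct of 12); her per-trial `offered`
is `UNKNOWN` and the totals live in record-level metadata (`aggregates`
in JSON, a `#meta` comment line in CSV) — scoring consumes the
aggregate, never an invented per-trial assignment. One orangutan's
forced-design trial with an "unclear selection" is encoded as an
incorrect selection, matching the published 11-of-14 denominator.

## Known non-reproducible published values

Two printed results cannot be derived from the stated rules, at any
simulation size; both are computed, reported, and flagged
`NOT_REPRODUCED` (never silently matched):

1. *Free-design complete sequences, first chimpanzee* — published
   p = 0.11 for 6 of 12 at chance 1/4; the one-tailed exact upper tail
   is 0.0544 (a symmetric two-sided construction gives ≈ 0.086; neither
   yields 0.11).
2. *Joint behavior, first chimpanzee* — published p < 0.001, but under
   the stated correct-behavior rule she scores 6 of 12 (she refused to
   trade in 6 trials while holding the target, which the rule counts as
   incorrect), giving 0.0544 under the chance agent.

## Synthetic subjects

A generative subject has item-preference weights (selection
proportional to weight; multi-item removal by successive draws
proportional to the remaining weights), a refusal propensity (refusing
to select / not entering), a distribution over removal counts 1..m, and
an exchange policy: probability `exchange_fidelity` of offering the
target when held and `spurious_offer_prob` of offering a random held
distractor otherwise. With uniform weights, `k ≡ 1`, fidelity 1 and
spurious-offer 1, the subject *is* the chance agent of every null
above, which is what the type-I error checks exploit (exact discrete
tests are conservative, so empirical rejection at nominal α stays at or
below α within Monte Carlo error). The generator does not model
learning or motivation drift across trials, session effects, or social
context — passing tests show the statistics are correct for the stated
generative model, not that real subjects satisfy it.

Rejection-rate estimation (`estimate_rejection_rate`) runs the full
score-then-test path per replicate; the suite uses 2,000 replicates for
type-I checks and a few hundred for power-style checks, sizes at which
the binomial standard error (≈ 0.005 at α = 0.05) is small relative to
every margin asserted.

## Numerical notes and edge cases

- Empty trial lists are rejected by the scorers; an empty k-profile
  (a subject who never entered) defines no conditional test and the
  pipeline reports counts with a note instead.
- `P(X ≥ 0)` is 1 by convention; observed counts beyond the number of
  profile trials are argument errors.
- Poisson-binomial convolution is float64; its error against exact
  enumeration is bounded well below 1e-12 at the n ≤ 14 scales of these
  designs.
- JSON output is canonical (sorted keys, fixed indent), so
  write → read → write is byte-identical.
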