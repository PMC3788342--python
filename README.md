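# apexchange

Scoring rules, exact binomial tests and conditional chance models for
**deferred token-exchange experiments** in great apes.

In a deferred-exchange task an ape first selects among four objects —
one of which (a metal strip) has been trained as exchangeable for food —
and only later, at a different location and after a delay, gets the
opportunity to hand an object to a human in exchange for a reward. The
package analyses the two standard designs:

* **Forced one-item selection** — the subject picks exactly one item
  from a tray (or refuses). With four equally available items the
  per-trial chance of picking the target is 1/4, and the number of
  correct selections (or of *complete behavioral sequences*: select,
  transport and exchange the target) is tested with the exact one-tailed
  binomial tail `P(X ≥ x), X ~ Bin(n, 1/4)`.
* **Free multi-item selection** — the subject may remove any subset of
  the four items from a baited compartment, so a standard binomial does
  not apply. Conditioning on the observed per-trial removal counts
  `k_1, …, k_n` (the *k-profile*), a chance-acting subject includes the
  target in trial *t* with probability `k_t/4`; the number of target
  retrievals is Poisson-binomial and its exact upper tail (or a
  50,000-replicate Monte Carlo estimate of it) is the selection p-value.
  A second null extends the chance agent to the exchange: it offers one
  of its `k_t` items uniformly at random, making each trial "correct"
  (target exchanged, or nothing offered when the target was not taken)
  with probability exactly `(k_t/4)·(1/k_t) = 1/4`, so the joint
  selection-and-exchange tail reduces to `Bin(n, 1/4)`.

The trial-by-trial records of the four study subjects (two chimpanzees,
two orangutans) are bundled as plain-text fixtures (JSON and CSV), and a
synthetic-subject generator (preference weights, refusal propensity,
removal-count law, exchange policy) makes every stage testable
end-to-end, including type-I error and power of each test.

## Worked example

```python
>>> from apexchange import (load_records, score_free, FreeSelectionNull,
...                         selection_pvalue_free, joint_behavior_pvalue)
>>> from apexchange.fixtures import load_fixture_records
>>> rec = {r.name: r for r in load_fixture_records()}["Maria-Magdalena"]
>>> trials = rec.experiments["exp2"]
>>> counts = score_free(trials)
>>> counts.n_correct_selections, counts.n_correct_behaviors
(7, 12)
>>> null = FreeSelectionNull.from_trials(trials)
>>> null.k_profile
(4, 2, 1, 1, 1, 1, 1, 2, 1, 2, 1, 1)
>>> round(selection_pvalue_free(null, 7).p_value, 4)
0.0936
>>> joint_behavior_pvalue(null, 12).p_value
5.960464477539063e-08
```

She retrieved the target in 7 of her 12 trials, which is *not* above
chance once her multi-item removals are conditioned on (p ≈ 0.094), yet
her behavior was jointly correct — exchange the target when held, refuse
otherwise — in all 12 trials, which is far beyond what the chance agent
produces (p ≈ 6×10⁻⁸). The dissociation between the two nulls is the
analytical heart of the package.

The whole published analysis, with the overview table of counts and
every test, is one command:

```sh
apexchange replicate                 # markdown report to stdout
apexchange replicate --method mc --n-sims 50000 --seed 7 --format json
```

Two published values are documented as **NOT_REPRODUCED** (one
chimpanzee's free-design complete-sequence and joint p-values cannot be
derived from the stated scoring rules; the report prints the computed
0.054 for both and flags them rather than matching the published
numbers). `--strict` turns any *other* count mismatch into a non-zero
exit.

Other subcommands: `analyze --trials FILE` for arbitrary CSV/JSON trial
tables, `simulate --params FILE` for synthetic subjects, and `power` for
rejection-rate estimation; see `apexchange --help`.

## Layout

| Module | Contents |
|---|---|
| `apexchange.model` | trial/record types, scoring rules, k-profile, preference tabulation |
| `apexchange.io` | CSV/JSON readers and writers with validation |
| `apexchange.fixtures` | the bundled trial-by-trial records of the four subjects |
| `apexchange.exact_tests` | exact binomial tails and the forced-design tests |
| `apexchange.chance_models` | Poisson-binomial convolution, Monte Carlo nulls |
| `apexchange.synthetic` | generative subject model, power / type-I estimation |
| `apexchange.pipeline`, `apexchange.cli` | replication pipeline, report rendering, CLI |

See `docs/methods.md` for the statistical model, parameter choices and
known limitations.
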