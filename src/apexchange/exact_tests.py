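"""Exact one-tailed binomial tests at the 25% chance convention.

With four equally available items the conservative chance level for
selecting (or exchanging) the target on any one trial is 1/4. Every test
is an upper tail: P(X >= x) for X ~ Binomial(n, chance), asking whether
the subject performed *above* chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction
from typing import Sequence

from .model import ObservedCounts

__all__ = ["TestResult", "binom_upper_tail", "binom_lower_tail",
           "selection_test_forced", "complete_sequence_test",
           "exchange_accuracy", "exchange_test"]

DEFAULT_CHANCE = 0.25

# Above this n the exact rational accumulation gets pointlessly expensive;
# fall back to log-space summation (still well under 1e-12 absolute error).
_EXACT_N_LIMIT = 200


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test: statistic, null, p-value, method."""

    statistic_name: str
    observed: int
    n: int
    null_spec: str
    p_value: float
    method: str = "exact"            # "exact" or "monte_carlo"
    n_sims: int | None = None
    seed: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.observed > self.n:
            raise ValueError("observed count exceeds n")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_args(x: int, n: int, p: float) -> None:
    if n < 0 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p={p} outside [0, 1]")


def binom_upper_tail(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p), by exact summation.

    For moderate n the tail is accumulated in exact rational arithmetic
    (the float argument ``p`` is itself an exact binary rational), so the
    only rounding is the final conversion to float.
    """
    _check_args(x, n, p)
    if x == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    if n <= _EXACT_N_LIMIT:
        pf = Fraction(p)
        qf = 1 - pf
        total = sum(math.comb(n, k) * pf**k * qf**(n - k)
                    for k in range(x, n + 1))
        return float(total)
    logp, logq = math.log(p), math.log1p(-p)
    terms = [math.exp(math.lgamma(n + 1) - math.lgamma(k + 1)
                      - math.lgamma(n - k + 1) + k * logp + (n - k) * logq)
             for k in range(x, n + 1)]
    return min(1.0, math.fsum(terms))


def binom_lower_tail(x: int, n: int, p: float) -> float:
    """P(X <= x); complements :func:`binom_upper_tail` at x+1."""
    _check_args(x, n, p)
    return 1.0 - binom_upper_tail(x + 1, n, p) if x < n else 1.0


def selection_test_forced(counts: ObservedCounts,
                          chance: float = DEFAULT_CHANCE) -> TestResult:
    """Exact upper-tail test of the number of correct (target) selections
    against per-trial chance. Refusal trials stay in the denominator."""
    if counts.n_trials == 0:
        raise ValueError("no trials")
    x, n = counts.n_correct_selections, counts.n_trials
    return TestResult(
        statistic_name="correct_selections", observed=x, n=n,
        null_spec=f"Binomial(n={n}, p={chance}) upper tail",
        p_value=binom_upper_tail(x, n, chance))


def complete_sequence_test(counts: ObservedCounts,
                           chance: float = DEFAULT_CHANCE) -> TestResult:
    """Exact upper-tail test of the number of complete behavioral
    sequences (selection, transportation and exchange of the target) over
    the full experimental trial count."""
    if counts.n_trials == 0:
        raise ValueError("no trials")
    x, n = counts.n_complete_sequences, counts.n_trials
    return TestResult(
        statistic_name="complete_sequences", observed=x, n=n,
        null_spec=f"Binomial(n={n}, p={chance}) upper tail",
        p_value=binom_upper_tail(x, n, chance))


def exchange_accuracy(counts: ObservedCounts) -> float | None:
    """Proportion of correct exchanges among trials where the target was
    available to exchange; None when it never was."""
    if counts.n_target_available == 0:
        return None
    return counts.n_correct_exchanges / counts.n_target_available


def exchange_test(counts: ObservedCounts,
                  chance: float = DEFAULT_CHANCE) -> TestResult:
    """Optional binomial tail on correct exchanges over all trials.

    The appropriate null for an exchange-only test is interpretation
    dependent (the result is flagged as such); accuracy itself is better
    reported as a proportion via :func:`exchange_accuracy`.
    """
    if counts.n_trials == 0:
        raise ValueError("no trials")
    x, n = counts.n_correct_exchanges, counts.n_trials
    return TestResult(
        statistic_name="correct_exchanges", observed=x, n=n,
        null_spec=f"Binomial(n={n}, p={chance}) upper tail",
        p_value=binom_upper_tail(x, n, chance),
        note="interpretation-dependent null")
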