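"""Chance models for free multi-item selection.

When a subject may remove any subset of the ``m`` items, a standard
binomial null no longer applies. Conditioning on the observed number of
items removed per trial (the *k-profile*), a chance-acting subject
includes the target in trial ``t`` with probability ``k_t / m`` (a uniform
draw of ``k_t`` of the ``m`` items without replacement), independently
across trials. The number of target retrievals is then Poisson-binomial
with per-trial probabilities ``k_t / m``; its upper tail is the
free-selection p-value. It is computed exactly by convolution, or by
Monte Carlo (the construction used in the original analysis, 50,000
replicates by default).

A second null extends the chance agent to the exchange: after removing
``k_t`` random items it offers exactly one of them uniformly at random,
so a trial is "correct" (target offered, or nothing offered when the
target was not removed) with probability ``(k_t/m)·(1/k_t) = 1/m``
exactly, and the exact tail reduces to a Binomial(n, 1/m). A non-default
variant lets the agent refuse with the same probability as each held item
(``k_t + 1`` equally likely options, per-trial correct probability
``1/(k_t+1)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exact_tests import TestResult, binom_upper_tail
from .model import FreeSelectionTrial, k_profile

__all__ = ["FreeSelectionNull", "poisson_binomial_pmf",
           "poisson_binomial_upper_tail", "simulate_free_selection",
           "selection_pvalue_free", "joint_behavior_pvalue",
           "null_histogram_tsv"]

DEFAULT_N_SIMS = 50_000
DEFAULT_SEED = 1729  # documented default; every entry point accepts a seed

OFFER_ALWAYS = "always_offer"
OFFER_OR_REFUSE = "offer_or_refuse"


@dataclass(frozen=True)
class FreeSelectionNull:
    """Null specification for free selection: per-trial removal counts and
    the item-universe size."""

    k_profile: tuple[int, ...]
    m: int = 4

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("item universe size m must be >= 2")
        for k in self.k_profile:
            if not 1 <= k <= self.m:
                raise ValueError(f"removal count {k} outside 1..{self.m}")

    @classmethod
    def from_trials(cls, trials: Sequence[FreeSelectionTrial],
                    m: int = 4) -> "FreeSelectionNull":
        return cls(tuple(k_profile(trials)), m=m)

    @property
    def n_trials(self) -> int:
        return len(self.k_profile)

    @property
    def inclusion_probs(self) -> tuple[float, ...]:
        """Per-trial probability that a chance draw includes the target."""
        return tuple(k / self.m for k in self.k_profile)


def _check_probs(probs: Sequence[float]) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1:
        raise ValueError("probs must be a 1-D sequence")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return arr


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Distribution of a sum of independent Bernoulli(p_t) variables,
    by iterative convolution (dynamic programming over the count)."""
    arr = _check_probs(probs)
    dist = np.zeros(arr.size + 1)
    dist[0] = 1.0
    for t, p in enumerate(arr):
        dist[1:t + 2] = dist[1:t + 2] * (1.0 - p) + dist[:t + 1] * p
        dist[0] *= 1.0 - p
    return dist


def poisson_binomial_upper_tail(probs: Sequence[float], x: int) -> float:
    """Exact P(X >= x) for the Poisson-binomial count X."""
    arr = _check_probs(probs)
    if not 0 <= x <= arr.size:
        raise ValueError(f"threshold x={x} outside 0..{arr.size}")
    if x == 0:
        return 1.0
    pmf = poisson_binomial_pmf(arr)
    return float(min(1.0, pmf[x:].sum()))


def simulate_free_selection(null: FreeSelectionNull,
                            rng_seed: int | np.random.Generator,
                            ) -> np.ndarray:
    """One chance replicate: a boolean target-inclusion vector, trial t
    true with probability k_t/m."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    probs = np.asarray(null.inclusion_probs)
    return rng.random(probs.size) < probs


def _simulated_selection_counts(null: FreeSelectionNull, n_sims: int,
                                rng: np.random.Generator) -> np.ndarray:
    probs = np.asarray(null.inclusion_probs)
    return (rng.random((n_sims, probs.size)) < probs).sum(axis=1)


def _mc_pvalue(hits: int, n_sims: int, add_one: bool) -> float:
    if add_one:
        return (hits + 1) / (n_sims + 1)
    return hits / n_sims


def selection_pvalue_free(null: FreeSelectionNull, observed: int,
                          method: str = "exact",
                          n_sims: int = DEFAULT_N_SIMS,
                          seed: int = DEFAULT_SEED,
                          add_one: bool = False) -> TestResult:
    """P-value for retrieving the target in at least ``observed`` trials
    under the uniform without-replacement null."""
    if not 0 <= observed <= null.n_trials:
        raise ValueError(
            f"observed={observed} outside 0..{null.n_trials}")
    null_spec = (f"Poisson-binomial upper tail, inclusion probs k_t/{null.m}, "
                 f"k profile {list(null.k_profile)}")
    if method == "exact":
        p = poisson_binomial_upper_tail(null.inclusion_probs, observed)
        return TestResult("target_retrievals", observed, null.n_trials,
                          null_spec, p, method="exact")
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        counts = _simulated_selection_counts(null, n_sims, rng)
        p = _mc_pvalue(int((counts >= observed).sum()), n_sims, add_one)
        return TestResult("target_retrievals", observed, null.n_trials,
                          null_spec, p, method="monte_carlo",
                          n_sims=n_sims, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def _joint_trial_probs(null: FreeSelectionNull, offer_policy: str,
                       ) -> list[float]:
    if offer_policy == OFFER_ALWAYS:
        # inclusion k/m times uniform offer 1/k
        return [1.0 / null.m] * null.n_trials
    if offer_policy == OFFER_OR_REFUSE:
        # k+1 equally likely options (each held item or refusal); correct is
        # offering the target when held, refusing when not held.
        return [1.0 / (k + 1) for k in null.k_profile]
    raise ValueError(f"unknown offer policy {offer_policy!r}")


def joint_behavior_pvalue(null: FreeSelectionNull, observed_correct: int,
                          method: str = "exact",
                          n_sims: int = DEFAULT_N_SIMS,
                          seed: int = DEFAULT_SEED,
                          offer_policy: str = OFFER_ALWAYS,
                          add_one: bool = False) -> TestResult:
    """P-value for at least ``observed_correct`` jointly correct behaviors
    (exchange the target, or refuse when the target was not removed) under
    the chance agent that removes ``k_t`` random items and then offers one
    of them uniformly at random."""
    if not 0 <= observed_correct <= null.n_trials:
        raise ValueError(
            f"observed_correct={observed_correct} outside 0..{null.n_trials}")
    trial_probs = _joint_trial_probs(null, offer_policy)
    null_spec = (f"chance agent ({offer_policy}): k_t uniform items of "
                 f"{null.m}, one uniform offer; per-trial correct probs "
                 f"{[round(p, 6) for p in trial_probs]}")
    if method == "exact":
        if offer_policy == OFFER_ALWAYS:
            p = binom_upper_tail(observed_correct, null.n_trials,
                                 1.0 / null.m)
        else:
            p = poisson_binomial_upper_tail(trial_probs, observed_correct)
        return TestResult("correct_behaviors", observed_correct,
                          null.n_trials, null_spec, p, method="exact")
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        ks = np.asarray(null.k_profile, dtype=float)
        # Simulate the mechanism, not the collapsed probability: draw the
        # inclusion, then the uniform offer among the k_t held options.
        included = rng.random((n_sims, ks.size)) < ks / null.m
        offer_draw = rng.random((n_sims, ks.size))
        if offer_policy == OFFER_ALWAYS:
            correct = included & (offer_draw < 1.0 / ks)
        else:
            offered_target = included & (offer_draw < 1.0 / (ks + 1.0))
            refused = ~included & (offer_draw < 1.0 / (ks + 1.0))
            correct = offered_target | refused
        counts = correct.sum(axis=1)
        p = _mc_pvalue(int((counts >= observed_correct).sum()), n_sims,
                       add_one)
        return TestResult("correct_behaviors", observed_correct,
                          null.n_trials, null_spec, p, method="monte_carlo",
                          n_sims=n_sims, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def null_histogram_tsv(null: FreeSelectionNull,
                       which: str = "selection",
                       offer_policy: str = OFFER_ALWAYS) -> str:
    """TSV dump of the exact null distribution (count, probability)."""
    if which == "selection":
        pmf = poisson_binomial_pmf(null.inclusion_probs)
    elif which == "joint":
        pmf = poisson_binomial_pmf(_joint_trial_probs(null, offer_policy))
    else:
        raise ValueError(f"unknown distribution {which!r}")
    lines = ["count\tprobability"]
    lines += [f"{i}\t{p:.12g}" for i, p in enumerate(pmf)]
    return "\n".join(lines) + "\n"
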