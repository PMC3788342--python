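"""Generative model of exchange-experiment subjects.

A synthetic subject is parameterised by item-preference weights (selection
is proportional to weight), a refusal propensity (refusing to select in
the forced design, not entering in the free design), a distribution over
the number of items removed per free trial, and an exchange policy: the
probability of offering the target when held (``exchange_fidelity``) and
of offering some non-target item when the target is not held
(``spurious_offer_prob``).

With uniform weights, zero refusal and k fixed at 1, a synthetic subject
realises the chance behavior assumed by every null model in the package,
which is what makes end-to-end type-I error checks possible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .chance_models import (
    FreeSelectionNull,
    joint_behavior_pvalue,
    selection_pvalue_free,
)
from .exact_tests import (
    TestResult,
    complete_sequence_test,
    selection_test_forced,
)
from .model import (
    DEFAULT_UNIVERSE,
    NONE,
    REFUSED,
    ForcedSelectionTrial,
    FreeSelectionTrial,
    ItemUniverse,
    ObservedCounts,
    SubjectRecord,
    score_forced,
    score_free,
)

__all__ = ["SubjectParams", "PowerEstimate", "simulate_subject",
           "estimate_rejection_rate", "TEST_NAMES"]


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one synthetic subject."""

    preference_weights: Mapping[str, float] = field(
        default_factory=lambda: {l: 1.0 for l in DEFAULT_UNIVERSE.labels})
    refusal_prob: float = 0.0
    k_distribution: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)  # over 1..m
    exchange_fidelity: float = 1.0
    spurious_offer_prob: float = 0.0

    def validate(self, universe: ItemUniverse = DEFAULT_UNIVERSE) -> None:
        weights = dict(self.preference_weights)
        if set(weights) != set(universe.labels):
            raise ValueError("preference_weights must cover exactly the "
                             f"item labels {universe.labels}")
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        for name in ("refusal_prob", "exchange_fidelity",
                     "spurious_offer_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        kd = self.k_distribution
        if len(kd) != universe.m:
            raise ValueError(f"k_distribution needs {universe.m} entries "
                             "(counts 1..m)")
        if any(p < 0 for p in kd) or not math.isclose(sum(kd), 1.0,
                                                      abs_tol=1e-9):
            raise ValueError("k_distribution must be a probability vector")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preference_weights"] = dict(self.preference_weights)
        d["k_distribution"] = list(self.k_distribution)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubjectParams":
        return cls(preference_weights=dict(d["preference_weights"]),
                   refusal_prob=float(d.get("refusal_prob", 0.0)),
                   k_distribution=tuple(d.get("k_distribution",
                                              (1.0, 0.0, 0.0, 0.0))),
                   exchange_fidelity=float(d.get("exchange_fidelity", 1.0)),
                   spurious_offer_prob=float(d.get("spurious_offer_prob",
                                                   0.0)))

    @classmethod
    def from_file(cls, path: str | Path) -> "SubjectParams":
        """Read parameters from a YAML or JSON config file."""
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class PowerEstimate:
    """Monte Carlo rejection-rate estimate for one test at one level."""

    alpha: float
    n_reps: int
    rejection_rate: float
    mc_se: float

    def to_dict(self) -> dict:
        return asdict(self)


def _weighted_sample(labels: Sequence[str], weights: np.ndarray, k: int,
                     rng: np.random.Generator) -> list[str]:
    """Successive draws proportional to the remaining weights."""
    pool = list(range(len(labels)))
    w = weights.astype(float).copy()
    out = []
    for _ in range(k):
        probs = w[pool] / w[pool].sum()
        j = rng.choice(len(pool), p=probs)
        out.append(labels[pool.pop(j)])
    return out


def simulate_subject(params: SubjectParams, design: str, n_trials: int,
                     seed: int, universe: ItemUniverse = DEFAULT_UNIVERSE,
                     name: str = "synthetic") -> SubjectRecord:
    """Simulate one subject's trial list; deterministic given ``seed``."""
    params.validate(universe)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(universe.labels)
    weights = np.array([params.preference_weights[l] for l in labels])
    tgt = universe.target
    trials: list = []
    if design == "forced":
        for i in range(1, n_trials + 1):
            if rng.random() < params.refusal_prob:
                trials.append(ForcedSelectionTrial(i, REFUSED, False, NONE))
                continue
            selected = _weighted_sample(labels, weights, 1, rng)[0]
            if selected == tgt:
                offered = tgt if rng.random() < params.exchange_fidelity \
                    else NONE
            else:
                offered = selected \
                    if rng.random() < params.spurious_offer_prob else NONE
            trials.append(ForcedSelectionTrial(i, selected, True, offered))
    elif design == "free":
        ks = np.arange(1, universe.m + 1)
        kd = np.asarray(params.k_distribution)
        for i in range(1, n_trials + 1):
            if rng.random() < params.refusal_prob:
                trials.append(FreeSelectionTrial(i, entered=False))
                continue
            k = int(rng.choice(ks, p=kd))
            removed = _weighted_sample(labels, weights, k, rng)
            if tgt in removed:
                offered = tgt if rng.random() < params.exchange_fidelity \
                    else NONE
            else:
                offered = removed[rng.integers(len(removed))] \
                    if rng.random() < params.spurious_offer_prob else NONE
            trials.append(FreeSelectionTrial(
                i, entered=True, removed=frozenset(removed),
                first_touch=removed[0], offered=offered))
    else:
        raise ValueError(f"unknown design {design!r}")
    record = SubjectRecord(name=name, species="synthetic",
                           experiments={"exp1" if design == "forced"
                                        else "exp2": trials})
    record.validate(universe)
    return record


# ----------------------------------------------------------------- power

def _forced_selection_p(counts: ObservedCounts, trials, m: int) -> float:
    return selection_test_forced(counts, chance=1.0 / m).p_value


def _forced_complete_p(counts: ObservedCounts, trials, m: int) -> float:
    return complete_sequence_test(counts, chance=1.0 / m).p_value


def _free_selection_p(counts: ObservedCounts, trials, m: int) -> float:
    null = FreeSelectionNull.from_trials(trials, m=m)
    if null.n_trials == 0:
        return 1.0
    return selection_pvalue_free(null, counts.n_correct_selections).p_value


def _free_joint_p(counts: ObservedCounts, trials, m: int) -> float:
    null = FreeSelectionNull.from_trials(trials, m=m)
    if null.n_trials == 0:
        return 1.0
    return joint_behavior_pvalue(null, counts.n_correct_behaviors).p_value


def _free_complete_p(counts: ObservedCounts, trials, m: int) -> float:
    return complete_sequence_test(counts, chance=1.0 / m).p_value


TEST_NAMES: dict[str, tuple[str, Callable]] = {
    "forced_selection": ("forced", _forced_selection_p),
    "forced_complete_sequence": ("forced", _forced_complete_p),
    "free_selection": ("free", _free_selection_p),
    "free_joint_behavior": ("free", _free_joint_p),
    "free_complete_sequence": ("free", _free_complete_p),
}


def estimate_rejection_rate(params: SubjectParams, design: str,
                            n_trials: int, test: str, alpha: float,
                            n_reps: int, seed: int,
                            universe: ItemUniverse = DEFAULT_UNIVERSE,
                            ) -> PowerEstimate:
    """Simulate ``n_reps`` subjects, apply scoring and the named test, and
    return the proportion of replicates with p <= alpha.

    Under the chance subject this estimates the type-I error rate; under
    an above-chance subject it estimates power. ``n_reps`` must be >= 1.
    """
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; choose from "
                         f"{sorted(TEST_NAMES)}")
    required_design, pfun = TEST_NAMES[test]
    if design != required_design:
        raise ValueError(f"test {test!r} requires design "
                         f"{required_design!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) \
        % (2**31)
    rejections = 0
    exp = "exp1" if design == "forced" else "exp2"
    for s in child_seeds:
        record = simulate_subject(params, design, n_trials, int(s), universe)
        trials = record.experiments[exp]
        counts = (score_forced(trials, universe) if design == "forced"
                  else score_free(trials, universe))
        if pfun(counts, trials, universe.m) <= alpha:
            rejections += 1
    rate = rejections / n_reps
    return PowerEstimate(alpha=alpha, n_reps=n_reps, rejection_rate=rate,
                         mc_se=math.sqrt(rate * (1 - rate) / n_reps))
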