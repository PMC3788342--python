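"""Domain model for deferred token-exchange experiments.

Two trial designs are represented. In the *forced* design the subject picks
exactly one of ``m`` items from a tray (or refuses), and may later offer an
item back to a human at a delayed, spatially displaced exchange. In the
*free* design the subject may enter a baited compartment and remove any
subset of the items, and may later offer one item at the exchange.

One item in the universe is the *target* (the trained exchangeable token);
the others are distractors. Scoring reduces each trial list to the counts
that feed the statistical tests: correct selections, correct exchanges,
complete behavioral sequences (select the target, transport it, exchange
it), the joint "correct behavior" rule (exchange the target, or refuse to
trade anything when the target was not selected), and first-touch counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

__all__ = [
    "REFUSED",
    "NONE",
    "UNKNOWN",
    "OTHER",
    "ItemUniverse",
    "DEFAULT_UNIVERSE",
    "ForcedSelectionTrial",
    "FreeSelectionTrial",
    "SubjectRecord",
    "ObservedCounts",
    "ModelError",
    "score_forced",
    "score_free",
    "k_profile",
    "tabulate_preferences",
    "meets_learning_criterion",
]

# Sentinels used in trial fields (and verbatim in the CSV/JSON schema).
REFUSED = "REFUSED"   # subject inspected the tray but touched nothing
NONE = "NONE"         # no item offered / nothing touched first
UNKNOWN = "UNKNOWN"   # outcome not recorded per trial (aggregate known)
OTHER = "OTHER"       # a non-target or foreign object was offered (see note)

_OFFER_SENTINELS = frozenset({NONE, UNKNOWN, OTHER})


class ModelError(ValueError):
    """Raised when a trial or record violates a structural invariant."""


@dataclass(frozen=True)
class ItemUniverse:
    """The set of selectable items, exactly one of which is the target."""

    labels: tuple[str, ...] = ("metal", "rope", "wood", "jute")
    target: str = "metal"

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ModelError("item universe needs at least 2 items")
        if len(set(self.labels)) != len(self.labels):
            raise ModelError("duplicate item labels")
        if self.target not in self.labels:
            raise ModelError(f"target {self.target!r} not among labels")

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def distractors(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l != self.target)


DEFAULT_UNIVERSE = ItemUniverse()


@dataclass(frozen=True)
class ForcedSelectionTrial:
    """One tray presentation: a single selection (or refusal) and the
    outcome of the delayed exchange opportunity."""

    index: int
    selected: str            # item label or REFUSED
    arrived: bool            # subject showed up at the exchange location
    offered: str = NONE      # item label, NONE, UNKNOWN, or OTHER
    note: str = ""

    def validate(self, universe: ItemUniverse = DEFAULT_UNIVERSE) -> None:
        if self.index < 1:
            raise ModelError(f"trial index {self.index} must be >= 1")
        if self.selected != REFUSED and self.selected not in universe.labels:
            raise ModelError(
                f"trial {self.index}: unknown selected label {self.selected!r}")
        if self.offered not in _OFFER_SENTINELS and \
                self.offered not in universe.labels:
            raise ModelError(
                f"trial {self.index}: unknown offered label {self.offered!r}")
        if self.selected == REFUSED and self.offered == universe.target:
            raise ModelError(
                f"trial {self.index}: refused selection cannot offer the target")


@dataclass(frozen=True)
class FreeSelectionTrial:
    """One compartment session: entry, the set of items removed, the first
    item touched, and the delayed exchange outcome."""

    index: int
    entered: bool
    removed: frozenset[str] = frozenset()
    first_touch: str = NONE  # item label, NONE, or UNKNOWN
    offered: str = NONE      # item label, NONE, UNKNOWN, or OTHER
    foreign_offer: str = ""  # annotation when a foreign object was offered
    note: str = ""

    def validate(self, universe: ItemUniverse = DEFAULT_UNIVERSE) -> None:
        if self.index < 1:
            raise ModelError(f"trial index {self.index} must be >= 1")
        bad = set(self.removed) - set(universe.labels)
        if bad:
            raise ModelError(f"trial {self.index}: unknown removed labels {bad}")
        if self.first_touch not in (NONE, UNKNOWN) and \
                self.first_touch not in universe.labels:
            raise ModelError(
                f"trial {self.index}: unknown first_touch {self.first_touch!r}")
        if self.offered not in _OFFER_SENTINELS and \
                self.offered not in universe.labels:
            raise ModelError(
                f"trial {self.index}: unknown offered label {self.offered!r}")
        if not self.entered:
            if self.removed:
                raise ModelError(
                    f"trial {self.index}: removed items without entering")
            if self.first_touch != NONE:
                raise ModelError(
                    f"trial {self.index}: first_touch without entering")
        if self.offered == universe.target and \
                universe.target not in self.removed:
            raise ModelError(
                f"trial {self.index}: target offered but never removed")
        if self.offered in universe.labels and \
                self.offered not in self.removed and not self.foreign_offer:
            raise ModelError(
                f"trial {self.index}: offered item not removed and no "
                "foreign_offer annotation")


@dataclass
class SubjectRecord:
    """All trials of one subject, keyed by experiment id.

    ``aggregates`` carries per-experiment exchange totals for experiments
    where per-trial exchange outcomes were not recorded (``offered`` marked
    UNKNOWN): ``{"exp2": {"correct_exchanges": 6, "incorrect_exchanges": 0}}``.
    """

    name: str
    species: str
    experiments: dict[str, list] = field(default_factory=dict)
    aggregates: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self, universe: ItemUniverse = DEFAULT_UNIVERSE) -> None:
        for exp, trials in self.experiments.items():
            indices = [t.index for t in trials]
            if indices != list(range(1, len(trials) + 1)):
                raise ModelError(
                    f"{self.name}/{exp}: trial indices {indices} are not a "
                    f"contiguous 1..{len(trials)} sequence")
            for t in trials:
                t.validate(universe)


@dataclass(frozen=True)
class ObservedCounts:
    """The observed statistics entering every test."""

    n_trials: int = 0
    n_entered: int = 0
    n_correct_selections: int = 0
    n_incorrect_selections: int = 0
    n_target_available: int = 0
    n_correct_exchanges: int = 0
    n_incorrect_exchanges: int = 0
    n_complete_sequences: int = 0
    n_correct_behaviors: int = 0
    n_first_touch_target: int = 0

    def __post_init__(self) -> None:
        if not (self.n_correct_exchanges <= self.n_target_available
                <= self.n_trials):
            raise ModelError("exchange/availability counts out of order")
        if self.n_complete_sequences > self.n_correct_selections:
            raise ModelError("complete sequences exceed correct selections")

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def score_forced(trials: Sequence[ForcedSelectionTrial],
                 universe: ItemUniverse = DEFAULT_UNIVERSE) -> ObservedCounts:
    """Reduce a forced-selection trial list to its observed counts.

    Refusal trials stay in the denominator ``n_trials``. An exchange is
    *incorrect* when something other than the target was offered (a wrong
    item, or OTHER covering foreign objects and failed deliveries).
    """
    if not trials:
        raise ModelError("empty trial list")
    tgt = universe.target
    n = len(trials)
    sel = sum(t.selected == tgt for t in trials)
    exch = sum(t.offered == tgt for t in trials)
    bad_exch = sum(t.offered not in (NONE, UNKNOWN, tgt) for t in trials)
    complete = sum(t.selected == tgt and t.offered == tgt for t in trials)
    behaviors = sum(
        t.offered == tgt or (t.selected != tgt and t.offered == NONE)
        for t in trials)
    return ObservedCounts(
        n_trials=n,
        n_entered=n,
        n_correct_selections=sel,
        n_incorrect_selections=n - sel,
        n_target_available=sel,
        n_correct_exchanges=exch,
        n_incorrect_exchanges=bad_exch,
        n_complete_sequences=complete,
        n_correct_behaviors=behaviors,
        n_first_touch_target=sel,
    )


def score_free(trials: Sequence[FreeSelectionTrial],
               universe: ItemUniverse = DEFAULT_UNIVERSE,
               exchange_aggregate: Mapping[str, int] | None = None,
               ) -> ObservedCounts:
    """Reduce a free-selection trial list to its observed counts.

    The joint "correct behavior" rule counts an entered trial as correct
    when the target was offered, or when the target had not been removed
    and nothing was offered. ``n_incorrect_selections`` is the total number
    of distractor items removed across trials.

    When per-trial ``offered`` values are UNKNOWN the exchange totals must
    be supplied through ``exchange_aggregate`` (keys ``correct_exchanges``
    and ``incorrect_exchanges``).
    """
    if not trials:
        raise ModelError("empty trial list")
    tgt = universe.target
    n = len(trials)
    entered = [t for t in trials if t.entered]
    sel = sum(tgt in t.removed for t in entered)
    distractor_items = sum(len(t.removed - {tgt}) for t in trials)
    first = sum(t.first_touch == tgt for t in trials)

    unknown = any(t.offered == UNKNOWN for t in trials)
    if unknown:
        if exchange_aggregate is None:
            raise ModelError(
                "per-trial offers are UNKNOWN; an exchange_aggregate with "
                "'correct_exchanges' is required")
        exch = int(exchange_aggregate["correct_exchanges"])
        bad_exch = int(exchange_aggregate.get("incorrect_exchanges", 0))
        # Exchanges of the target can only have happened in trials where it
        # was removed, so the sequence/behavior counts follow from totals.
        complete = min(exch, sel)
        behaviors = complete + sum(
            tgt not in t.removed and t.offered == NONE for t in entered)
    else:
        exch = sum(t.offered == tgt for t in trials)
        bad_exch = sum(t.offered not in (NONE, UNKNOWN, tgt) for t in trials)
        complete = sum(
            tgt in t.removed and t.offered == tgt for t in trials)
        behaviors = sum(
            t.offered == tgt
            or (tgt not in t.removed and t.offered == NONE
                and not t.foreign_offer)
            for t in entered)
    return ObservedCounts(
        n_trials=n,
        n_entered=len(entered),
        n_correct_selections=sel,
        n_incorrect_selections=distractor_items,
        n_target_available=sel,
        n_correct_exchanges=exch,
        n_incorrect_exchanges=bad_exch,
        n_complete_sequences=complete,
        n_correct_behaviors=behaviors,
        n_first_touch_target=first,
    )


def k_profile(trials: Iterable[FreeSelectionTrial]) -> list[int]:
    """Per-trial removal counts, in trial order, for entered trials that
    removed at least one item. This is the conditioning variable of the
    free-selection chance models."""
    return [len(t.removed) for t in trials if t.entered and len(t.removed) >= 1]


def tabulate_preferences(trials: Sequence[ForcedSelectionTrial],
                         universe: ItemUniverse = DEFAULT_UNIVERSE,
                         ) -> dict[str, int]:
    """Per-item selection counts plus a refusal count; values sum to the
    number of trials."""
    counts = {label: 0 for label in universe.labels}
    counts[REFUSED] = 0
    for t in trials:
        counts[t.selected] += 1
    return counts


def meets_learning_criterion(outcomes: Sequence[bool],
                             required: int = 4,
                             window: int = 5) -> bool:
    """Whether any ``window`` consecutive trials contain at least
    ``required`` successes (the training criterion of 4 correct exchanges
    out of 5 trials)."""
    outcomes = list(outcomes)
    if len(outcomes) < window:
        return False
    return any(sum(outcomes[i:i + window]) >= required
               for i in range(len(outcomes) - window + 1))
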