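"""Bundled trial-by-trial records of the four study subjects.

Two chimpanzees (Manda, Maria-Magdalena) and two orangutans (Naong, Dunja)
were tested on a deferred token-exchange task: a preference test and an
exchange-training phase, then a forced one-item selection experiment
("exp1") and a free multi-item selection experiment ("exp2"), each with a
delayed, spatially displaced exchange with a human.

The per-trial tables below are reconstructed deterministically from the
published trial-level results. Where a per-trial detail was not reported
(item identity of some incorrect selections, ordering of preference
trials, which of Manda's free-selection trials ended in an exchange) the
fixture either carries an explanatory note, or stores only the aggregate
(Manda's exp2 exchanges: per-trial ``offered`` is UNKNOWN and the total of
6 correct exchanges lives in record-level ``aggregates``). Every count a
statistic consumes is exactly as published.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import load_records, write_records
from .model import (
    NONE,
    OTHER,
    REFUSED,
    UNKNOWN,
    ForcedSelectionTrial,
    FreeSelectionTrial,
    SubjectRecord,
)

__all__ = ["build_fixture_records", "load_fixture_records",
           "fixture_path", "write_fixture_files"]

_RECONSTRUCTED = "order/identity reconstructed, not reported"


def _forced(idx, selected, arrived, offered, note=""):
    return ForcedSelectionTrial(index=idx, selected=selected,
                                arrived=arrived, offered=offered, note=note)


def _training_block() -> list[ForcedSelectionTrial]:
    # Test of learning (5/5) then first test of retention (5/5); criterion
    # was 4 correct exchanges out of 5. All subjects scored 5/5 on both.
    return [
        _forced(i, "metal", True, "metal",
                "test of learning" if i <= 5 else "test of retention")
        for i in range(1, 11)
    ]


def _preference(sequence: list[str]) -> list[ForcedSelectionTrial]:
    return [_forced(i, sel, False, NONE, _RECONSTRUCTED)
            for i, sel in enumerate(sequence, start=1)]


def _manda() -> SubjectRecord:
    pref = _preference(["wood"] * 4 + ["rope"] + ["wood"] * 4 + ["rope"]
                       + ["wood"] * 4 + ["jute"])
    # Correct selections in trials 4 and 6-13; all 9 exchanged (100%).
    correct = {4} | set(range(6, 14))
    exp1 = [
        _forced(i, "metal", True, "metal") if i in correct else
        _forced(i, "wood", True, NONE,
                "incorrect selection; distractor identity not reported")
        for i in range(1, 14)
    ]
    # Removal sets reconstructed from the published distractor lists
    # (rope in trials 2,3,4,10; wood in 1,2,7; jute in 1; metal in all 12).
    removed = {
        1: {"metal", "wood", "jute"}, 2: {"metal", "rope", "wood"},
        3: {"metal", "rope"}, 4: {"metal", "rope"}, 5: {"metal"},
        6: {"metal"}, 7: {"metal", "wood"}, 8: {"metal"}, 9: {"metal"},
        10: {"metal", "rope"}, 11: {"metal"}, 12: {"metal"},
    }
    exp2 = [
        FreeSelectionTrial(
            index=i, entered=True, removed=frozenset(removed[i]),
            first_touch=("metal" if i != 1 else UNKNOWN),
            offered=UNKNOWN,
            note=("metal touched first in 11 of 12 trials; exception trial "
                  "not reported, placed at trial 1" if i == 1 else
                  "exchange outcome known only in aggregate (6 of 12)"))
        for i in range(1, 13)
    ]
    return SubjectRecord(
        name="Manda", species="Pan troglodytes",
        experiments={"preference": pref, "training": _training_block(),
                     "exp1": exp1, "exp2": exp2},
        aggregates={"exp2": {"correct_exchanges": 6,
                             "incorrect_exchanges": 0}})


def _maria_magdalena() -> SubjectRecord:
    pref = _preference(["wood"] * 4 + ["rope"] + ["wood"] * 4 + ["rope"]
                       + ["wood"] * 4 + [REFUSED])
    removed = {
        1: {"metal", "rope", "wood", "jute"}, 2: {"wood", "jute"},
        3: {"metal"}, 4: {"metal"}, 5: {"metal"}, 6: {"metal"},
        7: {"metal"}, 8: {"rope", "wood"}, 9: {"metal"},
        10: {"rope", "wood"}, 11: {"rope"}, 12: {"rope"},
    }
    metal_trials = {1, 3, 4, 5, 6, 7, 9}
    first_metal = {3, 4, 5, 6, 7, 9}  # 6 metal-first trials reported
    exp2 = [
        FreeSelectionTrial(
            index=i, entered=True, removed=frozenset(removed[i]),
            first_touch=("metal" if i in first_metal else UNKNOWN),
            offered=("metal" if i in metal_trials else NONE),
            note=("" if i in first_metal else
                  "first touch not target; identity not reported"))
        for i in range(1, 13)
    ]
    return SubjectRecord(
        name="Maria-Magdalena", species="Pan troglodytes",
        experiments={"preference": pref, "training": _training_block(),
                     "exp2": exp2})


def _naong() -> SubjectRecord:
    pref = _preference(["rope", "wood", "metal", REFUSED, "wood", "rope",
                        "jute", REFUSED, "metal", "wood", REFUSED, "rope",
                        "metal", "wood", REFUSED])
    exp1 = []
    for i in range(1, 14):
        if i == 13:
            exp1.append(_forced(i, REFUSED, False, NONE,
                                "refused to select"))
        elif i == 2:
            exp1.append(_forced(i, "metal", True, OTHER,
                                "did not bring the selected metal strip "
                                "to the exchange"))
        else:
            exp1.append(_forced(i, "metal", True, "metal"))
    entered = {1, 2, 3, 8, 9, 10, 11, 12}
    exp2 = []
    for i in range(1, 13):
        if i not in entered:
            exp2.append(FreeSelectionTrial(index=i, entered=False,
                                           note="did not enter"))
        elif i == 11:
            exp2.append(FreeSelectionTrial(
                index=i, entered=True, removed=frozenset({"rope", "wood"}),
                first_touch="metal", offered="wood",
                note="metal touched first but accidentally swept out of "
                     "reach; took rope and wood, tried to exchange wood"))
        else:
            exp2.append(FreeSelectionTrial(
                index=i, entered=True, removed=frozenset({"metal"}),
                first_touch="metal", offered="metal"))
    return SubjectRecord(
        name="Naong", species="Pongo abelii",
        experiments={"preference": pref, "training": _training_block(),
                     "exp1": exp1, "exp2": exp2})


def _dunja() -> SubjectRecord:
    pref = _preference(["wood"] + [REFUSED] * 3 + ["wood"] + [REFUSED] * 10)
    correct = {1, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14}
    attended = {3, 7, 10, 11, 13}
    foreign = {3: "stick from enclosure", 7: "bark from enclosure",
               10: "stick from enclosure", 11: "pine needles from enclosure"}
    exp1 = []
    for i in range(1, 15):
        if i == 2:
            exp1.append(_forced(i, REFUSED, False, NONE, "refused to select"))
        elif i in correct:
            exp1.append(_forced(
                i, "metal", i in attended,
                OTHER if i in foreign else NONE,
                foreign.get(i, "selected item taken by the male orangutan "
                               "before the exchange")))
        else:  # trials 3 and 11
            exp1.append(_forced(
                i, "wood", i in attended,
                OTHER if i in foreign else NONE,
                ("unclear selection, scored as incorrect; " if i == 11 else
                 "incorrect selection; distractor identity not reported; ")
                + foreign.get(i, "")))
    exp2 = []
    for i in range(1, 13):
        if i in (1, 2):
            exp2.append(FreeSelectionTrial(
                index=i, entered=False, offered=OTHER,
                foreign_offer="faeces" if i == 1 else "sponge",
                note="came to the exchange location; trial placement of the "
                     "two foreign offers not reported"))
        else:
            exp2.append(FreeSelectionTrial(index=i, entered=False,
                                           note="did not enter"))
    return SubjectRecord(
        name="Dunja", species="Pongo abelii",
        experiments={"preference": pref, "training": _training_block(),
                     "exp1": exp1, "exp2": exp2})


def build_fixture_records() -> list[SubjectRecord]:
    """Construct the four subject records in code (the canonical source of
    the bundled ``data/`` files)."""
    records = [_manda(), _maria_magdalena(), _naong(), _dunja()]
    for rec in records:
        rec.validate()
    return records


def fixture_path(name: str = "fixtures.json") -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("apexchange").joinpath("data", name))


def load_fixture_records() -> list[SubjectRecord]:
    """Load the bundled JSON fixture through the ordinary reader."""
    return load_records(fixture_path("fixtures.json"), format="json")


def write_fixture_files(directory: str | Path) -> None:
    """Regenerate the bundled data files (JSON plus the two CSV tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = build_fixture_records()
    write_records(records, directory / "fixtures.json", format="json")
    write_records(records, directory / "forced_trials.csv", format="csv",
                  design="forced")
    write_records(records, directory / "free_trials.csv", format="csv",
                  design="free")
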