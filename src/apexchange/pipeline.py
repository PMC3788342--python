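"""One-command replication of the published analysis from the bundled
fixtures, plus report rendering.

For each subject the pipeline computes, per experiment:

* forced design — exact binomial selection test, exchange accuracy, and
  the complete-behavioral-sequence test, all at the 25% chance level;
* free design — the conditional (Poisson-binomial / Monte Carlo)
  selection test, the joint selection-and-exchange test, the
  complete-sequence test, and exchange accuracy.

Two published values are known not to be reproducible from the stated
scoring rules and nulls (both for Manda's free-selection experiment: the
complete-sequence p printed as 0.11 and the joint-behavior p printed as
< 0.001, where the stated rules give 0.054 for both). The pipeline
computes and reports its own values and attaches NOT_REPRODUCED notes
rather than silently matching the published ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .chance_models import (
    DEFAULT_N_SIMS,
    DEFAULT_SEED,
    FreeSelectionNull,
    joint_behavior_pvalue,
    selection_pvalue_free,
)
from .exact_tests import (
    TestResult,
    complete_sequence_test,
    exchange_accuracy,
    selection_test_forced,
)
from .fixtures import load_fixture_records
from .model import DEFAULT_UNIVERSE, ItemUniverse, ObservedCounts, \
    SubjectRecord, score_forced, score_free

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "SubjectAnalysis", "run_replication",
           "analyze_records", "render_report", "format_p",
           "EXPECTED_TABLE1", "KNOWN_DEVIATIONS"]

# Published overview counts: (correct selections, incorrect selections,
# correct exchanges, incorrect exchanges) per subject and experiment.
EXPECTED_TABLE1 = {
    ("Manda", "exp1"): (9, 4, 9, 0),
    ("Naong", "exp1"): (12, 1, 11, 1),
    ("Dunja", "exp1"): (11, 3, 0, 4),
    ("Manda", "exp2"): (12, 8, 6, 0),
    ("Maria-Magdalena", "exp2"): (7, 11, 7, 0),
    ("Naong", "exp2"): (7, 1, 7, 1),
    ("Dunja", "exp2"): (0, 0, 0, 2),
}

# Differences from the published overview/tests that are expected and
# documented; they are flagged in the report, never silently matched.
KNOWN_DEVIATIONS = {
    ("Naong", "exp2", "n_incorrect_selections"):
        "published overview prints 1 incorrect selection; counting "
        "distractor items removed (rope and wood in trial 11) gives 2",
    ("Manda", "exp2", "complete_sequences"):
        "NOT_REPRODUCED: published p = 0.11 for 6 complete sequences of "
        "12; the one-tailed exact upper tail at chance 1/4 is 0.054",
    ("Manda", "exp2", "correct_behaviors"):
        "NOT_REPRODUCED: published p < 0.001 for the joint "
        "selection-and-exchange test; 6 correct behaviors of 12 under the "
        "chance agent gives 0.054",
}


@dataclass
class SubjectAnalysis:
    subject: str
    species: str
    experiment: str
    counts: ObservedCounts
    tests: list[TestResult] = field(default_factory=list)
    exchange_accuracy: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"subject": self.subject, "species": self.species,
                "experiment": self.experiment,
                "counts": self.counts.as_dict(),
                "tests": [t.to_dict() for t in self.tests],
                "exchange_accuracy": self.exchange_accuracy,
                "notes": list(self.notes)}


@dataclass
class AnalysisReport:
    entries: list[SubjectAnalysis]
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {"entries": [e.to_dict() for e in self.entries],
                "config": dict(self.config), "version": self.version}

    def table1_mismatches(self) -> list[str]:
        """Counts that disagree with the published overview, excluding the
        documented known deviations."""
        out = []
        for e in self.entries:
            expected = EXPECTED_TABLE1.get((e.subject, e.experiment))
            if expected is None:
                continue
            got = (e.counts.n_correct_selections,
                   e.counts.n_incorrect_selections,
                   e.counts.n_correct_exchanges,
                   e.counts.n_incorrect_exchanges)
            names = ("n_correct_selections", "n_incorrect_selections",
                     "n_correct_exchanges", "n_incorrect_exchanges")
            for name, g, x in zip(names, got, expected):
                if g != x and (e.subject, e.experiment, name) \
                        not in KNOWN_DEVIATIONS:
                    out.append(f"{e.subject}/{e.experiment}/{name}: "
                               f"computed {g}, published {x}")
        return out


def format_p(p: float) -> str:
    """Published reporting convention: three decimals, '<0.001' below."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _analyze_forced(rec: SubjectRecord, exp: str, trials,
                    universe: ItemUniverse) -> SubjectAnalysis:
    counts = score_forced(trials, universe)
    chance = 1.0 / universe.m
    entry = SubjectAnalysis(rec.name, rec.species, exp, counts,
                            exchange_accuracy=exchange_accuracy(counts))
    entry.tests.append(selection_test_forced(counts, chance))
    entry.tests.append(complete_sequence_test(counts, chance))
    return entry


def _analyze_free(rec: SubjectRecord, exp: str, trials,
                  universe: ItemUniverse, method: str, n_sims: int,
                  seed: int) -> SubjectAnalysis:
    counts = score_free(trials, universe,
                        exchange_aggregate=rec.aggregates.get(exp))
    entry = SubjectAnalysis(rec.name, rec.species, exp, counts,
                            exchange_accuracy=exchange_accuracy(counts))
    null = FreeSelectionNull.from_trials(trials, m=universe.m)
    if null.n_trials == 0:
        entry.notes.append("did not enter the selection compartment; "
                           "no conditional test defined")
        return entry
    entry.tests.append(selection_pvalue_free(
        null, counts.n_correct_selections, method=method, n_sims=n_sims,
        seed=seed))
    entry.tests.append(joint_behavior_pvalue(
        null, counts.n_correct_behaviors, method=method, n_sims=n_sims,
        seed=seed))
    entry.tests.append(complete_sequence_test(counts, 1.0 / universe.m))
    return entry


def analyze_records(records: Sequence[SubjectRecord],
                    method: str = "exact",
                    n_sims: int = DEFAULT_N_SIMS,
                    seed: int = DEFAULT_SEED,
                    universe: ItemUniverse = DEFAULT_UNIVERSE,
                    experiments: tuple[str, ...] = ("exp1", "exp2"),
                    ) -> AnalysisReport:
    """Score and test every record; the general-purpose entry point behind
    both ``replicate`` and ``analyze``."""
    entries = []
    for rec in records:
        for exp in experiments:
            trials = rec.experiments.get(exp)
            if not trials:
                continue
            if exp == "exp2":
                entry = _analyze_free(rec, exp, trials, universe, method,
                                      n_sims, seed)
            else:
                entry = _analyze_forced(rec, exp, trials, universe)
            for (subj, e, stat), msg in KNOWN_DEVIATIONS.items():
                if subj == rec.name and e == exp:
                    entry.notes.append(msg)
            entries.append(entry)
            logger.info("analyzed %s/%s: %d trials, %d tests",
                        rec.name, exp, len(trials), len(entry.tests))
    config = {"method": method, "n_sims": n_sims, "seed": seed,
              "m": universe.m, "target": universe.target}
    return AnalysisReport(entries=entries, config=config)


def run_replication(method: str = "exact", n_sims: int = DEFAULT_N_SIMS,
                    seed: int = DEFAULT_SEED) -> AnalysisReport:
    """Replicate the published analysis from the bundled fixtures."""
    records = load_fixture_records()
    return analyze_records(records, method=method, n_sims=n_sims, seed=seed)


# ----------------------------------------------------------------- render

def _markdown(report: AnalysisReport) -> str:
    by_subject: dict[str, dict[str, SubjectAnalysis]] = {}
    for e in report.entries:
        by_subject.setdefault(e.subject, {})[e.experiment] = e
    lines = [
        "| Subject | E1 sel + | E1 sel - | E1 exch + | E1 exch - "
        "| E2 sel + | E2 sel - | E2 exch + | E2 exch - |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for subject, exps in by_subject.items():
        cells = [subject]
        for exp in ("exp1", "exp2"):
            e = exps.get(exp)
            if e is None:
                cells += ["-"] * 4
            else:
                c = e.counts
                cells += [str(c.n_correct_selections),
                          str(c.n_incorrect_selections),
                          str(c.n_correct_exchanges),
                          str(c.n_incorrect_exchanges)]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("| Subject | Experiment | Statistic | Observed | n | p |")
    lines.append("|---|---|---|---|---|---|")
    for e in report.entries:
        for t in e.tests:
            lines.append(
                f"| {e.subject} | {e.experiment} | {t.statistic_name} "
                f"| {t.observed} | {t.n} | {format_p(t.p_value)} |")
    notes = [f"- {e.subject}/{e.experiment}: {n}"
             for e in report.entries for n in e.notes]
    if notes:
        lines += ["", "Notes:"] + notes
    return "\n".join(lines) + "\n"


def _tsv(report: AnalysisReport) -> str:
    lines = ["subject\texperiment\tstatistic\tobserved\tn\tp_value\tmethod"]
    for e in report.entries:
        for t in e.tests:
            lines.append(f"{e.subject}\t{e.experiment}\t{t.statistic_name}"
                         f"\t{t.observed}\t{t.n}\t{t.p_value:.6g}"
                         f"\t{t.method}")
    return "\n".join(lines) + "\n"


def render_report(report: AnalysisReport, format: str = "markdown") -> str:
    """Render an analysis report as json, tsv, or a markdown table pair
    (counts overview, then per-test p-values)."""
    import json as _json
    if format == "json":
        return _json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        return _tsv(report)
    if format == "markdown":
        return _markdown(report)
    raise ValueError(f"unknown format {format!r}")
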