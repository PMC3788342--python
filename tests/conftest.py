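import pytest

from apexchange.fixtures import build_fixture_records
from apexchange.model import score_forced, score_free


@pytest.fixture(scope="session")
def records():
    """The four bundled subject records, keyed by name."""
    return {r.name: r for r in build_fixture_records()}


@pytest.fixture(scope="session")
def counts(records):
    """ObservedCounts per (subject, experiment) for exp1/exp2."""
    out = {}
    for name, rec in records.items():
        for exp, trials in rec.experiments.items():
            if exp == "exp1":
                out[(name, exp)] = score_forced(trials)
            elif exp == "exp2":
                out[(name, exp)] = score_free(
                    trials, exchange_aggregate=rec.aggregates.get(exp))
    return out
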