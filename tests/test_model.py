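"""Scoring rules and domain-type invariants."""

import pytest

from apexchange.model import (
    NONE,
    REFUSED,
    DEFAULT_UNIVERSE,
    ForcedSelectionTrial,
    FreeSelectionTrial,
    ItemUniverse,
    ModelError,
    k_profile,
    meets_learning_criterion,
    score_forced,
    score_free,
    tabulate_preferences,
)


class TestItemUniverse:
    def test_default_has_four_items_with_metal_target(self):
        assert DEFAULT_UNIVERSE.m == 4
        assert DEFAULT_UNIVERSE.target == "metal"
        assert "metal" not in DEFAULT_UNIVERSE.distractors

    @pytest.mark.parametrize("labels,target", [
        (("metal",), "metal"),                 # too small
        (("metal", "rope"), "wood"),           # target not present
        (("metal", "metal", "rope"), "metal"), # duplicate labels
    ])
    def test_invalid_universes_rejected(self, labels, target):
        with pytest.raises(ModelError):
            ItemUniverse(labels=labels, target=target)


class TestTrialInvariants:
    def test_refusal_cannot_offer_target(self):
        t = ForcedSelectionTrial(1, REFUSED, False, "metal")
        with pytest.raises(ModelError):
            t.validate()

    def test_not_entered_implies_nothing_removed(self):
        t = FreeSelectionTrial(1, entered=False,
                               removed=frozenset({"rope"}))
        with pytest.raises(ModelError):
            t.validate()

    def test_target_offer_requires_target_removed(self):
        t = FreeSelectionTrial(1, entered=True,
                               removed=frozenset({"rope"}), offered="metal")
        with pytest.raises(ModelError):
            t.validate()

    def test_nonremoved_offer_needs_foreign_annotation(self):
        t = FreeSelectionTrial(1, entered=True,
                               removed=frozenset({"metal"}), offered="rope")
        with pytest.raises(ModelError):
            t.validate()
        ok = FreeSelectionTrial(1, entered=True,
                                removed=frozenset({"metal"}),
                                offered="rope", foreign_offer="from floor")
        ok.validate()


class TestScoreForced:
    # (subject, n_trials, correct_sel, correct_exch, complete_seq)
    @pytest.mark.parametrize("subject,n,sel,exch,complete", [
        ("Manda", 13, 9, 9, 9),
        ("Naong", 13, 12, 11, 11),
        ("Dunja", 14, 11, 0, 0),
    ])
    def test_published_counts(self, counts, subject, n, sel, exch, complete):
        c = counts[(subject, "exp1")]
        assert (c.n_trials, c.n_correct_selections,
                c.n_correct_exchanges, c.n_complete_sequences) == \
            (n, sel, exch, complete)

    def test_all_refused_scores_zero(self):
        trials = [ForcedSelectionTrial(i, REFUSED, False, NONE)
                  for i in range(1, 6)]
        c = score_forced(trials)
        assert c.n_trials == 5
        assert c.n_correct_selections == 0
        assert c.n_correct_exchanges == 0
        assert c.n_complete_sequences == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ModelError):
            score_forced([])


class TestScoreFree:
    def test_maria_magdalena_counts(self, counts):
        c = counts[("Maria-Magdalena", "exp2")]
        assert c.n_correct_selections == 7
        assert c.n_correct_exchanges == 7
        assert c.n_correct_behaviors == 12
        assert c.n_complete_sequences == 7

    def test_manda_counts_from_aggregate(self, counts):
        c = counts[("Manda", "exp2")]
        assert c.n_correct_selections == 12
        assert c.n_first_touch_target == 11
        assert c.n_correct_exchanges == 6
        assert c.n_correct_behaviors == 6

    def test_naong_entered_trials_only(self, counts):
        c = counts[("Naong", "exp2")]
        assert c.n_entered == 8
        assert c.n_correct_selections == 7
        assert c.n_correct_behaviors == 7

    def test_unknown_offers_require_aggregate(self, records):
        trials = records["Manda"].experiments["exp2"]
        with pytest.raises(ModelError):
            score_free(trials)

    def test_invariant_chain_on_all_fixtures(self, counts):
        for c in counts.values():
            assert c.n_correct_exchanges <= c.n_target_available <= c.n_trials
            assert c.n_complete_sequences <= c.n_correct_selections
            assert c.n_correct_behaviors <= max(c.n_entered, c.n_trials)


class TestKProfile:
    @pytest.mark.parametrize("subject,profile", [
        ("Maria-Magdalena", [4, 2, 1, 1, 1, 1, 1, 2, 1, 2, 1, 1]),
        ("Manda", [3, 3, 2, 2, 1, 1, 2, 1, 1, 2, 1, 1]),
        ("Naong", [1, 1, 1, 1, 1, 1, 2, 1]),
    ])
    def test_reconstructed_profiles(self, records, subject, profile):
        assert k_profile(records[subject].experiments["exp2"]) == profile

    def test_sums_to_total_items_removed(self, records):
        # Maria-Magdalena removed 7 metal + 5 rope + 4 wood + 2 jute = 18
        trials = records["Maria-Magdalena"].experiments["exp2"]
        assert sum(k_profile(trials)) == 18 == \
            sum(len(t.removed) for t in trials if t.entered)

    def test_no_entered_trials_gives_empty_profile(self, records):
        assert k_profile(records["Dunja"].experiments["exp2"]) == []


class TestPreferences:
    @pytest.mark.parametrize("subject,expected", [
        ("Manda", {"wood": 12, "rope": 2, "jute": 1, "metal": 0,
                   REFUSED: 0}),
        ("Naong", {"rope": 3, "wood": 4, "jute": 1, "metal": 3,
                   REFUSED: 4}),
    ])
    def test_published_tabulations(self, records, subject, expected):
        table = tabulate_preferences(records[subject].experiments["preference"])
        assert table == expected
        assert sum(table.values()) == 15

    def test_empty_list_gives_all_zeros(self):
        table = tabulate_preferences([])
        assert set(table.values()) == {0}

    def test_no_subject_preferred_the_target(self, records):
        # the premise of the training phase: no spontaneous metal preference
        for rec in records.values():
            table = tabulate_preferences(rec.experiments["preference"])
            others = [v for k, v in table.items()
                      if k not in ("metal", REFUSED)]
            assert table["metal"] <= max(others)


class TestLearningCriterion:
    def test_four_of_five_passes(self):
        assert meets_learning_criterion([True, True, False, True, True])
        assert not meets_learning_criterion([True, False, False, True, True])

    def test_short_blocks_fail(self):
        assert not meets_learning_criterion([True] * 4)

    def test_fixture_training_blocks_pass(self, records):
        for rec in records.values():
            outcomes = [t.offered == "metal"
                        for t in rec.experiments["training"]]
            assert meets_learning_criterion(outcomes)
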