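import itertools

import numpy as np
import pandas as pd
import pytest

from asmd_sit import (Cohort, GeneratorConfig, PatientRecord, SelectionConfig,
                      best_subset_select, default_study_config,
                      forest_importance, generate, max_subset_size_from_epv,
                      merge_hepatosplenomegaly)
from asmd_sit import reference

TOOL_SET = ("hepatosplenomegaly", "interstitial_lung_disease",
            "mixed_dyslipidemia_low_hdl", "thrombocytopenia_bleeding")


class TestEpvRule:
    def test_published_case_count_caps_at_four(self):
        assert max_subset_size_from_epv(48, 10) == 4

    def test_boundary(self):
        assert max_subset_size_from_epv(10, 10) == 1

    def test_floor_arithmetic(self):
        assert max_subset_size_from_epv(199, 10) == 19

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="admissible"):
            max_subset_size_from_epv(9, 10)


class TestMergeHepatosplenomegaly:
    def _cohort(self, hep, spl):
        rec = PatientRecord("p1", "case", "male",
                            symptoms={"hepatomegaly": hep, "splenomegaly": spl})
        filler = PatientRecord("p2", "control", "female",
                               symptoms={"hepatomegaly": "absent",
                                         "splenomegaly": "absent"})
        return Cohort([rec, filler])

    @pytest.mark.parametrize("hep,spl,and_expected,or_expected", [
        ("present", "present", 1, 1),
        ("absent", "present", 0, 1),
        ("unknown", "present", pd.NA, 1),
        ("unknown", "absent", 0, pd.NA),
        ("unknown", "unknown", pd.NA, pd.NA),
    ])
    def test_truth_table(self, hep, spl, and_expected, or_expected):
        for rule, expected in (("and", and_expected), ("or", or_expected)):
            merged = merge_hepatosplenomegaly(self._cohort(hep, spl), rule=rule)
            got = merged.frame.loc[0, "hepatosplenomegaly"]
            if expected is pd.NA:
                assert got is pd.NA
            else:
                assert got == expected

    def test_sources_retained_and_catalog_extended(self, study_cohort):
        merged = merge_hepatosplenomegaly(study_cohort)
        assert "hepatomegaly" in merged.frame.columns
        assert "hepatosplenomegaly" in merged.catalog
        assert merged.catalog.organ_system("hepatosplenomegaly") == "visceral"

    def test_double_merge_rejected(self, merged_study_cohort):
        with pytest.raises(ValueError, match="already exists"):
            merge_hepatosplenomegaly(merged_study_cohort)


def _tiny_config(**overrides):
    prev = {}
    for g, ps in (("case", (0.9, 0.6, 0.5)), ("control", (0.4, 0.05, 0.5)),
                  ("non_case", (0.01, 0.0, 0.5))):
        for s, p in zip(("hepatomegaly", "interstitial_lung_disease", "diarrhea"), ps):
            prev[(g, s)] = p
    base = dict(group_sizes={"case": 60, "control": 60, "non_case": 200},
                prevalence=prev, dependence=0.0, seed=4)
    base.update(overrides)
    return GeneratorConfig(**base)


class TestBestSubsetSelect:
    def test_single_candidate_wins_every_repetition(self):
        cohort = generate(_tiny_config())
        report = best_subset_select(cohort, SelectionConfig(
            candidate_variables=("hepatomegaly",), repetitions=5, seed=1))
        assert report.occurrence_frequency["hepatomegaly"] == 1.0
        assert report.final_set == ("hepatomegaly",)

    def test_pure_noise_candidate_stays_below_threshold(self):
        """A symptom with identical prevalence in all groups (diarrhea, 50%
        everywhere) never reaches the 70% occurrence threshold."""
        cohort = generate(_tiny_config(group_sizes={
            "case": 150, "control": 150, "non_case": 400}))
        report = best_subset_select(cohort, SelectionConfig(
            candidate_variables=("hepatomegaly", "interstitial_lung_disease",
                                 "diarrhea"),
            repetitions=50, max_subset_size=2, seed=2))
        assert report.occurrence_frequency["diarrhea"] <= 0.70
        assert "diarrhea" not in report.final_set

    def test_frequencies_invariant_to_candidate_order(self):
        cohort = generate(_tiny_config())
        cands = ("hepatomegaly", "interstitial_lung_disease", "diarrhea")
        r1 = best_subset_select(cohort, SelectionConfig(
            candidate_variables=cands, repetitions=8, seed=5))
        r2 = best_subset_select(cohort, SelectionConfig(
            candidate_variables=cands[::-1], repetitions=8, seed=5))
        assert r1.occurrence_frequency == r2.occurrence_frequency
        assert r1.per_rep_winners == r2.per_rep_winners

    def test_winner_sizes_respect_epv_cap(self):
        cohort = generate(_tiny_config())
        report = best_subset_select(cohort, SelectionConfig(
            candidate_variables=("hepatomegaly", "interstitial_lung_disease",
                                 "diarrhea"),
            repetitions=5, epv=30, seed=3))  # 60 cases / 30 = cap 2
        assert report.max_subset_size == 2
        assert all(len(w) <= 2 for w in report.per_rep_winners)

    def test_missing_group_rejected(self):
        cohort = generate(_tiny_config(group_sizes={"case": 50, "control": 50}))
        with pytest.raises(ValueError, match="three groups"):
            best_subset_select(cohort, SelectionConfig(
                candidate_variables=("hepatomegaly",), repetitions=2))


def _expected_accuracy(subset, prevalences, priors):
    """Exact expected test accuracy of the Bayes rule on a variable subset
    under per-group independence (closed form over the 2^k cells)."""
    k = len(subset)
    cells = np.arange(1 << k)
    bits = (cells[:, None] >> np.arange(k)) & 1
    p_cell = np.ones((1 << k, 3))
    for j, sid in enumerate(subset):
        p = np.asarray(prevalences[sid])
        p_cell *= np.where(bits[:, j:j + 1] == 1, p, 1 - p)
    joint = p_cell * priors
    return float(joint.max(axis=1).sum())


def test_tool_variables_are_population_optimal_subset():
    """Under the published prevalences (independence, published group sizes)
    the four tool variables form the unique expected-accuracy-optimal
    4-subset among all size-4 subsets of the screening candidates."""
    prevalences = {}
    candidates = []
    for sid, counts in reference.SYMPTOM_COUNTS.items():
        if sid in ("hepatomegaly", "splenomegaly", "family_history_asmd"):
            continue
        p = [counts[i] / n for i, n in enumerate((48, 52, 808))]
        prevalences[sid] = p
        candidates.append(sid)
    hep = reference.SYMPTOM_COUNTS["hepatomegaly"]
    spl = reference.SYMPTOM_COUNTS["splenomegaly"]
    prevalences["hepatosplenomegaly"] = [
        (hep[i] / n) * (spl[i] / n) for i, n in enumerate((48, 52, 808))]
    candidates.append("hepatosplenomegaly")
    # candidates = the p<0.001 cases-vs-controls screening set
    from asmd_sit import ContingencyTable, fisher_exact_2x2
    kept = []
    for sid in candidates:
        if sid == "hepatosplenomegaly":
            kept.append(sid)
            continue
        a, c, _ = reference.SYMPTOM_COUNTS[sid]
        if fisher_exact_2x2(ContingencyTable(a, 48 - a, c, 52 - c)) < 0.001:
            kept.append(sid)
    priors = np.array([480, 520, 8080], float)
    priors /= priors.sum()
    scores = {
        S: _expected_accuracy(S, prevalences, priors)
        for S in itertools.combinations(sorted(kept), 4)}
    best = max(scores, key=scores.get)
    assert best == tuple(sorted(TOOL_SET))


class TestForestImportance:
    def test_informative_variable_ranks_first(self):
        cohort = generate(_tiny_config(group_sizes={
            "case": 200, "control": 200, "non_case": 400}))
        ranking = forest_importance(
            cohort, ["hepatomegaly", "diarrhea"], repetitions=5, seed=0,
            n_estimators=50)
        assert ranking[0][0] == "hepatomegaly"
        assert ranking[0][1] > ranking[1][1]

    def test_zero_variance_candidate_has_zero_importance(self):
        cfg = _tiny_config()
        cfg = GeneratorConfig(**{**cfg.__dict__, "prevalence": {
            **cfg.prevalence,
            ("case", "ataxia"): 0.0, ("control", "ataxia"): 0.0,
            ("non_case", "ataxia"): 0.0}})
        cohort = generate(cfg)
        ranking = dict(forest_importance(
            cohort, ["hepatomegaly", "ataxia"], repetitions=3, seed=1,
            n_estimators=30))
        assert ranking["ataxia"] == 0.0

    def test_duplicated_signal_shares_importance(self):
        cohort = generate(_tiny_config(group_sizes={
            "case": 300, "control": 300, "non_case": 300}))
        df = cohort.frame.copy()
        df["ataxia"] = df["hepatomegaly"]  # exact copy of the informative sign
        cohort2 = Cohort(df, cohort.catalog)
        ranking = dict(forest_importance(
            cohort2, ["hepatomegaly", "ataxia", "diarrhea"],
            repetitions=5, seed=2, n_estimators=50))
        assert ranking["hepatomegaly"] + ranking["ataxia"] > 2 * ranking["diarrhea"]
        assert ranking["hepatomegaly"] == pytest.approx(ranking["ataxia"], rel=0.35)
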