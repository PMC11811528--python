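"""Prioritized matching: exact sex, nearest age, motion tie-break, global uniqueness."""

import numpy as np
import pandas as pd
import pytest

from transdx import (
    ConfigError,
    MatchingInfeasibleError,
    balance_report,
    greedy_violations,
    healthy_pool,
    match_controls,
    subsample_to_reference,
)
from transdx.matching import MatchedCohort

from conftest import make_participants, random_pool


def test_age_priority_beats_motion():
    """Sex is exact; among same-sex controls the age-closest wins even when
    another control is a much better motion match."""
    parts = make_participants(
        [
            ("case1", "F", 50.0, 0.2, 0, "F32"),
            ("c_age", "F", 50.0, 0.9, 0, ""),
            ("c_motion", "F", 60.0, 0.2, 0, ""),
            ("c_male", "M", 50.0, 0.2, 0, ""),
        ]
    )
    matched = match_controls({"F32": {"case1"}}, parts, ["c_age", "c_motion", "c_male"])
    assert matched["F32"].pairs == [("case1", "c_age")]


def test_motion_breaks_age_ties_then_smallest_id():
    parts = make_participants(
        [
            ("case1", "M", 55.0, 0.30, 0, "G40"),
            ("cB", "M", 55.0, 0.70, 0, ""),
            ("cA", "M", 55.0, 0.31, 0, ""),
            ("cD", "M", 55.0, 0.31, 0, ""),
        ]
    )
    matched = match_controls({"G40": {"case1"}}, parts, ["cB", "cA", "cD"])
    # cA and cD tie on age and motion; smallest ID wins
    assert matched["G40"].pairs == [("case1", "cA")]


def test_identical_cases_consume_distinct_controls():
    parts = make_participants(
        [
            ("k1", "F", 50.0, 0.2, 0, "F32"),
            ("k2", "F", 50.0, 0.2, 0, "F32"),
            ("c1", "F", 50.0, 0.2, 0, ""),
            ("c2", "F", 50.0, 0.2, 0, ""),
        ]
    )
    matched = match_controls({"F32": {"k1", "k2"}}, parts, ["c1", "c2"])
    controls = matched["F32"].control_ids
    assert sorted(controls) == ["c1", "c2"]


def test_pool_exhaustion_names_group_and_stratum():
    parts = make_participants(
        [
            ("k1", "F", 50.0, 0.2, 0, "F32"),
            ("c1", "M", 50.0, 0.2, 0, ""),
        ]
    )
    with pytest.raises(MatchingInfeasibleError, match=r"F32.*'F'"):
        match_controls({"F32": {"k1"}}, parts, ["c1"])


def test_global_uniqueness_and_greedy_optimality_across_groups():
    rng = np.random.default_rng(0)
    pool = random_pool(600, seed=1)
    cases = make_participants(
        [
            (
                f"k{i:03d}",
                "F" if rng.random() < 0.5 else "M",
                float(rng.uniform(40, 70)),
                float(rng.lognormal(np.log(0.15), 0.4)),
                0,
                "F32" if i < 80 else "G40",
            )
            for i in range(120)
        ]
    )
    parts = pd.concat([cases, pool], ignore_index=True)
    groups = {
        "F32": set(cases["id"][:80]),
        "G40": set(cases["id"][80:]),
    }
    pool_ids = list(pool["id"])
    matched = match_controls(groups, parts, pool_ids, seed=5)
    all_controls = [c for mc in matched.values() for c in mc.control_ids]
    assert len(all_controls) == len(set(all_controls)) == 120
    assert greedy_violations(matched, parts, pool_ids) == []
    for mc in matched.values():
        sex = parts.set_index("id")["sex"]
        assert all(sex[a] == sex[b] for a, b in mc.pairs)


def test_determinism_given_seed_and_ordering():
    pool = random_pool(300, seed=2)
    cases = random_pool(40, seed=3).assign(icd10="F32")
    cases["id"] = ["k" + i for i in cases["id"]]
    parts = pd.concat([cases, pool], ignore_index=True)
    a = match_controls({"F32": set(cases["id"])}, parts, list(pool["id"]), seed=9)
    b = match_controls({"F32": set(cases["id"])}, parts, list(pool["id"]), seed=9)
    assert a["F32"].pairs == b["F32"].pairs


def test_healthy_pool_excludes_any_f_or_g_code():
    parts = make_participants(
        [
            ("p1", "F", 50.0, 0.2, 0, ""),
            ("p2", "M", 51.0, 0.2, 0, "F32"),
            ("p3", "M", 52.0, 0.2, 0, "I25"),  # non-brain chapter: still healthy here
            ("p4", "F", 53.0, 0.2, 0, "G40.1"),
        ]
    )
    assert healthy_pool(parts) == ["p1", "p3"]


class TestBalanceReport:
    def test_perfect_sex_match_gives_p_one(self):
        pool = random_pool(200, seed=4)
        cases = random_pool(30, seed=5).assign(icd10="F32")
        cases["id"] = ["k" + i for i in cases["id"]]
        parts = pd.concat([cases, pool], ignore_index=True)
        matched = match_controls({"F32": set(cases["id"])}, parts, list(pool["id"]))
        rep = balance_report(matched["F32"], parts)
        assert rep.sex_chi2_p == 1.0
        assert rep.degenerate == () or rep.degenerate == ("site",)

    def test_extreme_age_separation_detected(self):
        rows = [(f"a{i}", "F", 70.0, 0.2, 0, "") for i in range(30)]
        rows += [(f"b{i}", "F", 40.0, 0.2, 1, "") for i in range(30)]
        parts = make_participants(rows)
        cohort = MatchedCohort("X", [(f"a{i}", f"b{i}") for i in range(30)])
        rep = balance_report(cohort, parts)
        assert rep.age_p < 1e-6

    def test_cohort_against_itself_is_all_ones(self):
        pool = random_pool(40, seed=6)
        cohort = MatchedCohort("X", [(i, i) for i in pool["id"]])
        rep = balance_report(cohort, pool)
        assert rep.sex_chi2_p == 1.0
        assert rep.age_p == 1.0
        assert rep.motion_p == 1.0

    def test_single_sex_cohort_flagged_degenerate(self):
        rows = [(f"a{i}", "F", 50.0 + i, 0.2, 0, "") for i in range(10)]
        rows += [(f"b{i}", "F", 50.0 + i, 0.25, 1, "") for i in range(10)]
        parts = make_participants(rows)
        cohort = MatchedCohort("X", [(f"a{i}", f"b{i}") for i in range(10)])
        rep = balance_report(cohort, parts)
        assert rep.sex_chi2_p == 1.0
        assert "sex" in rep.degenerate

    def test_balance_quality_over_seeds(self):
        """With a rich pool, matched groups show no covariate differences:
        sex p = 1 always; age/motion p stay comfortably high on average.

        Ages are recorded in whole years here (the usual granularity of
        cohort age fields); exact-age tie sets are what lets the motion
        tie-break engage and balance motion as well as age.
        """

        def int_age_pool(n, seed, prefix="C"):
            rng = np.random.default_rng(seed)
            return make_participants(
                [
                    (
                        f"{prefix}{i:05d}",
                        "F" if rng.random() < 0.5 else "M",
                        float(rng.integers(40, 70)),
                        float(rng.lognormal(np.log(0.15), 0.4)),
                        int(rng.integers(0, 3)),
                        "",
                    )
                    for i in range(n)
                ]
            )

        age_ps, motion_ps = [], []
        for seed in range(20):
            pool = int_age_pool(2000, 100 + seed)
            cases = int_age_pool(200, 200 + seed, prefix="k").assign(icd10="F32")
            parts = pd.concat([cases, pool], ignore_index=True)
            matched = match_controls({"F32": set(cases["id"])}, parts, list(pool["id"]), seed=seed)
            rep = balance_report(matched["F32"], parts)
            assert rep.sex_chi2_p == 1.0
            age_ps.append(rep.age_p)
            motion_ps.append(rep.motion_p)
        assert np.mean(age_ps) > 0.3
        assert np.mean(motion_ps) > 0.7


class TestSubsample:
    def _matched_group(self, n_cases, seed):
        pool = random_pool(6 * n_cases, seed=seed)
        cases = random_pool(n_cases, seed=seed + 1).assign(icd10="F32")
        cases["id"] = ["k" + i for i in cases["id"]]
        parts = pd.concat([cases, pool], ignore_index=True)
        matched = match_controls({"F32": set(cases["id"])}, parts, list(pool["id"]), seed=seed)
        return matched["F32"], parts, cases

    def test_identity_when_already_at_target(self):
        mc, parts, cases = self._matched_group(40, seed=10)
        ref = cases[["id", "sex", "age", "motion"]]
        sub = subsample_to_reference(mc, ref, parts, target_n=40, seed=0)
        assert sorted(sub.pairs) == sorted(mc.pairs)

    def test_size_and_sex_composition_match_reference(self):
        mc, parts, _ = self._matched_group(300, seed=20)
        ref = random_pool(125, seed=77)[["id", "sex", "age", "motion"]]
        sub = subsample_to_reference(mc, ref, parts, target_n=125, seed=0)
        assert len(sub.pairs) == 125
        sex = parts.set_index("id")["sex"]
        assert sorted(sex[c] for c in sub.case_ids) == sorted(ref["sex"])
        # pairs keep their original controls
        original = dict(mc.pairs)
        assert all(original[c] == ctrl for c, ctrl in sub.pairs)

    def test_undersized_group_rejected(self):
        mc, parts, _ = self._matched_group(40, seed=30)
        ref = random_pool(125, seed=78)[["id", "sex", "age", "motion"]]
        with pytest.raises(ConfigError, match="target_n"):
            subsample_to_reference(mc, ref, parts, target_n=125)

    def test_tracks_reference_age_better_than_random_subsets(self):
        """The guided subsample lands closer to the reference mean age than a
        uniformly random subset in nearly all repetitions."""
        mc, parts, _ = self._matched_group(400, seed=40)
        cov = parts.set_index("id")
        case_ages = cov.loc[mc.case_ids, "age"].to_numpy()
        wins = 0
        reps = 100
        for rep in range(reps):
            ref = random_pool(125, seed=1000 + rep)
            ref = ref[(ref["age"] > 45) & (ref["age"] < 60)].iloc[:60]
            target = len(ref)
            sub = subsample_to_reference(mc, ref, parts, target_n=target, seed=rep)
            guided = abs(cov.loc[sub.case_ids, "age"].mean() - ref["age"].mean())
            rng = np.random.default_rng(rep)
            rand = abs(rng.choice(case_ages, size=target, replace=False).mean() - ref["age"].mean())
            wins += guided < rand
        assert wins >= 0.95 * reps
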