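"""Prioritized case-control matching with a global uniqueness constraint.

Each case is matched to a healthy control on sex, age, and head motion, in
that order of priority: the control must have identical sex; among unused
same-sex controls the one with minimal absolute age difference wins, ties
broken by minimal absolute motion difference, then by smallest control ID
(a deterministic final tie-break).  A control is consumed at most once
across *all* groups of a run, so the combined case and control samples
never share participants.

Groups are processed in ascending size so small groups are not starved of
close matches by large ones; within a group, cases are visited in a
seed-shuffled order.  Matching is greedy per case rather than a global
optimal assignment — "as close as possible, in this order of priority" is
a per-case lexicographic rule, and a transport-style global optimum would
change its semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, MatchingInfeasibleError
from .icd10 import Icd10Code, _codes_of

DEFAULT_PRIORITY = ("sex", "age", "motion")


@dataclass
class MatchedCohort:
    """Case-control pairing for one diagnostic group."""

    label: str
    pairs: list[tuple[str, str]]
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    @property
    def all_ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def to_frame(self, participants: pd.DataFrame) -> pd.DataFrame:
        """Tidy pair table with per-pair age and motion differences."""
        cov = participants.set_index("id")
        rows = []
        for case, control in self.pairs:
            rows.append(
                {
                    "group_label": self.label,
                    "case_id": case,
                    "control_id": control,
                    "age_diff": abs(cov.at[case, "age"] - cov.at[control, "age"]),
                    "motion_diff": abs(cov.at[case, "motion"] - cov.at[control, "motion"]),
                }
            )
        return pd.DataFrame(rows, columns=["group_label", "case_id", "control_id", "age_diff", "motion_diff"])


@dataclass(frozen=True)
class BalanceReport:
    """Covariate balance diagnostics for one matched cohort.

    ``sex_chi2_p`` comes from a 2x2 chi-square without continuity
    correction, so perfectly matched sexes give a statistic of exactly 0
    and p = 1.  ``age_p`` and ``motion_p`` are two-sided two-sample
    t-tests; ``site_p`` is a chi-square over the site × status table.
    Degenerate tables (a single sex or a single site) report p = 1 with
    the corresponding flag set.
    """

    sex_chi2_p: float
    age_p: float
    motion_p: float
    site_p: float
    site_counts: pd.DataFrame
    degenerate: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("sex_chi2_p", "age_p", "motion_p", "site_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")


def healthy_pool(participants: pd.DataFrame) -> list[str]:
    """IDs of participants with no chapter V/VI (F or G) ICD-10 codes."""
    pool = []
    for pid, raw in zip(participants["id"], participants["icd10"]):
        codes = [Icd10Code.parse(c, str(pid)) for c in _codes_of(raw)]
        if not any(c.letter in ("F", "G") for c in codes):
            pool.append(pid)
    return pool


class _Pool:
    """Mutable view of the unused control pool, indexable by sex stratum."""

    def __init__(self, participants: pd.DataFrame, pool_ids: Sequence[str]):
        sub = participants.set_index("id").loc[list(pool_ids)]
        self.ids = np.asarray(sub.index, dtype=object)
        self.sex = sub["sex"].to_numpy()
        self.age = sub["age"].to_numpy(dtype=float)
        self.motion = sub["motion"].to_numpy(dtype=float)
        self.unused = np.ones(len(self.ids), dtype=bool)

    def take(self, sex: str, age: float, motion: float, tie_order: Sequence[str]) -> str:
        cand = np.flatnonzero(self.unused & (self.sex == sex))
        if cand.size == 0:
            raise MatchingInfeasibleError(sex)
        diffs = {"age": np.abs(self.age[cand] - age), "motion": np.abs(self.motion[cand] - motion)}
        for key in tie_order:
            best = diffs[key].min()
            keep = diffs[key] == best
            cand = cand[keep]
            diffs = {k: v[keep] for k, v in diffs.items()}
        if cand.size > 1:  # final tie-break: smallest control ID
            chosen = min(cand, key=lambda i: str(self.ids[i]))
        else:
            chosen = cand[0]
        self.unused[chosen] = False
        return self.ids[chosen]


def match_controls(
    groups: Mapping[str, Iterable[str]],
    participants: pd.DataFrame,
    pool_ids: Sequence[str] | None = None,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    seed: int = 0,
) -> dict[str, MatchedCohort]:
    """Match a unique control to every case of every group.

    Parameters
    ----------
    groups
        Map group label → case IDs.
    participants
        Covariate table (columns ``id, sex, age, motion, site, icd10``).
    pool_ids
        Candidate control IDs; defaults to :func:`healthy_pool` minus any
        case of any group.  Must be at least as large as the total case
        count.
    priority
        Covariate priority; the first entry must be ``sex`` (matched
        exactly), the rest are nearest-distance tie levels in order.
    """
    priority = tuple(priority)
    if not priority or priority[0] != "sex":
        raise ConfigError("priority must start with exact sex matching")
    tie_order = priority[1:]
    if any(k not in ("age", "motion") for k in tie_order):
        raise ConfigError(f"unknown priority covariates in {priority}")

    all_cases = set()
    for ids in groups.values():
        all_cases.update(ids)
    if pool_ids is None:
        pool_ids = [pid for pid in healthy_pool(participants) if pid not in all_cases]
    if len(pool_ids) < sum(len(list(ids)) for ids in groups.values()):
        raise MatchingInfeasibleError(
            f"control pool ({len(pool_ids)}) smaller than total case count"
        )

    pool = _Pool(participants, pool_ids)
    cov = participants.set_index("id")
    rng = np.random.default_rng(seed)
    matched: dict[str, MatchedCohort] = {}
    # ascending group size protects small groups from pool depletion
    for label in sorted(groups, key=lambda lb: (len(set(groups[lb])), lb)):
        case_ids = sorted(set(groups[label]))
        rng.shuffle(case_ids)
        pairs: list[tuple[str, str]] = []
        for case in case_ids:
            sex, age, motion = cov.at[case, "sex"], cov.at[case, "age"], cov.at[case, "motion"]
            try:
                control = pool.take(sex, float(age), float(motion), tie_order)
            except MatchingInfeasibleError:
                raise MatchingInfeasibleError(
                    f"group {label}: control pool exhausted for sex stratum {sex!r}"
                ) from None
            pairs.append((case, control))
        matched[label] = MatchedCohort(label, pairs, priority)
    return matched


def subsample_to_reference(
    group: MatchedCohort,
    reference_cases: pd.DataFrame,
    participants: pd.DataFrame,
    target_n: int = 125,
    seed: int = 0,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> MatchedCohort:
    """Subsample a matched group to ``target_n`` pairs guided by a reference.

    Each reference case (typically a case of the smallest retained group)
    claims the nearest unused case of ``group`` under the same
    sex > age > motion rule; the selected cases keep their original
    controls.  This removes both size and covariate-composition differences
    between groups.

    ``reference_cases`` must be a covariate table (``id, sex, age,
    motion``) with at least ``target_n`` rows; ``participants`` supplies
    the covariates of the group's own cases.
    """
    if len(group.pairs) < target_n:
        raise ConfigError(
            f"group {group.label} has {len(group.pairs)} pairs < target_n={target_n}"
        )
    if len(reference_cases) < target_n:
        raise ConfigError(
            f"reference has {len(reference_cases)} cases < target_n={target_n}"
        )
    tie_order = tuple(priority)[1:]
    ref = reference_cases.sample(frac=1.0, random_state=np.random.RandomState(seed)).iloc[
        :target_n
    ]
    pool = _Pool(participants, group.case_ids)
    control_of = dict(group.pairs)
    pairs: list[tuple[str, str]] = []
    for _, row in ref.iterrows():
        try:
            case = pool.take(row["sex"], float(row["age"]), float(row["motion"]), tie_order)
        except MatchingInfeasibleError:
            raise MatchingInfeasibleError(
                f"group {group.label}: no unused case in sex stratum {row['sex']!r} "
                "to match the reference"
            ) from None
        pairs.append((case, control_of[case]))
    return MatchedCohort(group.label, pairs, tuple(priority))


def balance_report(cohort: MatchedCohort, participants: pd.DataFrame) -> BalanceReport:
    """Covariate balance diagnostics between the case and control arms."""
    cov = participants.set_index("id")
    cases = cov.loc[cohort.case_ids]
    controls = cov.loc[cohort.control_ids]
    degenerate: list[str] = []

    sex_table = pd.crosstab(
        np.repeat(["case", "control"], [len(cases), len(controls)]),
        np.concatenate([cases["sex"].to_numpy(), controls["sex"].to_numpy()]),
    )
    if sex_table.shape[1] < 2:
        sex_p = 1.0
        degenerate.append("sex")
    else:
        sex_p = float(stats.chi2_contingency(sex_table, correction=False).pvalue)

    def _tp(a: np.ndarray, b: np.ndarray) -> float:
        if np.array_equal(np.sort(a), np.sort(b)):
            return 1.0  # identical samples, t = 0 by construction
        res = stats.ttest_ind(a, b)
        p = float(res.pvalue)
        return 1.0 if np.isnan(p) else p

    age_p = _tp(cases["age"].to_numpy(float), controls["age"].to_numpy(float))
    motion_p = _tp(cases["motion"].to_numpy(float), controls["motion"].to_numpy(float))

    site_table = pd.crosstab(
        np.repeat(["case", "control"], [len(cases), len(controls)]),
        np.concatenate([cases["site"].to_numpy(), controls["site"].to_numpy()]),
    )
    if site_table.shape[1] < 2:
        site_p = 1.0
        degenerate.append("site")
    else:
        site_p = float(stats.chi2_contingency(site_table, correction=False).pvalue)

    return BalanceReport(
        sex_chi2_p=sex_p,
        age_p=age_p,
        motion_p=motion_p,
        site_p=site_p,
        site_counts=site_table,
        degenerate=tuple(degenerate),
    )


def greedy_violations(
    matched: Mapping[str, MatchedCohort],
    participants: pd.DataFrame,
    pool_ids: Sequence[str],
) -> list[tuple[str, str, str]]:
    """Post-hoc scan of the greedy optimality guarantee.

    Returns every (group, case, better_control) triple where a same-sex
    control left unused at the end of the run has strictly smaller absolute
    age difference than the control actually chosen.  An empty list means
    no chosen match can be improved on the top distance priority by any
    leftover control.
    """
    cov = participants.set_index("id")
    used = {ctrl for mc in matched.values() for ctrl in mc.control_ids}
    leftovers = [pid for pid in pool_ids if pid not in used]
    left = cov.loc[leftovers]
    violations = []
    for label, mc in matched.items():
        for case, control in mc.pairs:
            chosen_diff = abs(cov.at[case, "age"] - cov.at[control, "age"])
            same_sex = left[left["sex"] == cov.at[case, "sex"]]
            better = same_sex[np.abs(same_sex["age"] - cov.at[case, "age"]) < chosen_diff]
            for pid in better.index:
                violations.append((label, case, pid))
    return violations
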