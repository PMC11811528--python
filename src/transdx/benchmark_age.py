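"""Age-extremes classification benchmark.

Classifying the oldest against the youngest members of a cohort from the
same feature sets and with the same evaluation engine gives an upper-bound
reference for the diagnostic classifications: age has a strong, reliable
signature in structural brain features, so any feature set and classifier
worth its salt should separate the age extremes far above chance even at
the sample size of the smallest diagnostic group.

Two balanced old/young groups are built, size-matched to the largest and
smallest diagnostic groups.  Old and young members are paired to maximize
the within-pair age difference subject to exact sex matching, with head
motion as the nearest-neighbor tie-break, so the two arms cannot be told
apart by sex or motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MatchingInfeasibleError


@dataclass(frozen=True)
class AgeBenchmarkSpec:
    """Configuration of the two age-extreme benchmark groups.

    Ranges are in years and must be disjoint; ``n_large`` / ``n_small``
    are total group sizes (half old, half young) and must be even.
    """

    n_large: int
    n_small: int
    old_range: tuple[float, float] = (67.0, 70.0)
    young_range: tuple[float, float] = (40.0, 42.0)
    small_from_large: bool = False

    def __post_init__(self):
        for rng in (self.old_range, self.young_range):
            if not rng[0] <= rng[1]:
                raise ConfigError(f"invalid age range {rng}")
        if not (self.young_range[1] < self.old_range[0] or self.old_range[1] < self.young_range[0]):
            raise ConfigError("old_range and young_range must be disjoint")
        for n in (self.n_large, self.n_small):
            if n <= 0 or n % 2:
                raise ConfigError(f"group sizes must be positive and even, got {n}")
        if self.n_small > self.n_large:
            raise ConfigError("n_small must not exceed n_large")


def _pair_extremes(
    pool: pd.DataFrame,
    spec: AgeBenchmarkSpec,
    n_total: int,
    seed: int,
) -> pd.DataFrame:
    """Greedy maximal-age-difference pairing with exact sex match.

    Old candidates are visited in descending age order and each claims the
    youngest unused same-sex young candidate; equal-age ties are broken by
    nearest head motion, then by smallest ID.  The seed only randomizes the
    visiting order among old candidates of exactly equal age.
    """
    n_pairs = n_total // 2
    old = pool[(pool["age"] >= spec.old_range[0]) & (pool["age"] <= spec.old_range[1])]
    young = pool[(pool["age"] >= spec.young_range[0]) & (pool["age"] <= spec.young_range[1])]

    capacity = 0
    for sex in ("F", "M"):
        capacity += min((old["sex"] == sex).sum(), (young["sex"] == sex).sum())
    if capacity < n_pairs:
        deficit_sex = min(
            ("F", "M"),
            key=lambda s: min((old["sex"] == s).sum(), (young["sex"] == s).sum()),
        )
        raise MatchingInfeasibleError(
            f"cannot form {n_pairs} old/young pairs: sex stratum {deficit_sex!r} "
            f"supports only {capacity} pairs in total"
        )

    rng = np.random.RandomState(seed)
    old = old.sample(frac=1.0, random_state=rng).sort_values("age", ascending=False, kind="stable")
    y_ids = young["id"].to_numpy(dtype=object)
    y_sex = young["sex"].to_numpy()
    y_age = young["age"].to_numpy(dtype=float)
    y_motion = young["motion"].to_numpy(dtype=float)
    unused = np.ones(len(young), dtype=bool)

    rows = []
    pair_index = 0
    for _, o in old.iterrows():
        if pair_index == n_pairs:
            break
        cand = np.flatnonzero(unused & (y_sex == o["sex"]))
        if cand.size == 0:
            continue
        age_d = y_age[cand]
        cand = cand[age_d == age_d.min()]  # youngest -> largest age difference
        if cand.size > 1:
            mot_d = np.abs(y_motion[cand] - float(o["motion"]))
            cand = cand[mot_d == mot_d.min()]
        chosen = min(cand, key=lambda i: str(y_ids[i])) if cand.size > 1 else cand[0]
        unused[chosen] = False
        rows.append({"id": o["id"], "age": o["age"], "sex": o["sex"], "motion": o["motion"], "label": "old", "pair_index": pair_index})
        yrow = young.iloc[chosen]
        rows.append({"id": yrow["id"], "age": yrow["age"], "sex": yrow["sex"], "motion": yrow["motion"], "label": "young", "pair_index": pair_index})
        pair_index += 1
    return pd.DataFrame(rows)


def pair_capacity(
    participants: pd.DataFrame,
    old_range: tuple[float, float] = (67.0, 70.0),
    young_range: tuple[float, float] = (40.0, 42.0),
) -> int:
    """Maximum number of sex-matched old/young pairs the pool supports."""
    old = participants[participants["age"].between(*old_range)]
    young = participants[participants["age"].between(*young_range)]
    return sum(
        min((old["sex"] == s).sum(), (young["sex"] == s).sum()) for s in ("F", "M")
    )


def build_age_groups(
    participants: pd.DataFrame,
    spec: AgeBenchmarkSpec,
    eligible_ids: Iterable[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the large and small balanced old/young benchmark groups.

    ``eligible_ids`` restricts the pool (typically members of any retained
    diagnostic group plus the healthy pool); by default all participants
    are eligible.  Returns ``(large, small)`` tables with columns
    ``arm, id, age, sex, motion, label, pair_index``; each is exactly half
    "old" and half "young" with identical sex composition in both halves.

    By default the small group is a fresh pairing at ``n_small``; with
    ``spec.small_from_large`` it is instead the ``n_small/2`` largest-age-
    difference pairs of the large selection.
    """
    pool = participants
    if eligible_ids is not None:
        eligible = set(eligible_ids)
        pool = participants[participants["id"].isin(eligible)]
    large = _pair_extremes(pool, spec, spec.n_large, seed)
    if spec.small_from_large:
        small = large[large["pair_index"] < spec.n_small // 2].copy()
    else:
        small = _pair_extremes(pool, spec, spec.n_small, seed)
    large = large.copy()
    large.insert(0, "arm", "large")
    small = small.copy()
    small.insert(0, "arm", "small")
    return large, small


def age_labels(arm: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Extract ``(ids, binary old/young label vector)`` from one arm."""
    return list(arm["id"]), (arm["label"] == "old").astype(int).to_numpy()
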