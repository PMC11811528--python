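"""Synthetic cohort generation with planted diagnostic effects.

Real population-imaging cohorts with linked diagnostic codes are
access-restricted, so every downstream stage of this package is exercised
on simulated cohorts that reproduce the *structure* the analysis assumes:

* covariates — sex (Bernoulli), age (uniform on a bounded range, in years),
  an in-scanner head-motion summary (log-normal, positive-skewed), and a
  categorical acquisition site;
* diagnoses — each participant carries a set of ICD-10 codes.  Per-group
  prevalences are modulated by optional covariate effects and by a pairwise
  log-odds coupling between groups (an Ising-style model sampled with a
  fixed number of Gibbs passes), which produces controllable comorbidity;
* feature sets — one or more participant × feature matrices of Gaussian
  noise in which group membership shifts a configured subset of features by
  a configured standardized effect size (Cohen's d, in units of the feature
  noise SD), with optional linear age, sex, and additive site effects.

Effect sizes are *planted*, so downstream classifiers can be checked
against the generative ground truth (e.g. a Bayes-accuracy oracle) rather
than against irreproducible external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError, FormatError
from .icd10 import Icd10Code, code_in_range

logger = logging.getLogger(__name__)

_GIBBS_PASSES = 10  # fixed; enough to mix the small group-coupling models used here


@dataclass(frozen=True)
class CovariateShifts:
    """Optional case/covariate confounding for one diagnostic group.

    ``age_shift_years`` is the approximate mean age difference of cases
    versus the pool (implemented as a linear log-odds slope in age);
    ``sex_log_odds`` is added to the case log-odds for male participants;
    ``motion_shift`` is the approximate mean head-motion difference of
    cases, implemented analogously to age.
    """

    age_shift_years: float = 0.0
    sex_log_odds: float = 0.0
    motion_shift: float = 0.0


@dataclass(frozen=True)
class GroupSpec:
    """One planted diagnostic group: an ICD-10 code, its broad range, and
    the probability that a participant carries the code."""

    code: str
    parent_range: str
    prevalence: float
    covariate_shifts: CovariateShifts | None = None

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not code_in_range(Icd10Code.parse(self.code), self.parent_range):
            raise ConfigError(
                f"code {self.code} does not fall inside its parent range {self.parent_range}"
            )


@dataclass(frozen=True)
class FeatureSetSpec:
    """One feature matrix block and the effects planted into it.

    ``affected_features_per_group`` / ``effect_size_per_group`` map a group
    code to the column indices it shifts and the standardized shift (Cohen's
    d in units of ``noise_sd``).  ``age_effect`` is a linear slope (feature
    units per year, applied to ``age_affected`` columns about the age-range
    midpoint); ``sex_effect`` is a standardized shift added for female
    participants on ``sex_affected`` columns; ``site_shift`` is the SD (in
    ``noise_sd`` units) of per-site, per-feature additive offsets.
    """

    name: str
    n_features: int
    affected_features_per_group: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    effect_size_per_group: Mapping[str, float] = field(default_factory=dict)
    age_effect: float = 0.0
    age_affected: tuple[int, ...] = ()
    sex_effect: float = 0.0
    sex_affected: tuple[int, ...] = ()
    noise_sd: float = 1.0
    site_shift: float = 0.0

    def __post_init__(self):
        if self.n_features <= 0:
            raise ConfigError(f"n_features must be positive, got {self.n_features}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")
        for which in (self.affected_features_per_group.values(), [self.age_affected, self.sex_affected]):
            for idx in which:
                arr = np.asarray(idx, dtype=int)
                if arr.size and (arr.min() < 0 or arr.max() >= self.n_features):
                    raise ConfigError(
                        f"feature set {self.name}: affected indices out of range [0, {self.n_features})"
                    )
        missing = set(self.effect_size_per_group) ^ set(self.affected_features_per_group)
        if missing:
            raise ConfigError(
                f"feature set {self.name}: groups {sorted(missing)} must appear in both "
                "affected_features_per_group and effect_size_per_group"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one synthetic cohort.

    ``sex_fraction`` is the probability of being female; ``age_range`` is in
    years; ``motion_distribution`` holds log-normal parameters
    ``{"location": mu, "scale": sigma}`` on the log scale;
    ``comorbidity_coupling`` is a symmetric zero-diagonal matrix of pairwise
    log-odds increments between the groups in ``group_specs`` order.
    """

    n_participants: int
    group_specs: tuple[GroupSpec, ...] = ()
    feature_set_specs: tuple[FeatureSetSpec, ...] = ()
    sex_fraction: float = 0.53
    age_range: tuple[float, float] = (40.0, 70.0)
    motion_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"location": np.log(0.15), "scale": 0.4}
    )
    n_sites: int = 3
    comorbidity_coupling: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ConfigError("sex_fraction must lie in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must satisfy min < max")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        g = len(self.group_specs)
        if self.comorbidity_coupling is not None:
            J = np.asarray(self.comorbidity_coupling, dtype=float)
            if J.shape != (g, g):
                raise ConfigError(
                    f"comorbidity_coupling must be {g}x{g}, got shape {J.shape}"
                )
            if not np.allclose(J, J.T):
                raise ConfigError("comorbidity_coupling must be symmetric")
            if np.any(np.diag(J) != 0):
                raise ConfigError("comorbidity_coupling must have a zero diagonal")
            object.__setattr__(self, "comorbidity_coupling", J)

    @property
    def coupling(self) -> np.ndarray:
        g = len(self.group_specs)
        if self.comorbidity_coupling is None:
            return np.zeros((g, g))
        return self.comorbidity_coupling


def _sample_diagnoses(
    config: CohortConfig,
    sex_female: np.ndarray,
    age: np.ndarray,
    motion: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the participants × groups indicator matrix.

    Base log-odds per group come from the prevalence plus covariate-shift
    terms; pairwise coupling is applied by full Gibbs passes over groups.
    With zero coupling the initial independent draw is already exact and the
    Gibbs passes leave the law unchanged.
    """
    n = config.n_participants
    groups = config.group_specs
    g = len(groups)
    if g == 0:
        return np.zeros((n, 0), dtype=bool)
    base = np.empty((n, g))
    lo, hi = config.age_range
    age_var = (hi - lo) ** 2 / 12.0
    motion_var = motion.var()
    for j, spec in enumerate(groups):
        eta = np.full(n, logit(spec.prevalence))
        sh = spec.covariate_shifts
        if sh is not None:
            if sh.sex_log_odds:
                eta += sh.sex_log_odds * (~sex_female)
            if sh.age_shift_years:
                eta += (sh.age_shift_years / age_var) * (age - age.mean())
            if sh.motion_shift and motion_var > 0:
                eta += (sh.motion_shift / motion_var) * (motion - motion.mean())
        base[:, j] = eta
    Y = (rng.random((n, g)) < expit(base)).astype(float)
    J = config.coupling
    if np.any(J != 0):
        for _ in range(_GIBBS_PASSES):
            for j in range(g):
                eta = base[:, j] + Y @ J[:, j]  # J diagonal is zero
                Y[:, j] = rng.random(n) < expit(eta)
    return Y.astype(bool)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate a cohort and its feature matrices, deterministically in the seed.

    Returns
    -------
    participants
        Columns ``id, sex (M/F), age, motion, site, icd10`` (semicolon-
        delimited code list, possibly empty).
    features
        Map feature-set name → DataFrame with an ``id`` column followed by
        the named feature columns, row-aligned with ``participants``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = np.array([f"S{i:06d}" for i in range(n)])
    sex_female = rng.random(n) < config.sex_fraction
    age = rng.uniform(*config.age_range, size=n)
    mu, sigma = config.motion_distribution["location"], config.motion_distribution["scale"]
    motion = rng.lognormal(mean=mu, sigma=sigma, size=n)
    site = rng.integers(0, config.n_sites, size=n)

    Y = _sample_diagnoses(config, sex_female, age, motion, rng)
    codes = [
        ";".join(sorted(spec.code for j, spec in enumerate(config.group_specs) if Y[i, j]))
        for i in range(n)
    ]
    participants = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(sex_female, "F", "M"),
            "age": age,
            "motion": motion,
            "site": site,
            "icd10": codes,
        }
    )

    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
    code_index = {spec.code: j for j, spec in enumerate(config.group_specs)}
    features: dict[str, pd.DataFrame] = {}
    for spec in config.feature_set_specs:
        p = spec.n_features
        X = rng.normal(0.0, spec.noise_sd, size=(n, p))
        for code, idx in spec.affected_features_per_group.items():
            if code not in code_index:
                raise ConfigError(
                    f"feature set {spec.name} plants an effect for unknown group {code}"
                )
            d = spec.effect_size_per_group[code]
            members = Y[:, code_index[code]]
            X[np.ix_(members, np.asarray(idx, dtype=int))] += d * spec.noise_sd
        if spec.age_effect and len(spec.age_affected):
            X[:, np.asarray(spec.age_affected, int)] += spec.age_effect * (age - age_mid)[:, None]
        if spec.sex_effect and len(spec.sex_affected):
            X[np.ix_(sex_female, np.asarray(spec.sex_affected, int))] += (
                spec.sex_effect * spec.noise_sd
            )
        if spec.site_shift:
            offsets = rng.normal(0.0, spec.site_shift * spec.noise_sd, size=(config.n_sites, p))
            X += offsets[site]
        df = pd.DataFrame(X, columns=[f"f{j:04d}" for j in range(p)])
        df.insert(0, "id", ids)
        features[spec.name] = df
    return participants, features


# ---------------------------------------------------------------------------
# On-disk format: participants.csv + one CSV per feature set
# ---------------------------------------------------------------------------

def write_cohort(
    participants: pd.DataFrame,
    features: Mapping[str, pd.DataFrame],
    directory: str | Path,
) -> list[Path]:
    """Write a cohort to ``directory`` as plain CSV; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / "participants.csv"]
    participants.to_csv(paths[0], index=False)
    for name, df in features.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_cohort(directory: str | Path) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read a cohort written by :func:`write_cohort`.

    Every feature CSV in the directory is loaded; rows are validated
    against the participant table (unknown or missing IDs, incomplete rows)
    and re-aligned to participant order.
    """
    directory = Path(directory)
    ppath = directory / "participants.csv"
    if not ppath.exists():
        raise FormatError(f"no participants.csv in {directory}")
    participants = pd.read_csv(ppath, dtype={"id": str}, keep_default_na=False)
    participants["icd10"] = participants["icd10"].astype(str)
    participants["age"] = participants["age"].astype(float)
    participants["motion"] = participants["motion"].astype(float)
    participants["site"] = participants["site"].astype(int)
    ids = participants["id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"duplicate participant ID {dup!r}")
    features: dict[str, pd.DataFrame] = {}
    for path in sorted(directory.glob("*.csv")):
        if path.name == "participants.csv":
            continue
        df = pd.read_csv(path, dtype={"id": str})
        unknown = set(df["id"]) - set(ids)
        if unknown:
            raise FormatError(
                f"{path.name}: row ID {sorted(unknown)[0]!r} absent from participant table"
            )
        missing = set(ids) - set(df["id"])
        if missing:
            raise FormatError(
                f"{path.name}: participant {sorted(missing)[0]!r} has no feature row"
            )
        value_cols = [c for c in df.columns if c != "id"]
        bad = df[value_cols].isna().any(axis=1)
        if bad.any():
            raise FormatError(
                f"{path.name}: incomplete feature row for participant "
                f"{df.loc[bad, 'id'].iloc[0]!r}"
            )
        df = df.set_index("id").loc[ids].reset_index()
        features[path.stem] = df
    return participants, features


def study_like_config(
    n_participants: int = 6000,
    seed: int = 0,
    n_null_groups: int = 4,
    strong_effect: float = 1.0,
    weak_effect: float = 0.35,
) -> CohortConfig:
    """A scaled cohort echoing the structure of a population-imaging study.

    Two planted signals mirror the qualitative pattern of interest: a small
    nervous-system group (``G35``, demyelinating-like, prevalence chosen to
    yield on the order of 150 cases at the default ``n_participants``) with
    a strong effect in the volumetric-like feature set, and a large mood
    group (``F32``, depression-like, the most prevalent group) with a weak
    effect in the sociodemographic-like set.  ``F41`` (anxiety-like) is
    coupled to ``F32`` with a positive log-odds increment so a realistic
    share of diagnosed individuals carries more than one label.  Remaining
    groups are null fillers spread over chapters V/VI.
    """
    fillers = [
        ("F10", "F10-F19", 0.02),
        ("F20", "F20-F29", 0.012),
        ("G40", "G40-G47", 0.02),
        ("G43", "G40-G47", 0.025),
        ("F60", "F60-F69", 0.012),
        ("G20", "G20-G26", 0.012),
    ]
    groups = [
        GroupSpec("F32", "F30-F39", 0.085),
        GroupSpec("F41", "F40-F48", 0.05),
        GroupSpec("G35", "G35-G37", 0.027),
    ] + [GroupSpec(c, r, p) for c, r, p in fillers[:n_null_groups]]
    g = len(groups)
    # weak background coupling between all groups plus a strong
    # anxiety-depression link: overall comorbidity lands near 40% of
    # diagnosed individuals, with the mood-disorder overlap dominating
    J = np.full((g, g), 0.6)
    np.fill_diagonal(J, 0.0)
    J[0, 1] = J[1, 0] = 2.8
    volume_idx = tuple(range(12))
    socio_idx = tuple(range(10))
    feature_sets = (
        FeatureSetSpec(
            "structural_volume",
            n_features=153,
            affected_features_per_group={"G35": volume_idx},
            effect_size_per_group={"G35": strong_effect},
            age_effect=0.05,
            age_affected=tuple(range(40)),
            sex_effect=0.3,
            sex_affected=tuple(range(20, 40)),
            site_shift=0.1,
        ),
        FeatureSetSpec(
            "sociodemographic",
            n_features=36,
            affected_features_per_group={"F32": socio_idx},
            effect_size_per_group={"F32": weak_effect},
            age_effect=0.02,
            age_affected=tuple(range(12)),
        ),
    )
    return CohortConfig(
        n_participants=n_participants,
        group_specs=tuple(groups),
        feature_set_specs=feature_sets,
        comorbidity_coupling=J,
        seed=seed,
    )
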