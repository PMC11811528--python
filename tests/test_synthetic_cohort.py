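"""Generator correctness: determinism, planted effects, coupling, round-trip I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transdx import (
    CohortConfig,
    ConfigError,
    FeatureSetSpec,
    FormatError,
    GroupSpec,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from transdx.synthetic_cohort import CovariateShifts


def one_group_config(n=2000, prevalence=0.1, d=0.0, seed=0, n_features=10, idx=(0, 1, 2)):
    return CohortConfig(
        n_participants=n,
        group_specs=(GroupSpec("G35", "G35-G37", prevalence),),
        feature_set_specs=(
            FeatureSetSpec(
                "fs",
                n_features=n_features,
                affected_features_per_group={"G35": tuple(idx)},
                effect_size_per_group={"G35": d},
            ),
        ),
        seed=seed,
    )


def test_seed_determinism_is_bit_identical():
    cfg = one_group_config(n=500, d=0.5, seed=42)
    p1, f1 = generate_cohort(cfg)
    p2, f2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(p1, p2)
    for name in f1:
        pd.testing.assert_frame_equal(f1[name], f2[name])
    # a different seed must change the draw
    p3, _ = generate_cohort(dataclasses.replace(cfg, seed=43))
    assert not p1["age"].equals(p3["age"])


def test_case_count_within_binomial_bounds():
    """Observed case count falls in the central 99.9% binomial interval."""
    n, prev = 20_000, 0.01
    cfg = one_group_config(n=n, prevalence=prev, seed=7)
    participants, _ = generate_cohort(cfg)
    count = int((participants["icd10"] == "G35").sum())
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, prev)
    assert lo <= count <= hi


def test_null_config_features_independent_of_labels():
    """With zero effect sizes, per-feature case/control p-values behave as a null."""
    cfg = one_group_config(n=4000, prevalence=0.3, d=0.0, seed=3, n_features=200, idx=tuple(range(200)))
    participants, features = generate_cohort(cfg)
    cases = (participants["icd10"] == "G35").to_numpy()
    X = features["fs"].drop(columns="id").to_numpy()
    pvals = stats.ttest_ind(X[cases], X[~cases]).pvalue
    # ~5% of 200 independent nulls at alpha=0.05; allow 4 binomial SDs
    assert (pvals < 0.05).sum() <= 0.05 * 200 + 4 * np.sqrt(200 * 0.05 * 0.95)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_planted_effect_calibration():
    """Empirical Cohen's d between cases and non-cases matches the planted d."""
    d_planted = 0.8
    cfg = one_group_config(n=20_000, prevalence=0.3, d=d_planted, seed=11)
    participants, features = generate_cohort(cfg)
    cases = (participants["icd10"] == "G35").to_numpy()
    x = features["fs"]["f0000"].to_numpy()
    n1, n2 = cases.sum(), (~cases).sum()
    pooled = np.sqrt(((n1 - 1) * x[cases].var(ddof=1) + (n2 - 1) * x[~cases].var(ddof=1)) / (n1 + n2 - 2))
    d_hat = (x[cases].mean() - x[~cases].mean()) / pooled
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d_planted**2 / (2 * (n1 + n2)))
    assert abs(d_hat - d_planted) < 3 * se_d


def test_positive_coupling_raises_joint_prevalence():
    """P(both | either) grows with a large positive pairwise coupling."""

    def config(coupling, seed):
        J = np.array([[0.0, coupling], [coupling, 0.0]])
        return CohortConfig(
            n_participants=2000,
            group_specs=(
                GroupSpec("F32", "F30-F39", 0.05),
                GroupSpec("F41", "F40-F48", 0.05),
            ),
            comorbidity_coupling=J,
            seed=seed,
        )

    def p_both_given_either(coupling):
        both = either = 0
        for seed in range(50):
            participants, _ = generate_cohort(config(coupling, seed))
            has_a = participants["icd10"].str.contains("F32")
            has_b = participants["icd10"].str.contains("F41")
            both += (has_a & has_b).sum()
            either += (has_a | has_b).sum()
        return both / either

    assert p_both_given_either(3.0) > p_both_given_either(0.0)


def test_covariate_shift_moves_case_age():
    cfg = CohortConfig(
        n_participants=20_000,
        group_specs=(
            GroupSpec("G30", "G30-G32", 0.2, CovariateShifts(age_shift_years=5.0)),
        ),
        seed=5,
    )
    participants, _ = generate_cohort(cfg)
    cases = participants["icd10"] == "G30"
    shift = participants.loc[cases, "age"].mean() - participants["age"].mean()
    assert 3.0 < shift < 7.0


def test_site_shift_separates_sites():
    cfg = CohortConfig(
        n_participants=3000,
        n_sites=3,
        feature_set_specs=(FeatureSetSpec("fs", n_features=5, site_shift=2.0),),
        seed=9,
    )
    participants, features = generate_cohort(cfg)
    X = features["fs"].drop(columns="id").to_numpy()
    means = [X[participants["site"] == s].mean(axis=0) for s in range(3)]
    assert np.abs(means[0] - means[1]).max() > 1.0


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        cfg = CohortConfig(
            n_participants=10,
            group_specs=(GroupSpec("F32", "F30-F39", 0.4),),
            feature_set_specs=(
                FeatureSetSpec("a", n_features=2),
                FeatureSetSpec("b", n_features=3),
            ),
            seed=1,
        )
        participants, features = generate_cohort(cfg)
        write_cohort(participants, features, tmp_path)
        p2, f2 = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(participants, p2)
        assert set(f2) == {"a", "b"}
        for name in features:
            pd.testing.assert_frame_equal(features[name], f2[name])

    def test_empty_code_set_round_trips(self, tmp_path):
        cfg = CohortConfig(n_participants=6, seed=2)
        participants, _ = generate_cohort(cfg)
        assert (participants["icd10"] == "").all()
        write_cohort(participants, {}, tmp_path)
        p2, _ = read_cohort(tmp_path)
        assert (p2["icd10"] == "").all()

    def test_unknown_feature_row_id_is_format_error(self, tmp_path):
        cfg = CohortConfig(n_participants=5, feature_set_specs=(FeatureSetSpec("a", 2),), seed=3)
        participants, features = generate_cohort(cfg)
        bad = features["a"].copy()
        bad.loc[0, "id"] = "GHOST"
        write_cohort(participants, {"a": bad}, tmp_path)
        with pytest.raises(FormatError, match="GHOST"):
            read_cohort(tmp_path)

    def test_incomplete_feature_row_is_format_error(self, tmp_path):
        cfg = CohortConfig(n_participants=5, feature_set_specs=(FeatureSetSpec("a", 2),), seed=3)
        participants, features = generate_cohort(cfg)
        ragged = features["a"].copy()
        ragged.loc[2, "f0001"] = np.nan
        write_cohort(participants, {"a": ragged}, tmp_path)
        with pytest.raises(FormatError, match="S000002"):
            read_cohort(tmp_path)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_participants": 0},
        {"n_participants": 100, "sex_fraction": 1.5},
        {"n_participants": 100, "age_range": (70.0, 40.0)},
        {"n_participants": 100, "n_sites": 0},
    ],
)
def test_invalid_cohort_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        CohortConfig(**kwargs)


def test_asymmetric_or_misshapen_coupling_rejected():
    groups = (GroupSpec("F32", "F30-F39", 0.1), GroupSpec("F41", "F40-F48", 0.1))
    with pytest.raises(ConfigError, match="symmetric"):
        CohortConfig(100, group_specs=groups, comorbidity_coupling=np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ConfigError, match="2x2"):
        CohortConfig(100, group_specs=groups, comorbidity_coupling=np.zeros((3, 3)))
    with pytest.raises(ConfigError, match="diagonal"):
        CohortConfig(100, group_specs=groups, comorbidity_coupling=np.array([[1.0, 0.0], [0.0, 1.0]]))


def test_invalid_feature_spec_rejected():
    with pytest.raises(ConfigError, match="n_features"):
        FeatureSetSpec("a", 0)
    with pytest.raises(ConfigError, match="noise_sd"):
        FeatureSetSpec("a", 4, noise_sd=0.0)
    with pytest.raises(ConfigError, match="out of range"):
        FeatureSetSpec("a", 4, affected_features_per_group={"G35": (5,)}, effect_size_per_group={"G35": 1.0})


def test_invalid_group_spec_rejected():
    with pytest.raises(ConfigError, match="prevalence"):
        GroupSpec("F32", "F30-F39", 0.0)
    with pytest.raises(ConfigError, match="parent range"):
        GroupSpec("F32", "F40-F48", 0.1)
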