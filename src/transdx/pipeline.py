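"""End-to-end orchestration from a single run configuration.

A run configuration (YAML or dict) names a cohort source (a directory
written by :func:`transdx.synthetic_cohort.write_cohort`, an inline
generator configuration, or the packaged study-like generator), the stages
to execute, and per-stage options.  Stages run in dependency order::

    cohort -> groups -> match -> classify -> infer
                     \\-> multiclass / logo / age_bench (optional)

All randomness flows from the single top-level ``seed``.  Each stage
writes its outputs as soon as it finishes, so a failing stage leaves the
earlier artifacts on disk together with a manifest recording per-stage
status; re-running an identical configuration reproduces byte-identical
results.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark_age import AgeBenchmarkSpec, age_labels, build_age_groups, pair_capacity
from .classify import (
    build_multiclass_cohort,
    make_model,
    run_binary,
    run_logo,
    run_multiclass,
)
from .errors import ConfigError, StageError
from .icd10 import assign_members, comorbidity_stats, retain_groups, unique_case_list
from .inference import build_results_table, chance_test
from .matching import balance_report, healthy_pool, match_controls, subsample_to_reference
from .synthetic_cohort import (
    CohortConfig,
    CovariateShifts,
    FeatureSetSpec,
    GroupSpec,
    generate_cohort,
    read_cohort,
    study_like_config,
    write_cohort,
)

MODEL_ALIASES = {
    "rf": "random_forest",
    "svc": "support_vector",
    "knn": "k_nearest_neighbors",
    "random_forest": "random_forest",
    "support_vector": "support_vector",
    "k_nearest_neighbors": "k_nearest_neighbors",
}

_STAGE_ORDER = ["groups", "match", "classify", "infer", "multiclass", "logo", "age_bench"]
_STAGE_DEPS = {
    "groups": [],
    "match": ["groups"],
    "classify": ["match"],
    "infer": ["classify"],
    "multiclass": ["match"],
    "logo": ["match"],
    "age_bench": ["groups"],
}


def cohort_config_from_dict(raw: Mapping) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain (YAML-friendly) mapping."""
    raw = dict(raw)
    groups = []
    for g in raw.pop("group_specs", []):
        g = dict(g)
        shifts = g.pop("covariate_shifts", None)
        groups.append(
            GroupSpec(covariate_shifts=CovariateShifts(**shifts) if shifts else None, **g)
        )
    fsets = []
    for f in raw.pop("feature_set_specs", []):
        f = dict(f)
        for key in ("age_affected", "sex_affected"):
            if key in f:
                f[key] = tuple(f[key])
        if "affected_features_per_group" in f:
            f["affected_features_per_group"] = {
                k: tuple(v) for k, v in f["affected_features_per_group"].items()
            }
        fsets.append(FeatureSetSpec(**f))
    coupling = raw.pop("comorbidity_coupling", None)
    if coupling is not None:
        coupling = np.asarray(coupling, dtype=float)
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    return CohortConfig(
        group_specs=tuple(groups),
        feature_set_specs=tuple(fsets),
        comorbidity_coupling=coupling,
        **raw,
    )


def load_config(config) -> dict:
    """Load and validate a run configuration; returns the canonical dict.

    Validation happens before any compute: the stage list must be
    dependency-closed (e.g. ``classify`` without ``match`` is an error) and
    the cohort source must be specified exactly one way.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigError("run configuration must be a mapping")
    cfg = json.loads(json.dumps(dict(config)))  # deep copy, YAML-typed
    if "seed" not in cfg:
        raise ConfigError("run configuration must set a seed")
    cohort = cfg.get("cohort", {})
    sources = [k for k in ("directory", "config", "study_like") if k in cohort]
    if len(sources) != 1:
        raise ConfigError(
            "cohort must specify exactly one of: directory, config, study_like"
        )
    stages = cfg.get("stages", ["groups", "match", "classify", "infer"])
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        missing = [dep for dep in _STAGE_DEPS[stage] if dep not in stages]
        if missing:
            raise ConfigError(f"stage '{stage}' requires stages {missing} in the run")
    cfg["stages"] = [s for s in _STAGE_ORDER if s in stages]
    return cfg


def _cell_seed(base: int, *parts: str) -> int:
    return int((base + zlib.crc32("|".join(parts).encode())) % (2**31))


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class _Run:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, cfg: dict, out: Path):
        self.cfg = cfg
        self.out = out
        self.seed = int(cfg["seed"])
        self.participants: pd.DataFrame | None = None
        self.features: dict[str, pd.DataFrame] = {}
        self.retained = []
        self.matched = {}
        self.cells = {}
        self.acc_frames = []

    def feature_rows(self, name: str, ids: list[str]) -> pd.DataFrame:
        return self.features[name].set_index("id").loc[ids].reset_index()


def _stage_cohort(run: _Run) -> None:
    cohort = run.cfg["cohort"]
    if "directory" in cohort:
        run.participants, run.features = read_cohort(cohort["directory"])
    else:
        if "study_like" in cohort:
            kwargs = dict(cohort["study_like"])
            kwargs.setdefault("seed", run.seed)
            cc = study_like_config(**kwargs)
        else:
            raw = dict(cohort["config"])
            raw.setdefault("seed", run.seed)
            cc = cohort_config_from_dict(raw)
        run.participants, run.features = generate_cohort(cc)
        if run.cfg.get("write_cohort", False):
            write_cohort(run.participants, run.features, run.out / "cohort")


def _stage_groups(run: _Run) -> None:
    opts = run.cfg.get("groups", {})
    membership = assign_members(run.participants)
    run.retained = retain_groups(membership, min_n=int(opts.get("min_n", 125)))
    payload = []
    for g in sorted(run.retained, key=lambda g: g.label):
        payload.append(
            {"label": g.label, "level": g.level, "n_cases": g.n_cases, "case_ids": sorted(g.case_ids)}
        )
    out = {"groups": payload}
    if run.retained:
        rate, overlap = comorbidity_stats(run.retained)
        out["comorbidity_rate"] = rate
        out["pairwise_overlap"] = overlap.round(6).to_dict()
    (run.out / "groups.json").write_text(json.dumps(out, indent=1, sort_keys=True))


def _stage_match(run: _Run) -> None:
    groups = {g.label: set(g.case_ids) for g in run.retained}
    if not groups:
        raise ConfigError("no retained groups to match")
    run.matched = match_controls(groups, run.participants, seed=_cell_seed(run.seed, "match"))
    copts = run.cfg.get("classify", {})
    if copts.get("subsample_to_min", False):
        smallest = min(run.matched.values(), key=lambda mc: len(mc.pairs))
        ref = run.participants.set_index("id").loc[smallest.case_ids].reset_index()
        target = len(smallest.pairs)
        run.matched = {
            lb: (
                mc
                if lb == smallest.label
                else subsample_to_reference(
                    mc, ref, run.participants, target_n=target, seed=_cell_seed(run.seed, "sub", lb)
                )
            )
            for lb, mc in run.matched.items()
        }
    frames = [mc.to_frame(run.participants) for mc in run.matched.values()]
    pd.concat(frames, ignore_index=True).to_csv(run.out / "matches.csv", index=False)
    balance = {}
    for lb, mc in run.matched.items():
        rep = balance_report(mc, run.participants)
        balance[lb] = {
            "sex_chi2_p": rep.sex_chi2_p,
            "age_p": rep.age_p,
            "motion_p": rep.motion_p,
            "site_p": rep.site_p,
            "degenerate": list(rep.degenerate),
        }
    (run.out / "balance.json").write_text(json.dumps(balance, indent=1, sort_keys=True))


def _classify_opts(run: _Run) -> dict:
    opts = run.cfg.get("classify", {})
    fsets = opts.get("feature_sets") or sorted(run.features)
    models = [MODEL_ALIASES.get(m) for m in opts.get("models", ["rf"])]
    if None in models:
        raise ConfigError(f"unknown model alias in {opts.get('models')}")
    return {
        "feature_sets": fsets,
        "models": models,
        "n_splits": int(opts.get("n_splits", 100)),
        "train_fraction": float(opts.get("train_fraction", 0.8)),
        "inner_folds": int(opts.get("inner_folds", 5)),
        "tuning_grid": opts.get("tuning_grid"),
        "fixed_settings": opts.get("fixed_settings"),
    }


def _stage_classify(run: _Run) -> None:
    opts = _classify_opts(run)
    for label, mc in sorted(run.matched.items()):
        ids = mc.all_ids
        y = np.r_[np.ones(len(mc.pairs), int), np.zeros(len(mc.pairs), int)]
        for fs in opts["feature_sets"]:
            X = run.feature_rows(fs, ids)
            for fam in opts["models"]:
                model = make_model(fam, opts["fixed_settings"], opts["tuning_grid"])
                acc = run_binary(
                    X,
                    y,
                    model,
                    n_splits=opts["n_splits"],
                    train_fraction=opts["train_fraction"],
                    inner_folds=opts["inner_folds"],
                    seed=_cell_seed(run.seed, "classify", label, fs, fam),
                    group=label,
                    feature_set=fs,
                )
                run.cells[(label, fs, fam)] = acc
                run.acc_frames.append(acc.to_frame())
    pd.concat(run.acc_frames, ignore_index=True).to_csv(run.out / "accuracies.csv", index=False)


def _stage_infer(run: _Run) -> None:
    opts = run.cfg.get("infer", {})
    alpha = float(opts.get("alpha", 0.05))
    scope = opts.get("correction_scope") or _classify_opts(run)["feature_sets"]
    results = {key: chance_test(acc, alpha=alpha) for key, acc in run.cells.items()}
    table = build_results_table(
        results, scope, alpha=alpha, trend_alpha=float(opts.get("trend_alpha", 0.10))
    )
    table.to_csv(run.out / "results.csv", index=False)


def _stage_multiclass(run: _Run) -> None:
    opts = run.cfg.get("multiclass", {})
    unique = unique_case_list(run.retained)
    controls = sorted({c for mc in run.matched.values() for c in mc.control_ids})
    ids, labels = build_multiclass_cohort(
        unique,
        controls,
        n_per_class=opts.get("n_per_class"),
        seed=_cell_seed(run.seed, "multiclass"),
    )
    fs = opts.get("feature_set") or sorted(run.features)[0]
    cm = run_multiclass(
        run.feature_rows(fs, ids),
        labels,
        seed=_cell_seed(run.seed, "multiclass", fs),
        n_repeats=int(opts.get("n_repeats", 5)),
        n_folds=int(opts.get("n_folds", 5)),
        n_estimators=int(opts.get("n_estimators", 250)),
        pca_rank=int(opts.get("pca_rank", 50)),
    )
    cm.to_frame().to_csv(run.out / "confusion.csv", index=False)


def _stage_logo(run: _Run) -> None:
    opts = run.cfg.get("logo", {})
    fs = opts.get("feature_set") or sorted(run.features)[0]
    fam = MODEL_ALIASES.get(opts.get("model", "rf"))
    copts = _classify_opts(run)
    site_of = run.participants.set_index("id")["site"]
    payload = {}
    for label, mc in sorted(run.matched.items()):
        ids = mc.all_ids
        y = np.r_[np.ones(len(mc.pairs), int), np.zeros(len(mc.pairs), int)]
        model = make_model(fam, copts["fixed_settings"], copts["tuning_grid"])
        per_site, mean = run_logo(
            run.feature_rows(fs, ids),
            y,
            site_of.loc[ids].to_numpy(),
            model,
            inner_folds=copts["inner_folds"],
            seed=_cell_seed(run.seed, "logo", label, fs, fam),
        )
        payload[label] = {"per_site": {str(k): v for k, v in per_site.items()}, "mean": mean}
    (run.out / "logo.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _stage_age_bench(run: _Run) -> None:
    opts = run.cfg.get("age_bench", {})
    sizes = sorted(g.n_cases for g in run.retained)
    eligible = {pid for g in run.retained for pid in g.case_ids}
    eligible |= set(healthy_pool(run.participants))
    pool = run.participants[run.participants["id"].isin(eligible)]
    # defaults track the largest/smallest diagnostic group but are capped by
    # what the cohort's age-extreme tails can supply; explicit sizes are not
    capacity = 2 * pair_capacity(pool)
    n_large = int(opts.get("n_large", min(2 * sizes[-1], capacity) // 2 * 2))
    n_small = int(opts.get("n_small", min(2 * sizes[0], n_large) // 2 * 2))
    spec = AgeBenchmarkSpec(
        n_large=n_large,
        n_small=n_small,
        small_from_large=bool(opts.get("small_from_large", False)),
    )
    large, small = build_age_groups(
        run.participants, spec, eligible, seed=_cell_seed(run.seed, "age")
    )
    pd.concat([large, small], ignore_index=True).to_csv(run.out / "age_groups.csv", index=False)
    copts = _classify_opts(run)
    frames = []
    age_cells = {}
    for arm_name, arm in (("age_large", large), ("age_small", small)):
        ids, y = age_labels(arm)
        for fs in copts["feature_sets"]:
            for fam in copts["models"]:
                model = make_model(fam, copts["fixed_settings"], copts["tuning_grid"])
                acc = run_binary(
                    run.feature_rows(fs, ids),
                    y,
                    model,
                    n_splits=copts["n_splits"],
                    train_fraction=copts["train_fraction"],
                    inner_folds=copts["inner_folds"],
                    seed=_cell_seed(run.seed, "age", arm_name, fs, fam),
                    group=arm_name,
                    feature_set=fs,
                )
                frames.append(acc.to_frame())
                age_cells[(arm_name, fs, fam)] = chance_test(acc)
    pd.concat(frames, ignore_index=True).to_csv(run.out / "age_accuracies.csv", index=False)
    table = build_results_table(age_cells, copts["feature_sets"])
    table.to_csv(run.out / "age_results.csv", index=False)


_STAGE_FNS = {
    "groups": _stage_groups,
    "match": _stage_match,
    "classify": _stage_classify,
    "infer": _stage_infer,
    "multiclass": _stage_multiclass,
    "logo": _stage_logo,
    "age_bench": _stage_age_bench,
}


def run_pipeline(config, out_dir: str | Path) -> Path:
    """Execute a full run; returns the output directory.

    Writes a ``manifest.json`` with the configuration hash, seed, package
    version, timestamps, and per-stage status.  A stage failure raises
    :class:`~transdx.errors.StageError` after recording partial outputs.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": cfg["seed"],
        "transdx_version": __version__,
        "started": _utcnow(),
        "stages": [],
    }
    run = _Run(cfg, out)
    try:
        _stage_cohort(run)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        manifest["stages"].append({"stage": "cohort", "status": f"failed: {exc}"})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError("cohort", str(exc)) from exc
    manifest["stages"].append({"stage": "cohort", "status": "ok"})
    for stage in cfg["stages"]:
        try:
            _STAGE_FNS[stage](run)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            manifest["stages"].append({"stage": stage, "status": f"failed: {exc}"})
            manifest["finished"] = _utcnow()
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(stage, str(exc)) from exc
        manifest["stages"].append({"stage": stage, "status": "ok"})
    manifest["finished"] = _utcnow()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
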