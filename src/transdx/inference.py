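"""Conservative chance-level significance testing for split accuracies.

The decision statistic for one (group × feature set × model) cell is

    t = (sample mean accuracy - chance) / sample standard deviation

evaluated against the upper tail of a Student-t distribution whose degrees
of freedom equal the *number of shuffle-splits*.  Two deliberate departures
from a textbook one-sample t-test are part of the criterion's definition:

* the denominator is the standard deviation of the split accuracies, not
  the standard error of their mean.  The question being asked is whether a
  *single* re-drawn validation split of this dataset would classify above
  chance, not whether the population mean accuracy exceeds chance, and the
  missing factor of sqrt(n) makes the criterion strictly more conservative
  than the t-test whenever the mean is above chance;
* the degrees of freedom are the split count n, not n - 1.

Multiple-comparison control across feature sets is Benjamini-Hochberg FDR,
applied within each diagnostic group (never across groups).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of the chance-level criterion for one cell.

    ``p_fdr`` and ``significant`` are populated once the cell has been
    corrected within its feature-set family; ``degenerate`` flags the
    zero-variance limits where the t statistic is undefined.
    """

    mean_accuracy: float
    std_accuracy: float
    t_value: float
    df: int
    p_uncorrected: float
    p_fdr: float | None = None
    significant: bool | None = None
    degenerate: bool = False


def _as_array(accuracies) -> np.ndarray:
    acc = getattr(accuracies, "accuracies", accuracies)
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 1 or acc.size < 2:
        raise ConfigError("need a vector of at least 2 split accuracies")
    if np.any((acc < 0) | (acc > 1)):
        raise ConfigError("accuracies must lie in [0, 1]")
    return acc


def chance_test(accuracies, chance: float = 0.5, alpha: float = 0.05) -> SignificanceResult:
    """Apply the standard-deviation chance criterion to one accuracy vector.

    ``accuracies`` may be a plain vector or any object exposing an
    ``accuracies`` attribute (e.g. :class:`transdx.classify.SplitAccuracies`).
    Returns the uncorrected result; FDR fields are filled by
    :func:`build_results_table`.
    """
    acc = _as_array(accuracies)
    n = acc.size
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    if np.all(acc == acc[0]):
        # all splits identical: the t statistic degenerates to a sign test
        if mean > chance:
            return SignificanceResult(mean, sd, np.inf, n, 0.0, degenerate=True)
        if mean == chance:
            return SignificanceResult(mean, sd, 0.0, n, 0.5, degenerate=True)
        return SignificanceResult(mean, sd, -np.inf, n, 1.0, degenerate=True)
    t = (mean - chance) / sd
    p = float(stats.t.sf(t, df=n))
    return SignificanceResult(mean, sd, t, n, p)


def one_sample_ttest_p(accuracies, chance: float = 0.5) -> float:
    """Upper-tail p of the ordinary one-sample t-test against chance.

    Provided for stringency comparisons: for any vector with mean above
    chance this is never larger than the :func:`chance_test` p-value,
    because the two statistics differ by a factor of sqrt(n) in the
    denominator.
    """
    acc = _as_array(accuracies)
    return float(stats.ttest_1samp(acc, chance, alternative="greater").pvalue)


def fdr_correct(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(adjusted p-values, significance flags)`` with flags defined
    as ``adjusted < alpha``.  An empty input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def build_results_table(
    cells: Mapping[tuple[str, str, str], SignificanceResult],
    correction_scope: Mapping[str, Sequence[str]] | Sequence[str],
    alpha: float = 0.05,
    trend_alpha: float = 0.10,
) -> pd.DataFrame:
    """Assemble the tidy results table with within-group FDR correction.

    Parameters
    ----------
    cells
        Map ``(group, feature_set, model)`` → uncorrected
        :class:`SignificanceResult`.
    correction_scope
        The feature sets forming each group's correction family: either one
        list applied to every group, or a map group → list.  Correction is
        performed within each observed (group, model) pair across exactly
        these feature sets — never across groups; a scope naming a missing
        cell is an error.

    Returns
    -------
    DataFrame with columns ``group, feature_set, model, n_splits, mean_acc,
    std_acc, t, p_uncorrected, p_fdr, significant, trend`` where
    ``significant`` means ``p_fdr < alpha`` and ``trend`` means
    ``alpha <= p_fdr < trend_alpha``.
    """
    pairs = sorted({(g, m) for g, _, m in cells})
    if not isinstance(correction_scope, Mapping):
        correction_scope = {g: list(correction_scope) for g, _ in pairs}
    rows = []
    for group, model in pairs:
        scope = list(correction_scope.get(group, []))
        if not scope:
            raise ConfigError(f"no correction scope given for group {group}")
        keyed = []
        for fs in scope:
            key = (group, fs, model)
            if key not in cells:
                raise ConfigError(f"correction scope names missing cell {key}")
            keyed.append((fs, cells[key]))
        p_adj, flags = fdr_correct([r.p_uncorrected for _, r in keyed], alpha=alpha)
        for (fs, res), p_c, sig in zip(keyed, p_adj, flags):
            corrected = replace(res, p_fdr=float(p_c), significant=bool(sig))
            rows.append(
                {
                    "group": group,
                    "feature_set": fs,
                    "model": model,
                    "n_splits": corrected.df,
                    "mean_acc": corrected.mean_accuracy,
                    "std_acc": corrected.std_accuracy,
                    "t": corrected.t_value,
                    "p_uncorrected": corrected.p_uncorrected,
                    "p_fdr": corrected.p_fdr,
                    "significant": corrected.significant,
                    "trend": bool(alpha <= p_c < trend_alpha),
                }
            )
    return pd.DataFrame(rows)
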