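"""Group summaries and hypothesis tests used across all metrics tables.

Group differences are tested with a two-tailed Student's t-test on
log-transformed values (pooled variance by default, Welch by flag); raw-scale
means ± SEM are reported alongside, since the log transform serves only the
test.  The log base does not affect t or p.  No multiple-testing correction
is applied across the per-pulse tests, mirroring the per-parameter reporting
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, ParameterError


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    percent_difference: float  # of group b relative to group a
    test: str = "pooled"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def _check_positive(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    bad = np.nonzero(~(values > 0))[0]
    if bad.size:
        raise InputError(
            f"log transform requires positive values; {name} has "
            f"non-positive entries at indices {bad[:10].tolist()}"
        )
    return values


def log_t_test(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample two-tailed t-test on natural-log values.

    Raw-scale means and SEMs are reported; ``percent_difference`` is
    100·(mean_b - mean_a)/mean_a.  Non-positive values are an error naming
    the offending records — no silent offset is applied.
    """
    a = _check_positive(a, labels[0])
    b = _check_positive(b, labels[1])
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values for a t-test")
    t_stat, p_val = sps.ttest_ind(np.log(a), np.log(b), equal_var=equal_var)
    return GroupComparison(
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        t=float(t_stat),
        p=float(p_val),
        percent_difference=percent_increase(float(b.mean()), float(a.mean())),
        test="pooled" if equal_var else "welch",
    )


def pearson_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment r with the two-tailed p from its t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("correlation undefined: a variable has zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size))


def percent_increase(mean_b: float, mean_a: float) -> float:
    """100·(mean_b - mean_a)/mean_a."""
    if mean_a <= 0:
        raise ParameterError("reference mean must be positive")
    return 100.0 * (mean_b - mean_a) / mean_a


def compare_metric_by_pulse(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    labels: tuple[str, str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """One log-t-test per pulse on a tidy dendrite × pulse metrics table."""
    if labels is None:
        found = sorted(table[group_col].unique())
        if len(found) != 2:
            raise InputError(f"expected exactly 2 groups, found {found}")
        labels = (str(found[0]), str(found[1]))
    rows = []
    for pulse, sub in table.groupby("pulse"):
        a = sub.loc[sub[group_col].astype(str) == labels[0], metric].dropna()
        b = sub.loc[sub[group_col].astype(str) == labels[1], metric].dropna()
        cmp_ = log_t_test(a.to_numpy(), b.to_numpy(), labels=labels,
                          equal_var=equal_var)
        row = {"metric": metric, "pulse": pulse}
        row.update(cmp_.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
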