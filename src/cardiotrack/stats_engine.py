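"""Statistical layer: exact Fisher test, Welch t, ANOVA/Tukey, summaries.

The Fisher test is implemented in log space with exact log-factorials so
that extreme p-values (down to ~1e-300) retain at least three significant
figures; genotype--phenotype association tables in transgenesis screens
routinely produce p-values far below what naive summation of float
hypergeometric probabilities handles gracefully.  The t-test defaults to
Welch's unequal-variance form, and one-way ANOVA is followed by Tukey HSD
with compact-letter-display labels for figure-style reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp


@dataclass
class GroupComparison:
    """Result of one hypothesis test between labelled groups."""

    method: str                # "t" | "anova" | "tukey" | "fisher"
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    unit: str = "cell"         # unit of analysis: "cell" | "embryo" | "event"
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "groups": list(self.groups),
            "unit": self.unit,
            "n": list(self.n),
            **({"extra": self.extra} if self.extra else {}),
        }


@dataclass
class DistributionSummary:
    """Mean/SEM plus box-whisker quantities (whiskers = full data range)."""

    n: int
    mean: float
    sem: float                 # NaN when n == 1
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if not np.all(t == np.floor(t)) or np.any(t < 0):
        raise ValueError("contingency table entries must be non-negative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("contingency table is empty")
    return t


def fisher_exact(table, rel_tol: float = 1e-7, unit: str = "embryo") -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities of every table
    with the observed margins whose probability is at most that of the
    observed table (within relative tolerance ``rel_tol`` on the
    comparison, to absorb rounding in the log-space probabilities --
    the convention of R's fisher.test).  All arithmetic is in log space
    with exact log-factorials.  The reported statistic is the sample
    odds ratio (inf when b*c == 0 and a*d > 0).
    """
    t = _check_table(table)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logfact(k):
        return gammaln(np.asarray(k, dtype=float) + 1.0)

    log_norm = logfact(r1) + logfact(r2) + logfact(c1) + logfact(n - c1) - logfact(n)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = log_norm - (
        logfact(support) + logfact(r1 - support)
        + logfact(c1 - support) + logfact(r2 - c1 + support)
    )
    log_obs = logpmf[support == a][0]
    keep = logpmf <= log_obs + math.log1p(rel_tol)
    p = float(min(1.0, math.exp(logsumexp(logpmf[keep]))))
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return GroupComparison(
        method="fisher", statistic=odds, p_value=p, unit=unit,
        n=(r1, r2), extra={"table": t.tolist()},
    )


def two_sample_t(x: Sequence[float], y: Sequence[float], unit: str = "embryo",
                 equal_var: bool = False,
                 groups: tuple[str, str] = ("group1", "group2")) -> GroupComparison:
    """Two-sided two-sample t-test; Welch's unequal-variance form by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        method="t", statistic=float(res.statistic), p_value=float(res.pvalue),
        groups=groups, unit=unit, n=(len(x), len(y)),
        extra={"df": float(res.df), "equal_var": equal_var,
               "mean_diff": float(x.mean() - y.mean())},
    )


def _compact_letter_display(labels: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Letters such that two groups share a letter iff their pair is in
    ``not_different``.  Letters are the maximal cliques of the
    non-significance graph, assigned alphabetically by sorted clique
    membership (ties broken by group label)."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from(tuple(p) for p in not_different if len(p) == 2)
    cliques = sorted((sorted(c) for c in nx.find_cliques(g)), key=lambda c: (c[0], c))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for lab in clique:
            letters[lab].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


@dataclass
class AnovaTukeyResult:
    anova: GroupComparison
    pairwise: list[GroupComparison]
    letters: dict[str, str]


def one_way_anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05,
                        unit: str = "embryo") -> AnovaTukeyResult:
    """One-way ANOVA (global F) followed by Tukey HSD pairwise tests.

    Requires >= 3 groups of n >= 2 each (use :func:`two_sample_t` for two
    groups).  Pairwise adjusted p-values come from the studentized-range
    distribution; compact-letter-display labels mark groups that do not
    differ at ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError("one-way ANOVA here requires >= 3 groups; use two_sample_t for two")
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    for lab, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")
    f_stat, p = stats.f_oneway(*arrays)
    anova = GroupComparison(
        method="anova", statistic=float(f_stat), p_value=float(p),
        groups=tuple(labels), unit=unit, n=tuple(len(a) for a in arrays),
    )
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    codes = np.concatenate([[lab] * len(arr) for lab, arr in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    from itertools import combinations

    pair_labels = list(combinations([str(g) for g in tk.groupsunique], 2))
    pairwise: list[GroupComparison] = []
    not_different: set[frozenset] = set()
    for (g1, g2), meandiff, p_adj in zip(pair_labels, tk.meandiffs, tk.pvalues):
        pairwise.append(GroupComparison(
            method="tukey", statistic=float(meandiff), p_value=float(p_adj),
            groups=(str(g1), str(g2)), unit=unit,
        ))
        if p_adj > alpha:
            not_different.add(frozenset((str(g1), str(g2))))
    letters = _compact_letter_display(labels, not_different)
    return AnovaTukeyResult(anova=anova, pairwise=pairwise, letters=letters)


def normalize_blot(measurements, control_label: str):
    """Ratiometric immunoblot normalisation.

    ``measurements`` is a DataFrame with columns ``condition``,
    ``p_signal`` (phospho band) and ``total_signal`` (total band).
    Returns a copy with ``ratio = p_signal / total_signal`` and
    ``normalized_ratio = ratio / mean(control ratios)``, so the control
    condition has mean 1 by construction.
    """
    import pandas as pd

    df = pd.DataFrame(measurements).copy()
    for col in ("condition", "p_signal", "total_signal"):
        if col not in df.columns:
            raise ValueError(f"measurements missing column {col!r}")
    if (df["total_signal"] <= 0).any() or (df["p_signal"] <= 0).any():
        raise ValueError("band signals must be positive")
    df["ratio"] = df["p_signal"] / df["total_signal"]
    ctrl = df.loc[df["condition"] == control_label, "ratio"]
    if ctrl.empty:
        raise ValueError(f"no measurements for control condition {control_label!r}")
    df["normalized_ratio"] = df["ratio"] / ctrl.mean()
    return df


def proliferation_index(n_double_positive: int, n_total_positive: int) -> float:
    """Fraction of reporter-positive cells that are also S-phase positive."""
    if n_total_positive <= 0:
        raise ValueError("n_total_positive must be > 0")
    if not 0 <= n_double_positive <= n_total_positive:
        raise ValueError("n_double_positive must be in [0, n_total_positive]")
    return n_double_positive / n_total_positive


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Mean, SEM and box-whisker summary (whiskers span the full range,
    quartiles by linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    n = int(v.size)
    return DistributionSummary(
        n=n,
        mean=float(v.mean()),
        sem=float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        median=float(np.median(v)),
        q25=float(np.quantile(v, 0.25)),
        q75=float(np.quantile(v, 0.75)),
        whisker_low=float(v.min()),
        whisker_high=float(v.max()),
    )
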