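"""Ensemble-level statistical comparisons.

The unit of analysis is one value per independent run (not per snapshot),
so within-run autocorrelation cannot deflate the error estimates. Two
comparison routes are provided, matching common practice: one-way ANOVA
followed by Tukey's range test, and Kruskal–Wallis followed by pairwise
Wilcoxon signed-rank tests with multiple-testing correction (Holm by
default). Bootstrap standard errors of medians (or means) use seeded
resampling. Significance labels follow the star convention
(*: 0.01<p<0.05, **: 0.001<p<0.01, ***: p<0.001); boundary values get the
less significant label.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "anova_tukey", "kruskal_wilcoxon",
           "bootstrap_se", "significance_label", "select_test"]


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus and pairwise results over named groups of per-run values."""

    groups: dict
    omnibus_test: str
    omnibus_p: float
    pairwise: tuple  # of (pair, p, label)
    flagged: tuple = ()  # pairs tested although omnibus p >= 0.05


def significance_label(p: float) -> str:
    """Star label for a p-value; boundaries resolve to the weaker label."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:  # the boundary 0.001 falls to the weaker label
        return "**"
    if p < 0.05:  # likewise 0.01
        return "*"
    return ""


def _validate(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    return out


def anova_tukey(groups: dict) -> GroupComparison:
    """One-way ANOVA omnibus test with Tukey HSD pairwise follow-up."""
    g = _validate(groups)
    arrays = list(g.values())
    names = list(g.keys())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        omnibus_p = 1.0
        pairwise = tuple(((a, b), 1.0, "") for a, b in combinations(names, 2))
        return GroupComparison(groups=g, omnibus_test="anova", omnibus_p=omnibus_p,
                               pairwise=pairwise)
    f, omnibus_p = sps.f_oneway(*arrays)
    if np.isnan(omnibus_p):
        omnibus_p = 1.0
    hsd = sps.tukey_hsd(*arrays)
    pairwise, flagged = [], []
    for i, j in combinations(range(len(names)), 2):
        p = float(hsd.pvalue[i, j])
        pairwise.append(((names[i], names[j]), p, significance_label(p)))
        if omnibus_p >= 0.05:
            flagged.append((names[i], names[j]))
    return GroupComparison(groups=g, omnibus_test="anova", omnibus_p=float(omnibus_p),
                           pairwise=tuple(pairwise), flagged=tuple(flagged))


def kruskal_wilcoxon(groups: dict, paired: bool = True,
                     correction: str = "holm") -> GroupComparison:
    """Kruskal–Wallis omnibus with pairwise Wilcoxon follow-up.

    In paired mode (run-index pairing; requires equal group sizes) the
    signed-rank test is used; otherwise Mann–Whitney U. Pairwise p-values
    are adjusted with the configured correction.
    """
    g = _validate(groups)
    arrays = list(g.values())
    names = list(g.keys())
    if paired and len({len(a) for a in arrays}) != 1:
        raise ValueError("paired mode requires equal group sizes")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        omnibus_p = 1.0
    else:
        _, omnibus_p = sps.kruskal(*arrays)
    raw = []
    for i, j in combinations(range(len(names)), 2):
        a, b = arrays[i], arrays[j]
        if paired:
            if np.all(a == b):
                p = 1.0
            else:
                p = float(sps.wilcoxon(a, b).pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        raw.append(p)
    adjusted = multipletests(raw, method=correction)[1] if raw else []
    pairwise, flagged = [], []
    for k, (i, j) in enumerate(combinations(range(len(names)), 2)):
        p = float(min(1.0, adjusted[k]))
        pairwise.append(((names[i], names[j]), p, significance_label(p)))
        if omnibus_p >= 0.05:
            flagged.append((names[i], names[j]))
    return GroupComparison(groups=g, omnibus_test="kruskal", omnibus_p=float(omnibus_p),
                           pairwise=tuple(pairwise), flagged=tuple(flagged))


def bootstrap_se(values: Sequence[float], statistic: str | Callable = "median",
                 n_boot: int = 10_000, seed: int = 0) -> float:
    """Bootstrap standard error of a statistic (median or mean) of a sample."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if callable(statistic):
        fn = statistic
    elif statistic == "median":
        fn = np.median
    elif statistic == "mean":
        fn = np.mean
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    stats = np.apply_along_axis(fn, 1, values[idx]) if callable(statistic) \
        else (np.median(values[idx], axis=1) if statistic == "median"
              else np.mean(values[idx], axis=1))
    return float(np.std(stats, ddof=0))


def select_test(groups: dict, alpha: float = 0.05) -> str:
    """'anova' if every group passes Shapiro–Wilk and Levene holds, else 'kruskal'."""
    g = _validate(groups)
    for v in g.values():
        if np.ptp(v) == 0:
            return "kruskal"
        if sps.shapiro(v).pvalue < alpha:
            return "kruskal"
    if sps.levene(*g.values()).pvalue < alpha:
        return "kruskal"
    return "anova"
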