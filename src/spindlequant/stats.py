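"""Statistical summaries and tests for grouped per-cell measurements.

The conventions of the upstream analyses: mean +/- SEM for descriptive
summaries; Student's t or Mann-Whitney U for two groups; one-way ANOVA with
Tukey's multiple comparison or Kruskal-Wallis with Dunn's multiple
comparison for three or more; significance at p < 0.05.

Dunn's post-hoc test is implemented here directly (rank-based z statistics
with tie correction); the family-wise adjustment is Bonferroni by default
and switchable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import SchemaError

ALPHA = 0.05


@dataclass
class GroupedMeasurements:
    """Labeled measurement groups, optionally with replicate ids."""

    groups: dict[str, np.ndarray]
    replicates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for k, v in self.groups.items():
            if v.size < 1:
                raise SchemaError(f"group {k!r} is empty")


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise SchemaError("SEM needs n >= 2")
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(values.size))


def _check_groups(groups: dict, min_groups: int) -> dict:
    if len(groups) < min_groups:
        raise SchemaError(f"need >= {min_groups} groups")
    for k, v in groups.items():
        if len(np.asarray(v)) == 0:
            raise SchemaError(f"group {k!r} is empty")
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def kw_dunn(
    groups: dict, adjust: str = "bonferroni"
) -> tuple[float, float, dict[tuple, float]]:
    """Kruskal-Wallis omnibus test with Dunn's pairwise comparisons.

    Returns ``(H, omnibus_p, {pair: adjusted_p})``.  The omnibus statistic
    is tie-corrected (scipy); Dunn z statistics are computed on the pooled
    ranks with the standard tie correction and adjusted across all pairs
    (``"bonferroni"`` or ``"none"``).
    """
    groups = _check_groups(groups, 3)
    names = list(groups)
    values = [groups[k] for k in names]
    if np.ptp(np.concatenate(values)) == 0:
        # all observations identical: no evidence against the null
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*values)
    pooled = np.concatenate(values)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    rank_means, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        rank_means[name] = float(ranks[start : start + len(v)].mean())
        sizes[name] = len(v)
        start += len(v)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise: dict[tuple, float] = {}
    for a, b in pairs:
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1)))
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        if se == 0:
            pairwise[(a, b)] = 1.0
            continue
        z = (rank_means[a] - rank_means[b]) / se
        p_unadj = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            pairwise[(a, b)] = min(1.0, p_unadj * m)
        elif adjust == "none":
            pairwise[(a, b)] = p_unadj
        else:
            raise SchemaError(f"unknown adjustment {adjust!r}")
    return float(H), float(p), pairwise


def two_sample_tests(
    a, b, sided: str = "two-sided", parametric: bool = True
) -> float:
    """Two-group comparison p value.

    Student's t (``parametric=True``) or Mann-Whitney U; ``sided`` is
    ``"two-sided"``, ``"less"`` or ``"greater"`` (alternative about the
    first sample).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SchemaError("each sample needs n >= 2")
    if sided not in ("two-sided", "less", "greater"):
        raise SchemaError(f"unknown alternative {sided!r}")
    if parametric:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise SchemaError("zero variance in both samples: t-test undefined")
        return float(sps.ttest_ind(a, b, alternative=sided).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative=sided).pvalue)


def anova_tukey(groups: dict) -> tuple[float, float, dict[tuple, float]]:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Returns ``(F, omnibus_p, {pair: adjusted_p})``.  Identical groups give
    F = 0; F is invariant to a grand-mean shift of all groups.
    """
    groups = _check_groups(groups, 3)
    for k, v in groups.items():
        if len(v) < 2:
            raise SchemaError(f"group {k!r} needs n >= 2 for ANOVA")
    names = list(groups)
    values = [groups[k] for k in names]
    if np.ptp(np.concatenate(values)) == 0:
        F, p = 0.0, 1.0
        pairwise = {pair: 1.0 for pair in itertools.combinations(names, 2)}
        return F, p, pairwise
    F, p = sps.f_oneway(*values)
    res = sps.tukey_hsd(*values)
    pairwise = {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i, j in itertools.combinations(range(len(names)), 2)
    }
    return float(F), float(p), pairwise


def permutation_kruskal_p(groups: dict, n_permutations: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo permutation p value for the Kruskal-Wallis H statistic.

    Independent oracle for the asymptotic omnibus p: labels are permuted
    and H recomputed from first principles (rank means), not via the
    analysis path.
    """
    groups = _check_groups(groups, 2)
    values = [groups[k] for k in groups]
    sizes = [len(v) for v in values]
    pooled = np.concatenate(values)
    n = len(pooled)

    def h_stat(ranks):
        out = 0.0
        start = 0
        for size in sizes:
            r = ranks[start : start + size]
            out += size * (r.mean() - (n + 1) / 2.0) ** 2
            start += size
        h = 12.0 / (n * (n + 1)) * out
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
        return h / tie if tie > 0 else 0.0

    ranks = sps.rankdata(pooled)
    observed = h_stat(ranks)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    rng = np.random.default_rng(seed)
    count = 0
    bounds = np.cumsum([0] + sizes)
    batch = 10_000
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perm = np.argsort(rng.random((b, n)), axis=1)
        r = ranks[perm]
        h = np.zeros(b)
        for lo, hi, size in zip(bounds[:-1], bounds[1:], sizes):
            h += size * (r[:, lo:hi].mean(axis=1) - (n + 1) / 2.0) ** 2
        h *= 12.0 / (n * (n + 1))
        if tie > 0:
            h /= tie
        count += int(np.sum(h >= observed - 1e-12))
        done += b
    return (count + 1) / (n_permutations + 1)
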