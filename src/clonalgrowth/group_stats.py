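"""Group comparison: homogeneity check, (Welch) ANOVA, post hoc letters.

The comparison protocol mirrors common practice in plant-trait studies:
Brown-Forsythe (median-centred Levene) homogeneity check first; classic
one-way ANOVA with Fisher's LSD post hoc when variances are homogeneous
(p > 0.05), otherwise Welch's F with Games-Howell post hoc. Pairwise
outcomes are summarised as a compact letter display: groups sharing a
letter do not differ at the 0.05 level.

Classic F and the homogeneity statistic come from scipy; Welch's F, LSD
and Games-Howell are short closed forms over scipy's F, t and
studentized-range distributions and are written out here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ContractError

__all__ = [
    "HomogeneityResult",
    "PosthocResult",
    "GroupComparison",
    "variance_homogeneity",
    "oneway_f",
    "posthoc_letters",
    "compare_groups",
]

ALPHA = 0.05
MARGINAL = 0.10


def _as_groups(samples_by_group: Dict[str, Sequence[float]], min_n: int = 2):
    if len(samples_by_group) < 2:
        raise ContractError("need at least 2 groups")
    labels = list(samples_by_group)
    groups = [np.asarray(samples_by_group[g], dtype=float) for g in labels]
    for g, arr in zip(labels, groups):
        if len(arr) < min_n:
            raise ContractError(f"group {g!r} has n < {min_n}")
    return labels, groups


@dataclass(frozen=True)
class HomogeneityResult:
    statistic: float
    pvalue: float


def variance_homogeneity(samples_by_group: Dict[str, Sequence[float]]) -> HomogeneityResult:
    """Brown-Forsythe test (Levene on deviations from group medians)."""
    _, groups = _as_groups(samples_by_group)
    if all(np.ptp(g) == 0 for g in groups):
        # every group internally constant: zero spread everywhere
        return HomogeneityResult(0.0, 1.0)
    stat, p = stats.levene(*groups, center="median")
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return HomogeneityResult(float(stat), float(p))


def oneway_f(
    samples_by_group: Dict[str, Sequence[float]], welch: bool = False
) -> Tuple[float, float, float, float]:
    """One-way F test across groups; returns (F, df1, df2, p).

    ``welch=True`` computes Welch's heteroscedastic F with
    Satterthwaite denominator degrees of freedom.
    """
    _, groups = _as_groups(samples_by_group)
    k = len(groups)
    if not welch:
        n_tot = sum(len(g) for g in groups)
        stat, p = stats.f_oneway(*groups)
        if not np.isfinite(stat):  # all values identical
            stat, p = 0.0, 1.0
        return float(stat), float(k - 1), float(n_tot - k), float(p)

    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        v = np.maximum(v, 1e-300)
    w = n / v
    W = w.sum()
    mw = float((w * m).sum() / W)
    A = float((w * (m - mw) ** 2).sum() / (k - 1))
    frac = float((((1.0 - w / W) ** 2) / (n - 1)).sum())
    B = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * frac
    F = A / B
    df2 = (k**2 - 1.0) / (3.0 * frac) if frac > 0 else np.inf
    p = float(stats.f.sf(F, k - 1, df2))
    return float(F), float(k - 1), float(df2), p


def _pairwise_lsd(groups: List[np.ndarray]) -> np.ndarray:
    """Fisher's LSD: pooled-variance pairwise t using the ANOVA MSE df."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - k)
    df = N - k
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            se = np.sqrt(mse * (1.0 / n[i] + 1.0 / n[j]))
            if se == 0:
                pij = 1.0 if diff == 0 else 0.0
            else:
                t = abs(diff) / se
                pij = float(2.0 * stats.t.sf(t, df))
            p[i, j] = p[j, i] = pij
    return p


def _pairwise_games_howell(groups: List[np.ndarray]) -> np.ndarray:
    """Games-Howell: Welch pairwise t against the studentized range."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            if se2 == 0:
                pij = 1.0 if m[i] == m[j] else 0.0
            else:
                t = abs(m[i] - m[j]) / np.sqrt(se2)
                df = se2**2 / (
                    (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
                )
                pij = float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))
            p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


def _compact_letters(
    labels: List[str], means: np.ndarray, pmat: np.ndarray, alpha: float
) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    Letters are assigned alphabetically starting from the group with the
    largest mean; groups share a letter iff no pairwise test between any
    two members of that letter's set is significant.
    """
    k = len(labels)
    order = list(np.argsort(-means))  # indices, largest mean first
    sets: List[set] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if pmat[a, b] <= alpha:
                new_sets = []
                for s in sets:
                    if a in s and b in s:
                        new_sets.append(s - {a})
                        new_sets.append(s - {b})
                    else:
                        new_sets.append(s)
                # absorb subsets
                sets = [
                    s
                    for s in new_sets
                    if s and not any(s < t for t in new_sets if t is not s)
                ]
                # dedupe
                uniq = []
                for s in sets:
                    if s not in uniq:
                        uniq.append(s)
                sets = uniq
    # order letter groups by their best-ranked (largest-mean) member
    sets.sort(key=lambda s: min(order.index(i) for i in s))
    letters = {lab: "" for lab in labels}
    for ch_i, s in enumerate(sets):
        ch = chr(ord("a") + ch_i)
        for i in sorted(s, key=lambda i: order.index(i)):
            letters[labels[i]] += ch
    return letters


@dataclass(frozen=True)
class PosthocResult:
    labels: List[str]
    p_matrix: np.ndarray
    letters: Dict[str, str]
    method: str


def posthoc_letters(
    samples_by_group: Dict[str, Sequence[float]],
    method: str = "lsd",
    alpha: float = ALPHA,
) -> PosthocResult:
    """Pairwise post hoc p-matrix and compact letter display.

    ``method`` is ``"lsd"`` (pooled-variance pairwise t on the ANOVA MSE
    df) or ``"games-howell"`` (Welch-Satterthwaite pairwise t referred to
    the studentized range).
    """
    labels, groups = _as_groups(samples_by_group)
    if method == "lsd":
        pmat = _pairwise_lsd(groups)
    elif method == "games-howell":
        pmat = _pairwise_games_howell(groups)
    else:
        raise ContractError(f"unknown post hoc method {method!r}")
    means = np.array([g.mean() for g in groups])
    letters = _compact_letters(labels, means, pmat, alpha)
    return PosthocResult(labels=labels, p_matrix=pmat, letters=letters, method=method)


@dataclass(frozen=True)
class GroupComparison:
    """Full comparison record for one parameter across groups."""

    parameter: str
    groups: List[str]
    n_per_group: List[int]
    means: List[float]
    sds: List[float]
    homogeneity_p: float
    method: str  # "classic_anova+LSD" or "welch+games_howell"
    F: float
    df1: float
    df2: float
    p: float
    letters: Dict[str, str]
    marginal: bool  # 0.05 < p < 0.10
    low_power: bool  # some group has n <= 2


def compare_groups(
    parameter: str,
    samples_by_group: Dict[str, Sequence[float]],
    alpha: float = ALPHA,
) -> GroupComparison:
    """Run the full protocol for one parameter and return the record."""
    labels, groups = _as_groups(samples_by_group)
    hom = variance_homogeneity(samples_by_group)
    heteroscedastic = hom.pvalue <= alpha
    F, df1, df2, p = oneway_f(samples_by_group, welch=heteroscedastic)
    post = posthoc_letters(
        samples_by_group,
        method="games-howell" if heteroscedastic else "lsd",
        alpha=alpha,
    )
    return GroupComparison(
        parameter=parameter,
        groups=labels,
        n_per_group=[len(g) for g in groups],
        means=[float(g.mean()) for g in groups],
        sds=[float(g.std(ddof=1)) for g in groups],
        homogeneity_p=hom.pvalue,
        method="welch+games_howell" if heteroscedastic else "classic_anova+LSD",
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        letters=post.letters,
        marginal=bool(alpha < p < MARGINAL),
        low_power=any(len(g) <= 2 for g in groups),
    )
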