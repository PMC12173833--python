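"""Two-group and multi-group statistics for species trait comparisons.

The Mann–Whitney U here is oriented: U counts (second-group, first-group)
value pairs in which the second group's value is larger, with half credit
for ties, so supplying the non-pollinator group second reproduces the
published orientation.  The exact two-sided p-value enumerates every
possible group assignment of the observed values and doubles the observed
one-sided tail; the asymptotic Z uses the tie-corrected normal variance
with no continuity correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "MWUResult",
    "TTestResult",
    "AnovaTukeyResult",
    "mann_whitney",
    "one_sample_t",
    "anova_tukey",
]


@dataclass
class MWUResult:
    U: float  # pairs where the second group's value exceeds the first's (+0.5/tie)
    Z: float
    p_exact: float | None
    p_asymptotic: float
    n1: int
    n2: int
    exact: bool


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    ci95: tuple[float, float]
    cohens_d: float
    relative_elevation: float  # percent change of the mean relative to mu0


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj
    letters: dict[str, str]  # compact letter display


def _pair_u(a: np.ndarray, b: np.ndarray) -> float:
    """Count of (b, a) pairs with b > a, plus 0.5 per tie."""
    diff = b[:, None] - a[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _tie_sigma(pooled: np.ndarray, n1: int, n2: int) -> float:
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1))
    var = (n1 * n2 / 12.0) * ((N + 1) - tie_term)
    return float(np.sqrt(var))


def mann_whitney(
    values_a,
    values_b,
    max_enumeration: int = 1_000_000,
) -> MWUResult:
    """Mann–Whitney U of group B over group A with exact enumeration p.

    U is the number of (B, A) pairs where the B value is larger (ties count
    0.5).  When C(n1+n2, n2) <= ``max_enumeration`` the exact two-sided p is
    computed by complete enumeration of group assignments of the observed
    values (two-sided = doubled one-sided tail in the observed direction);
    otherwise the tie-corrected normal approximation is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    U = _pair_u(a, b)
    pooled = np.concatenate([a, b])
    sigma = _tie_sigma(pooled, n1, n2)
    mu = n1 * n2 / 2.0
    if sigma == 0:
        warnings.warn("all values identical; Z and p are undefined", stacklevel=2)
        return MWUResult(U, np.nan, None, np.nan, n1, n2, exact=False)
    Z = (U - mu) / sigma  # no continuity correction
    p_asym = 2.0 * stats.norm.sf(abs(Z))
    N = n1 + n2
    n_assign = comb(N, n2)
    if n_assign <= max_enumeration:
        # precompute the pairwise comparison matrix once; U for an
        # assignment S (indices of group B) is sum over j in S, i not in S
        M = (pooled[:, None] > pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        np.fill_diagonal(M, 0.0)
        colsum = M.sum(axis=1)
        ge = le = 0
        for S in itertools.combinations(range(N), n2):
            idx = list(S)
            u = colsum[idx].sum() - M[np.ix_(idx, idx)].sum()
            if u >= U - 1e-9:
                ge += 1
            if u <= U + 1e-9:
                le += 1
        tail = ge if U >= mu else le
        p_exact = min(1.0, 2.0 * tail / n_assign)
        return MWUResult(U, Z, p_exact, float(p_asym), n1, n2, exact=True)
    return MWUResult(U, Z, None, float(p_asym), n1, n2, exact=False)


def one_sample_t(values, mu0: float) -> TTestResult:
    """One-sample t-test with 95% CI, Cohen's d and relative elevation.

    ``relative_elevation`` is the percent excess of the sample mean over
    the reference value: 100 (mean - mu0) / mu0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0:
        warnings.warn("zero variance; t is infinite", stacklevel=2)
        t = np.inf if mean != mu0 else 0.0
        p = 0.0 if mean != mu0 else 1.0
    else:
        t, p = stats.ttest_1samp(x, popmean=mu0)
        t, p = float(t), float(p)
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
    d = (mean - mu0) / sd if sd > 0 else np.inf
    elev = 100.0 * (mean - mu0) / mu0 if mu0 != 0 else np.nan
    return TTestResult(
        t=t, df=df, p=p, mean=mean, sd=sd,
        ci95=(mean - half, mean + half),
        cohens_d=float(d), relative_elevation=float(elev),
    )


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise tests and compact letters.

    Groups sharing a letter are not significantly different at ``alpha``
    under the studentized-range (Tukey HSD) criterion.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    F, p = stats.f_oneway(*arrays)
    data = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(v) for n, v in zip(names, arrays)])
    if np.ptp(data) == 0:
        tukey_frame = pd.DataFrame(
            [
                (g1, g2, 0.0, 1.0)
                for g1, g2 in itertools.combinations(names, 2)
            ],
            columns=["group1", "group2", "meandiff", "p_adj"],
        )
        F = 0.0
        p = 1.0
    else:
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        tukey_frame = pd.DataFrame(
            res.summary().data[1:], columns=[c for c in res.summary().data[0]]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"p-adj": "p_adj"}
        )
    letters = _compact_letters(names, tukey_frame, alpha)
    return AnovaTukeyResult(float(F), float(p), tukey_frame, letters)


def _compact_letters(
    names: list[str], tukey: pd.DataFrame, alpha: float
) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff they belong to a
    common maximal clique of the 'not significantly different' graph."""
    ns_pairs = {
        frozenset((r.group1, r.group2))
        for r in tukey.itertuples()
        if r.p_adj >= alpha
    }

    def compatible(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) in ns_pairs
            for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for size in range(len(names), 0, -1):
        for subset in itertools.combinations(names, size):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    letters = {n: "" for n in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for n in clique:
            letters[n] += letter
    return letters
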