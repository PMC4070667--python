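"""Alpha/beta diversity and PCA ordination on OTN pattern tables.

Shannon–Wiener H is reported in nats and Simpson's index in its inverse form
1/sum(p^2) (the effective number of equally abundant OTUs) — the only variants
consistent with the magnitudes such tables produce for thousands of OTUs.
Between-group differences use an exact Mann–Whitney U test (full enumeration
with midrank ties), beta diversity uses chord distances (Euclidean distance
between unit-normalized abundance vectors), and ordination is plain centered
PCA with a cumulative-variance rule for the number of components retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .otn_core import PatternTable

__all__ = [
    "shannon",
    "inverse_simpson",
    "mann_whitney_exact",
    "chord_distance",
    "chord_distance_matrix",
    "Ordination",
    "pca_ordination",
    "diversity_report",
]

_EXACT_LIMIT = 200_000  # largest number of labelings enumerated exactly


def _probs(counts: Sequence[float]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    p = c / total
    return p[p > 0]


def shannon(counts: Sequence[float]) -> float:
    """Shannon–Wiener diversity H = -sum(p ln p), in nats."""
    p = _probs(counts)
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 avoids a signed zero


def inverse_simpson(counts: Sequence[float]) -> float:
    """Inverse Simpson index D = 1/sum(p^2): effective number of equal OTUs."""
    p = _probs(counts)
    return float(1.0 / (p ** 2).sum())


def mann_whitney_exact(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Exact Mann–Whitney U test by enumeration of all group labelings.

    Pooled values receive midranks; ``U`` is the U statistic of ``group_a``.
    The p-value is the exact permutation probability over all
    C(n_a+n_b, n_a) labelings: ``"greater"`` tests A > B via P(U* >= U),
    ``"less"`` tests A < B via P(U* <= U), and ``"two-sided"`` doubles the
    smaller tail (capped at 1). Enumeration is intended for small groups; very
    large problems fall back to the normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")

    na, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    offset = na * (na + 1) / 2
    u_obs = float(ranks[:na].sum() - offset)

    if comb(n, na) > _EXACT_LIMIT:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        return u_obs, float(res.pvalue)

    u_all = np.fromiter(
        (sum(sel) - offset for sel in combinations(ranks, na)),
        dtype=float,
        count=comb(n, na),
    )
    eps = 1e-9
    p_greater = float(np.mean(u_all >= u_obs - eps))
    p_less = float(np.mean(u_all <= u_obs + eps))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return u_obs, p


def chord_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Euclidean distance between unit-normalized abundance vectors; in [0, sqrt(2)]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("chord distance undefined for zero vectors")
    return float(np.linalg.norm(x / nx - y / ny))


def chord_distance_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise chord distances between the sample columns of a count table."""
    samples = list(counts.columns)
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for sa, sb in combinations(samples, 2):
        d = chord_distance(counts[sa].to_numpy(), counts[sb].to_numpy())
        out.loc[sa, sb] = out.loc[sb, sa] = d
    return out


@dataclass
class Ordination:
    """Centered-PCA scores with per-component explained variance fractions.

    ``scores`` holds all components; ``n_components`` is the number retained
    by the cumulative-variance rule (the first k whose variance fractions sum
    to at least the target).
    """

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    loadings: np.ndarray

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_components]


def pca_ordination(table: np.ndarray | pd.DataFrame, var_target: float = 0.5) -> Ordination:
    """PCA of a (binary or count) object x variable matrix after column centering.

    Components are retained until their cumulative explained variance reaches
    ``var_target`` (default 50%). Component signs follow the convention that
    each component's largest-magnitude loading is positive.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 objects and 2 variables")
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise ValueError("matrix has no variance")

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s ** 2
    ratio = var / var.sum()
    n_comp = int(np.searchsorted(np.cumsum(ratio), var_target - 1e-12) + 1)
    n_comp = min(n_comp, len(ratio))
    return Ordination(
        scores=u * s,
        explained_variance_ratio=ratio,
        n_components=n_comp,
        loadings=vt,
    )


def diversity_report(
    table: PatternTable | pd.DataFrame,
    groups: dict[str, str] | None = None,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample Shannon H and inverse Simpson D, with an optional group test.

    ``groups`` maps sample -> group label; when exactly two groups are
    present, an exact Mann–Whitney U test compares them for each index
    (``alternative`` refers to the alphabetically first group vs the second).
    Returns ``(per_sample_table, tests_table_or_None)``.
    """
    counts = table.counts if isinstance(table, PatternTable) else table
    rows = []
    for sample in counts.columns:
        c = counts[sample].to_numpy()
        c = c[c > 0]
        rows.append(
            {
                "sample": sample,
                "shannon_h": shannon(c),
                "inverse_simpson_d": inverse_simpson(c),
                "group": (groups or {}).get(sample, ""),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample")

    tests = None
    if groups:
        names = sorted(set(groups.values()))
        if len(names) == 2:
            ga = per_sample[per_sample["group"] == names[0]]
            gb = per_sample[per_sample["group"] == names[1]]
            recs = []
            for col in ("shannon_h", "inverse_simpson_d"):
                u, p = mann_whitney_exact(ga[col], gb[col], alternative=alternative)
                recs.append({"index": col, "group_a": names[0], "group_b": names[1],
                             "U": u, "p": p, "alternative": alternative})
            tests = pd.DataFrame(recs).set_index("index")
    return per_sample, tests
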