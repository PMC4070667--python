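"""Generation distances from shared-OTN fractions, NJ trees and column bootstrap.

Under neutral evolution an OTN survives a generation of one lineage with
probability ``1 - rate``, so the expected fraction of OTNs still shared by two
profiles decays exponentially in the number of generations ``gen`` separating
them. Inverting the decay gives the distance estimate

    gen = [ln(shared) - ln(total)] / ln(1 - rate)

with ``shared`` the shared-OTN count, ``total`` the summed OTN counts of both
profiles, and ``rate`` the per-generation trinucleotide mutation probability
(default 0.5e-9). By default each shared OTN is counted once per profile
(``shared = 2*|A∩B|``), so identical profiles are at distance zero; the
literal single count is available via ``literal_shared``.

Trees are standard Saitou–Nei neighbor joining on the resulting distance
matrix, with branch support from bootstrap resampling of OTN columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otn_core import OTNMatrix, PatternTable

__all__ = [
    "GenParams",
    "GenerationMatrix",
    "pairwise_generations",
    "generation_matrix",
    "nj_tree",
    "bootstrap_support",
    "tree_bipartitions",
]

logger = logging.getLogger(__name__)


@dataclass
class GenParams:
    """Parameters of the exponential-decay generation distance.

    rate
        Trinucleotide mutation probability per generation (default 0.5e-9,
        the neutral 16S per-position estimate).
    rate_mode
        ``"per_trinucleotide"`` uses ``rate`` as-is; ``"per_position_x3"``
        treats it as a per-position rate and scales by the 3 positions of a
        trinucleotide.
    literal_shared
        Count each shared OTN once in ``shared`` instead of once per profile
        (identical profiles then sit at ln(2)/|ln(1-rate)|, not 0).
    undefined
        What to do with profile pairs sharing no OTN: ``"error"`` (default),
        ``"nan"`` (leave a NaN sentinel) or ``"cap"`` (1.1 x the largest
        finite distance in the matrix).
    """

    rate: float = 0.5e-9
    rate_mode: str = "per_trinucleotide"
    literal_shared: bool = False
    undefined: str = "error"
    cap_factor: float = 1.1

    def __post_init__(self) -> None:
        if not 0.0 < self.rate < 1.0:
            raise ValueError("rate must lie strictly in (0, 1)")
        if self.rate_mode not in ("per_trinucleotide", "per_position_x3"):
            raise ValueError("rate_mode must be 'per_trinucleotide' or 'per_position_x3'")
        if self.undefined not in ("error", "nan", "cap"):
            raise ValueError("undefined must be 'error', 'nan' or 'cap'")

    @property
    def effective_rate(self) -> float:
        return self.rate * 3.0 if self.rate_mode == "per_position_x3" else self.rate


def pairwise_generations(
    a: np.ndarray, b: np.ndarray, params: GenParams | None = None
) -> float:
    """Generations separating two binary OTN profiles over the same column set.

    Returns NaN when the profiles share no OTN (undefined/infinite distance).
    Evaluated as ``log1p((shared-total)/total) / log1p(-rate)`` for numerical
    accuracy near identity and at tiny rates.
    """
    params = params or GenParams()
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles must share one OTN column set")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("empty OTN profile")
    inter = int((a & b).sum())
    if inter == 0:
        return math.nan
    shared = inter if params.literal_shared else 2 * inter
    total = na + nb
    # +0.0 normalizes the signed zero of the identical-profile case
    return math.log1p((shared - total) / total) / math.log1p(-params.effective_rate) + 0.0


@dataclass
class GenerationMatrix:
    """Symmetric pairwise generation distances with NaN sentinels for undefined pairs."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("generation matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("generation matrix must have a zero diagonal")

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.isnan(self.values))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j) if a < b]

    @property
    def max_finite(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(finite.max()) if finite.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _profiles_of(source) -> tuple[list[str], np.ndarray]:
    if isinstance(source, OTNMatrix):
        return [str(i) for i in source.data.index], source.profiles()
    if isinstance(source, PatternTable):
        return source.pattern_ids, source.patterns
    arr = np.asarray(source)
    return [f"t{i}" for i in range(len(arr))], arr


def generation_matrix(
    source: OTNMatrix | PatternTable | np.ndarray,
    params: GenParams | None = None,
    labels: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
) -> GenerationMatrix:
    """All pairwise generation distances between profiles (rows of ``source``).

    ``weights`` (per-column multiplicities, used by the bootstrap) default to
    1. Undefined pairs are handled per ``params.undefined``.
    """
    params = params or GenParams()
    auto_labels, profiles = _profiles_of(source)
    labels = list(labels) if labels is not None else auto_labels
    x = np.asarray(profiles, dtype=np.float64)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need at least two profiles")
    w = np.ones(x.shape[1]) if weights is None else np.asarray(weights, dtype=np.float64)

    sizes = x @ w
    if np.any(sizes == 0):
        raise ValueError("empty OTN profile")
    inter = (x * w) @ x.T
    shared = inter if params.literal_shared else 2.0 * inter
    total = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        gen = np.log1p((shared - total) / total) / math.log1p(-params.effective_rate)
    gen[inter == 0] = np.nan
    np.fill_diagonal(gen, 0.0)

    n_undef = int(np.isnan(gen).sum() // 2)
    if n_undef:
        if params.undefined == "error":
            mat = GenerationMatrix(labels, gen)
            raise ValueError(f"undefined pairs (no shared OTNs): {mat.undefined_pairs}")
        if params.undefined == "cap":
            finite = gen[np.isfinite(gen)]
            cap = params.cap_factor * (finite.max() if finite.size else 1.0)
            gen = np.where(np.isnan(gen), cap, gen)
            logger.info("capped %d undefined pairs at %.3g generations", n_undef, cap)
    mat = GenerationMatrix(labels, gen)
    logger.info("max pairwise distance: %.3g generations", mat.max_finite)
    return mat


def nj_tree(dist: GenerationMatrix | pd.DataFrame) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic (lowest-index pair on ties).

    Negative branch lengths are clamped to zero (and counted in the log).
    Returns an unrooted tree represented with a trifurcating root (or, for two
    taxa, a single split with the distance shared evenly).
    """
    if isinstance(dist, pd.DataFrame):
        dist = GenerationMatrix([str(c) for c in dist.columns], dist.to_numpy(dtype=float))
    d = dist.values.astype(float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes = [TreeNode(name=lab) for lab in dist.labels]
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least two taxa")
    clamped = 0

    def _attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        child.length = float(length)
        parent.append(child)

    if n == 2:
        root = TreeNode()
        _attach(root, nodes[0], d[0, 1] / 2)
        _attach(root, nodes[1], d[0, 1] / 2)
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first (lowest-index) minimum
        i, j = sorted(best)
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = sub[i, j] - li
        u = TreeNode()
        _attach(u, nodes[active[i]], li)
        _attach(u, nodes[active[j]], lj)
        # distances from the new node to every other active node
        new_d = 0.5 * (sub[i, :] + sub[j, :] - sub[i, j])
        gi, gj = active[i], active[j]
        d[gi, :] = 0.0  # row gi is recycled for the new node
        for k, gk in enumerate(active):
            if k in (i, j):
                continue
            d[gi, gk] = d[gk, gi] = new_d[k]
        nodes[gi] = u
        active.pop(j)

    a, b, c = active
    root = TreeNode()
    _attach(root, nodes[a], 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    _attach(root, nodes[b], 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    _attach(root, nodes[c], 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    if clamped:
        logger.info("clamped %d negative branch lengths to zero", clamped)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, one canonical side each.

    The side *not* containing the alphabetically first taxon is reported;
    splits isolating fewer than 2 or more than n-2 taxa are trivial and
    omitted.
    """
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    matrix: OTNMatrix | PatternTable | np.ndarray,
    replicates: int = 100,
    params: GenParams | None = None,
    seed: int = 1,
    labels: Sequence[str] | None = None,
) -> TreeNode:
    """NJ tree with bootstrap support from resampling OTN columns.

    Each replicate draws columns with replacement (same count), recomputes the
    generation matrix and an NJ tree; the support of each internal edge of the
    full-data tree is the percentage of replicates containing its bipartition
    (stored in ``node.support`` and as the internal node name). Replicates in
    which some pair shares no sampled OTN are dropped; more than 20% dropped
    is an error.
    """
    params = params or GenParams()
    auto_labels, profiles = _profiles_of(matrix)
    labels = list(labels) if labels is not None else auto_labels
    profiles = np.asarray(profiles)
    if len(labels) < 4:
        raise ValueError("bootstrap requires at least 4 taxa")
    n_cols = profiles.shape[1]

    full_params = GenParams(**{**params.__dict__, "undefined": "error"})
    full = nj_tree(generation_matrix(profiles, full_params, labels=labels))
    splits = tree_bipartitions(full)
    hits = {s: 0 for s in splits}

    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        weights = np.bincount(cols, minlength=n_cols).astype(float)
        try:
            rep_dist = generation_matrix(profiles, full_params, labels=labels, weights=weights)
        except ValueError:
            dropped += 1
            continue
        rep_splits = tree_bipartitions(nj_tree(rep_dist))
        for s in splits & rep_splits:
            hits[s] += 1
    if dropped > 0.2 * replicates:
        raise RuntimeError(f"{dropped}/{replicates} bootstrap replicates had undefined pairs")
    if dropped:
        logger.info("dropped %d/%d bootstrap replicates (undefined pairs)", dropped, replicates)

    kept = replicates - dropped
    taxa = frozenset(labels)
    ref = min(taxa)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if side in hits:
            # skbio serializes node.support as the internal newick label
            node.support = 100.0 * hits[side] / kept if kept else 0.0
    return full
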