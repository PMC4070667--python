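"""Positional trinucleotide histograms, peak binning and binary OTN tabulation.

The semi-alignment works on the insert coordinate system left after primer
removal (0-based offsets; a trinucleotide's "position" is its start offset).
Three steps turn a pool of reads into a character matrix:

1. :func:`build_histogram` — for every one of the 64 trinucleotides, count how
   often it starts at each offset across the pooled reads.
2. :func:`detect_peaks` — run a prominence-based peak scan on each
   trinucleotide's relative-frequency profile and partition the coordinate
   axis into half-open bins around the peaks. A (trinucleotide, bin) pair is
   an OTN: an orthologous trinucleotide character.
3. :func:`assign_otns` — mark which OTNs each read carries, then apply the
   multiplicity-discharge rule: if any single read carries the same
   trinucleotide more than once inside one bin (the signature of a
   homopolymer-tract sequencing error, or of a genuinely repetitive region
   that carries no positional signal), that OTN column is removed globally.

:func:`collapse_patterns` finally merges reads with identical OTN bit-vectors
into operational taxonomic units and optionally drops patterns seen only once
(likely sequencing errors or chimeras).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_prep import Read

__all__ = [
    "TRINUCLEOTIDES",
    "PositionalHistogram",
    "PeakConfig",
    "PeakTable",
    "OTNMatrix",
    "PatternTable",
    "build_histogram",
    "peakdet",
    "detect_peaks",
    "assign_otns",
    "collapse_patterns",
]

logger = logging.getLogger(__name__)

#: The 64 trinucleotides in lexicographic A<C<G<T order.
TRINUCLEOTIDES: tuple[str, ...] = tuple("".join(t) for t in product("ACGT", repeat=3))
_TRI_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PositionalHistogram:
    """Occurrence counts of all 64 trinucleotides along the insert coordinate.

    ``counts[t, p]`` is the number of reads whose trinucleotide starting at
    offset ``p`` is ``TRINUCLEOTIDES[t]``; ``coverage[p]`` counts the reads
    contributing any trinucleotide at ``p`` (long enough and free of N in the
    window), so each column of ``counts`` sums to ``coverage``.
    """

    counts: np.ndarray  # (64, Lmax) int64
    coverage: np.ndarray  # (Lmax,) int64

    def __post_init__(self) -> None:
        if self.counts.shape != (64, len(self.coverage)):
            raise ValueError("counts must be 64 x len(coverage)")
        if not np.array_equal(self.counts.sum(axis=0), self.coverage):
            raise ValueError("histogram violates conservation: column sums != coverage")

    @property
    def lmax(self) -> int:
        return len(self.coverage)

    def relative(self) -> np.ndarray:
        """Relative frequencies counts/coverage (0 where coverage is 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / self.coverage
        rel[:, self.coverage == 0] = 0.0
        return rel

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(TRINUCLEOTIDES))
        df.loc["coverage"] = self.coverage
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionalHistogram":
        cov = df.loc["coverage"].to_numpy(dtype=np.int64)
        counts = df.loc[list(TRINUCLEOTIDES)].to_numpy(dtype=np.int64)
        return cls(counts=counts, coverage=cov)


def build_histogram(reads: Sequence[Read]) -> PositionalHistogram:
    """Count trinucleotide occurrences per start offset over the pooled reads.

    Windows containing an N are skipped entirely (they contribute to neither
    counts nor coverage).
    """
    if not reads:
        raise ValueError("cannot build a histogram from an empty read set")
    lmax = max(len(r.seq) for r in reads) - 2
    if lmax < 1:
        raise ValueError("all reads shorter than one trinucleotide")

    counts = np.zeros((64, lmax), dtype=np.int64)
    for read in reads:
        codes = _encode(read.seq)
        n = len(codes) - 2
        if n < 1:
            continue
        tri = codes[:n] * 16 + codes[1 : n + 1] * 4 + codes[2 : n + 2]
        valid = (codes[:n] >= 0) & (codes[1 : n + 1] >= 0) & (codes[2 : n + 2] >= 0)
        pos = np.nonzero(valid)[0]
        np.add.at(counts, (tri[pos], pos), 1)
    return PositionalHistogram(counts=counts, coverage=counts.sum(axis=0))


def peakdet(series: Sequence[float], delta: float) -> tuple[list[int], list[int]]:
    """Alternating maxima/minima scan (Billauer-style prominence detection).

    A candidate maximum is emitted once the series subsequently drops by at
    least ``delta`` below the running maximum; minima symmetrically. Returns
    0-based ``(maxima, minima)`` positions.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    arr = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must be finite")

    maxima: list[int] = []
    minima: list[int] = []
    mx, mn = -np.inf, np.inf
    mxpos = mnpos = -1
    lookformax = True
    for i, v in enumerate(arr):
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn, mnpos = v, i
        if lookformax:
            if v <= mx - delta:
                maxima.append(mxpos)
                mn, mnpos = v, i
                lookformax = False
        else:
            if v >= mn + delta:
                minima.append(mnpos)
                mx, mxpos = v, i
                lookformax = True
    return maxima, minima


@dataclass
class PeakConfig:
    """Peak acceptance thresholds.

    delta
        Prominence required to accept a peak. In ``"relative"`` mode (the
        default) it is a fraction of the trinucleotide row's maximum relative
        frequency; in ``"absolute"`` mode it is used as-is.
    min_peak_freq
        Peaks whose relative frequency falls below this are dropped.
    boundary_mode
        ``"midpoint"`` places bin boundaries halfway between consecutive
        peaks; ``"valley"`` places them at the minimum of the profile between
        the peaks.
    """

    delta: float = 0.1
    min_peak_freq: float = 0.01
    delta_mode: str = "relative"
    boundary_mode: str = "midpoint"

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.delta_mode not in ("relative", "absolute"):
            raise ValueError("delta_mode must be 'relative' or 'absolute'")
        if self.boundary_mode not in ("midpoint", "valley"):
            raise ValueError("boundary_mode must be 'midpoint' or 'valley'")


@dataclass
class PeakTable:
    """Detected peaks and the derived half-open bin windows per trinucleotide."""

    peaks: dict[str, list[int]]  # trinucleotide -> ordered peak positions
    bins: dict[str, list[tuple[int, int]]]  # trinucleotide -> [start, end) windows
    lmax: int

    def __post_init__(self) -> None:
        for tri, pks in self.peaks.items():
            wins = self.bins.get(tri, [])
            for pk in pks:
                if sum(lo <= pk < hi for lo, hi in wins) != 1:
                    raise ValueError(f"peak {pk} of {tri} not inside exactly one bin")

    @property
    def n_peaks(self) -> int:
        return sum(len(p) for p in self.peaks.values())

    def bin_of(self, tri: str, pos: int) -> int | None:
        """Index of the bin of ``tri`` containing ``pos`` (None when outside all bins)."""
        for k, (lo, hi) in enumerate(self.bins.get(tri, [])):
            if lo <= pos < hi:
                return k
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tri in TRINUCLEOTIDES:
            for pk, (lo, hi) in zip(self.peaks.get(tri, []), self.bins.get(tri, [])):
                rows.append((tri, pk, lo, hi))
        return pd.DataFrame(rows, columns=["trinucleotide", "peak", "bin_start", "bin_end"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lmax: int) -> "PeakTable":
        peaks: dict[str, list[int]] = {}
        bins: dict[str, list[tuple[int, int]]] = {}
        for tri, grp in df.groupby("trinucleotide", sort=True):
            grp = grp.sort_values("peak")
            peaks[str(tri)] = [int(x) for x in grp["peak"]]
            bins[str(tri)] = [(int(a), int(b)) for a, b in zip(grp["bin_start"], grp["bin_end"])]
        return cls(peaks=peaks, bins=bins, lmax=lmax)


def _bin_windows(peaks: list[int], lmax: int, mode: str, profile: np.ndarray) -> list[tuple[int, int]]:
    """Partition [0, lmax) around peaks. Midpoint boundaries use ceil((p1+p2)/2)
    so each position joins its nearest peak (equidistant positions join the
    following bin); valley boundaries sit at the between-peak minimum."""
    if not peaks:
        return []
    bounds = [0]
    for p1, p2 in zip(peaks, peaks[1:]):
        if mode == "midpoint":
            bounds.append(-((p1 + p2) // -2))  # ceil division
        else:
            bounds.append(p1 + 1 + int(np.argmin(profile[p1 + 1 : p2])) if p2 > p1 + 1 else p2)
    bounds.append(lmax)
    return list(zip(bounds, bounds[1:]))


def detect_peaks(hist: PositionalHistogram, cfg: PeakConfig | None = None) -> PeakTable:
    """Per-trinucleotide peak detection on relative frequencies, with binning.

    For each trinucleotide row the prominence threshold is
    ``cfg.delta * row_max`` (relative mode) and peaks below
    ``cfg.min_peak_freq`` are discarded. A trinucleotide never observed simply
    yields no peaks. The coordinate axis of every trinucleotide that has peaks
    is partitioned into half-open bins per ``cfg.boundary_mode``.
    """
    cfg = cfg or PeakConfig()
    rel = hist.relative()
    peaks: dict[str, list[int]] = {}
    bins: dict[str, list[tuple[int, int]]] = {}
    for t, tri in enumerate(TRINUCLEOTIDES):
        row = rel[t]
        row_max = row.max(initial=0.0)
        if row_max <= 0.0:
            continue
        delta = cfg.delta * row_max if cfg.delta_mode == "relative" else cfg.delta
        maxima, _ = peakdet(row, delta)
        maxima = [p for p in maxima if row[p] >= cfg.min_peak_freq]
        if not maxima:
            continue
        peaks[tri] = maxima
        bins[tri] = _bin_windows(maxima, hist.lmax, cfg.boundary_mode, row)
    table = PeakTable(peaks=peaks, bins=bins, lmax=hist.lmax)
    logger.info("detected %d peaks over %d trinucleotides", table.n_peaks, len(peaks))
    return table


@dataclass
class OTNMatrix:
    """Binary read x OTN presence/absence matrix after multiplicity discharge.

    ``data`` rows are read ids, columns OTN ids formatted ``"ACG@2"``
    (trinucleotide @ bin index); ``samples`` maps read id -> sample label;
    ``discharged`` lists OTN ids removed because some read carried the
    trinucleotide more than once inside the bin.
    """

    data: pd.DataFrame  # int8, strictly 0/1
    samples: pd.Series  # index = read ids
    discharged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("OTN matrix must be strictly binary")
        if set(self.discharged) & set(self.data.columns):
            raise ValueError("discharged OTNs must not appear as columns")

    @property
    def n_reads(self) -> int:
        return len(self.data)

    def profiles(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    def sample_profiles(self) -> tuple[list[str], np.ndarray]:
        """Per-sample binary profiles: OTN present in any read of the sample."""
        grouped = self.data.groupby(self.samples).any().astype(np.int8)
        return [str(s) for s in grouped.index], grouped.to_numpy()


def assign_otns(reads: Sequence[Read], peaks: PeakTable) -> OTNMatrix:
    """Tabulate OTN presence per read and apply the multiplicity-discharge rule.

    Every occurrence of trinucleotide ``t`` at offset ``p`` maps to the bin of
    ``t`` containing ``p`` (occurrences of trinucleotides without bins, or
    outside every bin, carry no positional information and are ignored). After
    tabulation, any OTN for which *any* read had two or more occurrences
    within the bin is deleted globally and reported in ``discharged``.
    """
    # Per-trinucleotide boundary arrays for O(log b) bin lookup.
    bounds: dict[int, np.ndarray] = {}
    spans: dict[int, tuple[int, int]] = {}
    for tri, wins in peaks.bins.items():
        if wins:
            t = _TRI_INDEX[tri]
            bounds[t] = np.array([w[0] for w in wins[1:]], dtype=np.int64)
            spans[t] = (wins[0][0], wins[-1][1])

    col_ids: dict[tuple[int, int], int] = {}
    rows: list[dict[int, int]] = []
    for read in reads:
        codes = _encode(read.seq)
        n = len(codes) - 2
        occ: dict[int, int] = {}
        if n >= 1:
            tri = codes[:n] * 16 + codes[1 : n + 1] * 4 + codes[2 : n + 2]
            valid = (codes[:n] >= 0) & (codes[1 : n + 1] >= 0) & (codes[2 : n + 2] >= 0)
            for p in np.nonzero(valid)[0]:
                t = int(tri[p])
                if t not in bounds:
                    continue
                lo, hi = spans[t]
                if not lo <= p < hi:
                    continue
                b = int(np.searchsorted(bounds[t], p, side="right"))
                key = (t, b)
                col = col_ids.setdefault(key, len(col_ids))
                occ[col] = occ.get(col, 0) + 1
        rows.append(occ)

    n_cols = len(col_ids)
    counts = np.zeros((len(reads), n_cols), dtype=np.int16)
    for i, occ in enumerate(rows):
        for col, c in occ.items():
            counts[i, col] = min(c, np.iinfo(np.int16).max)

    names = [""] * n_cols
    for (t, b), col in col_ids.items():
        names[col] = f"{TRINUCLEOTIDES[t]}@{b}"
    multi = counts.max(axis=0) >= 2 if len(reads) else np.zeros(n_cols, bool)
    discharged = sorted(np.array(names)[multi].tolist())
    keep = ~multi

    data = pd.DataFrame(
        (counts[:, keep] >= 1).astype(np.int8),
        index=[r.id for r in reads],
        columns=[n for n, k in zip(names, keep) if k],
    )
    data = data[sorted(data.columns)]
    samples = pd.Series([r.sample for r in reads], index=data.index, name="sample")
    logger.info(
        "assigned %d OTN columns (%d discharged by the multiplicity rule)",
        data.shape[1], len(discharged),
    )
    return OTNMatrix(data=data, samples=samples, discharged=discharged)


@dataclass
class PatternTable:
    """Unique OTN patterns (OTUs) x samples count table.

    ``patterns`` holds one bit-vector row per unique pattern (columns follow
    ``columns``); ``counts`` gives per-sample read counts for each pattern.
    ``n_singletons``/``n_patterns_total`` describe the pre-filter pattern set,
    whether or not singletons were dropped.
    """

    patterns: np.ndarray  # (P, C) int8
    counts: pd.DataFrame  # index = pattern ids, columns = samples
    columns: list[str]
    singleton_filtered: bool
    n_singletons: int
    n_patterns_total: int

    def __post_init__(self) -> None:
        if self.singleton_filtered and len(self.counts):
            if (self.counts.sum(axis=1) < 2).any():
                raise ValueError("singleton-filtered table contains count-1 patterns")

    @property
    def pattern_ids(self) -> list[str]:
        return [str(i) for i in self.counts.index]

    @property
    def singleton_fraction(self) -> float:
        return self.n_singletons / self.n_patterns_total if self.n_patterns_total else 0.0

    def per_position_accuracy(self, read_length: int) -> float:
        """Heuristic per-position accuracy, treating singleton patterns as errors:
        ``1 - n_singletons / (n_patterns_total * read_length)``."""
        if self.n_patterns_total == 0 or read_length <= 0:
            raise ValueError("need patterns and a positive read length")
        return 1.0 - self.n_singletons / (self.n_patterns_total * read_length)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def top_patterns(self, k: int) -> tuple[list[str], np.ndarray]:
        """The k most abundant patterns (ids, bit-vectors), ties by pattern id."""
        order = self.totals().sort_values(ascending=False, kind="stable").index[:k]
        idx = [self.counts.index.get_loc(i) for i in order]
        return [str(i) for i in order], self.patterns[idx]


def collapse_patterns(matrix: OTNMatrix, drop_singletons: bool = True) -> PatternTable:
    """Merge reads with identical OTN bit-vectors into patterns (OTUs).

    Counts are split by sample. With ``drop_singletons`` (the default, as in
    the ecological analyses) patterns whose total count is 1 are removed.
    """
    profiles = matrix.profiles()
    keys = [row.tobytes() for row in profiles]
    order: dict[bytes, int] = {}
    first_row: list[int] = []
    for i, key in enumerate(keys):
        if key not in order:
            order[key] = len(order)
            first_row.append(i)

    sample_names = sorted(set(matrix.samples))
    counts = np.zeros((len(order), len(sample_names)), dtype=np.int64)
    s_index = {s: j for j, s in enumerate(sample_names)}
    for key, sample in zip(keys, matrix.samples):
        counts[order[key], s_index[sample]] += 1

    ids = [f"P{i:05d}" for i in range(len(order))]
    counts_df = pd.DataFrame(counts, index=ids, columns=sample_names)
    patterns = profiles[first_row] if len(profiles) else np.zeros((0, 0), dtype=np.int8)

    totals = counts_df.sum(axis=1)
    n_singletons = int((totals == 1).sum())
    n_total = len(counts_df)
    if drop_singletons:
        keep = totals >= 2
        counts_df = counts_df.loc[keep]
        patterns = patterns[keep.to_numpy()] if len(patterns) else patterns
    return PatternTable(
        patterns=patterns,
        counts=counts_df,
        columns=list(matrix.data.columns),
        singleton_filtered=drop_singletons,
        n_singletons=n_singletons,
        n_patterns_total=n_total,
    )
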