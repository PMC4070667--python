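"""Read loading, quality trimming, filtering, primer removal and depth normalization.

The cleaning stage mirrors standard practice for 454-era amplicon data:
modified-Mott quality trimming at an error-probability limit, a cap on
ambiguous bases, a minimum-length cutoff, exact (0-mismatch) primer matching
in either read orientation, and uniform subsampling of every sample to a
common depth so that downstream presence/absence statistics are comparable
across libraries.

Qualities are carried as per-base *error probabilities* (``p = 10**(-Q/10)``),
not Phred integers, because the trimmer and the simulator both reason in
probability space.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Read",
    "FilterConfig",
    "revcomp",
    "read_sequences",
    "mott_trim",
    "filter_reads",
    "strip_primers",
    "subsample",
    "FWD_PRIMER",
    "REV_PRIMER",
]

#: V3–V4 16S rRNA primer pair used as defaults throughout the package.
FWD_PRIMER = "TCCTACGGGAGGCAGCAGT"
REV_PRIMER = "GGACTACCAGGGTATCTAATCCTGTT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """One amplicon read: sequence, optional per-base error probabilities, sample label."""

    id: str
    seq: str
    qual: np.ndarray | None = None  # error probabilities in [0, 1]
    sample: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
            if len(self.qual) != len(self.seq):
                raise ValueError(
                    f"read {self.id!r}: quality length {len(self.qual)} "
                    f"!= sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterConfig:
    """Thresholds for read cleaning.

    max_ambiguous
        Maximum number of N bases tolerated per read.
    quality_limit
        Error-probability limit for modified-Mott trimming (bases with
        ``p > quality_limit`` score negatively).
    min_length
        Minimum read length in nucleotides; shorter reads are discarded.
    length_filter_stage
        ``"pre_primer"`` applies the length cutoff to the read before primer
        removal (the default), ``"post_primer"`` to the bare insert.
    """

    max_ambiguous: int = 2
    quality_limit: float = 0.05
    min_length: int = 300
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    length_filter_stage: str = "pre_primer"

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality_limit <= 1.0:
            raise ValueError("quality_limit must lie in [0, 1]")
        if self.min_length < 3:
            raise ValueError("min_length must be >= 3")
        if self.length_filter_stage not in ("pre_primer", "post_primer"):
            raise ValueError("length_filter_stage must be 'pre_primer' or 'post_primer'")


def read_sequences(path: str | Path, format: str | None = None, sample: str = "") -> list[Read]:
    """Load FASTA or FASTQ (Sanger Phred+33) records as :class:`Read` objects.

    Phred scores are converted to error probabilities ``p = 10**(-Q/10)``.
    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")

    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            qual = None
            if format == "fastq":
                phred = np.asarray(rec.letter_annotations["phred_quality"], dtype=float)
                qual = np.power(10.0, -phred / 10.0)
            reads.append(Read(id=rec.id, seq=str(rec.seq), qual=qual, sample=sample))
    except ValueError as exc:
        raise ValueError(f"malformed {format} record in {path}: {exc}") from exc
    if not reads:
        warnings.warn(f"{path}: no records parsed", stacklevel=2)
    return reads


def mott_trim(read: Read, limit: float = 0.05) -> Read:
    """Modified-Mott quality trimming.

    Keeps the contiguous subsequence maximizing ``sum(limit - p_i)``; returns
    an empty read when every partial sum is non-positive. Reads without
    qualities pass through untrimmed with a warning. The input is unchanged.
    """
    if read.qual is None:
        warnings.warn(f"read {read.id!r} has no qualities; not trimmed", stacklevel=2)
        return read

    scores = limit - read.qual
    # Kadane scan for the best-scoring segment; first maximum wins on ties.
    best, best_lo, best_hi = 0.0, 0, 0
    cur, cur_lo = 0.0, 0
    for i, s in enumerate(scores):
        cur += s
        if cur <= 0.0:
            cur, cur_lo = 0.0, i + 1
        elif cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    return replace(read, seq=read.seq[best_lo:best_hi], qual=read.qual[best_lo:best_hi])


def filter_reads(
    reads: Iterable[Read], cfg: FilterConfig
) -> tuple[list[Read], Counter[str]]:
    """Apply ambiguity and length filters; returns (kept reads, rejection counts).

    A read is kept when it has at most ``cfg.max_ambiguous`` N bases *and* is
    at least ``cfg.min_length`` nucleotides long. Input order is preserved.
    Rejection counts are keyed ``"ambiguous"`` and ``"too_short"`` (a read
    failing both rules is counted under the first that applies).
    """
    kept: list[Read] = []
    rejected: Counter[str] = Counter()
    for read in reads:
        if read.seq.count("N") > cfg.max_ambiguous:
            rejected["ambiguous"] += 1
        elif len(read.seq) < cfg.min_length:
            rejected["too_short"] += 1
        else:
            kept.append(read)
    return kept, rejected


def _find_insert(seq: str, fwd: str, rc_rev: str, slack: int) -> tuple[int, int] | None:
    """Locate fwd near the 5' end and revcomp(rev) near the 3' end; exact matches only."""
    i = seq.find(fwd, 0, slack + len(fwd))
    if i < 0:
        return None
    j = seq.rfind(rc_rev)
    if j < 0 or j + len(rc_rev) < len(seq) - slack:
        return None
    lo, hi = i + len(fwd), j
    if hi < lo:
        return None
    return lo, hi


def strip_primers(
    read: Read, fwd: str, rev: str, slack: int = 5
) -> tuple[Read | None, str]:
    """Exact primer matching and removal, orientation-aware.

    Requires a 0-mismatch occurrence of ``fwd`` within the first ``slack``
    bases and of ``revcomp(rev)`` ending within the last ``slack`` bases
    (small slack tolerates 454 key remnants). Both the read and its reverse
    complement are tested; whichever orientation matches is kept, re-oriented
    forward-primer-first, and the insert between the primers is returned.

    Returns ``(insert_read, "ok")`` on success, ``(None, "no_match")`` when
    neither orientation matches and ``(None, "ambiguous_orientation")`` in the
    degenerate case where both do.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    rc_rev = revcomp(rev)

    hit_f = _find_insert(read.seq, fwd, rc_rev, slack)
    rc_seq = revcomp(read.seq)
    hit_r = _find_insert(rc_seq, fwd, rc_rev, slack)

    if hit_f and hit_r:
        return None, "ambiguous_orientation"
    if hit_f:
        lo, hi = hit_f
        qual = read.qual[lo:hi] if read.qual is not None else None
        return replace(read, seq=read.seq[lo:hi], qual=qual), "ok"
    if hit_r:
        lo, hi = hit_r
        qual = read.qual[::-1][lo:hi] if read.qual is not None else None
        return replace(read, seq=rc_seq[lo:hi], qual=qual), "ok"
    return None, "no_match"


def subsample(
    samples: Mapping[str, Sequence[Read]],
    depth: int | str = "min",
    seed: int = 1,
) -> dict[str, list[Read]]:
    """Subsample every library to a common depth, without replacement.

    ``depth="min"`` uses the smallest library size. Sampling is uniform and
    deterministic for a given seed; sample keys are visited in sorted order so
    the result does not depend on mapping order.
    """
    sizes = {name: len(reads) for name, reads in samples.items()}
    if not sizes:
        return {}
    if depth == "min":
        depth = min(sizes.values())
    depth = int(depth)
    for name, size in sorted(sizes.items()):
        if depth > size:
            raise ValueError(f"sample {name!r} has only {size} reads (< depth {depth})")

    rng = np.random.default_rng(seed)
    out: dict[str, list[Read]] = {}
    for name in sorted(samples):
        reads = samples[name]
        idx = rng.choice(len(reads), size=depth, replace=False)
        out[name] = [reads[i] for i in sorted(idx)]
    return out
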