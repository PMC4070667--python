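"""End-to-end orchestration: cleaning -> histogram -> peaks -> OTN matrix -> patterns."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_prep import FilterConfig, Read, filter_reads, mott_trim, strip_primers, subsample
from .otn_core import (
    OTNMatrix,
    PatternTable,
    PeakConfig,
    PeakTable,
    PositionalHistogram,
    assign_otns,
    build_histogram,
    collapse_patterns,
    detect_peaks,
)

__all__ = ["preprocess_samples", "otn_pipeline", "PipelineResult"]


def preprocess_samples(
    samples: Mapping[str, Sequence[Read]],
    cfg: FilterConfig | None = None,
    depth: int | str = "min",
    seed: int = 1,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Trim, filter, strip primers and depth-normalize every sample.

    Order: modified-Mott trimming (reads with qualities), ambiguity/length
    filtering, exact primer removal, then uniform subsampling to a common
    depth. With ``cfg.length_filter_stage == "post_primer"`` the length cutoff
    is applied to the bare insert instead of the raw read. Returns the cleaned
    samples and a per-read rejection report (columns: read, sample, rule).
    """
    cfg = cfg or FilterConfig()
    rejects: list[dict[str, str]] = []
    cleaned: dict[str, list[Read]] = {}
    for name in sorted(samples):
        out: list[Read] = []
        for read in samples[name]:
            r = mott_trim(read, cfg.quality_limit) if read.qual is not None else read
            if r.seq.count("N") > cfg.max_ambiguous:
                rejects.append({"read": read.id, "sample": name, "rule": "ambiguous"})
                continue
            if cfg.length_filter_stage == "pre_primer" and len(r.seq) < cfg.min_length:
                rejects.append({"read": read.id, "sample": name, "rule": "too_short"})
                continue
            insert, code = strip_primers(r, cfg.fwd_primer, cfg.rev_primer)
            if insert is None:
                rejects.append({"read": read.id, "sample": name, "rule": code})
                continue
            if cfg.length_filter_stage == "post_primer" and len(insert.seq) < cfg.min_length:
                rejects.append({"read": read.id, "sample": name, "rule": "too_short"})
                continue
            out.append(insert)
        cleaned[name] = out
    normalized = subsample(cleaned, depth=depth, seed=seed)
    report = pd.DataFrame(rejects, columns=["read", "sample", "rule"])
    return normalized, report


@dataclass
class PipelineResult:
    histogram: PositionalHistogram
    peaks: PeakTable
    matrix: OTNMatrix
    patterns: PatternTable


def otn_pipeline(
    samples: Mapping[str, Sequence[Read]],
    peak_cfg: PeakConfig | None = None,
    drop_singletons: bool = True,
) -> PipelineResult:
    """Histogram on the pooled dataset, peak binning, OTN assignment, patterns.

    The histogram and peak table are built once on all samples pooled (so the
    OTN column set is identical everywhere) and then applied to every read.
    """
    pooled: list[Read] = [r for name in sorted(samples) for r in samples[name]]
    hist = build_histogram(pooled)
    peaks = detect_peaks(hist, peak_cfg)
    matrix = assign_otns(pooled, peaks)
    patterns = collapse_patterns(matrix, drop_singletons=drop_singletons)
    return PipelineResult(histogram=hist, peaks=peaks, matrix=matrix, patterns=patterns)
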