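"""Shared fixtures: small synthetic read sets and a two-clade simulation."""

from __future__ import annotations

import numpy as np
import pytest

from otnalign import (
    FWD_PRIMER,
    REV_PRIMER,
    Read,
    SimConfig,
    end_to_end_fixture,
    revcomp,
)

#: binary two-clade topology used wherever a resolvable tree is needed
TWO_CLADE_NEWICK = (
    "((T1:2e8,(T2:1e8,T3:1e8):1e8):5e8,"
    "(T4:2e8,(T5:1e8,T6:1e8):1e8):5e8);"
)


def make_amplicon(insert: str, rid: str = "r", sample: str = "s",
                  qual: float | None = None) -> Read:
    """A well-formed amplicon read: fwd primer + insert + revcomp(rev primer)."""
    seq = FWD_PRIMER + insert + revcomp(REV_PRIMER)
    q = np.full(len(seq), qual) if qual is not None else None
    return Read(id=rid, seq=seq, qual=q, sample=sample)


def random_insert(rng: np.random.Generator, length: int = 460) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130420)


@pytest.fixture(scope="session")
def two_clade_fixture():
    """6 taxa in two clades, error-free reads, known tree and distances."""
    cfg = SimConfig(n_taxa=6, reads_per_taxon=20, tree=TWO_CLADE_NEWICK, seed=3)
    return end_to_end_fixture(cfg)
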