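"""Synthetic amplicon read sets with known evolutionary and error structure.

The generator separates the two signal sources the semi-alignment must cope
with: (i) evolutionary divergence, modelled as independent per-position
substitutions accumulated along a tree whose edge lengths are measured in
generations (each position mutates with probability ``1-(1-r)^g`` on an edge
of ``g`` generations, to a uniformly chosen different base — no inherited
indels, so positional ground truth stays exact); and (ii) 454-style
sequencing error, modelled as ±1-base indels injected into homopolymer tracts
(runs of >= 3 identical bases) of individual reads, plus per-base error
probabilities that grow along the read.

Defaults emulate the V3–V4 study conditions: 460-nt inserts, the published
primer pair, a per-position rate of 0.5e-9 substitutions/generation, and
divergences in the 1e8–1e9 generation range.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_prep import FWD_PRIMER, REV_PRIMER, Read, revcomp

__all__ = ["SimConfig", "TruthSet", "simulate_taxa", "emit_reads", "write_fastq",
           "end_to_end_fixture", "random_tree"]

_BASES = np.array(list("ACGT"))
_HOMOPOLYMER = re.compile(r"(A{3,}|C{3,}|G{3,}|T{3,})")


@dataclass
class SimConfig:
    """Simulation parameters; every rate is a probability per the stated unit.

    insert_length
        Length of the amplified insert between the primers (default 460 nt,
        V3–V4-like).
    tree
        A newick string / TreeNode with edge lengths in generations, or None
        to draw a random topology with edge lengths uniform in
        ``edge_gen_range``.
    per_position_rate
        Substitution probability per position per generation (default 0.5e-9).
    homopolymer_indel_rate
        Probability of a ±1-base indel per homopolymer tract (>= 3 identical
        bases) per read — the dominant 454 error mode.
    quality_profile
        (error probability at read start, at read end); interpolated linearly.
    """

    insert_length: int = 460
    n_taxa: int = 6
    tree: str | TreeNode | None = None
    per_position_rate: float = 0.5e-9
    homopolymer_indel_rate: float = 0.0
    reads_per_taxon: int = 50
    quality_profile: tuple[float, float] = (0.001, 0.01)
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    edge_gen_range: tuple[float, float] = (1e8, 1e9)
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.per_position_rate, self.homopolymer_indel_rate, *self.quality_profile):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and error probabilities must lie in [0, 1]")
        if self.insert_length < 3:
            raise ValueError("insert_length must be >= 3")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")


class InjectedError(NamedTuple):
    read_id: str
    tract_start: int
    tract_length: int
    delta: int  # +1 insertion, -1 deletion


@dataclass
class TruthSet:
    """Ground truth of one simulation: sequences, tree and pairwise separations."""

    ancestor: str
    sequences: dict[str, str]  # taxon -> insert sequence
    tree: TreeNode
    generations: pd.DataFrame  # symmetric taxon x taxon path lengths
    errors: list[InjectedError] = field(default_factory=list)


def random_tree(n_taxa: int, rng: np.random.Generator,
                gen_range: tuple[float, float] = (1e8, 1e9)) -> TreeNode:
    """Random binary topology by sequential joining; edge lengths ~ U(gen_range)."""
    nodes = [TreeNode(name=f"T{i + 1}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (j, i):  # pop higher index first
            child = nodes.pop(k)
            child.length = float(rng.uniform(*gen_range))
            parent.append(child)
        nodes.append(parent)
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(*gen_range))
        root.append(child)
    return root


def _mutate(seq: np.ndarray, g: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability 1-(1-rate)^g, to a different base."""
    p_sub = -math.expm1(g * math.log1p(-rate))
    if p_sub > 0.5:
        warnings.warn(
            f"edge of {g:g} generations is near saturation (p_sub={p_sub:.2f})",
            stacklevel=3,
        )
    hit = rng.random(len(seq)) < p_sub
    out = seq.copy()
    if hit.any():
        # uniform over the three non-identical bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_taxa(cfg: SimConfig) -> TruthSet:
    """Draw an ancestor and evolve it along the tree; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.tree is None:
        tree = random_tree(cfg.n_taxa, rng, cfg.edge_gen_range)
    elif isinstance(cfg.tree, TreeNode):
        tree = cfg.tree
    else:
        tree = TreeNode.read([cfg.tree])

    ancestor = rng.integers(0, 4, size=cfg.insert_length)
    seqs: dict[str, str] = {}

    def _descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            g = float(child.length or 0.0)
            derived = _mutate(seq, g, cfg.per_position_rate, rng)
            if child.is_tip():
                seqs[child.name] = "".join(_BASES[derived])
            else:
                _descend(child, derived)

    _descend(tree, ancestor)
    taxa = sorted(seqs)
    tipdist = tree.tip_tip_distances(endpoints=taxa)
    gen = pd.DataFrame(tipdist.data, index=list(tipdist.ids), columns=list(tipdist.ids))
    gen = gen.loc[taxa, taxa]
    return TruthSet(
        ancestor="".join(_BASES[ancestor]),
        sequences=seqs,
        tree=tree,
        generations=gen,
    )


def _inject_homopolymer_indels(
    seq: str, rate: float, read_id: str, rng: np.random.Generator
) -> tuple[str, list[InjectedError]]:
    tracts = [(m.start(), m.end() - m.start()) for m in _HOMOPOLYMER.finditer(seq)]
    errors: list[InjectedError] = []
    # apply right-to-left so earlier tract coordinates stay valid
    for start, length in reversed(tracts):
        if rng.random() >= rate:
            continue
        delta = 1 if rng.random() < 0.5 else -1
        base = seq[start]
        if delta == 1:
            seq = seq[:start] + base + seq[start:]
        else:
            seq = seq[:start] + seq[start + 1 :]
        errors.append(InjectedError(read_id, start, length, delta))
    return seq, errors


def emit_reads(truth: TruthSet, cfg: SimConfig) -> dict[str, list[Read]]:
    """Per-taxon reads: primers attached, homopolymer indels and qualities injected.

    One sample per taxon, named after it. Injected indels are appended to
    ``truth.errors``. The RNG stream is seeded from ``cfg.seed`` (offset so it
    does not replay the mutation stream).
    """
    rng = np.random.default_rng(cfg.seed + 10_007)
    rc_rev = revcomp(cfg.rev_primer)
    p0, p1 = cfg.quality_profile
    samples: dict[str, list[Read]] = {}
    for taxon in sorted(truth.sequences):
        insert = truth.sequences[taxon]
        reads: list[Read] = []
        for j in range(cfg.reads_per_taxon):
            rid = f"{taxon}_r{j:04d}"
            body, errs = _inject_homopolymer_indels(
                insert, cfg.homopolymer_indel_rate, rid, rng
            )
            truth.errors.extend(errs)
            seq = cfg.fwd_primer + body + rc_rev
            qual = np.linspace(p0, p1, num=len(seq))
            reads.append(Read(id=rid, seq=seq, qual=qual, sample=taxon))
        samples[taxon] = reads
    return samples


def write_fastq(samples: dict[str, list[Read]], out_dir: str | Path) -> dict[str, Path]:
    """Write one Sanger FASTQ (Phred+33) per sample; returns sample -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, reads in sorted(samples.items()):
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for read in reads:
                p = read.qual if read.qual is not None else np.full(len(read.seq), 1e-3)
                q = np.clip(np.rint(-10.0 * np.log10(np.maximum(p, 1e-9))), 0, 40).astype(int)
                fh.write(f"@{read.id}\n{read.seq}\n+\n")
                fh.write("".join(chr(33 + int(v)) for v in q) + "\n")
        paths[sample] = path
    return paths


class EndToEndFixture(NamedTuple):
    samples: dict[str, list[Read]]
    truth: TruthSet
    expected_n_patterns: int
    expected_generations: pd.DataFrame


def end_to_end_fixture(cfg: SimConfig) -> EndToEndFixture:
    """Small simulated dataset bundled with its ground truth for pipeline tests."""
    if cfg.n_taxa > 12 or cfg.n_taxa * cfg.reads_per_taxon > 2000:
        raise ValueError("fixture configs are intentionally small (<=12 taxa, <=2000 reads)")
    truth = simulate_taxa(cfg)
    samples = emit_reads(truth, cfg)
    n_unique = len(set(truth.sequences.values()))
    return EndToEndFixture(
        samples=samples,
        truth=truth,
        expected_n_patterns=n_unique,
        expected_generations=truth.generations,
    )
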