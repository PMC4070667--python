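"""Plain-text artifact I/O shared by the CLI stages.

Every artifact is TSV / FASTA / Newick so each pipeline stage is independently
inspectable. TSV artifacts carry comment headers recording the tool version,
the artifact kind and the effective parameters; readers verify the kind and
name the producing subcommand when a file is missing or incompatible.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .io_prep import Read

__all__ = [
    "ArtifactError",
    "write_table",
    "read_table",
    "write_reads_fasta",
    "read_reads_fasta",
    "write_newick",
]

#: artifact kind -> subcommand that produces it
PRODUCERS = {
    "histogram": "histogram",
    "peaks": "peaks",
    "matrix": "otn",
    "patterns": "otn",
    "distance": "distance",
    "diversity": "diversity",
    "ordination": "pca",
    "rejections": "preprocess",
    "truth": "simulate",
}


class ArtifactError(RuntimeError):
    pass


def _header(kind: str, params: Mapping[str, object] | None) -> str:
    lines = [f"# otnalign {__version__} artifact={kind}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {kv}")
    return "\n".join(lines) + "\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    kind: str,
    params: Mapping[str, object] | None = None,
    extra_comments: Iterable[str] = (),
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(kind, params))
        for line in extra_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, kind: str, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV artifact, verifying its kind; errors name the producer."""
    path = Path(path)
    producer = PRODUCERS.get(kind, "?")
    if not path.exists():
        raise ArtifactError(
            f"{path} not found: expected a {kind!r} artifact "
            f"produced by the `{producer}` subcommand"
        )
    with open(path) as fh:
        first = fh.readline()
        if f"artifact={kind}" not in first:
            raise ArtifactError(
                f"{path} is not a {kind!r} artifact "
                f"(expected output of the `{producer}` subcommand)"
            )
        body = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t", index_col=index_col)


def read_comments(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line[1:].strip() for line in fh if line.startswith("#")]


def write_reads_fasta(reads: Iterable[Read], path: str | Path) -> None:
    """FASTA with the sample label kept in the description (``sample=NAME``)."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id} sample={read.sample}\n{read.seq}\n")


def read_reads_fasta(path: str | Path) -> list[Read]:
    path = Path(path)
    if not path.exists():
        raise ArtifactError(
            f"{path} not found: expected the filtered-reads FASTA "
            "produced by the `preprocess` subcommand"
        )
    reads: list[Read] = []
    name, desc, chunks = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    reads.append(_fasta_read(name, desc, chunks))
                fields = line[1:].split(None, 1)
                name = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            elif line and not line.startswith("#"):
                chunks.append(line)
    if name is not None:
        reads.append(_fasta_read(name, desc, chunks))
    return reads


def _fasta_read(name: str, desc: str, chunks: list[str]) -> Read:
    sample = ""
    for token in desc.split():
        if token.startswith("sample="):
            sample = token[len("sample=") :]
    return Read(id=name, seq="".join(chunks), sample=sample)


def write_newick(tree, path: str | Path) -> None:
    # Newick has no comment header; the parameters live in the run log.
    buf = io.StringIO()
    tree.write(buf, format="newick")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
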