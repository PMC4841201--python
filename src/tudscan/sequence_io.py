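"""FASTA/table I/O and the reverse-complement-extended genome representation.

Genomes are stored uppercase over the alphabet {A, C, G, T, N}. Any other
character (IUPAC ambiguity codes, gaps, stray symbols) is mapped to N on
input, with a logged count, so that real GenBank-derived FASTA loads without
error. Downstream k-mer counting skips every window that touches an N.

Before any word counting, a genome is *extended* by its reverse complement:
counts are taken over both strands so that the resulting usage statistics are
independent of which strand was deposited. The two strands are kept as
separate strings — no artificial words spanning a forward/reverse junction
are ever counted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase {A,C,G,T,N} string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A single nucleotide sequence with an identifier and optional group label.

    Parameters
    ----------
    id : str
        Unique identifier (the pre-whitespace FASTA header token).
    sequence : str
        Uppercase sequence over {A, C, G, T, N}.
    label : str, optional
        Cluster/subcluster annotation used only for reporting and
        monophyly checks.
    description : str
        Full FASTA header, retained for reporting only.
    """

    id: str
    sequence: str
    label: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("genome id must be nonempty")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StrandPair:
    """A genome together with its reverse complement, as two separate strands."""

    forward: str
    reverse: str
    source_id: str

    def __post_init__(self) -> None:
        if len(self.forward) != len(self.reverse):
            raise ValidationError("strands must have equal length")


def extend_with_revcomp(genome: Genome) -> StrandPair:
    """Pair a genome with its reverse complement for double-strand counting."""
    if genome.length == 0:
        raise ValidationError(f"genome {genome.id!r} has an empty sequence")
    return StrandPair(
        forward=genome.sequence,
        reverse=revcomp(genome.sequence),
        source_id=genome.id,
    )


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a multi-record FASTA file into a list of :class:`Genome`.

    The id of each record is the header token before the first whitespace.
    Characters outside {A, C, G, T, N} are replaced by N; the total number of
    replacements is logged as a warning. Duplicate ids and empty files raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    genomes: list[Genome] = []
    seen: set[str] = set()
    n_replaced = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValidationError(f"duplicate genome id in {path}: {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        bad = _NON_ACGTN.findall(seq)
        if bad:
            n_replaced += len(bad)
            seq = _NON_ACGTN.sub("N", seq)
        genomes.append(Genome(id=record.id, sequence=seq, description=record.description))
    if not genomes:
        raise ValidationError(f"no FASTA records found in {path}")
    if n_replaced:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, n_replaced)
    return genomes


def write_fasta(genomes: list[Genome], path: str | Path, width: int = 70) -> None:
    """Write genomes to FASTA, wrapping sequence lines at ``width`` columns."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=g.description or "")
        for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping genome id -> group label.

    Lines starting with '#' are ignored; no header is required (a header line
    is treated as a mapping like any other, so omit it).
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            labels[parts[0]] = parts[1]
    return labels


def apply_labels(genomes: list[Genome], labels: dict[str, str]) -> None:
    """Attach labels in-place; genomes absent from the mapping keep None."""
    for g in genomes:
        g.label = labels.get(g.id, g.label)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a labeled distance matrix as TSV (full float precision)."""
    df = pd.DataFrame(matrix.data, index=list(matrix.ids), columns=list(matrix.ids))
    # repr() gives the shortest string that round-trips the float exactly
    df.to_csv(path, sep="\t", index_label="id", float_format=lambda v: repr(float(v)))


def read_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
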