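"""Multiple-sequence-alignment container and readers.

A note on orientation: some alignment servers print the alignment
transposed, in fixed-width blocks, so that one *printed row* holds the
residues of every ortholog at a single sequence position.  This module
follows the universal MSA convention instead — a *row* is one aligned
sequence, a *column* is one residue position — and the wrapped-block
reader reassembles such block output into that orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Gap character.
GAP = "-"
#: Unknown-residue character (any other letter normalizes to this).
UNKNOWN = "X"

_ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or malformed block files."""


@dataclass(frozen=True)
class Msa:
    """An alignment: ``rows[k]`` is the aligned sequence of ortholog ``ids[k]``.

    All rows have identical length; the alphabet is the 20 amino acids,
    ``X`` for unknown and ``-`` for gaps.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no sequences")
        width = len(self.rows[0])
        if width == 0:
            raise AlignmentFormatError("alignment has zero width")
        for seq_id, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentFormatError(
                    f"ragged alignment: sequence {seq_id!r} has length "
                    f"{len(row)}, expected {width}"
                )
            bad = set(row) - _ALPHABET
            if bad:
                raise AlignmentFormatError(
                    f"sequence {seq_id!r} contains unnormalized characters {bad!r}"
                )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Alignment width (number of columns)."""
        return len(self.rows[0])


@dataclass(frozen=True)
class Column:
    """Residues observed at one alignment position across all orthologs.

    ``position`` is 1-based; ``residues[k]`` is the character of row ``k``.
    """

    position: int
    residues: str


def normalize_sequence(seq: str, seq_id: str = "?") -> str:
    """Uppercase and map any character outside the alphabet to ``X``."""
    seq = seq.upper()
    if set(seq) <= _ALPHABET:
        return seq
    out = []
    replaced = set()
    for c in seq:
        if c in _ALPHABET:
            out.append(c)
        else:
            replaced.add(c)
            out.append(UNKNOWN)
    log.warning(
        "sequence %s: normalized unknown characters %s to %s",
        seq_id, "".join(sorted(replaced)), UNKNOWN,
    )
    return "".join(out)


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Msa:
    """Read an alignment from *path*.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"aligned-fasta"`` (default) — standard aligned FASTA; or
        ``"wrapped-blocks"`` — fixed-width blocks of ``identifier
        subsequence`` lines separated by blank lines, with every block
        listing the same identifiers in the same order.  Blocks are
        concatenated per identifier in file order.
    """
    path = Path(path)
    if dialect in ("aligned-fasta", "fasta"):
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentFormatError(f"no sequences in {path}")
        ids = tuple(r.id for r in records)
        rows = tuple(normalize_sequence(str(r.seq), r.id) for r in records)
        return Msa(ids=ids, rows=rows)
    if dialect in ("wrapped-blocks", "blocks"):
        return _read_wrapped_blocks(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wrapped_blocks(path: Path) -> Msa:
    blocks: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for raw in path.read_text().splitlines():
        line = raw.rstrip()
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AlignmentFormatError(
                f"{path}: expected 'identifier subsequence', got {line!r}"
            )
        current.append((parts[0], parts[1]))
    if current:
        blocks.append(current)
    if not blocks:
        raise AlignmentFormatError(f"no blocks in {path}")

    ids = [seq_id for seq_id, _ in blocks[0]]
    parts_by_id: dict[str, list[str]] = {seq_id: [] for seq_id in ids}
    if len(parts_by_id) != len(ids):
        raise AlignmentFormatError(f"{path}: duplicate identifiers in first block")
    for k, block in enumerate(blocks):
        block_ids = [seq_id for seq_id, _ in block]
        if block_ids != ids:
            raise AlignmentFormatError(
                f"{path}: block {k + 1} lists identifiers {block_ids}, "
                f"expected {ids}"
            )
        widths = {len(sub) for _, sub in block}
        if len(widths) != 1:
            raise AlignmentFormatError(
                f"{path}: block {k + 1} has unequal subsequence widths {sorted(widths)}"
            )
        for seq_id, sub in block:
            parts_by_id[seq_id].append(sub)
    rows = tuple(
        normalize_sequence("".join(parts_by_id[seq_id]), seq_id) for seq_id in ids
    )
    return Msa(ids=tuple(ids), rows=rows)


def get_column(msa: Msa, position: int) -> Column:
    """Extract the 1-based *position* column of *msa*."""
    if not 1 <= position <= msa.length:
        raise IndexError(
            f"position {position} out of range 1..{msa.length}"
        )
    residues = "".join(row[position - 1] for row in msa.rows)
    return Column(position=position, residues=residues)


def iter_columns(msa: Msa):
    """Yield every column of *msa* in order."""
    for position in range(1, msa.length + 1):
        yield get_column(msa, position)


def write_fasta(msa: Msa, path: str | Path) -> None:
    """Write *msa* as aligned FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for seq_id, row in zip(msa.ids, msa.rows):
            fh.write(f">{seq_id}\n")
            for start in range(0, len(row), 60):
                fh.write(row[start:start + 60] + "\n")
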