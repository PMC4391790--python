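"""Per-column complexity scores: VAR, ENT and KOL.

Three measures of the diversity of residue types observed at one
alignment column:

* **VAR** — variability: the number of distinct residue types whose
  relative frequency at the column reaches a threshold (mutational
  flexibility: what the position *tolerates*).  The exact convention
  differs between alignment servers, so the definition is pluggable.
* **ENT** — normalized Shannon entropy of the residue-type frequencies,
  on a 0-100 scale: ``100 * (-sum p ln p) / ln 20``.  0 means fully
  conserved, 100 means uniform over all 20 amino acids.
* **KOL** — a practical stand-in for Kolmogorov complexity: the size of
  the column's residue string after bzip2 (block-sorting) compression,
  by default normalized by the raw size.  Conserved columns compress far
  better than diverse ones.

Byte-serialization convention for KOL (fixed, so scores are
bit-reproducible): the column's residues concatenated in ortholog order,
uppercase, gaps included verbatim, one ASCII byte per symbol, no
separators, no trailing newline; bzip2 at the configured level
(default 9, the maximum).
"""

from __future__ import annotations

import bz2
from collections import Counter
from dataclasses import dataclass
from math import log
from pathlib import Path
from typing import Callable, Iterable

from kolfold.msa import GAP, UNKNOWN, Column, Msa, iter_columns

_LN20 = log(20.0)

#: Flag values used in ComplexityRecord and TSV output.
FLAG_OK = "ok"
FLAG_ALL_GAP = "all-gap"


@dataclass(frozen=True)
class ComplexityRecord:
    """Scores for one alignment column.

    ``ent`` is on the 0-100 scale; ``var`` and ``ent`` are ``None`` on
    all-gap columns (``flag == "all-gap"``); ``kol`` is always defined
    because gaps are compressed verbatim.
    """

    position: int
    var: float | None
    ent: float | None
    kol: float
    flag: str = FLAG_OK


def _counted_frequencies(
    residues: str, include_gaps: bool = False
) -> dict[str, float]:
    """Relative frequencies of residue types in a column.

    ``X`` is always excluded (an unknown residue carries no type
    information); gaps are excluded unless *include_gaps* is set.
    """
    counts = Counter(residues)
    counts.pop(UNKNOWN, None)
    if not include_gaps:
        counts.pop(GAP, None)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {t: c / total for t, c in counts.items()}


def column_variability(
    column: Column,
    min_freq: float = 0.01,
    include_gaps: bool = False,
    definition: Callable[[dict[str, float]], float] | None = None,
) -> float | None:
    """Variability of a column.

    Default definition: the number of distinct residue types whose
    relative frequency is at least *min_freq*.  A different convention
    can be supplied via *definition*, a callable mapping the frequency
    dict to a score.  Returns ``None`` for an all-gap column.
    """
    freqs = _counted_frequencies(column.residues, include_gaps)
    if not freqs:
        return None
    if definition is not None:
        return definition(freqs)
    return float(sum(1 for p in freqs.values() if p >= min_freq))


def column_entropy(column: Column, include_gaps: bool = False) -> float | None:
    """Normalized Shannon entropy of a column on the 0-100 scale.

    ``ent = 100 * (-sum_t p_t ln p_t) / ln 20`` over residue-type
    frequencies (gaps and ``X`` excluded by default), clipped to
    [0, 100].  Returns ``None`` for an all-gap column.
    """
    freqs = _counted_frequencies(column.residues, include_gaps)
    if not freqs:
        return None
    h = -sum(p * log(p) for p in freqs.values() if p > 0.0)
    ent = 100.0 * h / _LN20
    return min(max(0.0, ent), 100.0)  # max(0.0, -0.0) -> +0.0


def column_kolmogorov(
    column: Column, level: int = 9, mode: str = "ratio"
) -> float:
    """Compression-based complexity of a column.

    The column's residue string (gaps included verbatim) is encoded one
    byte per symbol and compressed with bzip2 at *level*.  With
    ``mode="ratio"`` (default) returns compressed/raw byte count; with
    ``mode="raw-bytes"`` returns the compressed byte count.  Container
    overhead makes the ratio exceed 1 for short or incompressible
    inputs; no clipping is applied.
    """
    if not column.residues:
        raise ValueError("cannot compress an empty column")
    raw = column.residues.encode("ascii")
    compressed_size = len(bz2.compress(raw, compresslevel=level))
    if mode == "raw-bytes":
        return float(compressed_size)
    if mode == "ratio":
        return compressed_size / len(raw)
    raise ValueError(f"unknown mode {mode!r}")


def complexity_track(
    msa: Msa,
    min_freq: float = 0.01,
    include_gaps: bool = False,
    level: int = 9,
) -> list[ComplexityRecord]:
    """Score every column of *msa*; one record per position.

    All-gap positions are flagged ``"all-gap"`` (var/ent undefined),
    never dropped, so downstream tracks stay aligned to the MSA.
    """
    records = []
    for column in iter_columns(msa):
        var = column_variability(column, min_freq=min_freq, include_gaps=include_gaps)
        ent = column_entropy(column, include_gaps=include_gaps)
        kol = column_kolmogorov(column, level=level)
        flag = FLAG_OK if ent is not None else FLAG_ALL_GAP
        records.append(
            ComplexityRecord(
                position=column.position, var=var, ent=ent, kol=kol, flag=flag
            )
        )
    return records


def write_complexity_tsv(
    records: Iterable[ComplexityRecord], path: str | Path
) -> None:
    """Write records as TSV: ``position var ent kol flag`` ('.' = undefined)."""
    with open(path, "w") as fh:
        fh.write("position\tvar\tent\tkol\tflag\n")
        for r in records:
            var = "." if r.var is None else f"{r.var:g}"
            ent = "." if r.ent is None else f"{r.ent:.6f}"
            fh.write(f"{r.position}\t{var}\t{ent}\t{r.kol:.6f}\t{r.flag}\n")


def read_complexity_tsv(path: str | Path) -> list[ComplexityRecord]:
    """Read a TSV written by :func:`write_complexity_tsv`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["position", "var", "ent", "kol"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            pos = int(fields[0])
            var = None if fields[1] == "." else float(fields[1])
            ent = None if fields[2] == "." else float(fields[2])
            kol = float(fields[3])
            flag = fields[4] if len(fields) > 4 else FLAG_OK
            records.append(
                ComplexityRecord(position=pos, var=var, ent=ent, kol=kol, flag=flag)
            )
    return records
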